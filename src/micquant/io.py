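"""Reading and writing the pipeline's on-disk formats.

Everything tabular is tab-separated text with '#'-prefixed header comment
lines carrying the tool version and a config fingerprint; nested results
are JSON. Count tables are one file per sample (otu_id + one integer
column per replicate, calibrator row id "IC"); sample metadata, truth
tables and biomass series are single long-format TSVs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .config import (
    IC_OTU_ID,
    CalibrationConfig,
    PipelineConfig,
    SimulationConfig,
)
from .containers import BiomassSeries, OTUCountTable, SimulationTruth

FLOAT_FMT = "%.12g"


def _header(config_hash: Optional[str] = None) -> str:
    line = f"# micquant v{__version__}"
    if config_hash:
        line += f" config={config_hash}"
    return line + "\n"


def write_tsv(
    df: pd.DataFrame,
    path: Path,
    *,
    index: bool = True,
    config_hash: Optional[str] = None,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(config_hash))
        df.to_csv(fh, sep="\t", index=index, float_format=FLOAT_FMT)


def read_tsv(path: Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# --- count tables ---------------------------------------------------------


def write_count_table(
    table: OTUCountTable, path: Path, config_hash: Optional[str] = None
) -> None:
    write_tsv(table.counts, path, config_hash=config_hash)


def read_count_table(
    path: Path,
    sample_id: Optional[str] = None,
    sample_type: str = "sample",
    location: Optional[str] = None,
    month: Optional[int] = None,
    ic_otu_id: str = IC_OTU_ID,
) -> OTUCountTable:
    """Parse and validate one count table.

    Distinct diagnostics for a missing calibrator row, negative or
    non-integer counts, and duplicate OTU ids (raised by the container's
    own validation); the otu_id column itself is checked here.
    """
    path = Path(path)
    df = read_tsv(path)
    if "otu_id" not in df.columns:
        raise ValueError(f"{path.name}: first column must be 'otu_id'")
    df = df.set_index("otu_id")
    if df.shape[1] < 1:
        raise ValueError(f"{path.name}: no replicate columns found")
    return OTUCountTable(
        sample_id=sample_id or path.stem,
        counts=df,
        sample_type=sample_type,
        location=location,
        month=month,
        ic_otu_id=ic_otu_id,
    )


# --- sample metadata ------------------------------------------------------

METADATA_COLUMNS = ["sample_id", "location", "month", "type", "temperature"]


def write_metadata(meta: pd.DataFrame, path: Path, config_hash=None) -> None:
    write_tsv(meta[METADATA_COLUMNS], path, index=False, config_hash=config_hash)


def read_metadata(path: Path) -> pd.DataFrame:
    meta = read_tsv(path)
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns {sorted(missing)}")
    return meta.set_index("sample_id")


def campaign_metadata(truth: SimulationTruth) -> pd.DataFrame:
    """Sample metadata table (samples + monthly NECs) for a simulated campaign."""
    rows = []
    for month in truth.months:
        for loc in truth.locations:
            rows.append(
                {
                    "sample_id": f"{loc}-M{month}",
                    "location": loc,
                    "month": month,
                    "type": "sample",
                    "temperature": float(truth.temperature.at[loc, month]),
                }
            )
        rows.append(
            {
                "sample_id": f"NEC-M{month}",
                "location": "",
                "month": month,
                "type": "nec",
                "temperature": "",
            }
        )
    return pd.DataFrame(rows, columns=METADATA_COLUMNS)


def attach_metadata(
    tables: Sequence[OTUCountTable], meta: pd.DataFrame
) -> list[OTUCountTable]:
    """Fill each table's type/location/month from the metadata table."""
    out = []
    for t in tables:
        if t.sample_id not in meta.index:
            raise ValueError(f"sample {t.sample_id} absent from metadata")
        row = meta.loc[t.sample_id]
        t.sample_type = str(row["type"])
        loc = row["location"]
        t.location = None if pd.isna(loc) or loc == "" else str(loc)
        t.month = int(row["month"])
        out.append(t)
    return out


# --- truth ----------------------------------------------------------------


def write_truth(truth: SimulationTruth, outdir: Path, config_hash=None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    long = (
        truth.true_copies.stack(["location", "month"], future_stack=True)
        .rename("copies_per_100ul")
        .reset_index()
    )
    write_tsv(long, outdir / "true_copies.tsv", index=False, config_hash=config_hash)
    write_tsv(
        truth.contamination_copies.rename("copies_per_100ul").to_frame(),
        outdir / "contamination.tsv",
        config_hash=config_hash,
    )
    write_tsv(truth.temperature, outdir / "temperature.tsv", config_hash=config_hash)
    with open(outdir / "truth_meta.json", "w") as fh:
        json.dump(
            {
                "front_otus": truth.front_otus,
                "back_otus": truth.back_otus,
                "anomaly_otus": truth.anomaly_otus,
                "seed": truth.seed,
            },
            fh,
            indent=2,
        )


def read_truth(outdir: Path) -> SimulationTruth:
    outdir = Path(outdir)
    long = read_tsv(outdir / "true_copies.tsv")
    wide = long.pivot_table(
        index="otu_id", columns=["location", "month"], values="copies_per_100ul"
    )
    cont = read_tsv(outdir / "contamination.tsv").set_index("otu_id")[
        "copies_per_100ul"
    ]
    temp = read_tsv(outdir / "temperature.tsv").set_index("location")
    temp.columns = temp.columns.astype(int)
    meta = json.loads((outdir / "truth_meta.json").read_text())
    return SimulationTruth(
        true_copies=wide,
        contamination_copies=cont,
        temperature=temp,
        front_otus=meta["front_otus"],
        back_otus=meta["back_otus"],
        anomaly_otus=meta["anomaly_otus"],
        seed=meta["seed"],
    )


# --- profiles -------------------------------------------------------------


def write_profile(profile, outdir: Path, config_hash=None) -> None:
    from .containers import AbsoluteProfile  # noqa: F401  (type reference)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "copies_per_100ul": profile.copies,
            "n_replicates_detected": profile.n_replicates_detected,
        }
    )
    df.index.name = "otu_id"
    write_tsv(df, outdir / f"{profile.sample_id}.profile.tsv", config_hash=config_hash)
    sidecar = {
        "sample_id": profile.sample_id,
        "lod": profile.lod,
        "n_valid_replicates": profile.n_valid_replicates,
        "location": profile.location,
        "month": profile.month,
    }
    with open(outdir / f"{profile.sample_id}.profile.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_profile(tsv_path: Path):
    from .containers import AbsoluteProfile

    tsv_path = Path(tsv_path)
    df = read_tsv(tsv_path).set_index("otu_id")
    sidecar_path = tsv_path.with_name(tsv_path.name[: -len(".tsv")] + ".json")
    sidecar = json.loads(sidecar_path.read_text())
    return AbsoluteProfile(
        sample_id=sidecar["sample_id"],
        copies=df["copies_per_100ul"],
        n_replicates_detected=df["n_replicates_detected"].astype(int),
        lod=sidecar["lod"],
        n_valid_replicates=sidecar["n_valid_replicates"],
        location=sidecar["location"],
        month=sidecar["month"],
    )


# --- biomass series -------------------------------------------------------


def write_series(series: BiomassSeries, path: Path, config_hash=None) -> None:
    write_tsv(series.data, path, index=False, config_hash=config_hash)


def read_series(path: Path) -> BiomassSeries:
    return BiomassSeries(read_tsv(path))


# --- configs --------------------------------------------------------------

_CONFIG_TYPES = {
    "simulation": SimulationConfig,
    "calibration": CalibrationConfig,
    "pipeline": PipelineConfig,
}


def write_config(config, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = config.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
    else:
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_config_file(path: Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text) or {}
    return json.loads(text)
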