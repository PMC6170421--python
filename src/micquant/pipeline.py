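"""End-to-end orchestration: counts -> profiles -> dynamics -> concordance.

One NEC set is expected per month (one blank per extraction batch, batch =
month); each month's samples are decontaminated against their own month's
NEC. The run is fully deterministic given its inputs and configuration,
and every output table carries the tool version and a config fingerprint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .concordance import FoldDifference, fold_difference, trend_agreement
from .config import PipelineConfig, config_hash
from .containers import AbsoluteProfile, BiomassSeries, OTUCountTable
from .dynamics import DynamicsResult, analyze_dynamics, profiles_to_matrix
from .quantify import (
    NECProfile,
    UnquantifiableSampleError,
    nec_profile,
    quantify_sample,
    total_biomass,
)
from . import io as mio

MYC_METHOD = "myc_16s"


@dataclass
class ReportBundle:
    """Everything one pipeline run produces, in memory."""

    profiles: list[AbsoluteProfile]
    dynamics: DynamicsResult
    concordance: dict[str, dict]
    totals: pd.Series                  # per-sample total copies/100 uL
    flags: list[str] = field(default_factory=list)
    run_log: dict = field(default_factory=dict)


def quantify_campaign(
    tables: Sequence[OTUCountTable], config: PipelineConfig
) -> tuple[list[AbsoluteProfile], list[str]]:
    """Quantify every sample against its month's NEC. Returns (profiles, flags)."""
    necs: dict[int, list[OTUCountTable]] = {}
    samples: list[OTUCountTable] = []
    for t in tables:
        if t.sample_type == "nec":
            necs.setdefault(int(t.month), []).append(t)
        else:
            samples.append(t)
    if not samples:
        raise ValueError("no sample tables provided")
    if not necs:
        raise ValueError(
            "no NEC tables provided: decontamination requires at least one "
            "negative extraction control per month (sample type 'nec')"
        )
    nec_by_month: dict[int, NECProfile] = {}
    for month, month_necs in necs.items():
        nec_by_month[month] = nec_profile(month_necs, config.calibration)
    profiles, flags = [], []
    for t in samples:
        month = int(t.month)
        if month not in nec_by_month:
            raise ValueError(
                f"sample {t.sample_id}: no NEC available for month {month}; "
                "provide one NEC set per extraction batch"
            )
        try:
            profiles.append(
                quantify_sample(
                    t,
                    nec_by_month[month],
                    config.calibration,
                    consensus_min_replicates=config.consensus_min_replicates,
                    statistic=config.merge_statistic,
                    nec_margin_z=config.nec_margin_z,
                )
            )
        except UnquantifiableSampleError as err:
            flags.append(f"{t.sample_id}: unquantifiable ({err})")
    if not profiles:
        raise UnquantifiableSampleError("no sample could be quantified")
    return profiles, flags


def run_pipeline(
    tables: Sequence[OTUCountTable],
    config: PipelineConfig,
    series: Optional[BiomassSeries] = None,
    outdir: Optional[Path] = None,
) -> ReportBundle:
    """Quantify, analyse dynamics, and (optionally) score method concordance.

    ``series`` may carry external biomass methods (fcm_intact, qpcr_16s,
    hpc, batp, ...); each is compared against the pipeline's own total-16S
    series. Culture/ATP series (hpc, batp) are ingested and written but get
    no concordance statistic. If ``outdir`` is given, all tables plus a
    run log are written there (deterministically: same inputs + config =
    byte-identical files).
    """
    profiles, flags = quantify_campaign(tables, config)
    dyn = analyze_dynamics(
        profiles,
        dominance_threshold=config.dominance_threshold,
        fold_threshold=config.fold_threshold,
        anomaly_fraction_threshold=config.anomaly_fraction_threshold,
        trend_pooling=config.trend_pooling,
    )
    totals = pd.Series(
        {p.sample_id: total_biomass(p) for p in profiles}, name=MYC_METHOD
    )
    _, meta, _ = profiles_to_matrix(profiles)

    conc: dict[str, dict] = {}
    if series is not None:
        for method in series.methods:
            if method in ("hpc", "batp", MYC_METHOD):
                continue
            other = series.series(method)
            try:
                fd = fold_difference(other, totals)
            except ValueError as err:
                flags.append(f"concordance {method}: {err}")
                continue
            ta = trend_agreement(other, totals, meta)
            conc[method] = {
                "fold": fd,
                "trend": ta,
            }

    chash = config_hash(config)
    run_log = {
        "tool": "micquant",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": chash,
        "n_samples": len(profiles),
        "n_flags": len(flags),
        "flags": flags,
    }
    bundle = ReportBundle(
        profiles=profiles,
        dynamics=dyn,
        concordance=conc,
        totals=totals,
        flags=flags,
        run_log=run_log,
    )
    if outdir is not None:
        write_report(bundle, Path(outdir), chash)
    return bundle


def write_report(bundle: ReportBundle, outdir: Path, chash: str) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for p in bundle.profiles:
        mio.write_profile(p, outdir / "profiles", config_hash=chash)
    dyn = bundle.dynamics
    ddir = outdir / "dynamics"
    mio.write_tsv(dyn.location_medians, ddir / "location_medians.tsv", config_hash=chash)
    mio.write_tsv(
        dyn.relative_abundance, ddir / "relative_abundance.tsv", config_hash=chash
    )
    mio.write_tsv(dyn.dominant, ddir / "dominant.tsv", config_hash=chash)
    mio.write_tsv(
        dyn.fold_changes, ddir / "fold_changes.tsv", index=False, config_hash=chash
    )
    mio.write_tsv(dyn.trends, ddir / "trends.tsv", config_hash=chash)
    mio.write_tsv(dyn.anomalies, ddir / "anomalies.tsv", index=False, config_hash=chash)
    mio.write_tsv(
        bundle.totals.rename_axis("sample_id").to_frame(),
        outdir / "total_biomass.tsv",
        config_hash=chash,
    )
    summary: dict = {
        "dominant_otus": dyn.dominant_otus,
        "pseudo_floor": dyn.pseudo_floor,
        "anomalies": dyn.anomalies.to_dict(orient="records"),
        "concordance": {},
    }
    for method, res in bundle.concordance.items():
        fd: FoldDifference = res["fold"]
        mio.write_tsv(
            res["trend"],
            outdir / "concordance" / f"{method}_trend.tsv",
            index=False,
            config_hash=chash,
        )
        summary["concordance"][method] = {
            "mean_fold": fd.mean_fold,
            "sd_fold": fd.sd_fold,
            "n": fd.n,
            "fraction_method_higher": fd.fraction_a_higher,
            "n_dropped": fd.n_dropped,
        }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(bundle.run_log, fh, indent=2, sort_keys=True)
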