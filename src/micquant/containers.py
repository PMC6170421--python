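"""In-memory containers shared across the pipeline stages.

Tabular payloads are pandas objects; the dataclasses around them carry the
identifiers and flags the stages need to talk to each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import IC_OTU_ID


@dataclass
class OTUCountTable:
    """Replicate-level read counts for one sample (or one NEC).

    ``counts`` is indexed by otu_id (the calibrator row included) with one
    integer column per sequencing replicate.
    """

    sample_id: str
    counts: pd.DataFrame
    sample_type: str = "sample"  # "sample" | "nec"
    location: Optional[str] = None
    month: Optional[int] = None
    ic_otu_id: str = IC_OTU_ID

    def __post_init__(self) -> None:
        if self.sample_type not in ("sample", "nec"):
            raise ValueError("sample_type must be 'sample' or 'nec'")
        if self.counts.shape[1] < 1:
            raise ValueError("at least one replicate column required")
        if self.ic_otu_id not in self.counts.index:
            raise ValueError(
                f"{self.sample_id}: calibrator row '{self.ic_otu_id}' missing"
            )
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"{self.sample_id}: duplicate OTU ids {dups}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError(f"{self.sample_id}: counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError(f"{self.sample_id}: negative counts")

    @property
    def n_replicates(self) -> int:
        return self.counts.shape[1]

    @property
    def otu_ids(self) -> pd.Index:
        """All non-calibrator OTU ids."""
        return self.counts.index[self.counts.index != self.ic_otu_id]


@dataclass
class AbsoluteProfile:
    """Decontaminated absolute abundances for one sample.

    ``copies`` holds 16S gene copies/100 uL per OTU (calibrator excluded);
    ``n_replicates_detected`` counts replicates with nonzero
    post-subtraction signal; ``lod`` is the copies-equivalent of a single
    read at the weakest replicate's calibrator depth.
    """

    sample_id: str
    copies: pd.Series
    n_replicates_detected: pd.Series
    lod: float
    n_valid_replicates: int
    location: Optional[str] = None
    month: Optional[int] = None

    def __post_init__(self) -> None:
        if IC_OTU_ID in self.copies.index:
            raise ValueError("calibrator must not appear in an AbsoluteProfile")
        if (self.copies < 0).any():
            raise ValueError("copies must be >= 0")
        if not self.lod > 0:
            raise ValueError("lod must be > 0")


@dataclass
class SimulationTruth:
    """Ground truth emitted by the simulator.

    ``true_copies``: DataFrame indexed by otu_id with MultiIndex columns
    (location, month), in copies/100 uL; contaminant OTUs are present with
    0 copies in water. ``contamination_copies``: per-OTU copy load added to
    every extract, NECs included. ``temperature``: per (location, month) degC.
    """

    true_copies: pd.DataFrame
    contamination_copies: pd.Series
    temperature: pd.DataFrame  # index location, columns month
    front_otus: list[str]
    back_otus: list[str]
    anomaly_otus: list[str]
    seed: int

    @property
    def locations(self) -> list[str]:
        return list(self.true_copies.columns.levels[0])

    @property
    def months(self) -> list[int]:
        return list(self.true_copies.columns.levels[1])

    def total_copies(self) -> pd.Series:
        """True total water-community copies per (location, month) sample."""
        return self.true_copies.sum(axis=0)


@dataclass
class BiomassSeries:
    """Long-format per-sample biomass measurements from one or more methods.

    ``data`` columns: sample_id, method, value. Methods use their native
    units (copies/100 uL, cells/mL, ...); concordance statistics are
    unit-free ratios so no conversion is attempted.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "method", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"BiomassSeries missing columns {sorted(missing)}")
        if (self.data["value"] < 0).any():
            raise ValueError("biomass values must be >= 0")
        if self.data.duplicated(["sample_id", "method"]).any():
            raise ValueError("one value per (sample, method) required")

    def series(self, method: str) -> pd.Series:
        sub = self.data[self.data["method"] == method]
        return sub.set_index("sample_id")["value"]

    @property
    def methods(self) -> list[str]:
        return sorted(self.data["method"].unique())
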