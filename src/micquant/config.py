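"""Configuration objects for simulation, calibration and pipeline runs.

All configs are plain dataclasses that validate on construction, round-trip
through dicts (and hence JSON/YAML), and hash canonically so that every
output table can carry a short fingerprint of the parameters that made it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

IC_OTU_ID = "IC"

LOCATION_LABELS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def location_labels(n: int) -> list[str]:
    """Ordinal labels for consecutive sampling locations (A = plant effluent)."""
    if n < 1 or n > len(LOCATION_LABELS):
        raise ValueError(f"n_locations must be in [1, {len(LOCATION_LABELS)}]")
    return list(LOCATION_LABELS[:n])


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic drinking-water monitoring campaign.

    The defaults describe a six-location, five-month campaign sampled in
    triplicate: a 143-OTU water community in which three OTUs dominate the
    head of the system and three the tail, a disinfection kill-off between
    locations A and B, regrowth between B and C, stability from C onward,
    one anomalous warm month in which ~30% of OTUs surge at location B, a
    handful of reagent-contamination OTUs present in every extract, and a
    known quantity of internal-calibrator (IC) DNA spiked into each
    replicate before sequencing.
    """

    n_locations: int = 6
    n_months: int = 5
    n_replicates: int = 3
    n_otus: int = 143            # water-community OTUs (calibrator and contaminants extra)
    n_dominant_front: int = 3
    n_dominant_back: int = 3
    total_copies_range: tuple[float, float] = (4e4, 1.2e5)  # copies/100 uL at location A
    killoff_factor: float = 8.0      # multiplicative A->B reduction (disinfection)
    regrowth_factor: float = 6.0     # multiplicative B->C recovery (residual lost)
    seasonal_amplitude: float = 0.3  # unitless monthly modulation; 0 disables seasonality
    anomaly_month: Optional[int] = 3  # 1-based month index; None disables the anomaly
    anomaly_fraction: float = 0.30
    anomaly_spike_fold: float = 138.0  # B/A surge of the single most affected OTU
    contamination_otus: int = 5
    contamination_level: float = 200.0  # copies/100 uL per contaminant OTU, every extract
    ic_copies: float = 1e4           # calibrator 16S copies spiked per reaction
    read_depth: int = 15_000         # reads per sequencing replicate
    others_share_sigma: float = 6.0  # lognormal spread of the non-dominant OTU shares
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_locations", "n_months", "n_replicates", "n_otus"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_dominant_front < 0 or self.n_dominant_back < 0:
            raise ValueError("dominant OTU counts must be >= 0")
        if self.n_dominant_front + self.n_dominant_back > self.n_otus:
            raise ValueError("n_dominant_front + n_dominant_back exceeds n_otus")
        lo, hi = self.total_copies_range
        if not (0 < lo <= hi):
            raise ValueError("total_copies_range must be positive and ordered")
        if self.killoff_factor < 1:
            raise ValueError("killoff_factor must be >= 1")
        if self.regrowth_factor <= 0:
            raise ValueError("regrowth_factor must be > 0")
        if self.seasonal_amplitude < 0:
            raise ValueError("seasonal_amplitude must be >= 0")
        if not 0.0 <= self.anomaly_fraction <= 1.0:
            raise ValueError("anomaly_fraction must be in [0, 1]")
        if self.anomaly_month is not None and not (
            1 <= self.anomaly_month <= self.n_months
        ):
            raise ValueError("anomaly_month out of range")
        if self.contamination_otus < 0 or self.contamination_level < 0:
            raise ValueError("contamination settings must be >= 0")
        if self.ic_copies <= 0:
            raise ValueError("ic_copies must be > 0 (calibration impossible otherwise)")
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")

    @property
    def locations(self) -> list[str]:
        return location_labels(self.n_locations)

    @property
    def months(self) -> list[int]:
        return list(range(1, self.n_months + 1))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["total_copies_range"] = list(self.total_copies_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "total_copies_range" in d:
            d["total_copies_range"] = tuple(d["total_copies_range"])
        return cls(**d)


@dataclass(frozen=True)
class CalibrationConfig:
    """Conversion from calibrator-relative read counts to absolute copies.

    ``ic_copies`` is the number of calibrator 16S gene copies spiked into
    each reaction; ``volume_scale`` maps per-reaction copies onto
    copies/100 uL of source water (it bundles filtered volume, elution
    volume and template fraction, and defaults to 1 so per-reaction copies
    are reported directly).
    """

    ic_copies: float = 1e4
    volume_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.ic_copies <= 0:
            raise ValueError("ic_copies must be > 0")
        if self.volume_scale <= 0:
            raise ValueError("volume_scale must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationConfig":
        return cls(**d)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run settings: thresholds, rules and reproducibility seed."""

    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    dominance_threshold: float = 0.05   # strict > on median relative abundance
    fold_threshold: float = 2.0         # strict > (or < 1/threshold) on median fold
    anomaly_fraction_threshold: float = 0.30
    consensus_min_replicates: int = 2   # nonzero in >= this many replicates, 0 disables
    merge_statistic: str = "mean"       # or "median"
    nec_margin_z: float = 3.0           # Poisson clearance margin for NEC subtraction
    trend_pooling: str = "pooled"       # "pooled" (all months) or "per_month"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dominance_threshold <= 0 or self.fold_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.anomaly_fraction_threshold <= 1:
            raise ValueError("anomaly_fraction_threshold must be in (0, 1]")
        if self.consensus_min_replicates < 0:
            raise ValueError("consensus_min_replicates must be >= 0")
        if self.merge_statistic not in ("mean", "median"):
            raise ValueError("merge_statistic must be 'mean' or 'median'")
        if self.nec_margin_z < 0:
            raise ValueError("nec_margin_z must be >= 0")
        if self.trend_pooling not in ("pooled", "per_month"):
            raise ValueError("trend_pooling must be 'pooled' or 'per_month'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["calibration"] = self.calibration.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "calibration" in d and isinstance(d["calibration"], dict):
            d["calibration"] = CalibrationConfig.from_dict(d["calibration"])
        return cls(**d)


def config_hash(*configs) -> str:
    """Short stable fingerprint of one or more configs (for output headers)."""
    payload = json.dumps(
        [c.to_dict() if hasattr(c, "to_dict") else c for c in configs],
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
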