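"""Spatial and temporal dynamics of absolute OTU profiles.

Given decontaminated per-sample profiles (copies/100 uL), this module
reproduces the monitoring analyses: per-location medians over the campaign
months, the >5% median-relative-abundance dominance rule, consecutive-
location fold changes with the 2-fold significance rule (folds within
[1/2, 2] are attributed to technical variation), per-OTU Spearman trends
along the system, and detection of anomalous months in which a large
fraction of OTUs reverses the usual fold direction across one location
pair.

Zeros and ratios: medians of zero would make fold changes blow up, so both
median series get a shared pseudo-floor of half the smallest positive LOD
in the dataset before any ratio is formed. The floor is symmetric, which
keeps log2 fold changes antisymmetric under swapping the pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import AbsoluteProfile
from .stats import spearman_many


@dataclass
class DynamicsResult:
    """Bundle of every spatial/temporal statistic for one campaign."""

    location_medians: pd.DataFrame   # otu x location, copies/100 uL
    relative_abundance: pd.DataFrame  # otu x location, sums to 1 per location
    dominant: pd.DataFrame           # otu x location, bool (> threshold, strict)
    fold_changes: pd.DataFrame       # long: otu_id, pair, ratio, log2_ratio, significant
    trends: pd.DataFrame             # otu: rs, p_value, n, method
    anomalies: pd.DataFrame          # long: month, pair, n_otus_boosted, fraction
    pseudo_floor: float

    @property
    def dominant_otus(self) -> list[str]:
        """OTUs dominant (> threshold) at at least one location."""
        return self.dominant.index[self.dominant.any(axis=1)].tolist()


def profiles_to_matrix(
    profiles: Sequence[AbsoluteProfile],
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Stack profiles into (copies: otu x sample, metadata, min positive LOD)."""
    if not profiles:
        raise ValueError("no profiles given")
    copies = pd.DataFrame({p.sample_id: p.copies for p in profiles}).fillna(0.0)
    meta = pd.DataFrame(
        {
            "location": [p.location for p in profiles],
            "month": [p.month for p in profiles],
        },
        index=pd.Index([p.sample_id for p in profiles], name="sample_id"),
    )
    if meta["location"].isna().any() or meta["month"].isna().any():
        raise ValueError("profiles must carry location and month metadata")
    min_lod = min(p.lod for p in profiles)
    return copies, meta, min_lod


def location_medians(copies: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Median copies per OTU per location, taken across the sampled months.

    Missing samples are simply absent from the median; locations without a
    single sample are an error, never imputed.
    """
    locations = sorted(meta["location"].unique())
    out = {}
    for loc in locations:
        cols = meta.index[meta["location"] == loc]
        if len(cols) == 0:
            raise ValueError(f"location {loc} has no samples")
        out[loc] = copies[cols].median(axis=1)
    return pd.DataFrame(out)


def relative_abundance(medians: pd.DataFrame) -> pd.DataFrame:
    """Median copies as a fraction of each location's total median copies."""
    totals = medians.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = medians.div(totals.where(totals > 0), axis=1)
    return rel.fillna(0.0)


def classify_dominant(
    medians: pd.DataFrame, threshold: float = 0.05
) -> pd.DataFrame:
    """Dominance flags: median relative abundance strictly above ``threshold``.

    A location whose total median is zero has no dominant OTUs.
    """
    return relative_abundance(medians) > threshold


def consecutive_pairs(locations: Sequence[str]) -> list[tuple[str, str]]:
    return list(zip(locations[:-1], locations[1:]))


def consecutive_fold_changes(
    medians: pd.DataFrame,
    pseudo_floor: float,
    fold_threshold: float = 2.0,
) -> pd.DataFrame:
    """Downstream/upstream median fold per OTU for each consecutive pair.

    ``ratio = (median_down + f) / (median_up + f)`` with the shared
    pseudo-floor f; changes are significant only strictly beyond
    ``fold_threshold`` in either direction (ratio > 2 or < 0.5 at the
    default) — anything milder is within technical variation.
    """
    if pseudo_floor <= 0:
        raise ValueError("pseudo_floor must be > 0")
    rows = []
    for up, down in consecutive_pairs(list(medians.columns)):
        ratio = (medians[down] + pseudo_floor) / (medians[up] + pseudo_floor)
        log2r = np.log2(ratio)
        sig = (ratio > fold_threshold) | (ratio < 1.0 / fold_threshold)
        rows.append(
            pd.DataFrame(
                {
                    "otu_id": medians.index,
                    "pair": f"{up}->{down}",
                    "upstream": up,
                    "downstream": down,
                    "ratio": ratio.to_numpy(),
                    "log2_ratio": log2r.to_numpy(),
                    "significant": sig.to_numpy(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def spearman_trends(
    copies: pd.DataFrame,
    meta: pd.DataFrame,
    pooling: str = "pooled",
) -> pd.DataFrame:
    """Per-OTU Spearman trend of copies against location order.

    ``pooled`` uses every sample of every month (location as ordinal rank),
    the higher-power default; ``per_month`` computes one correlation per
    month and returns a (otu, month)-indexed table. Zero-variance series
    give nan (the correlation is undefined, never reported as 0).
    """
    locations = sorted(meta["location"].unique())
    loc_rank = {loc: i + 1 for i, loc in enumerate(locations)}
    if pooling == "pooled":
        x = meta["location"].map(loc_rank).to_numpy(dtype=float)
        rs, p = spearman_many(copies[meta.index].to_numpy(), x)
        return pd.DataFrame(
            {"rs": rs, "p_value": p, "n": len(x), "method": _method_label(len(x))},
            index=copies.index,
        )
    if pooling != "per_month":
        raise ValueError("pooling must be 'pooled' or 'per_month'")
    frames = []
    for month in sorted(meta["month"].unique()):
        sub = meta[meta["month"] == month]
        x = sub["location"].map(loc_rank).to_numpy(dtype=float)
        rs, p = spearman_many(copies[sub.index].to_numpy(), x)
        frames.append(
            pd.DataFrame(
                {
                    "month": month,
                    "rs": rs,
                    "p_value": p,
                    "n": len(x),
                    "method": _method_label(len(x)),
                },
                index=copies.index,
            )
        )
    out = pd.concat(frames)
    out.index.name = "otu_id"
    return out.set_index("month", append=True)


def _method_label(n: int) -> str:
    from .stats import EXACT_MAX_N

    return "exact" if n <= EXACT_MAX_N else "t-approx"


def detect_anomalies(
    copies: pd.DataFrame,
    meta: pd.DataFrame,
    pseudo_floor: float,
    fold_threshold: float = 2.0,
    fraction_threshold: float = 0.30,
) -> pd.DataFrame:
    """Months in which many OTUs reverse a pair's usual fold direction.

    For every month and consecutive location pair, count the detected OTUs
    whose per-month fold is at least ``fold_threshold``. The reference set
    is the OTUs detected at the downstream location that month: an OTU
    that increased >= 2-fold is by definition present downstream, so this
    is the population the boosted count is a fraction of. The (month,
    pair) is flagged anomalous when that count reaches
    ``fraction_threshold`` of the detected OTUs while the pair's
    cross-month median fold is below 1 — i.e. a mass increase across a
    step that normally shows a decrease, the September pattern.

    Returns the flagged rows only (empty DataFrame when nothing is
    anomalous), with the counts backing each flag.
    """
    if pseudo_floor <= 0:
        raise ValueError("pseudo_floor must be > 0")
    locations = sorted(meta["location"].unique())
    months = sorted(meta["month"].unique())
    pairs = consecutive_pairs(locations)

    def sample_of(loc: str, month) -> Optional[str]:
        hit = meta.index[(meta["location"] == loc) & (meta["month"] == month)]
        return hit[0] if len(hit) else None

    rows = []
    for up, down in pairs:
        per_month_folds = {}
        for month in months:
            s_up, s_down = sample_of(up, month), sample_of(down, month)
            if s_up is None or s_down is None:
                continue
            u, d = copies[s_up], copies[s_down]
            detected = d > 0
            folds = (d + pseudo_floor) / (u + pseudo_floor)
            per_month_folds[month] = (folds, detected)
        if not per_month_folds:
            continue
        typical = np.median(
            [np.median(f[d]) for f, d in per_month_folds.values() if d.any()]
        )
        for month, (folds, detected) in per_month_folds.items():
            n_det = int(detected.sum())
            if n_det == 0:
                continue
            boosted = int((folds[detected] >= fold_threshold).sum())
            fraction = boosted / n_det
            if fraction >= fraction_threshold and typical < 1.0:
                rows.append(
                    {
                        "month": month,
                        "pair": f"{up}->{down}",
                        "n_otus_boosted": boosted,
                        "n_otus_detected": n_det,
                        "fraction": fraction,
                        "typical_fold": float(typical),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "month",
            "pair",
            "n_otus_boosted",
            "n_otus_detected",
            "fraction",
            "typical_fold",
        ],
    )


def heatmap_table(
    copies: pd.DataFrame,
    meta: pd.DataFrame,
    otu_subset: Sequence[str],
    temperature: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Long-format (month, location, otu, copies[, temperature]) table.

    Exact copies values ready for heatmap plotting; unknown OTU ids are an
    error. ``temperature`` is an optional location x month table.
    """
    unknown = [o for o in otu_subset if o not in copies.index]
    if unknown:
        raise KeyError(f"unknown OTU id(s): {unknown}")
    rows = []
    for sample_id, row in meta.iterrows():
        loc, month = row["location"], row["month"]
        for otu in otu_subset:
            rec = {
                "month": month,
                "location": loc,
                "otu_id": otu,
                "copies": float(copies.at[otu, sample_id]),
            }
            if temperature is not None:
                rec["temperature"] = float(temperature.at[loc, month])
            rows.append(rec)
    return pd.DataFrame(rows)


def analyze_dynamics(
    profiles: Sequence[AbsoluteProfile],
    *,
    dominance_threshold: float = 0.05,
    fold_threshold: float = 2.0,
    anomaly_fraction_threshold: float = 0.30,
    trend_pooling: str = "pooled",
) -> DynamicsResult:
    """Run every dynamics analysis on a set of sample profiles."""
    copies, meta, min_lod = profiles_to_matrix(profiles)
    floor = min_lod / 2.0
    medians = location_medians(copies, meta)
    rel = relative_abundance(medians)
    dom = classify_dominant(medians, dominance_threshold)
    folds = consecutive_fold_changes(medians, floor, fold_threshold)
    trends = spearman_trends(copies, meta, trend_pooling)
    anomalies = detect_anomalies(
        copies, meta, floor, fold_threshold, anomaly_fraction_threshold
    )
    return DynamicsResult(
        location_medians=medians,
        relative_abundance=rel,
        dominant=dom,
        fold_changes=folds,
        trends=trends,
        anomalies=anomalies,
        pseudo_floor=floor,
    )
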