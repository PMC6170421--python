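"""Cross-method biomass concordance.

Different biomass proxies (sequencing-derived total 16S copies,
flow-cytometry intact cells, qPCR 16S copies) live in different units and
carry systematic offsets, so agreement is summarised in two unit-free
ways: the per-sample fold difference — the >= 1-oriented ratio
max(a, b)/min(a, b), summarised by mean +/- SD and by the fraction of
samples where one method reads higher — and the per-month Spearman
correlation of the two series across the locations, which captures whether
the methods see the same spatial dynamics regardless of offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import spearman


@dataclass(frozen=True)
class FoldDifference:
    mean_fold: float       # mean of max/min ratios, always >= 1
    sd_fold: float         # sample SD (ddof=1) of the ratios
    n: int                 # pairs actually compared
    fraction_a_higher: float
    n_dropped: int         # pairs lost to zero or missing values


def fold_difference(series_a: pd.Series, series_b: pd.Series) -> FoldDifference:
    """Mean +/- SD of the >=1-oriented per-sample fold between two series.

    Series are paired on their index (sample_id); pairs with a missing or
    non-positive value on either side are dropped and counted. Requires at
    least 2 usable pairs.
    """
    paired = pd.DataFrame({"a": series_a, "b": series_b})
    usable = paired.dropna()
    usable = usable[(usable["a"] > 0) & (usable["b"] > 0)]
    n_dropped = len(paired) - len(usable)
    if len(usable) < 2:
        raise ValueError(f"need >= 2 usable pairs, got {len(usable)}")
    a, b = usable["a"].to_numpy(), usable["b"].to_numpy()
    folds = np.maximum(a, b) / np.minimum(a, b)
    return FoldDifference(
        mean_fold=float(folds.mean()),
        sd_fold=float(folds.std(ddof=1)),
        n=len(folds),
        fraction_a_higher=float((a > b).mean()),
        n_dropped=n_dropped,
    )


def trend_agreement(
    series_a: pd.Series,
    series_b: pd.Series,
    meta: pd.DataFrame,
    min_locations: int = 3,
) -> pd.DataFrame:
    """Per-month Spearman correlation of two series across the locations.

    ``meta`` (indexed by sample_id) supplies location and month. Months
    with fewer than ``min_locations`` paired locations are skipped. The
    last row, month "median", carries the median R_s across months.
    """
    paired = pd.DataFrame({"a": series_a, "b": series_b}).dropna()
    rows = []
    for month in sorted(meta["month"].unique()):
        ids = meta.index[meta["month"] == month].intersection(paired.index)
        if len(ids) < min_locations:
            continue
        sub = paired.loc[ids]
        res = spearman(sub["a"].to_numpy(), sub["b"].to_numpy())
        rows.append(
            {"month": month, "rs": res.rs, "p_value": res.p_value, "n": res.n}
        )
    out = pd.DataFrame(rows, columns=["month", "rs", "p_value", "n"])
    if len(out):
        out.loc[len(out)] = {
            "month": "median",
            "rs": float(np.nanmedian(out["rs"].astype(float))),
            "p_value": np.nan,
            "n": int(out["n"].sum()),
        }
    return out
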