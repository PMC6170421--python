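"""Spearman rank correlation with exact small-sample p-values.

The trend statistic used throughout the dynamics and concordance analyses
is Spearman's R_s with mid-ranks for ties. Two-sided significance is exact
for n <= 9 — the permutation null is enumerated completely (n! rank
orderings) — and uses the usual t approximation with n - 2 degrees of
freedom above that, which is also what mainstream statistics packages do
at these sample sizes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

EXACT_MAX_N = 9
_ATOL = 1e-12


@dataclass(frozen=True)
class SpearmanResult:
    rs: float          # rank correlation in [-1, 1]; nan if undefined
    p_value: float     # two-sided; nan if rs undefined
    n: int
    method: str        # "exact" | "t-approx" | "undefined"

    @property
    def defined(self) -> bool:
        return not math.isnan(self.rs)


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))
    return float(xc @ yc / denom)


def _exact_p(rx: np.ndarray, ry: np.ndarray, r_obs: float) -> float:
    """Two-sided permutation p: enumerate every ordering of the y-ranks."""
    n = len(rx)
    perms = np.array(list(itertools.permutations(ry)))
    xc = rx - rx.mean()
    yc = perms - perms.mean(axis=1, keepdims=True)
    num = yc @ xc
    denom = np.sqrt((xc @ xc) * (yc * yc).sum(axis=1))
    r_all = num / denom
    hits = np.count_nonzero(np.abs(r_all) >= abs(r_obs) - _ATOL)
    return hits / len(perms)


def spearman(
    x: np.ndarray, y: np.ndarray, *, exact_max_n: int = EXACT_MAX_N
) -> SpearmanResult:
    """Spearman correlation of two paired series.

    A zero-variance series makes the correlation undefined; it is reported
    as nan (never silently as 0). Requires n >= 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(math.nan, math.nan, n, "undefined")
    rx, ry = _midranks(x), _midranks(y)
    rs = _pearson(rx, ry)
    if n <= exact_max_n:
        return SpearmanResult(rs, _exact_p(rx, ry, rs), n, "exact")
    return SpearmanResult(rs, _t_sf(rs, n), n, "t-approx")


def _t_sf(rs: float, n: int) -> float:
    if abs(rs) >= 1.0:
        return 0.0
    t = rs * math.sqrt((n - 2) / (1.0 - rs * rs))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman_many(
    ys: np.ndarray, x: np.ndarray, *, exact_max_n: int = EXACT_MAX_N
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Spearman of many series (rows of ``ys``) against one ``x``.

    Returns (rs, p) arrays; undefined correlations are nan. Rows fall back
    to the scalar routine only when n is small enough for the exact null.
    """
    ys = np.asarray(ys, dtype=float)
    x = np.asarray(x, dtype=float)
    n = ys.shape[1]
    if n != len(x):
        raise ValueError("row length of ys must match len(x)")
    if n <= exact_max_n:
        out = [spearman(x, row, exact_max_n=exact_max_n) for row in ys]
        return (
            np.array([r.rs for r in out]),
            np.array([r.p_value for r in out]),
        )
    rx = _midranks(x)
    ry = np.apply_along_axis(_midranks, 1, ys)
    xc = rx - rx.mean()
    yc = ry - ry.mean(axis=1, keepdims=True)
    sy = (yc * yc).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rs = (yc @ xc) / np.sqrt((xc @ xc) * sy)
    rs[np.ptp(ys, axis=1) == 0] = np.nan
    rs = np.clip(rs, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rs * np.sqrt((n - 2) / (1.0 - rs * rs))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rs) >= 1.0] = 0.0
    p[np.isnan(rs)] = np.nan
    return rs, p
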