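"""Synthetic drinking-water monitoring campaigns with known ground truth.

The generator emulates the structure of a full-scale, non-chlorinated
distribution system sampled monthly at consecutive locations:

* a diverse water community (~143 OTUs) in which a handful of OTUs dominate,
  front-dominant ones at the head of the system and back-dominant ones at
  the tail;
* a disinfection kill-off between locations A and B (chlorine dioxide dosed
  upstream of A, residual decaying through the first transport section);
* regrowth between B and C once the residual is gone, for the back-dominant
  OTUs and most of the rare flora, but not for the front-dominant OTUs;
* stability from C to the tap (expected copies constant C onward);
* a cosine seasonal covariate (water temperature peaking in the warmest
  month) that modulates total biomass and weakens the spatial trends in
  colder months;
* one optional anomalous month in which a configurable fraction of OTUs
  surges at location B by at least 2-fold relative to A — one designated
  OTU by a much larger factor — mimicking an early-regrowth event after
  accelerated disinfectant decay;
* reagent contamination: a few OTUs present at a fixed copy load in every
  extract, negative extraction controls (NECs) included, and absent from
  the water itself.

Sequencing is modeled at the template level: each replicate's reads are one
multinomial draw over the template molecules present in the reaction — the
sample's (or NEC's) 16S copies, the contamination load, and the spiked
internal calibrator. Clonal (micelle) amplification motivates the absence
of any amplification-bias term.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd

from .config import IC_OTU_ID, SimulationConfig
from .containers import BiomassSeries, OTUCountTable, SimulationTruth

# Relative-abundance pattern of the engineered dominant OTUs at their
# favoured end of the system (head for front-dominant, tail for back-dominant
# after regrowth). Extended geometrically if more dominants are requested.
_FRONT_SHARES = (0.23, 0.09, 0.07)
_BACK_SHARES = (0.045, 0.032, 0.022)
_OTHERS_SHARE_CAP = 0.018  # rare OTUs stay below dominance even after relative enrichment

_TRUTH_STREAM, _READS_STREAM, _SERIES_STREAM = 11, 22, 33


def _dominant_shares(base: tuple[float, ...], n: int) -> np.ndarray:
    shares = list(base[:n])
    while len(shares) < n:
        shares.append(shares[-1] * 0.6)
    return np.asarray(shares)


def _otu_ids(n: int, prefix: str = "OTU") -> list[str]:
    width = max(3, len(str(n)))
    return [f"{prefix}_{i + 1:0{width}d}" for i in range(n)]


def seasonal_temperature(months: list[int], peak_month: int = 3) -> np.ndarray:
    """Water temperature (degC) per campaign month, cosine-shaped.

    Month 1 maps to July; the default peak (month 3 = September) matches a
    surface-water system whose temperature lags air temperature.
    """
    cal = 6 + np.asarray(months, dtype=float)  # July = 7, ...
    peak_cal = 6 + peak_month
    return 13.0 + 7.0 * np.cos(2 * np.pi * (cal - peak_cal) / 12.0)


def simulate_truth(config: SimulationConfig) -> SimulationTruth:
    """Draw ground-truth absolute abundances for one monitoring campaign.

    Returns per-OTU expected 16S copies/100 uL for every (location, month),
    the contamination profile shared by all extracts, and the per-month
    temperature covariate. All structure described in the module docstring
    is guaranteed in expectation (and, for the anomaly count, exactly).
    """
    if config.n_dominant_front + config.n_dominant_back > config.n_otus:
        raise ValueError("more dominant OTUs requested than OTUs simulated")
    if config.anomaly_month is not None and config.anomaly_spike_fold < 2:
        raise ValueError("anomaly_spike_fold must be >= 2 (it is part of the boost set)")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _TRUTH_STREAM]))
    n = config.n_otus
    n_front, n_back = config.n_dominant_front, config.n_dominant_back
    otus = _otu_ids(n)
    front = otus[:n_front]
    back = otus[n_front : n_front + n_back]
    n_others = n - n_front - n_back

    # --- community composition at location A -----------------------------
    front_sh = _dominant_shares(_FRONT_SHARES, n_front) * rng.lognormal(0, 0.08, n_front)
    back_sh = _dominant_shares(_BACK_SHARES, n_back) * rng.lognormal(0, 0.08, n_back)
    # rare flora follow a fixed lognormal rank-abundance curve (quantiles of
    # the configured sigma) with per-OTU jitter and a random identity
    # assignment; quantiles keep the detectable-richness of a campaign
    # stable across seeds, as repeated field campaigns of one system are.
    q = (np.arange(n_others) + 0.5) / max(n_others, 1)
    from scipy.special import ndtri

    raw = np.exp(config.others_share_sigma * ndtri(q)) * rng.lognormal(
        0.0, 0.4, n_others
    )
    raw = rng.permutation(raw)
    dominant_total = front_sh.sum() + back_sh.sum()
    if n_others > 0 and dominant_total < 1.0:
        others_sh = raw / raw.sum() * (1.0 - dominant_total)
        # cap the rare flora so no undeclared OTU can reach dominance anywhere
        for _ in range(100):
            over = others_sh > _OTHERS_SHARE_CAP
            if not over.any() or over.all():
                break
            excess = (others_sh[over] - _OTHERS_SHARE_CAP).sum()
            others_sh[over] = _OTHERS_SHARE_CAP
            others_sh[~over] *= 1.0 + excess / others_sh[~over].sum()
    else:
        others_sh = np.zeros(n_others)
    shares = np.concatenate([front_sh, back_sh, others_sh])
    shares = shares / shares.sum()

    # --- seasonal covariate ----------------------------------------------
    months = config.months
    temp = seasonal_temperature(months)
    span = temp.max() - temp.min()
    theta = (temp - temp.min()) / span if span > 0 else np.ones_like(temp)
    month_scale = np.exp(config.seasonal_amplitude * (theta - 0.5))
    # colder months weaken the spatial fold effects
    trend_weight = np.clip(1.0 - config.seasonal_amplitude * (1.0 - theta), 0.2, None)

    total_a = math.exp(rng.uniform(*np.log(config.total_copies_range)))

    # --- per-OTU spatial fold exponents ----------------------------------
    kill_exp = rng.uniform(0.75, 1.25, n)
    kill_exp[n_front : n_front + n_back] *= 0.7  # back-dominants partly resist
    u_re = rng.uniform(0.8, 1.2, n)
    regrow_exp = np.zeros(n)
    regrow_exp[n_front : n_front + n_back] = u_re[n_front : n_front + n_back]
    if n_others > 0:
        others_idx = np.arange(n_front + n_back, n)
        regrowing = rng.random(n_others) < 0.7  # most, not all, rare OTUs regrow
        regrow_exp[others_idx[regrowing]] = 0.5 * u_re[others_idx[regrowing]]

    # --- assemble copies (otu, location, month) --------------------------
    n_loc, n_mon = config.n_locations, config.n_months
    copies = np.zeros((n, n_loc, n_mon))
    base = shares[:, None] * total_a * month_scale[None, :]  # location A
    copies[:, 0, :] = base
    if n_loc > 1:
        kill = config.killoff_factor ** (kill_exp[:, None] * trend_weight[None, :])
        copies[:, 1, :] = base / kill
    # beyond C the system is stable (every fold well within [1/2, 2]) but the
    # dominants keep a gentle monotone drift so their along-system trend is
    # rankable: front-dominants keep fading, back-dominants keep gaining.
    tail_step = np.ones((n, n_mon))
    tail_step[:n_front, :] = config.killoff_factor ** (-0.10 * trend_weight[None, :])
    tail_step[n_front : n_front + n_back, :] = config.regrowth_factor ** (
        0.08 * trend_weight[None, :]
    )
    for loc in range(2, n_loc):
        regrow = config.regrowth_factor ** (regrow_exp[:, None] * trend_weight[None, :])
        copies[:, loc, :] = copies[:, 1, :] * regrow * tail_step ** (loc - 2)

    # --- anomalous month at location B -----------------------------------
    anomaly_otus: list[str] = []
    if config.anomaly_month is not None and config.anomaly_fraction > 0 and n_loc > 1:
        m = config.anomaly_month - 1
        k = int(np.floor(config.anomaly_fraction * n + 0.5))
        k = max(min(k, n), 0)
        if k > 0:
            chosen = rng.choice(n, size=k, replace=False)
            spike = n_front if n_back > 0 else int(chosen[0])  # first back-dominant
            if spike not in chosen:
                chosen[0] = spike
            boost = rng.uniform(5.0, 20.0, size=k)
            boost[np.nonzero(chosen == spike)[0][0]] = config.anomaly_spike_fold
            # B rises to boost x the location-A level: fold(B/A) = boost >= 2
            copies[chosen, 1, m] = copies[chosen, 0, m] * boost
            # no die-off downstream of the surge in that month
            for loc in range(2, n_loc):
                copies[chosen, loc, m] = np.maximum(
                    copies[chosen, loc, m], copies[chosen, 1, m]
                )
            anomaly_otus = [otus[i] for i in sorted(chosen)]

    # --- contamination + assembly ----------------------------------------
    cont_ids = _otu_ids(config.contamination_otus, prefix="CONT")
    contamination = pd.Series(
        config.contamination_level, index=pd.Index(cont_ids, name="otu_id"), dtype=float
    )
    all_ids = otus + cont_ids
    cols = pd.MultiIndex.from_product(
        [config.locations, months], names=["location", "month"]
    )
    mat = np.concatenate([copies, np.zeros((len(cont_ids), n_loc, n_mon))])
    truth_df = pd.DataFrame(
        mat.reshape(len(all_ids), -1),
        index=pd.Index(all_ids, name="otu_id"),
        columns=cols,
    )
    temp_df = pd.DataFrame(
        np.tile(temp, (n_loc, 1)),
        index=pd.Index(config.locations, name="location"),
        columns=pd.Index(months, name="month"),
    )
    return SimulationTruth(
        true_copies=truth_df,
        contamination_copies=contamination,
        temperature=temp_df,
        front_otus=front,
        back_otus=back,
        anomaly_otus=anomaly_otus,
        seed=config.seed,
    )


def _draw_table(
    rng: np.random.Generator,
    sample_id: str,
    templates: pd.Series,
    config: SimulationConfig,
    sample_type: str,
    location: Optional[str],
    month: int,
) -> OTUCountTable:
    """One multinomial read draw per replicate over template molecules + IC."""
    t = np.append(templates.to_numpy(dtype=float), config.ic_copies)
    p = t / t.sum()
    counts = rng.multinomial(config.read_depth, p, size=config.n_replicates).T
    df = pd.DataFrame(
        counts,
        index=pd.Index(list(templates.index) + [IC_OTU_ID], name="otu_id"),
        columns=[f"replicate_{r + 1}" for r in range(config.n_replicates)],
    )
    return OTUCountTable(
        sample_id=sample_id,
        counts=df,
        sample_type=sample_type,
        location=location,
        month=month,
    )


def simulate_reads(
    truth: SimulationTruth, config: SimulationConfig
) -> list[OTUCountTable]:
    """Sequence the campaign: one count table per sample and per monthly NEC.

    Each replicate's reads are a single multinomial draw of ``read_depth``
    reads over the reaction's template molecules: water-community copies
    plus the contamination load plus ``ic_copies`` calibrator copies.
    NEC reactions contain only contamination and calibrator templates.
    """
    if config.ic_copies <= 0:
        raise ValueError("ic_copies must be > 0: calibration is impossible otherwise")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _READS_STREAM]))
    contamination = truth.contamination_copies.reindex(
        truth.true_copies.index, fill_value=0.0
    )
    tables = []
    for month in truth.months:
        for loc in truth.locations:
            templates = truth.true_copies[(loc, month)] + contamination
            tables.append(
                _draw_table(
                    rng, f"{loc}-M{month}", templates, config, "sample", loc, month
                )
            )
        nec_templates = contamination.copy()
        tables.append(
            _draw_table(rng, f"NEC-M{month}", nec_templates, config, "nec", None, month)
        )
    return tables


def simulate_companion_series(
    truth: SimulationTruth,
    cell_fold_offset: float = 4.9,
    qpcr_fold_offset: float = 1.3,
    noise_cv: float = 0.25,
    seed: int = 0,
) -> BiomassSeries:
    """Flow-cytometry and qPCR companion series with known offsets.

    FCM intact-cell counts are the true total copies times
    ``cell_fold_offset`` (cells systematically outnumber recovered 16S
    copies because of processing losses); qPCR total 16S copies carry the
    smaller ``qpcr_fold_offset``. Both get multiplicative lognormal noise
    with coefficient of variation ``noise_cv`` (mean exactly 1, so the
    offsets are recoverable). Calibrator and contamination are excluded
    from the totals by construction.
    """
    if cell_fold_offset <= 0 or qpcr_fold_offset <= 0:
        raise ValueError("offsets must be > 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, _SERIES_STREAM]))
    totals = truth.total_copies()
    sample_ids = [f"{loc}-M{m}" for loc, m in totals.index]
    n = len(totals)
    if noise_cv == 0:
        fcm_noise = qpcr_noise = np.ones(n)
    else:
        sigma = math.sqrt(math.log(1 + noise_cv**2))
        fcm_noise = np.exp(rng.normal(0, sigma, n) - sigma**2 / 2)
        qpcr_noise = np.exp(rng.normal(0, sigma, n) - sigma**2 / 2)
    rows = []
    for sid, tot, fn, qn in zip(sample_ids, totals.to_numpy(), fcm_noise, qpcr_noise):
        rows.append((sid, "fcm_intact", tot * cell_fold_offset * fn))
        rows.append((sid, "qpcr_16s", tot * qpcr_fold_offset * qn))
    return BiomassSeries(pd.DataFrame(rows, columns=["sample_id", "method", "value"]))
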