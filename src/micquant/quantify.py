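"""Internal-calibrator quantification and NEC decontamination.

Absolute quantification rests on a single proportionality: within one
(clonally amplified) sequencing replicate, reads are proportional to input
template molecules, so

    copies_o = reads_o / reads_IC * ic_copies * volume_scale

for every OTU o, where the internal calibrator (IC) was spiked at a known
``ic_copies`` per reaction. The copies-equivalent of a single read,
``ic_copies * volume_scale / reads_IC``, is the replicate's limit of
detection (LOD).

Contamination handling: negative extraction controls (NECs), processed in
triplicate alongside the samples, are calibrated on the same scale and
averaged into a per-OTU contamination load, which is subtracted from every
sample replicate and clipped at zero. Because the subtraction of two noisy
counts is symmetric around zero, a plain clip leaves a positive residue in
about half the replicates; contaminated OTUs are therefore cleared to zero
unless the replicate exceeds the contamination load by a Poisson-scaled
margin (``nec_margin_z`` standard deviations of the expected counting
noise). Finally the (>= 2 of 3) replicate consensus zeroes any OTU not
reproducibly detected, and surviving replicates are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import CalibrationConfig  # noqa: F401 (public type)
from .containers import AbsoluteProfile, OTUCountTable


class InvalidReplicateError(ValueError):
    """A replicate without calibrator reads cannot be quantified."""


class UnquantifiableSampleError(ValueError):
    """Fewer than the required number of valid replicates."""


@dataclass
class NECProfile:
    """Mean calibrated contamination per OTU, with the NEC's own LOD scale."""

    copies: pd.Series  # mean copies/100 uL per OTU over valid NEC replicates
    lod: float         # mean per-replicate LOD of the NECs
    n_replicates: int


def calibrate_replicate(
    counts: pd.Series, config: CalibrationConfig, ic_otu_id: str = "IC"
) -> tuple[pd.Series, float]:
    """Convert one replicate's read counts to absolute copies/100 uL.

    Returns (per-OTU copies with the calibrator row removed, LOD). Zero
    reads map to exactly zero copies. Raises :class:`InvalidReplicateError`
    when the calibrator itself got no reads — quantification is undefined
    then and is never imputed.
    """
    if ic_otu_id not in counts.index:
        raise InvalidReplicateError(f"calibrator row '{ic_otu_id}' missing")
    reads_ic = float(counts.loc[ic_otu_id])
    if reads_ic <= 0:
        raise InvalidReplicateError("calibrator received zero reads")
    scale = config.ic_copies * config.volume_scale / reads_ic
    copies = counts.drop(ic_otu_id).astype(float) * scale
    return copies, scale  # lod == copies per single read


def calibrate_table(
    table: OTUCountTable, config: CalibrationConfig
) -> tuple[pd.DataFrame, pd.Series]:
    """Calibrate every replicate of a table, dropping invalid ones.

    Returns (copies DataFrame: OTUs x valid replicates, per-replicate LODs).
    Raises :class:`InvalidReplicateError` if no replicate is valid.
    """
    cols, lods = {}, {}
    for rep in table.counts.columns:
        try:
            copies, lod = calibrate_replicate(
                table.counts[rep], config, table.ic_otu_id
            )
        except InvalidReplicateError:
            continue
        cols[rep] = copies
        lods[rep] = lod
    if not cols:
        raise InvalidReplicateError(
            f"{table.sample_id}: no replicate has calibrator reads"
        )
    return pd.DataFrame(cols), pd.Series(lods, dtype=float)


def nec_profile(
    nec_tables: Sequence[OTUCountTable], config: CalibrationConfig
) -> NECProfile:
    """Mean per-OTU contamination copies across all valid NEC replicates.

    OTUs absent from every NEC have contamination zero (handled downstream
    by zero-filled alignment). Raises if no NEC replicate is valid.
    """
    if not nec_tables:
        raise UnquantifiableSampleError("no NEC tables provided")
    frames, lods = [], []
    for table in nec_tables:
        try:
            copies, rep_lods = calibrate_table(table, config)
        except InvalidReplicateError:
            continue
        frames.append(copies)
        lods.extend(rep_lods.tolist())
    if not frames:
        raise UnquantifiableSampleError("all NEC replicates invalid")
    merged = pd.concat(frames, axis=1).fillna(0.0)
    return NECProfile(
        copies=merged.mean(axis=1),
        lod=float(np.mean(lods)),
        n_replicates=merged.shape[1],
    )


def decontaminate(sample_copies: pd.Series, contamination: pd.Series) -> pd.Series:
    """Subtract the contamination load and clip at zero (both in copies/100 uL)."""
    cont = contamination.reindex(sample_copies.index, fill_value=0.0)
    return (sample_copies - cont).clip(lower=0.0)


def _clearance_threshold(
    contamination: pd.Series, replicate_lod: float, nec: NECProfile, z: float
) -> pd.Series:
    """Copies a replicate must exceed before a contaminated OTU counts as signal.

    Counting noise of the replicate's own contamination estimate is
    approximately Poisson with variance ``c * lod`` (c copies observed at
    lod copies/read); the NEC mean adds ``c * lod_nec / n_nec``.
    """
    var = contamination * (replicate_lod + nec.lod / max(nec.n_replicates, 1))
    return contamination + z * np.sqrt(var)


def merge_replicates(
    replicate_copies: pd.DataFrame,
    lods: Sequence[float],
    *,
    consensus_min_replicates: int = 2,
    statistic: str = "mean",
    min_valid: int = 2,
) -> tuple[pd.Series, pd.Series, float]:
    """Combine decontaminated replicate profiles into one consensus profile.

    Per OTU: the mean (or median) over valid replicates, zeroed unless the
    OTU is nonzero in at least ``consensus_min_replicates`` of them. The
    profile LOD is the worst (largest) replicate LOD. Raises
    :class:`UnquantifiableSampleError` below ``min_valid`` replicates.
    """
    n_reps = replicate_copies.shape[1]
    if n_reps < min_valid:
        raise UnquantifiableSampleError(
            f"only {n_reps} valid replicate(s); >= {min_valid} required"
        )
    detected = (replicate_copies > 0).sum(axis=1).astype(int)
    if statistic == "median":
        combined = replicate_copies.median(axis=1)
    else:
        combined = replicate_copies.mean(axis=1)
    if consensus_min_replicates > 0:
        combined = combined.where(detected >= consensus_min_replicates, 0.0)
    return combined, detected, float(np.max(lods))


def quantify_sample(
    table: OTUCountTable,
    nec: Optional[NECProfile],
    config: CalibrationConfig,
    *,
    consensus_min_replicates: int = 2,
    statistic: str = "mean",
    nec_margin_z: float = 3.0,
    min_valid: int = 2,
) -> AbsoluteProfile:
    """Full per-sample quantification: calibrate, subtract NEC, merge.

    ``nec=None`` skips decontamination (contamination taken as zero).
    """
    rep_copies, lods = calibrate_table(table, config)
    if nec is not None:
        cont = nec.copies.reindex(rep_copies.index, fill_value=0.0)
        cleaned = {}
        for rep in rep_copies.columns:
            vals = decontaminate(rep_copies[rep], cont)
            if nec_margin_z > 0:
                thresh = _clearance_threshold(cont, lods[rep], nec, nec_margin_z)
                vals = vals.where(rep_copies[rep] > thresh, 0.0)
            cleaned[rep] = vals
        rep_copies = pd.DataFrame(cleaned)
    copies, detected, lod = merge_replicates(
        rep_copies,
        lods.tolist(),
        consensus_min_replicates=consensus_min_replicates,
        statistic=statistic,
        min_valid=min_valid,
    )
    return AbsoluteProfile(
        sample_id=table.sample_id,
        copies=copies,
        n_replicates_detected=detected,
        lod=lod,
        n_valid_replicates=rep_copies.shape[1],
        location=table.location,
        month=table.month,
    )


def total_biomass(profile: AbsoluteProfile) -> float:
    """Total 16S copies/100 uL in the sample (calibrator already excluded)."""
    return float(profile.copies.sum())


def observed_richness(profile: AbsoluteProfile) -> int:
    """Number of OTUs with nonzero copies after decontamination and consensus."""
    return int((profile.copies > 0).sum())
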