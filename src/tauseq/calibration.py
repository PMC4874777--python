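"""Absolute-abundance calibration of count matrices.

Two stages convert raw per-gene sequencing counts into copies per cell:

1. *Initial (spike-in) calibration* — in vitro transcribed spike-in RNAs of
   known per-cell copy number are spiked into every sample; the per-sample
   factor is the mean over spike-ins of (known copies per cell)/(observed
   counts), and every species in the sample is scaled by it.
2. *Final (stable-RNA) calibration* — a designated highly stable RNA
   (tmRNA by default) is pinned to a fixed copy number at every time point,
   which removes residual sample-to-sample variation in extraction
   efficiency.  The default target, 597 copies per cell, is the calibrated
   tmRNA level in exponentially growing E. coli.

Counts themselves are obtained by summing reads overlapping each gene's
start..stop span (1-based inclusive coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationResult",
    "summarize_gene_counts",
    "initial_calibration",
    "final_calibration",
    "calibrate",
    "DEFAULT_STABLE_RNA",
    "DEFAULT_STABLE_TARGET",
]

DEFAULT_STABLE_RNA = "tmRNA"
DEFAULT_STABLE_TARGET = 597.0  # copies per cell


@dataclass(frozen=True)
class CalibrationResult:
    """Output of the two-stage calibration."""

    calibrated: pd.DataFrame          # species x samples, copies per cell
    initial_factors: pd.Series        # copies per count, per sample
    final_factors: pd.Series          # dimensionless, per sample
    stable_rna_id: str
    target_value: float


def summarize_gene_counts(
    reads_by_sample: Mapping[str, Sequence[tuple]],
    genes: pd.DataFrame,
    *,
    stranded: bool = True,
) -> pd.DataFrame:
    """Sum reads overlapping each gene's CDS span into a count matrix.

    Parameters
    ----------
    reads_by_sample : mapping sample -> iterable of (start, end) or
        (start, end, strand) tuples, 1-based inclusive.
    genes : DataFrame indexed by gene id with columns ``start``, ``end``
        and optionally ``strand``.
    stranded : bool
        When True (directional library prep) a read with a strand only
        counts toward genes on the same strand; reads or genes without a
        strand match everything.

    A read contributes to every gene whose span it overlaps by at least one
    base.
    """
    samples = list(reads_by_sample)
    counts = pd.DataFrame(
        0.0, index=genes.index, columns=samples, dtype=float
    )
    gstart = genes["start"].to_numpy(dtype=float)
    gend = genes["end"].to_numpy(dtype=float)
    gstrand = (
        genes["strand"].to_numpy() if "strand" in genes.columns else None
    )
    for sample, reads in reads_by_sample.items():
        col = np.zeros(len(genes))
        for read in reads:
            if len(read) == 2:
                start, end, strand = *read, None
            else:
                start, end, strand = read[0], read[1], read[2]
            if not (np.isfinite(start) and np.isfinite(end)) or end < start:
                raise ValueError(f"malformed read interval {read!r}")
            hit = (gstart <= end) & (gend >= start)
            if stranded and strand is not None and gstrand is not None:
                hit &= gstrand == strand
            col += hit
        counts[sample] = col
    return counts


def initial_calibration(
    counts: pd.DataFrame,
    spikein_copies: Mapping[str, float],
    *,
    mean: str = "arithmetic",
) -> tuple[pd.Series, pd.DataFrame]:
    """Spike-in calibration: counts -> copies per cell.

    ``spikein_copies`` maps spike-in species ids (rows of ``counts``) to
    their known copies per cell.  The per-sample factor is the arithmetic
    (default) or geometric mean over spike-ins of known/observed.

    Returns (per-sample factors, calibrated matrix).
    """
    spike_ids = list(spikein_copies)
    missing = [s for s in spike_ids if s not in counts.index]
    if missing or not spike_ids:
        raise ValueError(f"spike-ins missing from count matrix: {missing or 'none given'}")
    known = pd.Series(spikein_copies, dtype=float)
    factors = {}
    for sample in counts.columns:
        obs = counts.loc[spike_ids, sample]
        if (obs <= 0).any():
            bad = obs.index[obs <= 0].tolist()
            raise ValueError(
                f"sample {sample!r}: zero spike-in counts for {bad}"
            )
        per_spike = known / obs
        if mean == "arithmetic":
            factors[sample] = float(per_spike.mean())
        elif mean == "geometric":
            factors[sample] = float(np.exp(np.log(per_spike).mean()))
        else:
            raise ValueError(f"unknown mean {mean!r}")
    f = pd.Series(factors)
    return f, counts.mul(f, axis=1)


def final_calibration(
    copies: pd.DataFrame,
    stable_rna_id: str = DEFAULT_STABLE_RNA,
    target: float = DEFAULT_STABLE_TARGET,
) -> CalibrationResult:
    """Pin the stable RNA to ``target`` copies per cell at every time point.

    Every sample (column) is scaled by ``target / stable_rna_level`` so the
    stable RNA row becomes exactly constant; ratios between species within a
    sample are untouched.
    """
    if stable_rna_id not in copies.index:
        raise ValueError(f"stable RNA {stable_rna_id!r} not in matrix")
    level = copies.loc[stable_rna_id]
    zero = level[~(level > 0)]
    if len(zero):
        raise ValueError(
            f"stable RNA {stable_rna_id!r} non-positive at time point(s) "
            f"{list(zero.index)}"
        )
    final_factors = target / level
    calibrated = copies.mul(final_factors, axis=1)
    # pin exactly (guards the row against floating-point drift)
    calibrated.loc[stable_rna_id] = target
    return CalibrationResult(
        calibrated=calibrated,
        initial_factors=pd.Series(1.0, index=copies.columns),
        final_factors=final_factors,
        stable_rna_id=stable_rna_id,
        target_value=float(target),
    )


def calibrate(
    counts: pd.DataFrame,
    spikein_copies: Mapping[str, float],
    stable_rna_id: str = DEFAULT_STABLE_RNA,
    target: float = DEFAULT_STABLE_TARGET,
    *,
    drop_spikeins: bool = False,
    mean: str = "arithmetic",
) -> CalibrationResult:
    """Run both calibration stages on a raw count matrix."""
    init_factors, copies = initial_calibration(counts, spikein_copies, mean=mean)
    result = final_calibration(copies, stable_rna_id, target)
    calibrated = result.calibrated
    if drop_spikeins:
        calibrated = calibrated.drop(index=list(spikein_copies))
    return CalibrationResult(
        calibrated=calibrated,
        initial_factors=init_factors,
        final_factors=result.final_factors,
        stable_rna_id=stable_rna_id,
        target_value=float(target),
    )
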