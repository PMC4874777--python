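"""Comparative statistics of half-lives across protein-localization groups.

mRNAs are grouped by the predicted subcellular location of the protein they
encode (cytoplasm, inner membrane, periplasm, outer membrane; extracellular
and unknown are excluded from analysis).  Distributions of half-lives are
compared with the two-sided Kolmogorov–Smirnov test, replicate concordance
is summarised by Pearson correlation of log10 values, condition effects by
per-species log2 half-life ratios, and fusion-library signal sequences by
their nucleotide composition binned against half-life.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LOCATIONS",
    "ANALYSIS_LOCATIONS",
    "GroupComparison",
    "assign_groups",
    "compare_groups_ks",
    "pairwise_ks",
    "log2_halflife_ratios",
    "replicate_concordance",
    "nucleotide_composition_analysis",
    "CompositionAnalysis",
]

LOCATIONS = (
    "cytoplasm",
    "inner membrane",
    "periplasm",
    "outer membrane",
    "extracellular",
    "unknown",
)
#: groups actually analysed; extracellular and unknown carry too few genes
ANALYSIS_LOCATIONS = LOCATIONS[:4]

#: exact KS p-values are computed when n*m does not exceed this
EXACT_KS_LIMIT = 10_000


def assign_groups(
    halflives: Mapping[str, float] | pd.Series,
    annotation: Mapping[str, str],
    groups: Sequence[str] = ANALYSIS_LOCATIONS,
) -> dict[str, list[float]]:
    """Partition per-species half-lives by predicted protein location.

    Species annotated outside ``groups`` (extracellular, unknown) are
    excluded; species missing from the annotation are excluded with a
    warning.
    """
    halflives = pd.Series(halflives, dtype=float)
    out: dict[str, list[float]] = {g: [] for g in groups}
    missing = []
    for sid, tau in halflives.items():
        loc = annotation.get(sid)
        if loc is None:
            missing.append(sid)
            continue
        if loc in out:
            out[loc].append(float(tau))
    if missing:
        warnings.warn(
            f"{len(missing)} species without location annotation excluded: "
            f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
        )
    return out


def compare_groups_ks(a, b, *, mode: str = "auto") -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov–Smirnov test.

    Returns ``(D, p)`` with D = sup |ECDF_a - ECDF_b|.  The exact
    permutation distribution is used when ``n*m <= 10_000`` (or always with
    ``mode='exact'``); otherwise the asymptotic approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if mode == "auto":
        mode = "exact" if len(a) * len(b) <= EXACT_KS_LIMIT else "asymp"
    res = stats.ks_2samp(a, b, alternative="two-sided", method=mode)
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass
class GroupComparison:
    """Per-group summaries and all pairwise KS tests."""

    groups: dict[str, list[float]]
    summary: pd.DataFrame = field(init=False)
    pairwise: pd.DataFrame = field(init=False)

    def __post_init__(self):
        rows = []
        for name, vals in self.groups.items():
            v = np.asarray(vals, dtype=float)
            rows.append(
                {
                    "group": name,
                    "n": len(v),
                    "mean": v.mean() if len(v) else np.nan,
                    "sem": v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
                    "median": np.median(v) if len(v) else np.nan,
                }
            )
        self.summary = pd.DataFrame(rows).set_index("group")
        self.pairwise = pairwise_ks(self.groups)


def pairwise_ks(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """KS statistic and two-sided p for every pair of non-empty groups."""
    rows = []
    names = [g for g, v in groups.items() if len(v)]
    for g1, g2 in itertools.combinations(names, 2):
        d, p = compare_groups_ks(groups[g1], groups[g2])
        rows.append({"group_a": g1, "group_b": g2, "D": d, "p": p})
    return pd.DataFrame(rows, columns=["group_a", "group_b", "D", "p"])


def log2_halflife_ratios(tau_a: pd.Series, tau_b: pd.Series) -> pd.Series:
    """Per-species log2(tau_A / tau_B) on the species passing in both."""
    tau_a = pd.Series(tau_a, dtype=float)
    tau_b = pd.Series(tau_b, dtype=float)
    shared = tau_a.index.intersection(tau_b.index)
    a, b = tau_a.loc[shared], tau_b.loc[shared]
    ok = (a > 0) & (b > 0)
    return np.log2(a[ok] / b[ok])


def replicate_concordance(
    table_a: pd.Series, table_b: pd.Series, transform=np.log10
) -> tuple[float, int]:
    """Pearson correlation of transformed values shared between replicates.

    Non-positive and missing values are excluded; at least 3 shared species
    are required.  Returns (r, n_shared).
    """
    a = pd.Series(table_a, dtype=float)
    b = pd.Series(table_b, dtype=float)
    shared = a.index.intersection(b.index)
    a, b = a.loc[shared], b.loc[shared]
    ok = (a > 0) & (b > 0) & np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise ValueError(f"only {len(a)} shared positive species; need >= 3")
    r, _ = stats.pearsonr(transform(a), transform(b))
    return float(r), int(len(a))


@dataclass
class CompositionAnalysis:
    """Nucleotide-composition vs half-life analysis of signal sequences."""

    percent: pd.DataFrame          # class x nucleotide, percent
    binned: pd.DataFrame           # class, nucleotide, bin, mean tau, sem, n
    bin_width: int

    def ratio_curve(self, nucleotide: str, num_class: str, den_class: str) -> pd.Series:
        """Ratio of mean half-life per matched composition bin."""
        sel = self.binned[self.binned["nucleotide"] == nucleotide]
        num = sel[sel["class"] == num_class].set_index("bin")["mean_tau"]
        den = sel[sel["class"] == den_class].set_index("bin")["mean_tau"]
        shared = num.index.intersection(den.index)
        return num.loc[shared] / den.loc[shared]


def nucleotide_composition_analysis(
    sequences_by_class: Mapping[str, Sequence[str]],
    halflives_by_class: Mapping[str, Sequence[float]],
    bin_width: int = 3,
) -> CompositionAnalysis:
    """Relate signal-sequence nucleotide composition to half-life.

    All sequences must share one length (the 90-nt signal region).  For each
    class the percent A/C/G/T is reported; for each nucleotide, sequences
    are binned by their per-sequence count in ``bin_width``-count increments
    and the mean half-life ± SEM per bin is computed.  Ratio curves between
    classes over matched bins come from :meth:`CompositionAnalysis.ratio_curve`.
    """
    lengths = {
        len(s) for seqs in sequences_by_class.values() for s in seqs
    }
    if len(lengths) > 1:
        raise ValueError(f"sequences must share one length, got {sorted(lengths)}")
    pct_rows, bin_rows = {}, []
    for cls, seqs in sequences_by_class.items():
        taus = np.asarray(halflives_by_class[cls], dtype=float)
        if len(taus) != len(seqs):
            raise ValueError(f"class {cls!r}: {len(seqs)} sequences vs {len(taus)} half-lives")
        counts = pd.DataFrame(
            {nt: [s.upper().count(nt) for s in seqs] for nt in "ACGT"}
        )
        total = counts.sum(axis=1).replace(0, np.nan)
        pct_rows[cls] = (100.0 * counts.sum(axis=0) / counts.values.sum())
        for nt in "ACGT":
            # bins cover 1..w, w+1..2w, ... so counts 10,11,12 share a bin
            # at the default width of 3; a count of zero joins the first bin
            bins = (counts[nt].clip(lower=1) - 1) // bin_width
            for b, idx in pd.Series(range(len(seqs))).groupby(bins):
                vals = taus[idx.to_numpy()]
                bin_rows.append(
                    {
                        "class": cls,
                        "nucleotide": nt,
                        "bin": int(b),
                        "bin_low": int(b) * bin_width + 1,
                        "mean_tau": float(np.mean(vals)),
                        "sem": float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                        if len(vals) > 1
                        else np.nan,
                        "n": len(vals),
                    }
                )
    percent = pd.DataFrame(pct_rows).T
    percent.index.name = "class"
    binned = pd.DataFrame(
        bin_rows,
        columns=["class", "nucleotide", "bin", "bin_low", "mean_tau", "sem", "n"],
    )
    return CompositionAnalysis(percent=percent, binned=binned, bin_width=bin_width)
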