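"""Design of massively multiplexed signal-peptide fusion libraries.

Each library member fuses a 30-amino-acid signal-peptide window (90 nt) to
a test gene through a common GGSGGS linker.  Signal peptides are classified
from external predictor outputs:

* **SRP** (co-translational membrane targeting): more than one predicted
  transmembrane span and a predicted inner-membrane location.  The window
  is centered on the first TM span (clamped to the N-terminus).
* **SecB** (post-translational export): a positive signal-peptide
  prediction, excluding proteins with two or more TM spans (those are
  hydrophobic N-terminal TMs misread as signal peptides, i.e. SRP
  substrates).  Window = first 30 residues.
* **cyto_control**: cytoplasmic proteins in neither class, sampled at
  random.  Window = first 30 residues.

Three nucleotide encodings are built per window — the native CDS substring,
a synthetic recoding with synonymous codons drawn by genome codon usage,
and an untranslated variant whose first two codons become TAA TAA — and
each is crossed with every test gene.  The variable 90-nt signal region is
the only part amplified and sequenced, so it doubles as the construct's
barcode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .codons import ECOLI_CODON_USAGE, sample_codon, translate_dna

__all__ = [
    "ProteinRecord",
    "SignalPeptide",
    "FusionConstruct",
    "LINKER_AA",
    "LINKER_NT",
    "DEFAULT_TEST_GENES",
    "classify_signal_type",
    "extract_signal_window",
    "synthetic_encoding",
    "untranslated_encoding",
    "build_library",
    "extract_barcode_counts",
    "library_manifest",
]

LINKER_AA = "GGSGGS"
#: fixed nucleotide encoding of the linker (translates to GGSGGS)
LINKER_NT = "GGTGGATCAGGAGGTTCA"

DEFAULT_TEST_GENES = ("mMaple3", "neo", "bla", "lacZ", "phoA")

WINDOW_AA = 30
WINDOW_NT = 3 * WINDOW_AA

SIGNAL_CLASSES = ("SRP", "SecB", "cyto_control")
ENCODINGS = ("native", "synthetic", "untranslated")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein with its CDS and external predictor annotations.

    TM spans are 1-based inclusive residue intervals; ``psortb_location``
    is one of the six location labels; ``signalp_positive`` flags a
    predicted cleavable signal peptide.
    """

    gene_id: str
    sequence: str
    cds: str
    tm_spans: tuple[tuple[int, int], ...] = ()
    signalp_positive: bool = False
    psortb_location: str = "unknown"

    def __post_init__(self):
        if translate_dna(self.cds).rstrip("*") != self.sequence.rstrip("*"):
            raise ValueError(f"{self.gene_id}: CDS does not translate to sequence")
        for s, e in self.tm_spans:
            if not (1 <= s <= e <= len(self.sequence)):
                raise ValueError(f"{self.gene_id}: TM span ({s},{e}) outside protein")


@dataclass(frozen=True)
class SignalPeptide:
    source_gene: str
    signal_class: str
    aa_window: str
    native_nt: str
    window_start: int  # 1-based residue index of the window's first residue

    def __post_init__(self):
        if len(self.aa_window) != WINDOW_AA:
            raise ValueError("signal window must be 30 amino acids")
        if translate_dna(self.native_nt) != self.aa_window:
            raise ValueError("native_nt does not translate to aa_window")


@dataclass(frozen=True)
class FusionConstruct:
    peptide: SignalPeptide
    encoding: str
    signal_nt: str
    test_gene: str
    test_cds: str

    @property
    def barcode(self) -> str:
        return self.signal_nt

    @property
    def full_cds(self) -> str:
        return self.signal_nt + LINKER_NT + self.test_cds

    @property
    def construct_id(self) -> str:
        return f"{self.peptide.source_gene}|{self.encoding}|{self.test_gene}"


def classify_signal_type(record: ProteinRecord) -> str | None:
    """Classify a protein into SRP / SecB / cyto_control, or None (excluded)."""
    n_tm = len(record.tm_spans)
    if n_tm > 1 and record.psortb_location == "inner membrane":
        return "SRP"
    if record.signalp_positive and n_tm < 2:
        return "SecB"
    if record.psortb_location == "cytoplasm":
        return "cyto_control"
    return None


def extract_signal_window(record: ProteinRecord, signal_class: str) -> SignalPeptide:
    """Extract the 30-aa signal window and its native 90-nt encoding.

    SRP windows are centered on the midpoint of the first TM span
    (residues center-14 .. center+15); a window running past the N-terminus
    is replaced by residues 1–30, and one running past the C-terminus is
    clamped to the last 30 residues (with a warning).  SecB and control
    windows are always residues 1–30.
    """
    if len(record.sequence) < WINDOW_AA:
        raise ValueError(
            f"{record.gene_id}: protein shorter than {WINDOW_AA} aa, excluded"
        )
    if signal_class == "SRP":
        if not record.tm_spans:
            raise ValueError(f"{record.gene_id}: SRP record without TM spans")
        s, e = record.tm_spans[0]
        center = (s + e) // 2
        start = center - 14
        if start < 1:
            start = 1
        if start + WINDOW_AA - 1 > len(record.sequence):
            warnings.warn(
                f"{record.gene_id}: TM-centered window past C-terminus; "
                "clamped to the last 30 residues"
            )
            start = len(record.sequence) - WINDOW_AA + 1
    else:
        start = 1
    aa = record.sequence[start - 1 : start - 1 + WINDOW_AA]
    nt = record.cds[(start - 1) * 3 : (start - 1 + WINDOW_AA) * 3]
    return SignalPeptide(record.gene_id, signal_class, aa, nt, start)


def synthetic_encoding(
    aa_window: str,
    usage: Mapping[str, float] = ECOLI_CODON_USAGE,
    seed: int | np.random.Generator = 0,
) -> str:
    """Recode a window with synonymous codons drawn by usage weight."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return "".join(sample_codon(aa, usage, rng) for aa in aa_window)


def untranslated_encoding(native_nt: str) -> str:
    """Replace the first two codons with a pair of TAA stop codons."""
    if len(native_nt) % 3:
        raise ValueError(f"length {len(native_nt)} not divisible by 3")
    if len(native_nt) < 6:
        raise ValueError("need at least two codons")
    return "TAATAA" + native_nt[6:]


def build_library(
    records: Iterable[ProteinRecord],
    test_gene_cds: Mapping[str, str] | None = None,
    usage: Mapping[str, float] = ECOLI_CODON_USAGE,
    *,
    n_cyto_controls: int | None = None,
    extra_secb: Sequence[ProteinRecord] = (),
    seed: int = 0,
) -> tuple[list[FusionConstruct], pd.DataFrame]:
    """Build the full fusion library from classified protein records.

    Every classified signal peptide is encoded three ways and crossed with
    every test gene.  ``extra_secb`` adds non-native SecB substrates (e.g.
    beta-lactamase) to the SecB set regardless of classification;
    ``n_cyto_controls`` subsamples the cytoplasmic controls with a seeded
    uniform draw without replacement.  Duplicate barcodes are removed with
    a warning (the barcode must uniquely identify a construct).

    Returns the construct list and a design report (per-class peptide and
    construct counts).
    """
    rng = np.random.default_rng(seed)
    if test_gene_cds is None:
        test_gene_cds = {g: "" for g in DEFAULT_TEST_GENES}
    peptides: dict[str, list[SignalPeptide]] = {c: [] for c in SIGNAL_CLASSES}
    for rec in records:
        cls = classify_signal_type(rec)
        if cls is None:
            continue
        try:
            peptides[cls].append(extract_signal_window(rec, cls))
        except ValueError as exc:
            warnings.warn(str(exc))
    for rec in extra_secb:
        peptides["SecB"].append(extract_signal_window(rec, "SecB"))
    if n_cyto_controls is not None and len(peptides["cyto_control"]) > n_cyto_controls:
        idx = rng.choice(
            len(peptides["cyto_control"]), size=n_cyto_controls, replace=False
        )
        peptides["cyto_control"] = [peptides["cyto_control"][i] for i in sorted(idx)]

    constructs: list[FusionConstruct] = []
    seen_barcodes: set[str] = set()
    dropped = 0
    for cls in SIGNAL_CLASSES:
        for pep in peptides[cls]:
            encodings = {
                "native": pep.native_nt,
                "synthetic": synthetic_encoding(pep.aa_window, usage, rng),
                "untranslated": untranslated_encoding(pep.native_nt),
            }
            for enc_name, nt in encodings.items():
                if nt in seen_barcodes:
                    dropped += len(test_gene_cds)
                    warnings.warn(
                        f"duplicate barcode for {pep.source_gene}/{enc_name}; dropped"
                    )
                    continue
                seen_barcodes.add(nt)
                for gene, cds in test_gene_cds.items():
                    constructs.append(FusionConstruct(pep, enc_name, nt, gene, cds))

    report = pd.DataFrame(
        {
            "n_peptides": {c: len(peptides[c]) for c in SIGNAL_CLASSES},
            "n_constructs": {
                c: sum(1 for f in constructs if f.peptide.signal_class == c)
                for c in SIGNAL_CLASSES
            },
        }
    )
    report.loc["total"] = report.sum()
    report.attrs["n_test_genes"] = len(test_gene_cds)
    report.attrs["n_encodings"] = len(ENCODINGS)
    report.attrs["n_dropped_duplicates"] = dropped
    return constructs, report


def library_manifest(constructs: Sequence[FusionConstruct]) -> pd.DataFrame:
    """TSV-ready manifest: one row per construct."""
    return pd.DataFrame(
        {
            "construct_id": [c.construct_id for c in constructs],
            "source_gene": [c.peptide.source_gene for c in constructs],
            "signal_class": [c.peptide.signal_class for c in constructs],
            "encoding": [c.encoding for c in constructs],
            "test_gene": [c.test_gene for c in constructs],
            "window_start": [c.peptide.window_start for c in constructs],
            "barcode": [c.barcode for c in constructs],
        }
    ).set_index("construct_id")


def extract_barcode_counts(
    reads_by_sample: Mapping[str, Iterable[str]],
    constructs: Sequence[FusionConstruct],
    *,
    max_offset: int = 8,
) -> tuple[pd.DataFrame, pd.Series]:
    """Tally sequenced barcode reads per construct and sample.

    Library amplicons carry a random-length prefix (used to break low
    sequence complexity on the sequencer), so each read is scanned for an
    exact 90-nt barcode match at offsets 0..``max_offset``.  Unmatched
    reads are tallied separately per sample.
    """
    barcode_to_id = {}
    for c in constructs:
        if c.barcode in barcode_to_id and barcode_to_id[c.barcode] != c.construct_id:
            raise ValueError(f"barcode collision for {c.construct_id}")
        barcode_to_id.setdefault(c.barcode, c.construct_id)
    ids = sorted({c.construct_id for c in constructs})
    samples = list(reads_by_sample)
    counts = pd.DataFrame(0, index=ids, columns=samples, dtype=int)
    unmatched = pd.Series(0, index=samples, dtype=int)
    for sample, reads in reads_by_sample.items():
        for read in reads:
            hit = None
            for off in range(0, max_offset + 1):
                cand = read[off : off + WINDOW_NT]
                if len(cand) < WINDOW_NT:
                    break
                cid = barcode_to_id.get(cand)
                if cid is not None:
                    hit = cid
                    break
            if hit is None:
                unmatched[sample] += 1
            else:
                counts.at[hit, sample] += 1
    return counts, unmatched
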