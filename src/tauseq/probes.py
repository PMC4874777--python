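"""Array-derived FISH probe-pool design.

A probe template is the concatenation

    I1 | RTP | nick1 | rc(TR) | rc(nick2) | I2

where I1/I2 are 20-nt group-specific index primers, RTP the common reverse
transcription primer, nick1/nick2 nicking-enzyme sites, and TR a 30-nt
targeting region complementary to a cellular RNA.  Index primers let a
probe group be PCR-selected out of a complex oligo pool; the amplified
templates are transcribed in vitro and reverse-transcribed with a labeled
primer to yield single-stranded fluorescent probes.

Targeting regions are screened for length, GC content, duplex melting
temperature, and cross-hybridization (a shared exact substring with any
other transcript or previously accepted region, a conservative proxy for a
hybridization-free-energy screen).  Melting temperatures come from
nearest-neighbour thermodynamics reported at the 1 M Na+ convention used by
oligo-design tools; salt and formamide corrections are configurable.

The transcriptome is partitioned into stain groups by predicted protein
location crossed with abundance range (1/3–3, 3–30, 30–300 copies per
cell), by alternating 100-kb genomic windows, and optionally by
polycistronic linkage to inner-membrane cistrons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp as _mt

__all__ = [
    "RTP",
    "T7_PROMOTER",
    "NICK_BSMI",
    "NICK_BSRDI",
    "TRConstraints",
    "PrimerConstraints",
    "TargetingRegion",
    "IndexPrimer",
    "ProbeTemplate",
    "ProbeGroup",
    "ABUNDANCE_RANGES",
    "revcomp",
    "duplex_tm",
    "primer_tm",
    "design_targeting_regions",
    "select_index_primers",
    "assemble_template",
    "parse_template",
    "derive_probe_sequence",
    "partition_transcriptome",
    "abundance_range",
]

#: common reverse-transcription primer (P9)
RTP = "CAGGCATCCGAGAGGTCTGG"
T7_PROMOTER = "TAATACGACTCACTATAGGG"
#: Nb.BsmI and Nb.BsrDI recognition sites
NICK_BSMI = "GAATGC"
NICK_BSRDI = "GCAATG"

#: abundance ranges in copies per cell, half-open [low, high)
ABUNDANCE_RANGES = (
    ("1/3-3", 1.0 / 3.0, 3.0),
    ("3-30", 3.0, 30.0),
    ("30-300", 30.0, 300.0),
)


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _gc_percent(seq: str) -> float:
    seq = seq.upper()
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def duplex_tm(seq: str, *, na_mM: float = 1000.0, formamide_pct: float = 0.0) -> float:
    """Melting temperature (degC) of a probe:RNA duplex.

    Nearest-neighbour model at the 1 M Na+ reporting convention; an
    optional formamide correction of -0.6 degC per percent is applied.
    """
    tm = _mt.Tm_NN(seq, nn_table=_mt.DNA_NN4, Na=na_mM)
    return tm - 0.6 * formamide_pct


def primer_tm(seq: str, *, na_mM: float = 1000.0) -> float:
    """Melting temperature of a PCR primer (same NN model as duplex_tm)."""
    return _mt.Tm_NN(seq, nn_table=_mt.DNA_NN4, Na=na_mM)


@dataclass(frozen=True)
class TRConstraints:
    """Targeting-region design constraints."""

    length: int = 30
    gc_range: tuple[float, float] = (50.0, 60.0)
    tm_range: tuple[float, float] = (80.0, 85.0)
    crosshyb_k: int = 16       # shared exact substring length triggering rejection
    na_mM: float = 1000.0
    formamide_pct: float = 0.0


@dataclass(frozen=True)
class PrimerConstraints:
    """Index-primer selection constraints."""

    length: int = 20
    tm_range: tuple[float, float] = (65.0, 70.0)
    gc_range: tuple[float, float] = (50.0, 60.0)
    max_run: int = 3           # runs of max_run+1 identical bases are rejected
    clamp_gc: tuple[int, int] = (2, 3)   # G/C count allowed in the final 5 nt
    homology_k: int = 12       # shared substring >= k rejects
    na_mM: float = 1000.0


@dataclass(frozen=True)
class TargetingRegion:
    transcript_id: str
    start: int                 # 1-based position on the transcript
    sequence: str              # the probe-side 30-mer (rc of the transcript)
    gc_percent: float
    duplex_tm: float
    crosshyb_flag: bool = False

    @property
    def target_substring(self) -> str:
        """The transcript-sense substring this region hybridizes to."""
        return revcomp(self.sequence)


@dataclass(frozen=True)
class IndexPrimer:
    sequence: str
    tm: float
    gc_percent: float
    role: str = "I1"


@dataclass(frozen=True)
class ProbeTemplate:
    i1: str
    rtp: str
    nick1: str
    tr: str
    nick2: str
    i2: str

    @property
    def full_sequence(self) -> str:
        return (
            self.i1 + self.rtp + self.nick1 + revcomp(self.tr)
            + revcomp(self.nick2) + self.i2
        )


@dataclass(frozen=True)
class ProbeGroup:
    key: str
    members: tuple[str, ...]           # transcript ids
    tr_ids: tuple[str, ...] = ()       # "<transcript>:<start>" labels


def _kmers(seq: str, k: int):
    for i in range(len(seq) - k + 1):
        yield seq[i : i + k]


def design_targeting_regions(
    transcripts: Mapping[str, str],
    constraints: TRConstraints = TRConstraints(),
    background: Mapping[str, str] | None = None,
) -> list[TargetingRegion]:
    """Screen every transcript for acceptable, non-overlapping 30-nt regions.

    A candidate window is accepted when its GC and duplex-Tm fall in range
    and none of its ``crosshyb_k``-mers occurs in any *other* transcript
    (input or background, either strand) or in an already accepted region.
    Accepted windows within one transcript are greedy left-to-right and
    non-overlapping.  Transcripts shorter than the window yield nothing.
    """
    c = constraints
    # k-mer -> set of transcript ids containing it (both strands)
    pool: dict[str, str] = {k: v.upper() for k, v in transcripts.items()}
    if background:
        for k, v in background.items():
            pool.setdefault(k, v.upper())
    kmer_owners: dict[str, set[str]] = {}
    for tid, seq in pool.items():
        for strand_seq in (seq, revcomp(seq)):
            for km in _kmers(strand_seq, c.crosshyb_k):
                kmer_owners.setdefault(km, set()).add(tid)
    accepted: list[TargetingRegion] = []
    accepted_kmers: set[str] = set()
    for tid in transcripts:
        seq = pool[tid]
        if len(seq) < c.length:
            continue
        next_free = 0
        for i in range(len(seq) - c.length + 1):
            if i < next_free:
                continue
            window = seq[i : i + c.length]
            if set(window) - set("ACGT"):
                continue
            gc = _gc_percent(window)
            if not c.gc_range[0] <= gc <= c.gc_range[1]:
                continue
            tm = duplex_tm(window, na_mM=c.na_mM, formamide_pct=c.formamide_pct)
            if not c.tm_range[0] <= tm <= c.tm_range[1]:
                continue
            # cross-hybridization: window k-mers (either strand) seen in any
            # other transcript or in an already accepted region
            clash = False
            for sub in (window, revcomp(window)):
                for km in _kmers(sub, c.crosshyb_k):
                    owners = kmer_owners.get(km, set())
                    if owners - {tid} or km in accepted_kmers:
                        clash = True
                        break
                if clash:
                    break
            if clash:
                continue
            tr_seq = revcomp(window)
            accepted.append(
                TargetingRegion(tid, i + 1, tr_seq, gc, tm, False)
            )
            for sub in (window, revcomp(window)):
                accepted_kmers.update(_kmers(sub, c.crosshyb_k))
            next_free = i + c.length
    return accepted


def _has_run(seq: str, max_run: int) -> bool:
    run, prev = 1, ""
    for ch in seq:
        run = run + 1 if ch == prev else 1
        if run > max_run:
            return True
        prev = ch
    return False


def select_index_primers(
    candidates: Iterable[str],
    transcriptome: Mapping[str, str] | None = None,
    reserved: Sequence[str] = (T7_PROMOTER, RTP),
    constraints: PrimerConstraints = PrimerConstraints(),
) -> list[IndexPrimer]:
    """Truncate candidate oligos to 20 nt and apply the primer filters.

    Filters: melting temperature and GC windows, no run of four or more
    identical bases, a 3' GC clamp of 2–3 G/C in the final five bases, and
    low homology — no shared exact substring of ``homology_k`` or more
    bases (either strand) with the transcriptome, the reserved sequences
    (T7 promoter and RTP by default), or any previously accepted primer.
    """
    c = constraints
    screen_kmers: set[str] = set()

    def add_screen(seq: str):
        seq = seq.upper()
        for s in (seq, revcomp(seq)):
            screen_kmers.update(_kmers(s, c.homology_k))

    for seq in reserved:
        add_screen(seq)
    if transcriptome:
        for seq in transcriptome.values():
            add_screen(seq)

    out: list[IndexPrimer] = []
    for cand in candidates:
        p = cand.upper()[: c.length]
        if len(p) < c.length or set(p) - set("ACGT"):
            continue
        gc = _gc_percent(p)
        if not c.gc_range[0] <= gc <= c.gc_range[1]:
            continue
        tm = primer_tm(p, na_mM=c.na_mM)
        if not c.tm_range[0] <= tm <= c.tm_range[1]:
            continue
        if _has_run(p, c.max_run):
            continue
        clamp = sum(p[-5:].count(b) for b in "GC")
        if not c.clamp_gc[0] <= clamp <= c.clamp_gc[1]:
            continue
        if any(km in screen_kmers for km in _kmers(p, c.homology_k)) or any(
            km in screen_kmers for km in _kmers(revcomp(p), c.homology_k)
        ):
            continue
        out.append(IndexPrimer(p, tm, gc))
        add_screen(p)
    return out


def assemble_template(
    i1: str,
    tr: str,
    i2: str,
    nick1: str = NICK_BSMI,
    nick2: str = NICK_BSRDI,
    rtp: str = RTP,
) -> ProbeTemplate:
    """Assemble an array-oligo template I1|RTP|nick1|rc(TR)|rc(nick2)|I2."""
    for name, part in (("i1", i1), ("tr", tr), ("i2", i2),
                       ("nick1", nick1), ("nick2", nick2), ("rtp", rtp)):
        if not part or set(part.upper()) - set("ACGT"):
            raise ValueError(f"template part {name!r} empty or non-ACGT")
    return ProbeTemplate(i1.upper(), rtp.upper(), nick1.upper(),
                         tr.upper(), nick2.upper(), i2.upper())


def parse_template(
    full: str,
    *,
    i1_len: int = 20,
    i2_len: int = 20,
    tr_len: int = 30,
    nick1: str = NICK_BSMI,
    nick2: str = NICK_BSRDI,
    rtp: str = RTP,
) -> ProbeTemplate:
    """Recover the parts of an assembled template (round-trip of assemble)."""
    expect = i1_len + len(rtp) + len(nick1) + tr_len + len(nick2) + i2_len
    if len(full) != expect:
        raise ValueError(f"template length {len(full)} != expected {expect}")
    pos = 0
    i1 = full[pos : pos + i1_len]; pos += i1_len
    if full[pos : pos + len(rtp)] != rtp:
        raise ValueError("RTP not found at expected position")
    pos += len(rtp)
    if full[pos : pos + len(nick1)] != nick1:
        raise ValueError("nick site 1 mismatch")
    pos += len(nick1)
    rc_tr = full[pos : pos + tr_len]; pos += tr_len
    if full[pos : pos + len(nick2)] != revcomp(nick2):
        raise ValueError("nick site 2 mismatch")
    pos += len(nick2)
    i2 = full[pos:]
    return ProbeTemplate(i1, rtp, nick1, revcomp(rc_tr), nick2, i2)


@dataclass(frozen=True)
class ProbeSequence:
    primer: str
    targeting_segment: str

    @property
    def sequence(self) -> str:
        return self.primer + self.targeting_segment


def derive_probe_sequence(template: ProbeTemplate, mode: str = "sense") -> ProbeSequence:
    """Trace the modeled PCR -> IVT -> RT chain to the final probe.

    In ``sense`` mode the labeled RT primer is the RTP and the probe's
    targeting segment is the TR itself (complementary to the cellular RNA).
    In ``antisense_control`` mode amplification is re-primed so the probe
    carries rc(TR) — a sequence-matched control that cannot hybridize to
    the target RNA.
    """
    if mode == "sense":
        return ProbeSequence(template.rtp, template.tr)
    if mode == "antisense_control":
        return ProbeSequence(template.i2, revcomp(template.tr))
    raise ValueError(f"unknown probe mode {mode!r}")


def abundance_range(copies_per_cell: float) -> str | None:
    """Half-open abundance range label, or None outside [1/3, 300)."""
    for label, low, high in ABUNDANCE_RANGES:
        if low <= copies_per_cell < high:
            return label
    return None


def partition_transcriptome(
    annotation: pd.DataFrame,
    tr_by_transcript: Mapping[str, Sequence[str]] | None = None,
    *,
    scheme: str = "location",
    window_kb: float = 100.0,
    cyto_tr_fraction: float = 1.0 / 3.0,
    split_polycistronic: bool = False,
    seed: int = 0,
) -> list[ProbeGroup]:
    """Partition annotated genes into probe stain groups.

    ``annotation`` is indexed by gene id with columns ``location``,
    ``copies_per_cell``, ``start`` and optionally ``operon_id``.

    scheme="location": groups keyed location x abundance range; genes with
    no abundance range are collected under "unexpressed" and excluded from
    location groups; cytoplasmic groups keep a seeded random 1/3 of their
    candidate targeting regions; with ``split_polycistronic`` the
    non-inner-membrane groups are subdivided by whether the gene shares an
    operon with an inner-membrane gene.

    scheme="genomic": alternating ``window_kb`` windows (the 2nd, 4th, ...
    window: 100-200 kb, 300-400 kb, ...) for genes in the two lower
    abundance ranges, assigned by gene start coordinate.
    """
    rng = np.random.default_rng(seed)
    tr_by_transcript = tr_by_transcript or {}
    groups: dict[str, dict] = {}

    def add(key: str, gene: str, trs: Sequence[str]):
        g = groups.setdefault(key, {"members": [], "trs": []})
        g["members"].append(gene)
        g["trs"].extend(trs)

    if scheme == "location":
        im_operons = set()
        if split_polycistronic and "operon_id" in annotation.columns:
            im = annotation["location"] == "inner membrane"
            im_operons = set(annotation.loc[im, "operon_id"].dropna())
        for gene, row in annotation.iterrows():
            rng_label = abundance_range(float(row["copies_per_cell"]))
            if rng_label is None:
                add("unexpressed", gene, ())
                continue
            loc = row["location"]
            trs = list(tr_by_transcript.get(gene, ()))
            if loc == "cytoplasm" and trs:
                n_keep = max(1, round(len(trs) * cyto_tr_fraction))
                idx = rng.choice(len(trs), size=n_keep, replace=False)
                trs = [trs[i] for i in sorted(idx)]
            key = f"{loc}|{rng_label}"
            if (
                split_polycistronic
                and loc in ("cytoplasm", "periplasm", "outer membrane")
                and "operon_id" in annotation.columns
            ):
                tag = "im-polycistronic" if row.get("operon_id") in im_operons else "monofunctional"
                key = f"{key}|{tag}"
            add(key, gene, trs)
    elif scheme == "genomic":
        w = window_kb * 1000.0
        for gene, row in annotation.iterrows():
            rng_label = abundance_range(float(row["copies_per_cell"]))
            if rng_label not in ("1/3-3", "3-30"):
                continue
            win = int(float(row["start"]) // w)
            if win % 2 == 0:
                continue  # alternating windows: keep 100-200, 300-400, ...
            lo, hi = int(win * window_kb), int((win + 1) * window_kb)
            add(f"genomic|{lo}-{hi}kb", gene, tr_by_transcript.get(gene, ()))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    return [
        ProbeGroup(key, tuple(g["members"]), tuple(g["trs"]))
        for key, g in sorted(groups.items())
    ]
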