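"""Codon usage weights and synonymous-codon sampling.

``ECOLI_CODON_USAGE`` holds genome-wide E. coli K-12 codon frequencies
(per-1000-codon scale; only relative weights within a synonymous family
matter here).  Any mapping codon -> positive weight can be supplied in its
place.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from Bio.Data import CodonTable

__all__ = ["ECOLI_CODON_USAGE", "synonymous_codons", "sample_codon", "translate_dna"]

# genome-wide usage, per 1000 codons (standard K-12 reference values)
ECOLI_CODON_USAGE: dict[str, float] = {
    "TTT": 22.2, "TTC": 16.6, "TTA": 13.9, "TTG": 13.7,
    "CTT": 11.0, "CTC": 11.0, "CTA": 3.9, "CTG": 52.6,
    "ATT": 30.3, "ATC": 25.1, "ATA": 4.4, "ATG": 27.9,
    "GTT": 18.3, "GTC": 15.3, "GTA": 10.9, "GTG": 26.4,
    "TCT": 8.5, "TCC": 8.6, "TCA": 7.2, "TCG": 8.9,
    "CCT": 7.0, "CCC": 5.5, "CCA": 8.4, "CCG": 23.2,
    "ACT": 9.0, "ACC": 23.4, "ACA": 7.1, "ACG": 14.4,
    "GCT": 15.3, "GCC": 25.5, "GCA": 20.1, "GCG": 33.6,
    "TAT": 16.2, "TAC": 12.2, "TAA": 2.0, "TAG": 0.2,
    "CAT": 12.9, "CAC": 9.7, "CAA": 15.3, "CAG": 28.8,
    "AAT": 17.7, "AAC": 21.7, "AAA": 33.6, "AAG": 10.3,
    "GAT": 32.1, "GAC": 19.1, "GAA": 39.4, "GAG": 17.8,
    "TGT": 5.2, "TGC": 6.4, "TGA": 1.0, "TGG": 15.2,
    "CGT": 20.9, "CGC": 22.0, "CGA": 3.6, "CGG": 5.4,
    "AGT": 8.8, "AGC": 16.1, "AGA": 2.1, "AGG": 1.2,
    "GGT": 24.7, "GGC": 29.6, "GGA": 8.0, "GGG": 11.1,
}

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: amino acid (one-letter) -> list of codons, standard table, stops under '*'
_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in _STANDARD.forward_table.items():
    _AA_TO_CODONS.setdefault(aa, []).append(codon)
_AA_TO_CODONS["*"] = sorted(_STANDARD.stop_codons)


def synonymous_codons(amino_acid: str) -> list[str]:
    """Codons encoding a one-letter amino acid ('*' for stop), sorted."""
    try:
        return sorted(_AA_TO_CODONS[amino_acid.upper()])
    except KeyError:
        raise KeyError(f"unknown amino acid {amino_acid!r}") from None


def sample_codon(
    amino_acid: str,
    usage: Mapping[str, float],
    rng: np.random.Generator,
) -> str:
    """Draw one codon for an amino acid with usage-weighted probability."""
    codons = synonymous_codons(amino_acid)
    weights = np.array([usage.get(c, 0.0) for c in codons], dtype=float)
    if weights.sum() <= 0:
        raise ValueError(f"no usage weight for any codon of {amino_acid!r}")
    return codons[rng.choice(len(codons), p=weights / weights.sum())]


def translate_dna(seq: str) -> str:
    """Translate a DNA string (length divisible by 3) with the standard table."""
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3].upper()
        if codon in _STANDARD.stop_codons:
            out.append("*")
        else:
            out.append(_STANDARD.forward_table[codon])
    return "".join(out)
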