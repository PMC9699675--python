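"""Small sequence helpers shared across the pipeline.

Conventions: 3'UTRs and octamers are DNA (T), mature miRNAs are RNA (U).
All coordinates are 0-based, half-open, on the sense strand.
"""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = "ACGT"
RNA_ALPHABET = "ACGU"

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_RNA_TO_DNA = str.maketrans("Uu", "Tt")
_DNA_TO_RNA = str.maketrans("Tt", "Uu")


def rna_to_dna(seq: str) -> str:
    """U -> T."""
    return seq.translate(_RNA_TO_DNA)


def dna_to_rna(seq: str) -> str:
    """T -> U."""
    return seq.translate(_DNA_TO_RNA)


def reverse_complement_dna(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complementary)."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def reverse_complement_rna_to_dna(seq: str) -> str:
    """Reverse complement of an RNA string, written in the DNA alphabet."""
    return reverse_complement_dna(rna_to_dna(seq))


def random_seq(rng: np.random.Generator, length: int, alphabet: str = DNA_ALPHABET) -> str:
    return "".join(np.asarray(list(alphabet))[rng.integers(0, len(alphabet), size=length)])


def dinucleotide_counts(seq: str) -> dict[str, int]:
    """Multiset of overlapping dinucleotides."""
    counts: dict[str, int] = {}
    for i in range(len(seq) - 1):
        d = seq[i : i + 2]
        counts[d] = counts.get(d, 0) + 1
    return counts


def validate_alphabet(seq: str, alphabet: str, what: str = "sequence") -> None:
    bad = set(seq) - set(alphabet)
    if bad:
        raise ValueError(f"{what} contains characters outside {alphabet}: {sorted(bad)}")
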