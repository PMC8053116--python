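"""Genetic-code constants and built-in codon groups."""

from __future__ import annotations

BASES = "ACGT"

STOP_CODONS: frozenset[str] = frozenset({"TAA", "TAG", "TGA"})

ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES
)

#: The 61 sense codons, alphabetical.
SENSE_CODONS: tuple[str, ...] = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

START_CODON = "ATG"

ARG_CODONS: frozenset[str] = frozenset({"CGT", "CGC", "CGA", "CGG", "AGA", "AGG"})
GLN_CODONS: frozenset[str] = frozenset({"CAA", "CAG"})

#: Built-in codon groups used for pause-fraction and occupancy summaries.
DEFAULT_CODON_GROUPS: dict[str, frozenset[str]] = {
    "Arg": ARG_CODONS,
    "Gln": GLN_CODONS,
}


def is_sense(codon: str) -> bool:
    return codon in _SENSE_SET


_SENSE_SET = frozenset(SENSE_CODONS)
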