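"""Small shared sequence helpers (RNA alphabet internally, U not T)."""

from __future__ import annotations

_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")
_TO_RNA = str.maketrans("Tt", "Uu")
_TO_DNA = str.maketrans("Uu", "Tt")
_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_RNA = frozenset("ACGUN")


def normalize_rna(seq: str) -> str:
    """Upper-case and convert T->U."""
    return seq.upper().translate(_TO_RNA)


def to_dna(seq: str) -> str:
    return seq.upper().translate(_TO_DNA)


def reverse_complement_rna(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


def reverse_complement_dna(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]
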