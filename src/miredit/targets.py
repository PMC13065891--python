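"""Canonical seed-site target prediction and edited-vs-unedited rewiring.

Edited mature sequences replace inosine with guanosine (I:C pairs like G:C
for hybridization), canonical 3'UTR sites (8mer, 7mer-m8, 7mer-A1) are
located by exact matching, and rewiring is summarized as the Jaccard overlap
of the unedited and edited target sets. Editing positions are also annotated
by functional domain of the mature sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from miredit._seq import normalize_rna, reverse_complement_rna

SITE_TYPE_PRIORITY = ("8mer", "7mer-m8", "7mer-A1")

# Functional domains of a mature miRNA: (first position, last position, name).
_DOMAINS = (
    (1, 1, "5p_anchor"),
    (2, 8, "seed"),
    (9, 12, "central"),
    (13, 16, "supplementary_3p"),
    (17, None, "tail_3p"),
)


@dataclass(frozen=True)
class TargetSite:
    """One canonical site match in a 3'UTR (1-based start)."""

    utr_id: str
    site_type: str
    utr_pos: int


@dataclass(frozen=True)
class DomainAnnotation:
    mature_pos: int
    domain: str


def edited_mature(mature_seq: str, mature_pos: int) -> str:
    """Single A->G substitution at a 1-based mature position."""
    seq = normalize_rna(mature_seq)
    if not 1 <= mature_pos <= len(seq):
        raise ValueError(f"position {mature_pos} outside mature sequence of length {len(seq)}")
    if seq[mature_pos - 1] != "A":
        raise ValueError(
            f"base at mature position {mature_pos} is {seq[mature_pos - 1]}, not A"
        )
    return seq[: mature_pos - 1] + "G" + seq[mature_pos:]


def seed_site_patterns(mature_seq: str) -> dict[str, str]:
    """Canonical target-site patterns for a mature miRNA, 5'->3' in the UTR.

    7mer-m8 is the reverse complement of miRNA nts 2-8; 7mer-A1 is the
    reverse complement of nts 2-7 followed by A; 8mer is 7mer-m8 followed by
    A.
    """
    seq = normalize_rna(mature_seq)
    if len(seq) < 8:
        raise ValueError(f"mature sequence too short for seed patterns: {len(seq)} < 8")
    m8 = reverse_complement_rna(seq[1:8])  # nts 2-8
    a1 = reverse_complement_rna(seq[1:7]) + "A"  # nts 2-7 then target A
    return {"8mer": m8 + "A", "7mer-m8": m8, "7mer-A1": a1}


def scan_utrs(
    patterns: Mapping[str, str], utrs: Mapping[str, str]
) -> tuple[list[TargetSite], set[str]]:
    """Find all canonical sites in a set of 3'UTRs.

    An occurrence matching the 8mer is reported once as 8mer; the 7mer
    sub-matches it implies (7mer-m8 at the same start, 7mer-A1 one position
    downstream) are suppressed. Returns the site list plus the distinct set
    of utr ids with at least one site (the target-gene set).
    """
    sites: list[TargetSite] = []
    for utr_id in sorted(utrs):
        seq = normalize_rna(utrs[utr_id])
        claimed: set[tuple[str, int]] = set()
        for site_type in SITE_TYPE_PRIORITY:
            pattern = patterns[site_type]
            start = seq.find(pattern)
            while start != -1:
                pos = start + 1  # 1-based
                if (site_type, pos) not in claimed:
                    sites.append(TargetSite(utr_id=utr_id, site_type=site_type, utr_pos=pos))
                    if site_type == "8mer":
                        claimed.add(("7mer-m8", pos))
                        claimed.add(("7mer-A1", pos + 1))
                start = seq.find(pattern, start + 1)
    gene_set = {s.utr_id for s in sites}
    return sites, gene_set


def target_overlap(set_unedited: Iterable[str], set_edited: Iterable[str]) -> float:
    """Jaccard overlap |A n B| / |A u B|; 0.0 when both sets are empty."""
    a, b = set(set_unedited), set(set_edited)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def retained_fraction(set_unedited: Iterable[str], set_edited: Iterable[str]) -> float:
    """Alternative rewiring metric: fraction of unedited targets retained."""
    a, b = set(set_unedited), set(set_edited)
    if not a:
        return 0.0
    return len(a & b) / len(a)


def annotate_domain(mature_pos: int) -> DomainAnnotation:
    """Functional-domain label for a 1-based mature position.

    nt 1 is the 5' anchor, nts 2-8 the seed, 9-12 the central region, 13-16
    the 3' supplementary region, and 17 onward the 3' tail.
    """
    if mature_pos < 1:
        raise ValueError(f"mature position must be >= 1, got {mature_pos}")
    for lo, hi, name in _DOMAINS:
        if mature_pos >= lo and (hi is None or mature_pos <= hi):
            return DomainAnnotation(mature_pos=mature_pos, domain=name)
    raise AssertionError("unreachable")
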