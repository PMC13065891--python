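"""Two-pass, no-mismatch assignment of reads to hairpin references.

Pass 1 matches each collapsed read as an exact full-length substring of an
unedited hairpin. Only reads unmatched in pass 1 are tried against the
single-site edited references, and an edited hit counts only if the read's
match interval covers the substituted position — otherwise the read carries
no editing evidence and is re-routed to unedited status. Optionally, edited
reads whose sequence occurs perfectly in a supplied genome (either strand,
DNA alphabet) are demoted to unassigned.

Exact full-length substring matching implements the paper-pipeline contract
of no-mismatch BLAST alignment: with zero mismatches and full query
containment the two are equivalent, and exact matching is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from miredit._seq import reverse_complement_dna, to_dna
from miredit.preprocess import CollapsedRead
from miredit.references import EditedReference, PreMiRNA

logger = logging.getLogger(__name__)

ARM_TOLERANCE = 2  # nt of slack on either side of a mature arm for attribution


@dataclass(frozen=True)
class Hit:
    """One exact placement of a read on a reference (1-based start)."""

    reference_id: str
    start: int
    site_id: str | None = None
    mature_id: str | None = None

    def end(self, read_length: int) -> int:
        return self.start + read_length - 1


@dataclass
class Assignment:
    """Outcome of two-pass assignment for one collapsed read."""

    read: CollapsedRead
    status: str  # "unedited" | "edited" | "unassigned"
    hits: list[Hit] = field(default_factory=list)
    reason: str | None = None

    @property
    def read_sequence(self) -> str:
        return self.read.sequence

    @property
    def weight(self) -> float:
        """Per-hit multi-mapping weight (1/k over hits)."""
        return 1.0 / len(self.hits) if self.hits else 0.0


class SubstringIndex:
    """Exact substring lookup for short queries over a reference set.

    Indexes every window of each reference whose length lies in
    [min_len, max_len]; lookup is a single dict probe, O(query length + hits).
    """

    def __init__(
        self,
        references: Mapping[str, str],
        *,
        min_len: int = 16,
        max_len: int = 25,
    ) -> None:
        self.min_len = min_len
        self.max_len = max_len
        self._table: dict[str, list[tuple[str, int]]] = {}
        for ref_id, seq in references.items():
            n = len(seq)
            for length in range(min_len, max_len + 1):
                for start in range(n - length + 1):
                    window = seq[start : start + length]
                    self._table.setdefault(window, []).append((ref_id, start + 1))

    def lookup(self, query: str) -> list[tuple[str, int]]:
        """All (reference_id, start_1based) exact full-length placements."""
        return list(self._table.get(query, ()))


def build_index(
    references: Mapping[str, str], *, min_len: int = 16, max_len: int = 25
) -> SubstringIndex:
    if not references:
        raise ValueError("reference set must be non-empty")
    return SubstringIndex(references, min_len=min_len, max_len=max_len)


def assign_read(
    read: CollapsedRead,
    unedited_index: SubstringIndex,
    edited_index: SubstringIndex,
    edited_refs: Mapping[str, EditedReference],
) -> Assignment:
    """Two-pass assignment of one collapsed read.

    ``edited_index`` must be keyed by site_id; ``edited_refs`` maps site_id to
    its EditedReference (for the substituted position and hairpin id).
    """
    seq = read.sequence
    pass1 = unedited_index.lookup(seq)
    if pass1:
        hits = [Hit(reference_id=r, start=s) for r, s in sorted(pass1)]
        return Assignment(read=read, status="unedited", hits=hits)

    pass2 = edited_index.lookup(seq)
    covering: list[Hit] = []
    rerouted: list[Hit] = []
    for site_id, start in sorted(pass2):
        ref = edited_refs[site_id]
        end = start + len(seq) - 1
        if start <= ref.pre_pos <= end:
            covering.append(Hit(reference_id=ref.pre_id, start=start, site_id=site_id))
        else:
            rerouted.append(Hit(reference_id=ref.pre_id, start=start))
    if covering:
        return Assignment(read=read, status="edited", hits=covering)
    if rerouted:
        # Match does not span the substituted base: identical to the unedited
        # hairpin over the matched interval, so no editing evidence.
        unique = sorted({(h.reference_id, h.start) for h in rerouted})
        hits = [Hit(reference_id=r, start=s) for r, s in unique]
        return Assignment(read=read, status="unedited", hits=hits, reason="rerouted")
    return Assignment(read=read, status="unassigned", reason="no_match")


def assign_reads(
    reads: Iterable[CollapsedRead],
    refs: Sequence[PreMiRNA],
    edited: Sequence[EditedReference],
    *,
    min_len: int = 16,
    max_len: int = 25,
) -> list[Assignment]:
    """Build both indexes and assign every collapsed read."""
    unedited_index = SubstringIndex(
        {r.id: r.sequence for r in refs}, min_len=min_len, max_len=max_len
    )
    edited_index = SubstringIndex(
        {e.site_id: e.sequence for e in edited}, min_len=min_len, max_len=max_len
    )
    edited_by_site = {e.site_id: e for e in edited}
    return [assign_read(c, unedited_index, edited_index, edited_by_site) for c in reads]


def exclude_genome_matchers(
    assignments: Iterable[Assignment],
    genome: Mapping[str, str] | None,
) -> list[Assignment]:
    """Demote edited reads whose sequence perfectly matches the genome.

    Both strands are checked in the DNA alphabet. With no genome supplied the
    stage is skipped with a warning and every assignment is retained.
    """
    assignments = list(assignments)
    if genome is None:
        logger.warning("no genome provided: perfect-match exclusion skipped")
        return assignments
    haystack = "#".join(g.upper() for g in genome.values())
    out: list[Assignment] = []
    for a in assignments:
        if a.status == "edited":
            dna = to_dna(a.read_sequence)
            if dna in haystack or reverse_complement_dna(dna) in haystack:
                out.append(
                    Assignment(read=a.read, status="unassigned", hits=[], reason="genomic")
                )
                continue
        out.append(a)
    return out


def attribute_mature(
    assignment: Assignment, refs_by_id: Mapping[str, PreMiRNA]
) -> list[tuple[str, float]]:
    """Attribute an assigned read to mature arm(s) with fractional weights.

    A hit is attributed to a mature arm when its interval lies within
    [arm.start - 2, arm.end + 2]. A read attributed to k distinct mature ids
    across references contributes weight 1/k to each.
    """
    if assignment.status == "unassigned":
        raise ValueError("cannot attribute an unassigned read")
    read_len = len(assignment.read_sequence)
    mature_ids: set[str] = set()
    for hit in assignment.hits:
        pre = refs_by_id[hit.reference_id]
        end = hit.end(read_len)
        for arm in pre.mature_arms:
            if hit.start >= arm.start - ARM_TOLERANCE and end <= arm.end + ARM_TOLERANCE:
                mature_ids.add(arm.mature_id)
    if not mature_ids:
        return []
    w = 1.0 / len(mature_ids)
    return [(mid, w) for mid in sorted(mature_ids)]


def count_mapped_16_25(
    assignments: Iterable[Assignment], *, min_len: int = 16, max_len: int = 25
) -> int:
    """Multiplicity-expanded count of assigned reads in the 16-25 nt window."""
    total = 0
    for a in assignments:
        if a.status in ("unedited", "edited") and min_len <= len(a.read_sequence) <= max_len:
            total += a.read.count
    return total
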