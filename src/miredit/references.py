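"""Hairpin reference database: loading, validation, and edited variants.

Mature-arm coordinates are 1-based inclusive in all I/O, matching the
annotation TSV dialect. Known editing sites must sit on an A in the hairpin;
each validated site yields exactly one single-substitution (A->G) edited
reference. Multi-site co-edited haplotypes are deliberately not enumerated.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from miredit._seq import VALID_RNA, normalize_rna

MIN_HAIRPIN_LEN = 40
MAX_HAIRPIN_LEN = 200
MIN_ARM_LEN = 15
MAX_ARM_LEN = 30


class ReferenceError(ValueError):
    """Raised for malformed reference inputs (duplicate ids, bad intervals...)."""


@dataclass(frozen=True)
class MatureArm:
    """A mature miRNA interval within its hairpin (1-based inclusive)."""

    mature_id: str
    start: int
    end: int
    arm: str  # "5p" | "3p"

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise ReferenceError(f"{self.mature_id}: arm must be 5p or 3p, got {self.arm!r}")
        if self.start > self.end:
            raise ReferenceError(f"{self.mature_id}: start {self.start} > end {self.end}")
        length = self.end - self.start + 1
        if not MIN_ARM_LEN <= length <= MAX_ARM_LEN:
            raise ReferenceError(
                f"{self.mature_id}: mature arm length {length} outside "
                f"[{MIN_ARM_LEN}, {MAX_ARM_LEN}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PreMiRNA:
    """A pre-miRNA hairpin with its annotated mature arm(s)."""

    id: str
    sequence: str
    mature_arms: tuple[MatureArm, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        seq = normalize_rna(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if not MIN_HAIRPIN_LEN <= len(seq) <= MAX_HAIRPIN_LEN:
            raise ReferenceError(
                f"{self.id}: hairpin length {len(seq)} outside "
                f"[{MIN_HAIRPIN_LEN}, {MAX_HAIRPIN_LEN}]"
            )
        bad = set(seq) - VALID_RNA
        if bad:
            raise ReferenceError(f"{self.id}: invalid bases {sorted(bad)}")
        arms = tuple(self.mature_arms)
        object.__setattr__(self, "mature_arms", arms)
        seen_arm_labels: set[str] = set()
        for arm in arms:
            if arm.start < 1 or arm.end > len(seq):
                raise ReferenceError(
                    f"{self.id}/{arm.mature_id}: interval [{arm.start}, {arm.end}] "
                    f"outside hairpin of length {len(seq)}"
                )
            if arm.arm in seen_arm_labels:
                raise ReferenceError(f"{self.id}: more than one {arm.arm} arm")
            seen_arm_labels.add(arm.arm)

    def arm_sequence(self, arm: MatureArm) -> str:
        return self.sequence[arm.start - 1 : arm.end]

    def get_arm(self, mature_id: str) -> MatureArm:
        for arm in self.mature_arms:
            if arm.mature_id == mature_id:
                return arm
        raise KeyError(mature_id)


@dataclass(frozen=True)
class KnownEditSite:
    """A catalogued A-to-I editing position within a mature arm.

    ``mature_pos`` is 1-based within the mature arm; ``pre_pos`` is the derived
    1-based position within the hairpin (arm.start + mature_pos - 1).
    """

    site_id: str
    pre_id: str
    mature_id: str
    mature_pos: int
    pre_pos: int
    ref_base: str = "A"

    def __post_init__(self) -> None:
        if self.ref_base != "A":
            raise ReferenceError(f"{self.site_id}: reference base must be A")


@dataclass(frozen=True)
class EditedReference:
    """A hairpin variant carrying G instead of A at one editing position."""

    site_id: str
    pre_id: str
    sequence: str
    pre_pos: int


def _read_tsv(path: Path | str, required: list[str]) -> list[dict[str, str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ReferenceError(f"{path}: empty file, header row required")
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise ReferenceError(f"{path}: missing required columns {missing}")
        return [row for row in reader]


def load_references(premirna_fasta: Path | str, mature_tsv: Path | str) -> list[PreMiRNA]:
    """Load hairpin FASTA plus mature-arm TSV into validated records.

    T is normalized to U and sequences are upper-cased. Duplicate FASTA ids,
    mature rows referencing unknown hairpins, and out-of-bounds intervals are
    hard errors naming the offending record.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(premirna_fasta), "fasta"):
        if rec.id in sequences:
            raise ReferenceError(f"duplicate hairpin id {rec.id!r} in {premirna_fasta}")
        sequences[rec.id] = normalize_rna(str(rec.seq))
    if not sequences:
        raise ReferenceError(f"{premirna_fasta}: no FASTA records")

    arms_by_pre: dict[str, list[MatureArm]] = {pid: [] for pid in sequences}
    for row in _read_tsv(mature_tsv, ["pre_id", "mature_id", "start", "end", "arm"]):
        pre_id = row["pre_id"]
        if pre_id not in sequences:
            raise ReferenceError(
                f"mature record {row['mature_id']!r} references unknown hairpin {pre_id!r}"
            )
        arms_by_pre[pre_id].append(
            MatureArm(
                mature_id=row["mature_id"],
                start=int(row["start"]),
                end=int(row["end"]),
                arm=row["arm"],
            )
        )
    return [
        PreMiRNA(id=pid, sequence=seq, mature_arms=tuple(arms_by_pre[pid]))
        for pid, seq in sequences.items()
    ]


def load_sites(sites_tsv: Path | str, refs: Iterable[PreMiRNA]) -> list[KnownEditSite]:
    """Load and validate the known editing-site table against the references.

    Derives pre_pos from the mature-arm start and checks that the hairpin base
    there is A; anything else is a hard error listing the site id.
    """
    by_id = {r.id: r for r in refs}
    sites: list[KnownEditSite] = []
    seen: set[str] = set()
    for row in _read_tsv(sites_tsv, ["site_id", "pre_id", "mature_id", "mature_pos"]):
        site_id = row["site_id"]
        if site_id in seen:
            raise ReferenceError(f"duplicate site id {site_id!r}")
        seen.add(site_id)
        pre = by_id.get(row["pre_id"])
        if pre is None:
            raise ReferenceError(f"site {site_id!r}: unknown hairpin {row['pre_id']!r}")
        try:
            arm = pre.get_arm(row["mature_id"])
        except KeyError:
            raise ReferenceError(
                f"site {site_id!r}: unknown mature id {row['mature_id']!r} on {pre.id}"
            ) from None
        mature_pos = int(row["mature_pos"])
        if not 1 <= mature_pos <= arm.length:
            raise ReferenceError(
                f"site {site_id!r}: mature_pos {mature_pos} outside arm of length {arm.length}"
            )
        pre_pos = arm.start + mature_pos - 1
        base = pre.sequence[pre_pos - 1]
        if base != "A":
            raise ReferenceError(
                f"site {site_id!r}: hairpin base at position {pre_pos} is {base}, not A"
            )
        sites.append(
            KnownEditSite(
                site_id=site_id,
                pre_id=pre.id,
                mature_id=row["mature_id"],
                mature_pos=mature_pos,
                pre_pos=pre_pos,
            )
        )
    return sites


def build_edited_references(
    refs: Iterable[PreMiRNA], sites: Iterable[KnownEditSite]
) -> list[EditedReference]:
    """One single-substitution A->G hairpin variant per known site."""
    by_id = {r.id: r for r in refs}
    out: list[EditedReference] = []
    bad: list[str] = []
    for site in sites:
        pre = by_id[site.pre_id]
        idx = site.pre_pos - 1
        if pre.sequence[idx] != "A":
            bad.append(site.site_id)
            continue
        edited = pre.sequence[:idx] + "G" + pre.sequence[idx + 1 :]
        out.append(
            EditedReference(
                site_id=site.site_id, pre_id=site.pre_id, sequence=edited, pre_pos=site.pre_pos
            )
        )
    if bad:
        raise ReferenceError(f"sites not on an A base: {bad}")
    return out
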