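"""Read-level QC, 3' A/U trimming, collapsing, and dataset-level gates.

Stage order: per-read filter (N-count, 15-25 nt QC window, mean Phred) ->
3' A/U trim (max 2 bases) -> collapse identical sequences -> final 16-25 nt
retention gate. Trimming is applied before collapsing so that 3'-tailed
variants of the same molecule merge into one collapsed read.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from miredit._seq import normalize_rna

# Per-read gate defaults (drop if violated).
MAX_N_COUNT = 5
QC_MIN_LEN = 15
QC_MAX_LEN = 25
MIN_MEAN_PHRED = 20.0  # mean quality <= 20 drops (boundary inclusive)
FINAL_MIN_LEN = 16
FINAL_MAX_LEN = 25

# Dataset gate defaults.
MIN_CLEAN_READS = 1_000_000
MIN_FRACTION_BASES_RETAINED = 0.60
MIN_MAPPED_16_25 = 100_000


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read, RNA alphabet, Sanger Phred qualities."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"{self.read_id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )


@dataclass(frozen=True)
class CollapsedRead:
    """A unique post-trim sequence with its multiplicity.

    ``mean_base_quality`` holds the per-position arithmetic mean Phred score
    across the collapsed duplicates.
    """

    sequence: str
    count: int
    mean_base_quality: tuple[float, ...]


@dataclass
class DatasetQC:
    """Per-dataset accounting and the three retention gates."""

    total_raw_reads: int = 0
    clean_reads: int = 0
    total_raw_bases: int = 0
    retained_bases: int = 0
    mapped_16_25_reads: int = 0
    drop_reasons: dict[str, int] = field(default_factory=dict)
    min_clean_reads: int = MIN_CLEAN_READS
    min_fraction_bases_retained: float = MIN_FRACTION_BASES_RETAINED
    min_mapped_16_25: int = MIN_MAPPED_16_25

    @property
    def fraction_bases_retained(self) -> float:
        if self.total_raw_bases == 0:
            return 0.0
        return self.retained_bases / self.total_raw_bases

    @property
    def passes(self) -> bool:
        return (
            self.clean_reads >= self.min_clean_reads
            and self.fraction_bases_retained >= self.min_fraction_bases_retained
            and self.mapped_16_25_reads >= self.min_mapped_16_25
        )

    def to_dict(self) -> dict:
        return {
            "total_raw_reads": self.total_raw_reads,
            "clean_reads": self.clean_reads,
            "total_raw_bases": self.total_raw_bases,
            "retained_bases": self.retained_bases,
            "fraction_bases_retained": self.fraction_bases_retained,
            "mapped_16_25_reads": self.mapped_16_25_reads,
            "drop_reasons": dict(self.drop_reasons),
            "pass": self.passes,
        }

    def write_json(self, path: Path | str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def write_tsv(self, path: Path | str) -> None:
        d = self.to_dict()
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("metric\tvalue\n")
            for key in sorted(d):
                if key == "drop_reasons":
                    for reason in sorted(d[key]):
                        fh.write(f"dropped_{reason}\t{d[key][reason]}\n")
                else:
                    fh.write(f"{key}\t{d[key]}\n")


def filter_read(
    read: ReadRecord,
    *,
    max_n: int = MAX_N_COUNT,
    min_len: int = QC_MIN_LEN,
    max_len: int = QC_MAX_LEN,
    min_mean_quality: float = MIN_MEAN_PHRED,
) -> str | None:
    """Return None to keep the read, or the drop reason.

    Drops reads with more than ``max_n`` ambiguous bases, lengths outside
    [min_len, max_len], or mean Phred <= ``min_mean_quality`` (inclusive).
    """
    n = len(read.sequence)
    if n < min_len or n > max_len:
        return "length"
    if read.sequence.count("N") > max_n:
        return "ambiguous"
    if sum(read.qualities) / n <= min_mean_quality:
        return "quality"
    return None


def trim_three_prime_au(sequence: str) -> str:
    """Remove up to two 3'-terminal bases, each only if it is A or U.

    The rule is iterative: the terminal base is inspected and removed if A/U,
    then the new terminal base likewise, for at most two removals total.
    """
    for _ in range(2):
        if sequence and sequence[-1] in "AU":
            sequence = sequence[:-1]
        else:
            break
    return sequence


def trim_read(read: ReadRecord) -> ReadRecord:
    """Apply 3' A/U trimming to a read, keeping qualities in register."""
    trimmed = trim_three_prime_au(read.sequence)
    if len(trimmed) == len(read.sequence):
        return read
    return replace(read, sequence=trimmed, qualities=read.qualities[: len(trimmed)])


def collapse(reads: Iterable[ReadRecord]) -> list[CollapsedRead]:
    """Collapse identical sequences, averaging per-position qualities.

    Output is sorted by (-count, sequence) for deterministic downstream
    ordering; total multiplicity is conserved.
    """
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for read in reads:
        seq = read.sequence
        if seq in counts:
            counts[seq] += 1
            sums[seq] += np.asarray(read.qualities, dtype=np.float64)
        else:
            counts[seq] = 1
            sums[seq] = np.asarray(read.qualities, dtype=np.float64)
    out = [
        CollapsedRead(
            sequence=seq,
            count=counts[seq],
            mean_base_quality=tuple(sums[seq] / counts[seq]),
        )
        for seq in counts
    ]
    out.sort(key=lambda c: (-c.count, c.sequence))
    return out


def length_gate_final(
    collapsed: CollapsedRead, *, min_len: int = FINAL_MIN_LEN, max_len: int = FINAL_MAX_LEN
) -> bool:
    """Final retention window after trimming and collapsing."""
    return min_len <= len(collapsed.sequence) <= max_len


def parse_fastq(path: Path | str) -> Iterator[ReadRecord]:
    """Stream a (possibly gzipped) Sanger FASTQ as RNA-alphabet ReadRecords."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt", encoding="utf-8") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            fh.readline()  # separator
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@"):
                raise ValueError(f"{path}: malformed FASTQ header {header!r}")
            yield ReadRecord(
                read_id=header[1:].split()[0],
                sequence=normalize_rna(seq),
                qualities=tuple(ord(c) - 33 for c in qual),
            )


def preprocess_reads(
    reads: Iterable[ReadRecord],
    *,
    max_n: int = MAX_N_COUNT,
    qc_min_len: int = QC_MIN_LEN,
    qc_max_len: int = QC_MAX_LEN,
    min_mean_quality: float = MIN_MEAN_PHRED,
    final_min_len: int = FINAL_MIN_LEN,
    final_max_len: int = FINAL_MAX_LEN,
    qc: DatasetQC | None = None,
) -> tuple[list[CollapsedRead], DatasetQC]:
    """Run filter -> trim -> collapse -> final length gate over a read stream.

    Returns the retained collapsed reads and the dataset QC accounting (clean
    read and base counters filled; the mapped-read counter is filled by the
    alignment stage).
    """
    if qc is None:
        qc = DatasetQC()
    kept: list[ReadRecord] = []
    for read in reads:
        qc.total_raw_reads += 1
        qc.total_raw_bases += len(read.sequence)
        reason = filter_read(
            read,
            max_n=max_n,
            min_len=qc_min_len,
            max_len=qc_max_len,
            min_mean_quality=min_mean_quality,
        )
        if reason is not None:
            qc.drop_reasons[reason] = qc.drop_reasons.get(reason, 0) + 1
            continue
        kept.append(trim_read(read))

    collapsed = collapse(kept)
    retained: list[CollapsedRead] = []
    for c in collapsed:
        if length_gate_final(c, min_len=final_min_len, max_len=final_max_len):
            retained.append(c)
            qc.clean_reads += c.count
            qc.retained_bases += c.count * len(c.sequence)
        else:
            qc.drop_reasons["final_length"] = qc.drop_reasons.get("final_length", 0) + c.count
    return retained, qc


def preprocess_fastq(path: Path | str, **kwargs) -> tuple[list[CollapsedRead], DatasetQC]:
    """Convenience wrapper: preprocess straight from a FASTQ file."""
    return preprocess_reads(parse_fastq(path), **kwargs)
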