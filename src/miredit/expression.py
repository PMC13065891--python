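"""Mature-miRNA expression in reads per million (RPM), plus a batch hook.

RPM = (mature-attributed mapped reads / total mapped reads) x 1e6, where the
denominator is the weighted sum of reads attributed to any mature arm in the
sample. Records with RPM below 10 are flagged as not retained. Batch
correction is delegated to an injectable ComBat-compatible callable; the
built-in fallback performs only a per-batch location (mean) adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from miredit.align import Assignment, attribute_mature
from miredit.references import PreMiRNA

logger = logging.getLogger(__name__)

MIN_RPM = 10.0


@dataclass(frozen=True)
class ExpressionRecord:
    sample_id: str
    mature_id: str
    mapped_reads: float
    rpm: float
    retained: bool


def compute_rpm(
    assignments: Iterable[Assignment],
    refs: Sequence[PreMiRNA],
    sample_id: str,
    *,
    min_rpm: float = MIN_RPM,
) -> list[ExpressionRecord]:
    """Per-mature-miRNA RPM for one sample from attributed assignments.

    Counts are multiplicity-expanded and fractionally weighted for
    multi-mapping reads; before the retention filter the RPM values sum to
    1e6. Zero mapped reads is a hard error naming the sample.
    """
    refs_by_id = {r.id: r for r in refs}
    counts: dict[str, float] = {}
    for a in assignments:
        if a.status == "unassigned":
            continue
        for mature_id, weight in attribute_mature(a, refs_by_id):
            counts[mature_id] = counts.get(mature_id, 0.0) + a.read.count * weight
    total = sum(counts.values())
    if total <= 0:
        raise ValueError(f"sample {sample_id!r}: no reads mapped to any mature arm")
    records = [
        ExpressionRecord(
            sample_id=sample_id,
            mature_id=mature_id,
            mapped_reads=mapped,
            rpm=(rpm := mapped / total * 1e6),
            retained=rpm >= min_rpm,
        )
        for mature_id, mapped in sorted(counts.items())
    ]
    return records


def expression_matrix(records: Iterable[ExpressionRecord]) -> pd.DataFrame:
    """Samples x mature-miRNAs RPM matrix (absent combinations are 0)."""
    rows = [(r.sample_id, r.mature_id, r.rpm) for r in records]
    df = pd.DataFrame(rows, columns=["sample_id", "mature_id", "rpm"])
    return df.pivot_table(
        index="sample_id", columns="mature_id", values="rpm", fill_value=0.0
    ).sort_index()


def _mean_center_by_batch(matrix: pd.DataFrame, batches: pd.Series) -> pd.DataFrame:
    """Location-only adjustment: align each batch's column means to the grand mean."""
    grand = matrix.mean(axis=0)
    out = matrix.copy()
    for batch in batches.unique():
        idx = batches[batches == batch].index
        out.loc[idx] = matrix.loc[idx] - matrix.loc[idx].mean(axis=0) + grand
    return out


def batch_correct_hook(
    matrix: pd.DataFrame,
    batches: Mapping[str, str] | pd.Series,
    corrector: Callable[[pd.DataFrame, pd.Series], pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Batch-correct a samples x miRNAs expression matrix.

    ``corrector`` may be any ComBat-compatible callable taking (matrix,
    batch series) and returning a corrected matrix of identical shape; when
    omitted, a per-batch mean-centering fallback is used. A single batch is
    an identity pass-through with a warning; a sample without a batch label
    is an error.
    """
    batches = pd.Series(dict(batches) if not isinstance(batches, pd.Series) else batches)
    missing = [s for s in matrix.index if s not in batches.index or pd.isna(batches[s])]
    if missing:
        raise ValueError(f"samples missing batch labels: {missing}")
    batches = batches.loc[matrix.index]
    if batches.nunique() < 2:
        logger.warning("single batch: batch correction is an identity pass-through")
        return matrix.copy()
    counts = batches.value_counts()
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"batches with fewer than 2 samples: {list(small.index)}")
    if corrector is None:
        corrector = _mean_center_by_batch
    corrected = corrector(matrix, batches)
    if corrected.shape != matrix.shape:
        raise ValueError("batch corrector changed the matrix shape")
    return corrected
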