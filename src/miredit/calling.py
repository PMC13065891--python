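"""Per-sample editing quantification and significance calling.

For each known site the caller forms a weighted pileup over assigned reads,
computes the editing level (edited / coverage), tests the edited count
against a one-sided binomial sequencing-error null, applies
Benjamini-Hochberg correction across all covered sites of the sample, and
flags calls passing the >=2 edited reads / >=5% level / q<0.05 gates.
High-confidence sites are those passing in at least ten samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from miredit.align import Assignment
from miredit.references import KnownEditSite

logger = logging.getLogger(__name__)

MIN_SITE_BASE_QUALITY = 30.0  # G calls below this are masked out
MIN_EDITED_READS = 2.0
MIN_EDITING_LEVEL = 0.05
MAX_Q_VALUE = 0.05
MIN_HC_SAMPLES = 10
DEFAULT_EPSILON = 0.001
MIN_BASES_FOR_ESTIMATE = 10_000


@dataclass(frozen=True)
class SitePileup:
    """Weighted read support at one editing position."""

    site_id: str
    coverage: float
    edited_count: float

    def __post_init__(self) -> None:
        if not 0 <= self.edited_count <= self.coverage + 1e-9:
            raise ValueError(
                f"{self.site_id}: edited_count {self.edited_count} exceeds "
                f"coverage {self.coverage}"
            )


@dataclass(frozen=True)
class ErrorModel:
    """Probability that a true A is sequenced as G at a single base."""

    epsilon_AG: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if not 0 < self.epsilon_AG < 0.25:
            raise ValueError(f"epsilon_AG {self.epsilon_AG} outside (0, 0.25)")


@dataclass(frozen=True)
class EditingCall:
    sample_id: str
    site_id: str
    coverage: float
    edited_count: float
    level: float
    p_value: float
    q_value: float
    passes: bool


def pileup(
    assignments: Iterable[Assignment],
    site: KnownEditSite,
    *,
    min_site_quality: float = MIN_SITE_BASE_QUALITY,
) -> SitePileup:
    """Weighted pileup at one site from a single sample's assignments.

    Edited reads contribute only if their (collapsed mean) base quality at
    the substituted position is >= ``min_site_quality``; masked reads leave
    both numerator and denominator. Unedited reads covering the position
    always contribute to coverage. Multi-mapping reads contribute their
    fractional per-hit weight.
    """
    coverage = 0.0
    edited = 0.0
    for a in assignments:
        if a.status == "unedited":
            n_cover = sum(
                1
                for h in a.hits
                if h.reference_id == site.pre_id
                and h.start <= site.pre_pos <= h.end(len(a.read_sequence))
            )
            if n_cover:
                coverage += a.read.count * a.weight * n_cover
        elif a.status == "edited":
            site_hits = [h for h in a.hits if h.site_id == site.site_id]
            if not site_hits:
                continue
            n_sites = len({h.site_id for h in a.hits})
            w = a.read.count / n_sites
            for h in site_hits:
                offset = site.pre_pos - h.start  # 0-based index into the read
                if a.read.mean_base_quality[offset] >= min_site_quality:
                    coverage += w
                    edited += w
    return SitePileup(site_id=site.site_id, coverage=coverage, edited_count=edited)


def editing_level(p: SitePileup) -> float:
    """Edited fraction: edited_count / coverage (coverage must be > 0)."""
    if p.coverage <= 0:
        raise ValueError(f"{p.site_id}: editing level undefined at zero coverage")
    return p.edited_count / p.coverage


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def site_test(p: SitePileup, error_model: ErrorModel) -> float:
    """One-sided upper-tail binomial p-value against the error null.

    P[X >= edited | X ~ Binomial(coverage, epsilon_AG)], with fractional
    weighted counts rounded half-up to integers for the test only.
    """
    n = _round_half_up(p.coverage)
    k = min(_round_half_up(p.edited_count), n)
    if n < 1:
        raise ValueError(f"{p.site_id}: site test requires coverage >= 1")
    return float(stats.binom.sf(k - 1, n, error_model.epsilon_AG))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


def call_sites(
    pileups: Mapping[str, SitePileup],
    error_model: ErrorModel,
    sample_id: str,
    *,
    min_edited_reads: float = MIN_EDITED_READS,
    min_level: float = MIN_EDITING_LEVEL,
    max_q: float = MAX_Q_VALUE,
) -> list[EditingCall]:
    """Emit one call per site with coverage >= 1 in this sample.

    The BH correction universe is all covered candidate sites of the sample.
    Levels are reported for failing sites too (they feed the cohort matrix).
    """
    covered = [p for p in pileups.values() if p.coverage >= 1]
    covered.sort(key=lambda p: p.site_id)
    p_values = [site_test(p, error_model) for p in covered]
    q_values = bh_adjust(p_values)
    calls: list[EditingCall] = []
    for p, pv, qv in zip(covered, p_values, q_values):
        level = editing_level(p)
        passes = p.edited_count >= min_edited_reads and level >= min_level and qv < max_q
        calls.append(
            EditingCall(
                sample_id=sample_id,
                site_id=p.site_id,
                coverage=p.coverage,
                edited_count=p.edited_count,
                level=level,
                p_value=pv,
                q_value=qv,
                passes=passes,
            )
        )
    return calls


def aggregate_high_confidence(
    calls: Iterable[EditingCall],
    *,
    min_samples: int = MIN_HC_SAMPLES,
    min_edited_reads: float = MIN_EDITED_READS,
) -> list[tuple[str, int, float]]:
    """Cross-sample high-confidence sites.

    A site qualifies when it passes the per-sample gates, with at least
    ``min_edited_reads`` supporting reads, in at least ``min_samples``
    samples. Returns (site_id, n_samples_detected, mean_level) sorted by id.
    """
    per_site: dict[str, list[float]] = {}
    for call in calls:
        if call.passes and call.edited_count >= min_edited_reads:
            per_site.setdefault(call.site_id, []).append(call.level)
    out = [
        (site_id, len(levels), float(np.mean(levels)))
        for site_id, levels in per_site.items()
        if len(levels) >= min_samples
    ]
    out.sort(key=lambda t: t[0])
    return out


def estimate_error_rate(
    assignments: Iterable[Assignment],
    *,
    default_epsilon: float = DEFAULT_EPSILON,
    min_bases: int = MIN_BASES_FOR_ESTIMATE,
) -> ErrorModel:
    """Estimate the A->G miscall rate from Phred scores of aligned reads.

    epsilon_AG = mean per-base miscall probability 10^(-Q/10) across all
    aligned bases (multiplicity-weighted), divided by 3 for the uniform
    miscall-direction assumption. Falls back to ``default_epsilon`` with a
    warning when fewer than ``min_bases`` aligned bases are available.
    """
    total_bases = 0
    total_prob = 0.0
    for a in assignments:
        if a.status not in ("unedited", "edited"):
            continue
        quals = np.asarray(a.read.mean_base_quality, dtype=float)
        total_bases += a.read.count * quals.size
        total_prob += a.read.count * float(np.sum(10.0 ** (-quals / 10.0)))
    if total_bases < min_bases:
        logger.warning(
            "only %d aligned bases (< %d): using default epsilon %.2g",
            total_bases,
            min_bases,
            default_epsilon,
        )
        return ErrorModel(epsilon_AG=default_epsilon)
    return ErrorModel(epsilon_AG=total_prob / total_bases / 3.0)
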