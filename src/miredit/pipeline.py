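"""End-to-end orchestration: references -> QC -> align -> call -> express.

Every threshold of the method is a named RunConfig field with its published
default; stages write plain TSV artifacts into the run directory in a fixed
order so that re-running with identical inputs and seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from miredit import calling, cohort, expression, preprocess, targets
from miredit.align import (
    Assignment,
    assign_reads,
    attribute_mature,
    count_mapped_16_25,
    exclude_genome_matchers,
)
from miredit._seq import normalize_rna
from miredit.calling import ErrorModel
from miredit.references import (
    KnownEditSite,
    PreMiRNA,
    build_edited_references,
    load_references,
    load_sites,
)

logger = logging.getLogger(__name__)


class DatasetExcludedError(RuntimeError):
    """Raised when every input dataset fails the dataset-level QC gates."""


@dataclass
class RunConfig:
    """All pipeline inputs and thresholds (defaults are the published values)."""

    hairpin_fasta: str = ""
    mature_tsv: str = ""
    sites_tsv: str = ""
    metadata_tsv: str = ""  # columns: sample_id, fastq[, condition, batch]
    genome_fasta: str | None = None
    utr_fasta: str | None = None
    seed: int = 0

    # read-level gates
    max_n: int = 5
    qc_min_len: int = 15
    qc_max_len: int = 25
    min_mean_quality: float = 20.0
    final_min_len: int = 16
    final_max_len: int = 25

    # calling
    min_site_quality: float = 30.0
    min_edited_reads: float = 2.0
    min_level: float = 0.05
    max_q: float = 0.05
    epsilon: float | None = None  # None: estimate from Phred scores
    default_epsilon: float = 0.001

    # expression
    min_rpm: float = 10.0

    # cross-sample
    hc_min_samples: int = 10

    # dataset gates
    min_clean_reads: int = 1_000_000
    min_fraction_bases_retained: float = 0.60
    min_mapped_16_25: int = 100_000
    enforce_dataset_gates: bool = True

    # cohort
    healthy_label: str | None = None
    selection_p: float = 0.1
    pca_scale: bool = False

    _DEFAULTS_FROZEN = {
        "max_n": 5,
        "qc_min_len": 15,
        "qc_max_len": 25,
        "min_mean_quality": 20.0,
        "final_min_len": 16,
        "final_max_len": 25,
        "min_site_quality": 30.0,
        "min_edited_reads": 2.0,
        "min_level": 0.05,
        "max_q": 0.05,
        "min_rpm": 10.0,
        "hc_min_samples": 10,
        "min_clean_reads": 1_000_000,
        "min_fraction_bases_retained": 0.60,
        "min_mapped_16_25": 100_000,
        "selection_p": 0.1,
    }

    def __post_init__(self) -> None:
        for name, default in self._DEFAULTS_FROZEN.items():
            value = getattr(self, name)
            if value != default:
                logger.info("threshold override: %s = %r (default %r)", name, value, default)

    @classmethod
    def from_file(cls, path: Path | str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            if str(path).endswith((".yaml", ".yml")):
                import yaml

                data = yaml.safe_load(fh)
            else:
                data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class SampleResult:
    sample_id: str
    qc: preprocess.DatasetQC
    excluded: bool
    assignments: list[Assignment] = field(default_factory=list)
    calls: list[calling.EditingCall] = field(default_factory=list)
    expression: list[expression.ExpressionRecord] = field(default_factory=list)
    error_model: ErrorModel | None = None


def read_metadata(path: Path | str) -> list[dict[str, str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "sample_id" not in reader.fieldnames:
            raise ValueError(f"{path}: metadata TSV needs a sample_id column")
        return list(reader)


def load_genome(path: Path | str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def load_utrs(path: Path | str) -> dict[str, str]:
    return {rec.id: normalize_rna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def process_sample(
    sample_id: str,
    reads,
    refs: list[PreMiRNA],
    sites: list[KnownEditSite],
    config: RunConfig,
    genome: dict[str, str] | None = None,
) -> SampleResult:
    """Run one sample from raw reads to editing calls and expression."""
    edited = build_edited_references(refs, sites)
    collapsed, qc = preprocess.preprocess_reads(
        reads,
        max_n=config.max_n,
        qc_min_len=config.qc_min_len,
        qc_max_len=config.qc_max_len,
        min_mean_quality=config.min_mean_quality,
        final_min_len=config.final_min_len,
        final_max_len=config.final_max_len,
    )
    qc.min_clean_reads = config.min_clean_reads
    qc.min_fraction_bases_retained = config.min_fraction_bases_retained
    qc.min_mapped_16_25 = config.min_mapped_16_25
    if config.enforce_dataset_gates and qc.clean_reads < config.min_clean_reads:
        logger.warning("sample %s excluded: %d clean reads", sample_id, qc.clean_reads)
        return SampleResult(sample_id=sample_id, qc=qc, excluded=True)

    assignments = assign_reads(
        collapsed, refs, edited, min_len=config.final_min_len, max_len=config.final_max_len
    )
    assignments = exclude_genome_matchers(assignments, genome)
    qc.mapped_16_25_reads = count_mapped_16_25(
        assignments, min_len=config.final_min_len, max_len=config.final_max_len
    )
    if config.enforce_dataset_gates and not qc.passes:
        logger.warning("sample %s excluded by dataset QC gates", sample_id)
        return SampleResult(sample_id=sample_id, qc=qc, excluded=True)

    if config.epsilon is not None:
        error_model = ErrorModel(epsilon_AG=config.epsilon)
    else:
        error_model = calling.estimate_error_rate(
            assignments, default_epsilon=config.default_epsilon
        )
    pileups = {
        s.site_id: calling.pileup(assignments, s, min_site_quality=config.min_site_quality)
        for s in sites
    }
    calls = calling.call_sites(
        pileups,
        error_model,
        sample_id,
        min_edited_reads=config.min_edited_reads,
        min_level=config.min_level,
        max_q=config.max_q,
    )
    try:
        expr = expression.compute_rpm(assignments, refs, sample_id, min_rpm=config.min_rpm)
    except ValueError:
        expr = []
    return SampleResult(
        sample_id=sample_id,
        qc=qc,
        excluded=False,
        assignments=assignments,
        calls=calls,
        expression=expr,
        error_model=error_model,
    )


def _write_tsv(path: Path, rows: list[dict], columns: list[str]) -> None:
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, sep="\t", index=False)


_ASSIGNMENT_COLUMNS = [
    "read_sequence",
    "count",
    "status",
    "reference_id",
    "start",
    "mature_id",
    "site_id",
    "weight",
    "mean_base_quality",
]


def write_collapsed(path: Path | str, collapsed) -> None:
    rows = [
        {
            "sequence": c.sequence,
            "count": c.count,
            "mean_base_quality": ",".join(f"{q:.4f}" for q in c.mean_base_quality),
        }
        for c in collapsed
    ]
    _write_tsv(Path(path), rows, ["sequence", "count", "mean_base_quality"])


def read_collapsed(path: Path | str):
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        preprocess.CollapsedRead(
            sequence=row.sequence,
            count=int(row.count_),
            mean_base_quality=tuple(float(x) for x in row.mean_base_quality.split(",")),
        )
        for row in df.rename(columns={"count": "count_"}).itertuples()
    ]


def write_assignments(path: Path, result: SampleResult, refs_by_id) -> None:
    rows = []
    for a in result.assignments:
        mature = dict(attribute_mature(a, refs_by_id)) if a.status != "unassigned" else {}
        qual = ",".join(f"{q:.4f}" for q in a.read.mean_base_quality)
        if not a.hits:
            rows.append(
                {
                    "read_sequence": a.read_sequence,
                    "count": a.read.count,
                    "status": a.status,
                    "reference_id": "",
                    "start": "",
                    "mature_id": "",
                    "site_id": "",
                    "weight": "",
                    "mean_base_quality": qual,
                }
            )
            continue
        mature_str = ";".join(sorted(mature))
        for h in a.hits:
            rows.append(
                {
                    "read_sequence": a.read_sequence,
                    "count": a.read.count,
                    "status": a.status,
                    "reference_id": h.reference_id,
                    "start": h.start,
                    "mature_id": mature_str,
                    "site_id": h.site_id or "",
                    "weight": round(a.weight, 6),
                    "mean_base_quality": qual,
                }
            )
    _write_tsv(path, rows, _ASSIGNMENT_COLUMNS)


def read_assignments(path: Path | str) -> list[Assignment]:
    """Reconstruct assignments (reads, status, hits) from the stage TSV."""
    from miredit.align import Hit

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    grouped: dict[str, Assignment] = {}
    for row in df.itertuples(index=False):
        seq = row.read_sequence
        if seq not in grouped:
            read = preprocess.CollapsedRead(
                sequence=seq,
                count=int(row.count),
                mean_base_quality=tuple(
                    float(x) for x in row.mean_base_quality.split(",")
                ),
            )
            grouped[seq] = Assignment(read=read, status=row.status, hits=[])
        if row.reference_id:
            grouped[seq].hits.append(
                Hit(
                    reference_id=row.reference_id,
                    start=int(row.start),
                    site_id=row.site_id or None,
                )
            )
    return list(grouped.values())


def run(config: RunConfig, outdir: Path | str) -> dict[str, SampleResult]:
    """Execute the full stage graph and write all artifacts under ``outdir``.

    Returns per-sample results. Raises DatasetExcludedError when every
    dataset fails the QC gates (CLI exit code 2).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    refs = load_references(config.hairpin_fasta, config.mature_tsv)
    sites = load_sites(config.sites_tsv, refs)
    refs_by_id = {r.id: r for r in refs}
    sites_by_id = {s.site_id: s for s in sites}
    genome = load_genome(config.genome_fasta) if config.genome_fasta else None
    metadata = read_metadata(config.metadata_tsv)

    results: dict[str, SampleResult] = {}
    for row in metadata:
        sample_id = row["sample_id"]
        reads = preprocess.parse_fastq(row["fastq"])
        result = process_sample(sample_id, reads, refs, sites, config, genome)
        results[sample_id] = result
        result.qc.write_json(outdir / f"qc_{sample_id}.json")
        result.qc.write_tsv(outdir / f"qc_{sample_id}.tsv")
        if not result.excluded:
            write_assignments(outdir / f"assignments_{sample_id}.tsv", result, refs_by_id)

    # Calls across included samples.
    call_rows = []
    for sample_id, result in results.items():
        for c in result.calls:
            site = sites_by_id[c.site_id]
            call_rows.append(
                {
                    "sample_id": c.sample_id,
                    "site_id": c.site_id,
                    "mirna": site.mature_id,
                    "mature_pos": site.mature_pos,
                    "coverage": round(c.coverage, 6),
                    "edited_count": round(c.edited_count, 6),
                    "level": round(c.level, 6),
                    "p": c.p_value,
                    "q": c.q_value,
                    "passes": c.passes,
                }
            )
    _write_tsv(
        outdir / "calls.tsv",
        call_rows,
        ["sample_id", "site_id", "mirna", "mature_pos", "coverage", "edited_count", "level", "p", "q", "passes"],
    )

    all_calls = [c for r in results.values() for c in r.calls]
    hc = calling.aggregate_high_confidence(
        all_calls, min_samples=config.hc_min_samples, min_edited_reads=config.min_edited_reads
    )
    _write_tsv(
        outdir / "high_confidence.tsv",
        [
            {"site_id": s, "n_samples_detected": n, "mean_level": round(lvl, 6)}
            for s, n, lvl in hc
        ],
        ["site_id", "n_samples_detected", "mean_level"],
    )

    expr_rows = [
        {
            "sample_id": e.sample_id,
            "mature_id": e.mature_id,
            "mapped_reads": round(e.mapped_reads, 6),
            "rpm": round(e.rpm, 6),
            "retained": e.retained,
        }
        for r in results.values()
        for e in r.expression
    ]
    _write_tsv(
        outdir / "expression.tsv",
        expr_rows,
        ["sample_id", "mature_id", "mapped_reads", "rpm", "retained"],
    )

    all_expr = [e for r in results.values() for e in r.expression]
    if all_expr:
        matrix = expression.expression_matrix(all_expr)
        matrix.to_csv(outdir / "expression_matrix_raw.tsv", sep="\t")
        batches = {row["sample_id"]: row.get("batch", "") for row in metadata}
        if len({b for b in batches.values() if b}) >= 2:
            corrected = expression.batch_correct_hook(
                matrix, {s: b for s, b in batches.items() if s in matrix.index}
            )
            corrected.to_csv(outdir / "expression_matrix_corrected.tsv", sep="\t")

    # Target rewiring for each known site with a UTR set.
    if config.utr_fasta:
        utrs = load_utrs(config.utr_fasta)
        rewire_rows = []
        for s in sites:
            pre = refs_by_id[s.pre_id]
            arm = pre.get_arm(s.mature_id)
            mature_seq = pre.arm_sequence(arm)
            edited_seq = targets.edited_mature(mature_seq, s.mature_pos)
            _, genes_un = targets.scan_utrs(targets.seed_site_patterns(mature_seq), utrs)
            _, genes_ed = targets.scan_utrs(targets.seed_site_patterns(edited_seq), utrs)
            rewire_rows.append(
                {
                    "site_id": s.site_id,
                    "mirna": s.mature_id,
                    "mature_pos": s.mature_pos,
                    "domain": targets.annotate_domain(s.mature_pos).domain,
                    "n_targets_unedited": len(genes_un),
                    "n_targets_edited": len(genes_ed),
                    "overlap_jaccard": round(targets.target_overlap(genes_un, genes_ed), 6),
                }
            )
        _write_tsv(
            outdir / "target_rewiring.tsv",
            rewire_rows,
            ["site_id", "mirna", "mature_pos", "domain", "n_targets_unedited", "n_targets_edited", "overlap_jaccard"],
        )

    # Cohort analysis when conditions are annotated.
    conditions = {row["sample_id"]: row.get("condition", "") for row in metadata}
    have_conditions = len({c for c in conditions.values() if c}) >= 2
    if all_calls and have_conditions:
        m = cohort.matrix_from_calls(all_calls, conditions)
        m.levels.to_csv(outdir / "editing_matrix.tsv", sep="\t")
        if config.healthy_label:
            selected = cohort.select_sites(
                m, config.healthy_label, p_threshold=config.selection_p
            )
            _write_tsv(
                outdir / "selected_sites.tsv",
                [{"site_id": s} for s in selected],
                ["site_id"],
            )
            if len(selected) >= 2 and len(m.samples) >= 3:
                imputed = cohort.impute_missing(m, seed=config.seed)
                scores, loadings, evr = cohort.run_pca(
                    imputed, selected, scale=config.pca_scale
                )
                scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
                loadings.to_csv(outdir / "pca_loadings.tsv", sep="\t")
                pd.DataFrame(
                    {"component": [f"PC{i+1}" for i in range(len(evr))], "explained_variance_fraction": evr}
                ).to_csv(outdir / "pca_variance.tsv", sep="\t", index=False)

    if results and all(r.excluded for r in results.values()):
        raise DatasetExcludedError("all input datasets failed dataset-level QC gates")
    return results
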