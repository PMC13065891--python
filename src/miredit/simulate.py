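"""Synthetic fixture generation: references, genomes, UTRs, reads, truth.

Everything the pipeline consumes can be generated here deterministically
from a seed: hairpin references with annotated mature arms, known-site
tables placed on A bases, genomes embedding the hairpin loci (with optional
planted decoys identical to edited reads, to exercise genome exclusion),
random 3'UTR sets, and per-sample FASTQ read sets with read-level Bernoulli
editing, Phred-calibrated miscalls, and optional 3' A/U tailing. Truth
tables record the drawn editing counts for acceptance testing.

Editing is simulated per read (Bernoulli at the true level), matching the
binomial model the caller tests against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from miredit._seq import to_dna
from miredit.cohort import EditingMatrix
from miredit.preprocess import ReadRecord
from miredit.references import KnownEditSite, MatureArm, PreMiRNA, build_edited_references

_BASES = np.array(list("ACGU"))


@dataclass
class SimulationConfig:
    """Knobs for reference and read simulation. ``seed`` is mandatory."""

    seed: int
    n_hairpins: int = 10
    n_sites: int = 5
    n_samples: int = 1
    coverage: int = 1000  # reads per mature arm per sample
    editing_level: float = 0.1
    site_levels: Mapping[str, float] | None = None  # per-site overrides
    conditions: Mapping[str, int] | None = None  # condition -> n samples
    condition_shifts: Mapping[str, float] = field(default_factory=dict)
    phred_mean: float = 35.0
    phred_sd: float = 2.0
    miscall_rate: float | None = None  # None: derive per-base from drawn Phred
    tail_fraction: float = 0.0  # reads receiving a 1-2 nt 3' A/U tail
    ambiguous_fraction: float = 0.0  # reads with 6 N bases injected
    site_positions: Sequence[int] = (2, 5)  # mature positions, cycled over sites
    plant_edited_decoys: bool = False
    n_utrs: int = 50
    utr_length: int = 60

    def __post_init__(self) -> None:
        if not 0 <= self.editing_level <= 1:
            raise ValueError("editing_level must lie in [0, 1]")
        if self.conditions is not None and sum(self.conditions.values()) != self.n_samples:
            raise ValueError("condition sample counts must sum to n_samples")

    def sample_ids(self) -> list[str]:
        return [f"s{i:03d}" for i in range(self.n_samples)]

    def sample_conditions(self) -> dict[str, str]:
        ids = self.sample_ids()
        if self.conditions is None:
            return {s: "c0" for s in ids}
        out: dict[str, str] = {}
        i = 0
        for condition, n in self.conditions.items():
            for _ in range(n):
                out[ids[i]] = condition
                i += 1
        return out

    def true_level(self, site_id: str, condition: str) -> float:
        base = self.editing_level
        if self.site_levels is not None and site_id in self.site_levels:
            base = self.site_levels[site_id]
        return float(np.clip(base + self.condition_shifts.get(condition, 0.0), 0.0, 1.0))


@dataclass
class ReferenceBundle:
    """All simulated reference-side inputs, in memory plus TSV/FASTA writers."""

    refs: list[PreMiRNA]
    sites: list[KnownEditSite]
    genome: dict[str, str]  # DNA alphabet
    utrs: dict[str, str]  # RNA alphabet

    def write(self, outdir: Path | str) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "hairpin_fasta": outdir / "hairpins.fa",
            "mature_tsv": outdir / "mature.tsv",
            "sites_tsv": outdir / "sites.tsv",
            "genome_fasta": outdir / "genome.fa",
            "utr_fasta": outdir / "utrs.fa",
        }
        with open(paths["hairpin_fasta"], "w", encoding="utf-8") as fh:
            for r in self.refs:
                fh.write(f">{r.id}\n{r.sequence}\n")
        with open(paths["mature_tsv"], "w", encoding="utf-8") as fh:
            fh.write("pre_id\tmature_id\tstart\tend\tarm\n")
            for r in self.refs:
                for arm in r.mature_arms:
                    fh.write(f"{r.id}\t{arm.mature_id}\t{arm.start}\t{arm.end}\t{arm.arm}\n")
        with open(paths["sites_tsv"], "w", encoding="utf-8") as fh:
            fh.write("site_id\tpre_id\tmature_id\tmature_pos\n")
            for s in self.sites:
                fh.write(f"{s.site_id}\t{s.pre_id}\t{s.mature_id}\t{s.mature_pos}\n")
        with open(paths["genome_fasta"], "w", encoding="utf-8") as fh:
            for name, seq in self.genome.items():
                fh.write(f">{name}\n{seq}\n")
        with open(paths["utr_fasta"], "w", encoding="utf-8") as fh:
            for name, seq in self.utrs.items():
                fh.write(f">{name}\n{seq}\n")
        return paths


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def simulate_references(cfg: SimulationConfig) -> ReferenceBundle:
    """Generate hairpins, mature arms, sites, a genome, and 3'UTRs.

    Hairpins are flank + 5p arm + loop + 3p arm + flank (60-90 nt overall,
    arms 20-23 nt). Site j goes on the 5p arm of hairpin j mod n_hairpins at
    the (cycled) configured mature position, with an A forced there. The
    genome embeds every hairpin locus plus decoy sequence; with
    ``plant_edited_decoys`` the edited arm sequences are planted verbatim.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    refs: list[PreMiRNA] = []
    for i in range(cfg.n_hairpins):
        len5 = int(rng.integers(20, 24))
        len3 = int(rng.integers(20, 24))
        loop = int(rng.integers(8, 16))
        seq = _random_rna(rng, 3 + len5 + loop + len3 + 3)
        arms = (
            MatureArm(mature_id=f"m{i:03d}-5p", start=4, end=3 + len5, arm="5p"),
            MatureArm(
                mature_id=f"m{i:03d}-3p",
                start=3 + len5 + loop + 1,
                end=3 + len5 + loop + len3,
                arm="3p",
            ),
        )
        refs.append(PreMiRNA(id=f"hp{i:03d}", sequence=seq, mature_arms=arms))

    sites: list[KnownEditSite] = []
    positions = list(cfg.site_positions)
    for j in range(cfg.n_sites):
        pre = refs[j % cfg.n_hairpins]
        arm = pre.mature_arms[0]  # 5p
        mature_pos = positions[j % len(positions)]
        pre_pos = arm.start + mature_pos - 1
        if pre.sequence[pre_pos - 1] != "A":
            seq = pre.sequence[: pre_pos - 1] + "A" + pre.sequence[pre_pos:]
            pre = PreMiRNA(id=pre.id, sequence=seq, mature_arms=pre.mature_arms)
            refs[j % cfg.n_hairpins] = pre
        sites.append(
            KnownEditSite(
                site_id=f"site{j:03d}",
                pre_id=pre.id,
                mature_id=arm.mature_id,
                mature_pos=mature_pos,
                pre_pos=pre_pos,
            )
        )

    genome: dict[str, str] = {}
    for r in refs:
        flank5 = _random_rna(rng, 50)
        flank3 = _random_rna(rng, 50)
        genome[f"chr_{r.id}"] = to_dna(flank5 + r.sequence + flank3)
    decoy = _random_rna(rng, 500)
    if cfg.plant_edited_decoys:
        by_id = {r.id: r for r in refs}
        for e in build_edited_references(refs, sites):
            pre = by_id[e.pre_id]
            arm = pre.mature_arms[0]
            decoy += e.sequence[arm.start - 1 : arm.end]
        decoy += _random_rna(rng, 100)
    genome["chr_decoy"] = to_dna(decoy)

    utrs = {f"utr{k:04d}": _random_rna(rng, cfg.utr_length) for k in range(cfg.n_utrs)}
    return ReferenceBundle(refs=refs, sites=sites, genome=genome, utrs=utrs)


def simulate_reads(
    cfg: SimulationConfig,
    bundle: ReferenceBundle,
    sample_index: int,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Simulate one sample's reads plus its per-site truth table.

    Each mature arm receives ``cfg.coverage`` reads of the exact arm
    sequence. Reads on arms carrying a site are edited (A->G) with
    probability equal to the sample's true level; each base is then
    independently miscalled (uniform among the other three bases) with
    probability 10^(-Q/10) from its drawn Phred score, or at the fixed
    ``miscall_rate`` when configured. Read ids encode the origin
    (edited/unedited) of each read.
    """
    rng = np.random.default_rng([cfg.seed, 1, sample_index])
    sample_id = cfg.sample_ids()[sample_index]
    condition = cfg.sample_conditions()[sample_id]
    sites_by_arm: dict[str, list[KnownEditSite]] = {}
    for s in bundle.sites:
        sites_by_arm.setdefault(s.mature_id, []).append(s)

    reads: list[ReadRecord] = []
    truth_rows: list[dict] = []
    for pre in bundle.refs:
        for arm in pre.mature_arms:
            arm_seq = pre.arm_sequence(arm)
            length = len(arm_seq)
            arm_sites = sites_by_arm.get(arm.mature_id, [])
            # At most one site per arm in generated fixtures; tolerate more.
            edited_mask = np.zeros((cfg.coverage, len(arm_sites)), dtype=bool)
            for k, site in enumerate(arm_sites):
                level = cfg.true_level(site.site_id, condition)
                edited_mask[:, k] = rng.random(cfg.coverage) < level
                truth_rows.append(
                    {
                        "sample_id": sample_id,
                        "site_id": site.site_id,
                        "true_level": level,
                        "true_coverage": cfg.coverage,
                        "true_edited": int(edited_mask[:, k].sum()),
                    }
                )
            quals = np.clip(
                np.rint(rng.normal(cfg.phred_mean, cfg.phred_sd, size=(cfg.coverage, length))),
                2,
                41,
            ).astype(np.int64)
            if cfg.miscall_rate is None:
                p_err = 10.0 ** (-quals / 10.0)
            else:
                p_err = np.full((cfg.coverage, length), cfg.miscall_rate)
            miscall = rng.random((cfg.coverage, length)) < p_err
            shifts = rng.integers(1, 4, size=(cfg.coverage, length))
            tails = rng.random(cfg.coverage) < cfg.tail_fraction
            n_inject = rng.random(cfg.coverage) < cfg.ambiguous_fraction
            base_idx = {b: i for i, b in enumerate("ACGU")}
            arm_idx = np.array([base_idx[b] for b in arm_seq])
            for r in range(cfg.coverage):
                idx = arm_idx.copy()
                origin = "unedited"
                for k, site in enumerate(arm_sites):
                    if edited_mask[r, k]:
                        idx[site.mature_pos - 1] = base_idx["G"]
                        origin = "edited"
                if miscall[r].any():
                    idx = np.where(miscall[r], (idx + shifts[r]) % 4, idx)
                seq = "".join(_BASES[idx])
                q = quals[r]
                if tails[r]:
                    n_tail = int(rng.integers(1, 3))
                    seq += "".join(rng.choice(["A", "U"], size=n_tail))
                    q = np.concatenate([q, np.clip(
                        np.rint(rng.normal(cfg.phred_mean, cfg.phred_sd, size=n_tail)), 2, 41
                    ).astype(np.int64)])
                if n_inject[r]:
                    pos = rng.choice(len(seq), size=min(6, len(seq)), replace=False)
                    seq_list = list(seq)
                    for p in pos:
                        seq_list[p] = "N"
                    seq = "".join(seq_list)
                    origin = "noise"
                reads.append(
                    ReadRecord(
                        read_id=f"{sample_id}:{arm.mature_id}:{r}:{origin}",
                        sequence=seq,
                        qualities=tuple(int(v) for v in q),
                    )
                )
    truth = pd.DataFrame(
        truth_rows, columns=["sample_id", "site_id", "true_level", "true_coverage", "true_edited"]
    )
    return reads, truth


def write_fastq(reads: Iterable[ReadRecord], path: Path | str) -> None:
    """Write reads as Sanger Phred+33 FASTQ (T alphabet, as a sequencer would)."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in reads:
            qual = "".join(chr(min(q, 41) + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{to_dna(r.sequence)}\n+\n{qual}\n")


def simulate_editing_matrix(
    *,
    seed: int,
    n_sites: int = 20,
    planted_sites: int = 5,
    n_per_condition: int = 20,
    conditions: Sequence[str] = ("healthy", "cancer_a", "cancer_b"),
    healthy_label: str = "healthy",
    base_level: float = 0.2,
    shift: float = 0.2,
    noise_sd: float = 0.05,
    missing_fraction: float = 0.0,
) -> tuple[EditingMatrix, list[str]]:
    """Direct matrix-level cohort simulator (no reads).

    The first ``planted_sites`` sites get a mean-level shift in every
    non-healthy condition; all levels are Gaussian around their mean (sd
    ``noise_sd``), clipped to [0, 1]; a fraction of cells can be knocked out
    to missing. Returns the matrix and the planted site ids.
    """
    rng = np.random.default_rng(seed)
    site_ids = [f"site{j:03d}" for j in range(n_sites)]
    planted = site_ids[:planted_sites]
    sample_ids: list[str] = []
    cond_map: dict[str, str] = {}
    for c in conditions:
        for i in range(n_per_condition):
            sid = f"{c}_{i:02d}"
            sample_ids.append(sid)
            cond_map[sid] = c
    data = np.empty((n_sites, len(sample_ids)))
    for j, site in enumerate(site_ids):
        for i, sample in enumerate(sample_ids):
            mean = base_level
            if site in planted and cond_map[sample] != healthy_label:
                mean += shift
            data[j, i] = np.clip(rng.normal(mean, noise_sd), 0.0, 1.0)
    if missing_fraction > 0:
        mask = rng.random(data.shape) < missing_fraction
        data = np.where(mask, np.nan, data)
    levels = pd.DataFrame(data, index=site_ids, columns=sample_ids)
    return EditingMatrix(levels=levels, conditions=pd.Series(cond_map)), planted


def mean_phred_to_epsilon(phred_mean: float) -> float:
    """A->G miscall rate implied by a mean Phred score (uniform direction)."""
    return 10.0 ** (-phred_mean / 10.0) / 3.0


def expected_epsilon_ag(cfg: SimulationConfig) -> float:
    """The A->G error rate the caller should test against for this config."""
    if cfg.miscall_rate is not None:
        return cfg.miscall_rate / 3.0
    return mean_phred_to_epsilon(cfg.phred_mean)
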