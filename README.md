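# miredit

Detection and characterization of A-to-I miRNA editing from small RNA-seq
reads, from raw FASTQ to per-sample editing calls, expression levels,
cross-sample high-confidence sites, edited-vs-unedited target rewiring, and
cohort-level editing-profile analysis.

Inosine is read as guanosine by sequencers, so A-to-I edits surface as A→G
mismatches. The pipeline works against a catalogue of known editing sites:

1. **reference_db** (`miredit.references`) — load hairpin (pre-miRNA) FASTA
   and mature-arm annotations, validate known editing sites (must sit on an
   A), and build one single-substitution A→G *edited reference* per site.
2. **read_preprocess** (`miredit.preprocess`) — per-read gates (>5 N drop,
   15–25 nt QC window, mean Phred ≤ 20 drop), iterative 3′ A/U trimming
   (max 2 nt), collapsing of identical reads with per-position mean
   qualities, the final 16–25 nt retention window, and the dataset-level
   gates (≥1 M clean reads, ≥60 % bases retained, ≥0.1 M mapped reads).
3. **alignment** (`miredit.align`) — two-pass, no-mismatch assignment:
   exact full-length substring match against unedited hairpins first, then
   against the edited references (a hit counts as edited only if the read
   covers the substituted base), perfect-match genome exclusion of edited
   candidates (both strands), and fractional mature-arm attribution for
   multi-mapping reads.
4. **editing_caller** (`miredit.calling`) — weighted site pileups with the
   base-quality ≥ 30 mask on G calls, editing level = edited/coverage,
   one-sided binomial test against the sequencing-error rate (estimated
   from Phred scores or fixed), Benjamini–Hochberg correction per sample,
   the ≥2 edited reads / ≥5 % level / q < 0.05 call gates, and
   high-confidence aggregation (passing in ≥10 samples).
5. **expression** (`miredit.expression`) — mature-miRNA RPM
   (mapped/total × 10⁶) with the ≥10 RPM retention flag and an injectable
   ComBat-compatible batch-correction hook.
6. **target_rewire** (`miredit.targets`) — canonical 8mer / 7mer-m8 /
   7mer-A1 3′UTR site scanning for unedited and edited (I→G) mature
   sequences, Jaccard target-set overlap, and functional-domain annotation
   (5′ anchor / seed / central / 3′ supplementary / 3′ tail).
7. **cohort_analysis** (`miredit.cohort`) — sites × samples editing-level
   matrix, per-condition decision-tree imputation, p < 0.1 site selection
   (healthy vs each other condition, exact rank-sum for small groups), PCA
   with a deterministic sign convention, and per-site group comparisons
   with significance tiers (* p < 0.05, ** p < 0.01).
8. **synthetic_fixtures** (`miredit.simulate`) — seeded generators for
   hairpins, site tables, genomes (with optional planted decoys identical
   to edited reads), 3′UTRs, and FASTQ read sets with read-level Bernoulli
   editing, Phred-calibrated miscalls, and 3′ A/U tailing, plus truth
   tables.

## CLI

```bash
miredit simulate --seed 1 --n-samples 2 --coverage 500 --out sim/   # fixtures
miredit run-all --config config.json --out run/                     # full pipeline
# per-stage commands: make-refs, qc, align, call, express, rewire, cohort
```

`config.json` holds input paths and every threshold as a named field (all
defaulting to the published values), e.g.:

```json
{
  "hairpin_fasta": "sim/hairpins.fa",
  "mature_tsv": "sim/mature.tsv",
  "sites_tsv": "sim/sites.tsv",
  "metadata_tsv": "sim/metadata.tsv",
  "genome_fasta": "sim/genome.fa",
  "seed": 1,
  "enforce_dataset_gates": false
}
```

Exit codes: 0 success, 2 dataset excluded by QC gates, 1 error. Outputs are
plain TSV/JSON (calls, expression, high-confidence sites, target rewiring,
editing matrix, PCA artifacts, per-sample QC reports); re-running with the
same config and seed reproduces byte-identical files.

## Notes on method choices

- No-mismatch BLAST alignment is implemented as exact full-length substring
  matching (equivalent for zero-mismatch full-containment queries, and
  deterministic).
- Edited-reference hits that do not cover the substituted base are
  re-routed to unedited status — they carry no editing evidence.
- Multi-mapping reads are attributed fractionally (1/k) for expression and
  pileups.
- 3′ A/U trimming runs before collapsing so tailing variants merge.
- The significance test is a one-sided binomial upper tail against the
  A→G error rate (mean Phred miscall probability / 3 by default).
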