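# coexpipe

Cross-cohort validated weighted gene co-expression network analysis for bulk
expression data, built around a severe-heart-failure skeletal-muscle use
case: construct a co-expression network in a discovery cohort, validate its
edges and communities in independent cohorts, relate community eigengenes to
clinical traits, test gene-set over-representation against a rest-of-network
background, and assess tercile-coded survival prognosis. A bundled synthetic
multi-cohort generator (planted co-expressed communities, trait links,
proportional-hazards survival, per-cohort batch effects) makes the whole
pipeline testable without any external data.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (exact Fisher
reproductions, brute-force oracle equivalences, planted-module recovery,
preservation calibration, Cox parameter recovery, TMM properties, eigengene
closed form, end-to-end reproducibility).

The acceptance report is produced by:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Pipeline stages

1. **simulate / ingest** (`coexpipe.synthetic`) — negative-binomial count or
   Gaussian log-intensity cohorts with planted one-factor communities
   (standardized expression = loading × latent eigengene + noise), traits,
   survival, batch effects, and ground-truth accessors.
2. **preprocess** (`coexpipe.preprocessing`) — TMM normalization (weighted
   trimmed mean of M-values, trim 30 %/5 %, factors geometric-mean 1) with
   log2CPM conversion; expression-fraction filter (count > 1 in ≥ 20 % of
   libraries); IQR filter (IQR < 2 excluded) for array intensities;
   location-scale batch adjustment.
3. **network** (`coexpipe.network`) — Pearson correlations, soft-threshold
   adjacency (default β = 13, unsigned |r|^β; signed mode available),
   scale-free topology fit scan, topological overlap matrix, average-linkage
   community detection with a static height cut, eigengene-based merging of
   communities at dissimilarity cut-height 0.25.
4. **validate** (`coexpipe.validation`) — every discovery edge recomputed in
   each external cohort (confirmed = same sign, p < 0.05 in ≥ 1 cohort;
   unconfirmed edges pruned); permutation preservation Z per community
   (density + intramodular-connectivity statistics, Z_summary = their mean);
   communities retained when Z_summary ≥ 3 in ≥ 1 cohort.
5. **associate** (`coexpipe.community`) — community eigengenes (first
   principal component of standardized expression, sign aligned to mean
   expression), Pearson trait correlations (patients-only scope supported),
   Welch group tests, one-way ANOVA.
6. **enrich** (`coexpipe.enrichment`) — exact Fisher 2×2 tests (one- and
   two-sided), community over-representation against the rest-of-network
   universe, Benjamini–Hochberg FDR, GMT gene-set I/O.
7. **survival** (`coexpipe.survival`) — tercile split (cuts at ranks ⌈n/3⌉,
   ⌈2n/3⌉), Cox proportional hazards by Newton maximization of the Breslow
   partial likelihood, ordinal and high-vs-low codings, Kaplan–Meier
   coordinate export, death-class ANOVA.
8. **match** (`coexpipe.matching`) — logistic (IRLS) propensity scores on
   age/sex/BMI/diabetes, greedy 1:1 nearest-neighbor matching without
   replacement within a caliper (default 0.2 × sd of logit scores),
   standardized-mean-difference diagnostics.

## CLI

```bash
coexpipe run --seed 1 --out-dir run1          # full synthetic workflow
coexpipe simulate --seed 1 --out simdata       # synthetic cohorts + truth
coexpipe preprocess counts.tsv --out expr.tsv --factors-out factors.csv
coexpipe network expr.tsv --out-dir net --power 13
coexpipe validate expr.tsv net/partition.tsv --cohort gtex gtex.tsv --out-dir val
coexpipe associate expr.tsv val/partition_retained.tsv ann.csv --trait lvef --out assoc.csv
coexpipe enrich val/partition_retained.tsv sets.gmt --out enr.csv
coexpipe survival expr.tsv val/partition_retained.tsv surv.csv --out prog.csv
coexpipe match covariates.csv --label-col case --out pairs.csv
```

`coexpipe run` accepts a YAML pipeline config (`--config`) mirroring
`PipelineConfig`; every stage writes outputs plus a `provenance.json`
(seed, parameters, sha256 of outputs) into the run directory, and a global
`summary.json` aggregates stage summaries. A single `--seed` fans out to
per-stage seeds via `numpy.random.SeedSequence(seed).spawn`, so identical
configs reproduce all outputs bit-exactly.

## File formats

- **Expression / counts TSV** — tab-separated; header row of sample IDs,
  first column `gene`; floats written with 10 significant digits.
- **Annotations CSV** — indexed by `sample`; columns used by the pipeline:
  `cohort`, `group` (patient|control), traits, `time`, `event`,
  `age`, `sex`, `bmi`, `diabetes`, optional `death_class` (1–4).
- **GMT** — `name <tab> description <tab> member...`, one set per line.
- **Edge list TSV** — `gene_a, gene_b, correlation, adjacency, tom`
  (upper triangle, optional TOM floor to bound file size); GraphML export
  carries the same attributes.
- **Partition TSV** — `gene <tab> community` (0 = background/unassigned).
- **Survival CSV** — `sample, time, event` (+ optional `death_class`).
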