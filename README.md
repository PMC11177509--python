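# pmnpipe

Integrative analysis of proximal-MYC-network (PMN) alterations in IDH-mutant
astrocytoma cohorts, as a tested, reusable pipeline:

- **Gene-level SCNA calling** from SEG copy-number segments
  (overlap-length-weighted segment means, ±0.3 log-ratio threshold).
- **PMN-hit status** per sample (any SCNA or non-silent mutation in the
  14-gene PMN: MYC/MYCN/MYCL/MLXIPL/MLXIP, FBXW7/MGA/MNT/MXD4/MXD3/MXI1/MXD1,
  MAX/MLX).
- **Stratified Monte-Carlo permutation test** for SCNA enrichment in a gene
  set (add-one empirical p, 10,000 iterations by default).
- **Two-filter MYC-regulator screen** over PMN-WT samples: (a) Pearson
  correlation with MYC expression (|r| > 0.2, p < 0.05), (b) one-tailed
  Wilcoxon rank-sum association of somatic alteration (10–90% frequency) with
  higher MYC expression.
- **Minimal-common-region (MCR) discovery**: sweep-line intersection of
  merged per-sample loss footprints, gene containment, arm-level loss flags.
- **Genomic-instability metrics**: SNV/indel burden, wGII, CAER, copy-number
  amplitude, chromothripsis flag, with group comparisons.
- **3-way subclassification** (PMN-hit / MCR-loss / WT) with a MYC linear
  model adjusting for grade, Cochran–Armitage grade trend, k-group log-rank
  on progression-free interval, and an r×c Fisher exact test.
- **Single-cell validation**: cancer-cell selection, per-cell MCR-loss
  dichotomization, and a per-region Poisson regression (IRLS, log link) of
  MYC counts on copy-number estimates interacting with loss status:
  `E[count] = exp(b0 + b1·CN·I(with loss) + b2·CN·I(without loss))`.
- **Synthetic-data generators** (`pmnpipe.synthetic_data`) producing bulk
  cohorts and single-cell matrices with planted PMN hits, a planted focal
  19q-like deletion in PMN-WT samples, graded MYC effects, and exact truth
  tables — every stage is testable without downloads.

All genomic coordinates are 1-based, fully closed (SEG convention); only the
BED export is 0-based half-open. Expression values are assumed already
log-scale normalized.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: oracle equivalence
of every statistical primitive against brute-force recomputation,
permutation-test calibration, end-to-end planted-structure recovery,
type-I-error / CI-coverage calibration, and file-format round-trips.

## CLI

One subcommand per stage (`pmnpipe --help` for options):

```sh
pmnpipe simulate --outdir sim --seed 1
pmnpipe call-scna --seg sim/segments.seg --genes sim/genes.tsv --out calls.tsv
pmnpipe pmn-hit --calls calls.tsv --maf sim/variants.maf.tsv --out hits.tsv
pmnpipe perm-test --calls calls.tsv --gene-set pmn_genes.txt --iterations 10000 \
    --seed 1 --out-json perm.json
pmnpipe screen --expr sim/expression.tsv --calls calls.tsv \
    --maf sim/variants.maf.tsv --hits hits.tsv --out screen.tsv
pmnpipe mcr --seg sim/segments.seg --samples loss_samples.txt \
    --genes sim/genes.tsv --out-json mcr.json --out-bed mcr.bed
pmnpipe instability --seg sim/segments.seg --maf sim/variants.maf.tsv \
    --genome-config sim/genome.yaml --out metrics.tsv
pmnpipe classify --hits hits.tsv --seg sim/segments.seg --mcr-json mcr.json \
    --expr sim/expression.tsv --clinical sim/clinical.tsv --out-prefix cls
pmnpipe sc-assoc --cn-matrix sim/cell_cn.tsv --cell-meta sim/cell_meta.tsv \
    --mcr-json mcr.json --out fits.json
```

## Notes on statistical conventions

- Permutation p-values use the add-one estimator `(1 + #{null ≥ obs})/(B+1)`.
- The permutation test's default observed statistic (counted over samples
  selected for having events in the target genes, mirroring the source
  procedure) is anti-conservative by construction; pass `sample_subset=` /
  use a fixed sample set for calibration-grade inference. See
  `pmnpipe.permtest.stratified_permutation_test`.
- Wilcoxon rank-sum: exact enumeration for small tie-free groups, otherwise
  normal approximation with tie and continuity corrections.
- Fisher exact tests beyond 2×2 use full enumeration of margin-fixed tables
  with a Monte-Carlo fallback (flagged in the result) for large tables.
- No multiple-testing correction is applied by default anywhere.
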