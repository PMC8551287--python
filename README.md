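# ssikit

Sparse selection indices (SSI) for genomic prediction in multi-generation
breeding programs. The package implements:

- **BLUP baselines** over an additive genomic relationship matrix
  (`G = ZZ'/p` on column-standardised markers) and Gaussian kernels
  `K_ij = exp(-theta * scaled squared distance)` with bandwidths
  0.2 / 1 / 5, plus variance-weighted kernel averaging.
- **Per-individual L1-penalized selection indices**: each prediction
  individual's row of the Hat matrix solves
  `min_b 0.5 b'(K_TS + lambda0 I)b - k_i'b + lambda * ||b||_1`
  by cyclic coordinate descent with soft-thresholding, warm starts along a
  descending penalty path and an active-set speedup. `lambda = 0` recovers
  the dense BLUP row; the penalty is chosen by k-fold cross-validation
  within the training set.
- **Variance components** on the training set: deterministic REML for a
  single kernel (eigendecomposition + 1-D search) and a Gibbs sampler for
  the three-kernel model, which also supplies kernel-averaging weights.
- **Marker QC** for dominant 0/1 markers: chi-square segregation test
  against an expected ratio (default 3:1) with Benjamini–Hochberg FDR,
  followed by a MAF filter.
- **Phenotype adjustment**: genotype BLUEs from plot-level records under
  multi-location (`Y = mu + G + L + R(L) + B + GxL + e`) and
  single-location (`Y = mu + G + R + B + e`) mixed models with a random
  incomplete-block effect (REML profiled over the single variance ratio).
- **A doubled-haploid population simulator**: multi-cycle biparental DH
  families with shared parents across cycles (Haldane recombination, fully
  homozygous 0/1 lines), per-cycle correlated QTL effects (the
  heterogeneity dial `rho_g`), phenotypes at a target heritability, and
  plot-level trial records.
- **Evaluation**: training/prediction scenario arithmetic (85/15 split of
  the prediction cycle, nested augmentation fractions), repeated random
  partitions with paired model comparisons, accuracy (Pearson correlation)
  and gain summaries.

## Command-line interface

```bash
ssikit simulate --config config.yaml --out sim/       # DH population
ssikit qc --markers sim/markers.tsv --out qc/         # segregation + MAF QC
ssikit adjust --records plots.csv --out adjusted.csv  # genotype BLUEs
ssikit kernel --markers qc/markers_qc.tsv --kind grm --out G.tsv
ssikit fit --markers ... --phenotypes ... --model gssi --lambda cv \
       --prediction-cycle 3 --out fit/
ssikit evaluate --config config.yaml --out results/   # scenario grid
ssikit run --config config.yaml --out run/            # full pipeline
```

The YAML config controls the simulation (cycles, families, DH per family,
markers, `rho_g`, `h2`, seed), the model list (`GBLUP`, `GSSI`, `K1BLUP`,
..., `KASSI`), partitions and CV settings. See
`tests/test_io_cli.py::TestCLI` for a minimal example.

## Layout

```
src/ssikit/
  simdata.py       DH population, trait architecture, trial simulator
  marker_qc.py     segregation-distortion + MAF filtering
  kernels.py       GRM, Gaussian kernels, averaging, partitioning
  pheno_adjust.py  BLUEs from plot-level records (profiled REML)
  varcomp.py       REML and Gibbs variance components
  predictors.py    BLUP/SSI Hat matrices, coordinate descent, CV
  evaluation.py    scenarios, partitions, accuracy, gains
  io.py, cli.py    tabular IO and the click CLI
  _cd.py           numba coordinate-descent kernel
```
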