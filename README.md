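# tsblup

Whole-genome prediction with trait-specific kinship matrices.

`tsblup` implements genomic BLUP (GBLUP) and its ridge-regression
equivalent (RRBLUP) through a single-pass equivalent algorithm, plus a
trait-specific extension in which the realized relationship matrix `G`
is blended with a genetic-architecture matrix `S` built from the
top-effect SNPs selected *within the training data*:

```
T = omega * S + (1 - omega) * G
```

`S = M1 D M1' / (m1/2)` uses the centered genotypes of the selected
markers (top fraction `top_pct`, expanded by `nflank` map-adjacent SNPs
per side) weighted by a diagonal `D` of effect-derived weights rescaled
to mean 1. The three hyperparameters `(omega, top_pct, nflank)` are
chosen by seeded k-fold cross-validated grid search in the reference
population (training stage) and then applied once to predict never-used
candidates (application stage).

The package also ships:

- REML variance components for a single-kinship mixed model
  (eigendecomposition of the projected `ZKZ'` + 1-D likelihood search);
- accuracy (Pearson r) and unbiasedness (regression of the reference
  value on the GEBV) metrics;
- model-choice diagnostics: cumulative genetic-variance curves
  (`2p(1-p)a^2`), marker-effect rescaling to mean |effect| = 1, the
  zero-intercept regression of the accuracy gain on the `T`–`G` distance
  `sigma`, and dosage-ordered matrix export for heat maps;
- a quantitative-trait simulator (AR(1) Gaussian-copula genotypes,
  normal or random-signed gamma QTL effects, target heritability,
  optional major QTL pinned to a fixed variance share) with named
  presets: `gsa_gamma`, `gsa_normal`, `qtlmas_like`, `major_gene`,
  `polygenic`.

## CLI

Every subcommand writes a `manifest.json` echoing the resolved
configuration; all randomness flows from a single `--seed`.

```bash
# simulate a dataset (dosage TSV + .map + phenotypes + TBV + manifest)
tsblup simulate --preset major_gene --seed 1 --out data/ --set n_cand=0

# realized relationship matrix
tsblup grm --genotypes data/genotypes.tsv --out G.tsv

# REML + GBLUP fit (GEBVs for everyone, RRBLUP marker effects, sidecar)
tsblup fit-gblup --genotypes data/genotypes.tsv \
    --phenotypes data/phenotypes.tsv --map data/markers.map --out fit/

# training stage: cross-validated grid search
tsblup train --genotypes data/genotypes.tsv --phenotypes data/phenotypes.tsv \
    --map data/markers.map --config grid.yaml --out train/

# application stage: predict candidates with the selected parameters
tsblup predict --genotypes ref.tsv --phenotypes data/phenotypes.tsv \
    --cand-genotypes cand.tsv --map data/markers.map \
    --params train/best_params.json --cand-values cand_tbv.tsv --out pred/

# diagnostics
tsblup diagnose --genotypes data/genotypes.tsv --phenotypes data/phenotypes.tsv \
    --map data/markers.map --points delta_sigma.tsv --order-by c1_m00001 --out diag/
```

`grid.yaml` example:

```yaml
grid:
  omegas: [0.0, 0.02, 0.1, 0.3, 0.45, 0.6]
  top_pcts: [0.001, 0.01, 0.05]
  nflanks: [0, 3]
n_folds: 5
n_replicates: 20
seed: 1
variance_policy: reuse_lambda   # or: reestimate
```

Input dialects: dosage TSV (marker-ID header, individual IDs in the
first column, 0/1/2 with missing cells mean-imputed at load), PLINK 1.x
`--recode A` raw files, and PLINK `.map`-style marker maps. All
relationship matrices use the fixed allele-frequency convention p = 0.5
(centering = dosage − 1).

## Library quick start

```python
from tsblup.simulate import preset, simulate_dataset
from tsblup.workflow import train, apply_stage

sim = simulate_dataset(preset("major_gene", seed=1))
result = train(sim.reference_dataset(), n_folds=5, n_replicates=2, seed=1)
report = apply_stage(sim.reference_dataset(), sim.candidate_dataset(),
                     result.best_params)
print(report.accuracy_gblup, report.accuracy_model, report.params)
```
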