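# phenopred

Phenomic and genomic prediction for structured hybrid breeding populations.

Hybrid rapeseed breeding programmes evaluate hundreds of test hybrids —
inbred pollinator lines crossed to male-sterile testers — in multi-location,
multi-year field trials. Genomic selection (GS) predicts the performance of
untested hybrids from genome-wide SNP markers; phenomic selection (PS)
replaces the markers with near-infrared (NIR) reflectance spectra of
harvested seed, which are routinely collected at a fraction of the cost of
genotyping. `phenopred` implements the full analysis pipeline needed to
compare the two — and their combination — on realistic synthetic data:

1. **Simulation** of a structured test-hybrid population: founder × elite
   subfamilies of fully inbred pollinators, a partial crossing design with
   two testers, partially replicated (p-rep) field trials with check
   varieties, row/column field effects and genotype-by-environment
   interaction, and plot-level seed NIR spectra with technical replicates,
   baseline drift and noise.
2. **Mixed-model adjustment** (REML) of plot records to entry means
   (BLUEs), per trait and per wavelength, plus Cullis-style heritability.
3. **Spectral preprocessing**: technical-replicate averaging,
   Savitzky–Golay first derivative (window 37), centring and scaling.
4. **Relationship matrices**: VanRaden additive GRM from SNPs, its spectral
   analogue from preprocessed NIR profiles, and Gaussian kernels for RKHS.
5. **Five prediction models**: GBLUP / NIRS-BLUP (and their combination),
   Bayesian LASSO, RKHS kernel averaging, random forest and support-vector
   regression with model-based hyperparameter optimisation.
6. **Evaluation**: random (80/20 × 200 runs) and familywise
   cross-validation, Pearson prediction accuracy, and selection accuracy via
   the Czekanowski similarity of the predicted and observed top-*k* sets.

## Models

Entry means are obtained from the linear mixed model

```
y_ijklmn = μ + g_i + e_j + r_k(e_j) + c_l(e_j) + a_m + l_n + (g_i × e_j) + ε
```

with genotype `g_i` fixed and environment, row- and column-within-
environment, year, location and G×E random; the adjusted mean is `μ + g_i`.
Heritability on the entry-mean scale is `H² = σ²_g / (σ²_g + v̄ΔBLUE/2)`
where `v̄ΔBLUE` is the mean variance of pairwise BLUE differences.

Prediction uses `y = Xβ + Z_a a + Z_NIRS i + e` with
`a ~ N(0, G_a σ²_a)`, `i ~ N(0, G_NIRS σ²_i)`, where
`G_a = ZZ'/(2Σ p_i(1−p_i))` (VanRaden) and `G_NIRS = WW'/l` on the
preprocessed spectra `W`. `X` carries an intercept and a one-hot indicator
of the male-sterile tester. The Bayesian LASSO puts double-exponential
priors on marker and wavelength effects (`y = Xβ + Ma + Wi + e`); RKHS
kernel averaging regresses on Gaussian kernels at bandwidths
{0.1, 0.5, 2.5}, weighted by their estimated variance components. Selection
accuracy is `CZ = 2a/(2a + b + c)` over correctly selected (a), wrongly
selected (b) and wrongly discarded (c) genotypes.

## Worked example

A small within-generation scenario — 80 hybrids from 5 subfamilies, three
environments, 400 markers, 200-point spectra, 20 cross-validation runs:

```bash
phenopred run --config demo.yaml --seed 1 --out demo_out
```

with `demo.yaml`:

```yaml
scenario: within-generation
simulation:
  n_markers: 400
  n_wavelengths: 200
  family_sizes: [12, 12, 12, 12, 12]
  n_both: 30
  n_t1_only: 10
  n_t2_only: 10
  environments: [[RHH, '2020'], [HOH, '2020'], [RHH, '2021']]
  n_checks: 3
  check_reps: 5
preprocess: {window: 17}
n_runs: 20
selection_sizes: [14, 7]
```

prints

```
          model predictor_set      trait  median_r
          GBLUP           SNP seed_yield  0.399497
GBLUP+NIRS-BLUP      SNP+NIRS seed_yield  0.391909
      NIRS-BLUP          NIRS seed_yield  0.091226
artefacts in demo_out
```

`median_r` is the median Pearson correlation between predicted and observed
adjusted means over the masked 20% test sets. In this generator's default
setting the spectra carry genotype-driven (relatedness) signal but are not
directly linked to the trait, so SNP-based prediction dominates and the
spectra add little — at this small population size the combination is
essentially GBLUP. `demo_out/selection.csv` holds the corresponding top-14
and top-7 selection classifications with their CZ values, e.g.
`GBLUP,SNP,14,2,12,12,54,0.1428…` (2 of the true top 14 correctly
selected). All intermediate artefacts (plot table, adjusted means,
preprocessed spectra, kinships, per-run accuracies, provenance log) are
written next to it.

The same pipeline runs `single-location` (spectra from one location,
adjusted with the reduced model), `familywise` (leave-one-subfamily-out)
and `across-generation` (pollinator spectra predicting hybrid performance)
scenarios; see `phenopred run --help` and the other subcommands
(`simulate`, `adjust`, `preprocess`, `kinship`, `cv`, `select`, `report`).

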