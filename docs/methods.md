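# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `phenopred`.

## Population and trial simulation

The generator emulates a commercial hybrid-rapeseed testcross experiment.

**Genomes.** Per-marker B-allele frequencies are drawn Uniform(0.1, 0.9) —
bounded away from fixation so the expected-heterozygosity filter
(≥ 0.095) is non-degenerate — and every parental line (5 founders, 1 elite,
2 male-sterile testers) is fully homozygous. Pollinators are
doubled-haploid-like offspring of founder × elite crosses: the genome is an
abstract linear arrangement of markers split into `n_blocks` contiguous
blocks (default 20), each inherited intact from one parent with probability
1/2. There is no genetic map or centimorgan scale; the blocks provide
enough linkage structure to make kinship contrasts between subfamilies
meaningful without one. F1 hybrid dosages are the parental means, so a
hybrid is heterozygous exactly where its parents differ.

**Crossing design.** By default 159 pollinators are crossed to both
testers and 46 to each single tester: 410 hybrids from 251 pollinators in
5 subfamilies (sizes 50/50/50/50/51, within the 45–53 range of the real
design). Assignment of pollinators to the both/single groups is a seeded
permutation.

**Traits.** `n_qtl` markers (default 200) receive standard-normal additive
effects. The genotypic values are centred and rescaled so that the
heritability of an adjusted entry mean,
`h² = σ²_g / (σ²_g + V_err)` with
`V_err ≈ σ²_gxe/E + (σ²_row + σ²_col + σ²_ε)/(E(1+ρ))`
(E environments, ρ the replicate fraction), hits the configured target.
Defining the target on the entry-mean (Cullis) scale makes the
heritability-recovery check a genuine end-to-end test of the adjustment
machinery rather than a tautology. The trial variance components default to
σ²_env = 1, σ²_gxe = 0.25, σ²_row = σ²_col = 0.1, σ²_ε = 1 — free
parameters of the generator chosen as plausible relative magnitudes for
multi-environment yield trials (design effects smaller than residual, G×E a
quarter of the residual), not calibrated values.

**Field trials.** Each environment is a (location, year) cell; the default
grid is 5 locations × 2 years. Within an environment 20% of test genotypes
are duplicated (p-rep, 1.2 replicates) and checks (default 3 varieties ×
10 plots) are laid out alongside on a near-square row × column grid. Year
and location influence plots only through the environment effect; separate
year/location variance dials are deliberately not part of the generator,
though the adjustment model can still carry those terms (their generative
variance is then zero). An optional random plot-drop mask emulates
weather-related exclusions.

**Spectra.** A plot's seed spectrum is the sum of a fixed smooth base
curve, a genotype-driven low-rank signal (latent factor scores — random
linear functions of the centred dosages — loaded onto Gaussian-bump
wavelength profiles, rank 10 by default, which reproduces the strong
inter-wavelength correlation of real NIR data), a smooth
environment-specific effect, a per-measurement baseline drift increasing
linearly with wavelength, and iid noise. Two technical replicates share
everything but drift and noise. The default wavelength grid is
680–2499 nm at 1 nm (1,820 points).

What the generator does *not* emulate: instrument-specific scatter
artefacts, water-band saturation, non-additive (dominance/epistatic) trait
architecture by default, selection or drift across generations, and any
direct biochemical link between the trait and the spectra (the spectral
genetic factors are independent of the trait QTL). Passing tests therefore
demonstrate that the machinery is correct under the stated generative
assumptions, not that phenomic prediction will reach any particular
accuracy on real material.

## REML engine

All adjustment and BLUP models are fitted by one engine:
`y = Xβ + Σ_u Z_u u_u + e`, `u_u ~ N(0, σ²_u K_u)`. Correlated terms
(kinship/kernel BLUP) are whitened through a symmetric factor
`K = LL'` (eigendecomposition with negative eigenvalues clipped), so the
solver only ever sees iid effects. The restricted likelihood is profiled
over σ²_e and maximised over log variance ratios λ_u = σ²_u/σ²_e with
L-BFGS-B (bounds e^±, ftol 1e-10), followed by a Nelder–Mead polish on
small systems where finite-difference noise limits quasi-Newton accuracy.
Each evaluation solves Henderson's mixed-model equations; the determinant
identity `log|V| + log|X'V⁻¹X| = (n−p) log σ²_e + log|C| + Σ q_u log λ_u`
assembles the likelihood from the Cholesky (dense) or SuperLU (sparse)
factor of the ratio-form coefficient matrix C.

For large crossed designs one identity-covariance term is *absorbed*: with
G×E in the model, the residual structure `I + λ Z Z'` is block-diagonal
over the term's level groups (a p-rep cell holds at most a few plots), so
each block inverts in closed form (`(I_s + λ11')⁻¹ = I − λ/(1+sλ) 11'`,
`log det = log(1+sλ)`) and the explicit equations shrink from thousands to
a few hundred — a ~70× speedup at the 410-hybrid × 10-environment scale
with bit-identical likelihood (verified against the unabsorbed path in the
tests). Variance ratios hitting the lower bound (1e-10) are reported as 0;
non-convergence raises a RuntimeWarning and is flagged on the result, never
silent.

`v̄ΔBLUE` is computed exactly from the genotype-contrast covariance
(including the zero-variance reference level) for up to 1,000 genotypes,
else from 10,000 sampled pairs. Adjusted spectra default to re-estimating
variance components at every wavelength (`mode="exact"`); `mode="fast"`
estimates them on 50 evenly spaced wavelengths, fixes the ratios at their
medians and solves all wavelengths against one shared factorisation —
orders of magnitude faster and nearly identical output on smooth spectra.

## Preprocessing

Technical replicates are averaged arithmetically. The Savitzky–Golay first
derivative uses a 37-point window and polynomial order 2 — the lowest order
that smooths while admitting a first derivative; the paper-scale window is
kept configurable. Edges are trimmed, not padded: (window−1)/2 points per
side, so a 1,820-point profile keeps 1,784 interior wavelengths (the
reported counts for this instrument are internally inconsistent by one to
two points; the package documents its exact arithmetic instead of forcing a
number). The derivative is per wavelength unit. Centring/scaling uses the
sample standard deviation; constant columns are dropped with a warning and
recorded in the provenance.

## Kinships and kernels

Marker QC removes markers with >10% missing calls, non-biallelic codings,
or expected heterozygosity 2p(1−p) < 0.095 (boundary inclusive), then
mean-imputes remaining gaps — mean imputation being the GBLUP-standard
choice. The VanRaden GRM uses allele frequencies of the supplied
individuals (train+test union by default, so one matrix serves all CV
splits; a training-only option exists by passing frequencies explicitly).
Gaussian kernels normalise the squared Euclidean distances by their mean
off-diagonal value before applying bandwidths {0.1, 0.5, 2.5}; without
this the bandwidth grid would be meaningless for 6,200-marker inputs
(switchable via `normalise=False`). PSD repair adds escalating diagonal
jitter (1e-6 ×10 per step, at most 6 steps) and records the amount.

## Bayesian samplers

The Bayesian LASSO Gibbs sampler uses flat fixed-effect priors,
conditional-normal effects with inverse-Gaussian-sampled exponential mixing
variances (the scale-mixture form of the double-exponential prior), a
per-block λ² ~ Gamma(1.1, rate = 0.1/λ0²) hyperprior with
λ0² = 2 Σ_j var(x_j) (an "R² ≈ 0.5" heuristic), and a scaled-inverse-χ²
residual prior (df 5). Chain defaults are 12,000 iterations, 2,000
burn-in, thinning 5; tests run far shorter chains. σ²_e and λ can be
pinned, which the tests use to check the sampler against a 2-D quadrature
oracle and (with the normal-prior switch) against the ridge closed form.

RKHS kernel averaging samples each kernel's effect in its eigenbasis,
where the conditional posterior is independent normal, with
scaled-inverse-χ² priors on the per-kernel variances; kernel weighting
emerges from those variance components. Unobserved individuals are
predicted through the conditional prior mean `K_ts K_tt⁺ u_train`, which
reproduces the kernel-ridge closed form exactly under fixed variance
ratios; the joint posterior of test-individual effects is not sampled.

## Machine learning tuning

Both learners follow the same budget: 12 Latin-hypercube configurations,
then 6 chosen by expected improvement under a Gaussian-process (Matérn 5/2)
surrogate, then a refit of the best configuration on all training data.
Random forest (500 trees) minimises out-of-bag MSE over mtry ∈ [100,
columns/3] (clamped for narrow matrices) and min.node.size ∈ [3, 15]; the
support-vector machine (RBF) minimises 5-fold CV RMSE over C ∈ (0, 2¹⁰]
(the degenerate lower bound 0 is implemented as 1e-6) and ε ∈ [0, 0.5].
Integer parameters are rounded; every evaluated configuration is recorded
in the tuning trace.

## Evaluation

Random CV draws floor(0.8·n) training individuals per run (200 runs by
default); familywise CV holds out each subfamily once. Accuracies are
reported per run and summarised by medians; selection accuracy is computed
on predictions averaged over all runs in which a genotype was in the test
set. Top-k ties break lexicographically by id so results are
platform-independent; with fixed-size selections b = c and CZ = a/k. A
constant prediction vector yields a missing (NaN) accuracy, never zero.

## Validation design (what the test suite checks)

* Closed-form oracles: balanced-ANOVA = REML on one-way layouts; GBLUP =
  marker ridge; single-kernel RKHS = kernel ridge; Gram matrices = dense
  double loops; SG derivative exact on polynomials of its fit order.
* Parameter recovery at scale: 410 hybrids × (5 locations × 2 years), 20
  seeds — components with many levels are compared to their generative
  values at the median; the environment term (10 levels) is compared to
  the realised variance of its drawn effects, since the realised-vs-nominal
  gap of 10 draws is χ²₉ sampling noise no estimator can remove.
  Cullis H² must track the generative target within 0.05.
* Behavioural properties: a trait that is exactly linear in the spectra is
  predicted by NIRS-BLUP with r > 0.99; on family-confounded traits whose
  value is directly reflected in the spectra, the familywise-vs-random
  accuracy gap of phenomic prediction is smaller than the genomic one in
  ≥ 70% of seeds; on epistatic traits in the structured population the
  Gaussian-kernel model matches or beats GBLUP in ≥ 70% of seeds.

Test problem sizes (tens of hybrids, hundreds of markers/wavelengths, tens
of CV runs) are deliberately small; the package's defaults carry the
full-scale values.

## Known limitations

* Residuals are independent; no AR1×AR1 spatial correlation models.
* The GBLUP family is additive-only — no dominance or epistatic GRMs
  (epistasis is reachable through the RKHS kernels instead).
* Bayesian prior constants are documented package choices, not
  reproductions of any particular software's internals.
* The effect-wise Gibbs loop of the Bayesian LASSO is pure Python; at
  6,200 markers × 12,000 iterations it is slow (minutes), though exact.
* VCF reading handles biallelic records only; others are skipped with a
  count.
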