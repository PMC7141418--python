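# Methods

This note documents the statistical models, algorithms and numerical
choices behind gsweave, in the order the pipeline applies them.

## Data model and quality control

Genotypes are biallelic SNP dosages in {0, 1, 2} (count of the
non-reference allele) with missing calls carried as NaN; `{−1,0,1}`
coded files are detected on read (presence of −1, absence of 2) and
shifted.  QC removes markers whose minor-allele frequency — computed on
observed calls only, MAF = min(p, 1−p) with p = mean(dosage)/2 — falls
below `maf_min` (default 0.05) or whose missing fraction exceeds
`max_missing` (default 0.20).  QC runs **before** imputation, so the
thresholds refer to what was actually genotyped.  Allele frequencies
used by the relationship matrix are recomputed from the (imputed)
matrix at call time, never cached.

The additive relationship matrix is VanRaden's
`A = WW′ / (2 Σⱼ pⱼ(1−pⱼ))` with `W = dosage − 2pⱼ` per column;
the scaled form divides entry (i,k) by `√(A_ii·A_kk)` so the diagonal is
one and off-diagonals read as coancestry coefficients.  Every inverse
of a kinship downstream adds a ridge of 1e−8 to the diagonal first;
finite-sample `A` is routinely numerically singular.

Broad-sense heritability is computed from user-supplied variance
components as `h² = σ²g / (σ²g + σ²ge/n_env + σ²e/n_plot)`; its square
root is reported as the ceiling on prediction accuracy.  (The
mixed-model pre-adjustment that produces the BLUEs and the variance
components is upstream of this package: it consumes already-adjusted
phenotypes.)

## Imputation

**MNI** replaces each missing call with the mean of the observed
dosages of its marker (real-valued, never rounded — all downstream
models consume real dosages).

**EMI** imputes under the additive-relationship model: a missing,
centred dosage is replaced by its conditional expectation given the
observed calls of related lines,
`E[w_m | w_o] = A_mo A_oo⁻¹ w_o` per marker column (computed from
whichever of the observed or missing block is smaller — two
algebraically identical routes).  Around that E-step:

* the **initial kinship** is a pairwise-complete VanRaden estimate:
  each entry normalised by the expected variance of the markers the
  pair actually shares (unbiased under random missingness), shrunk by
  `overlap/(overlap + 100)` markers to damp the sampling noise of
  sparsely shared pairs, and capped by the Cauchy–Schwarz bound
  `|A_ik| ≤ √(A_ii A_kk)`.  On dense panels the shrinkage vanishes and
  the estimate coincides with the plug-in VanRaden matrix.
* the **E-step ridge**: the conditioning covariance is `A + δI` with
  δ = 0.05 × mean(diag A).  It plays the role of per-marker residual
  variance around the kinship model, keeps the solves well-posed when
  related lines are near-clones, and shrinks imputations slightly
  toward the marker mean.  Imputed dosages are clipped to the feasible
  [0, 2] range inside the loop.
* the **M-step blend**: the re-estimated kinship is
  `w·A_obs + (1−w)·A_plugin` with `w` = the missing fraction, where
  `A_obs` is the fixed observed-data estimate and `A_plugin` the
  VanRaden matrix of the completed data.  Imputed cells carry no
  information about relatedness beyond the current kinship, so the
  completed-data estimate is down-weighted exactly by how much of it is
  imputation; as missingness → 0 this reduces to the classical plug-in
  EM.  A pure plug-in M-step was tried first and is unstable above
  ~50% missingness at desk-scale marker counts (a few thousand): the
  kinship sampling noise (≈ 1/√overlap per entry) feeds back through
  the conditional means and predictive ability collapses below the MNI
  baseline.  At the marker densities of real SNP panels (tens of
  thousands) the kinship noise is an order of magnitude smaller and
  the distinction disappears.
* **stopping**: max-norm change of the kinship < 0.02 (`tol`), a hard
  cap of 100 iterations (with a warning if hit), and a stall rule —
  once the max-norm change stops improving for three iterations it is
  a bounded oscillation of a few clipped entries and iteration ends.

Both methods leave observed calls bitwise untouched, and the E-step is
chunkable by marker blocks (columns are conditionally independent, so
block size cannot change the result; it only bounds memory).

## Marker reduction

* **RMR** — uniform random subset of k markers, seeded.
* **LD pruning** — within each chromosome (map positions are a sorting
  key only), markers are scanned in position order; for each surviving
  pair with squared Pearson correlation r² above the threshold, the
  member with more missing calls is removed (ties broken at random,
  seeded).  r² is computed on pairwise-complete observations; pairs
  sharing fewer than 10 lines are treated as unlinked.  Markers on
  different chromosomes are never compared.
* **ANOVA screen** — per marker, the single-degree-of-freedom
  regression-slope F-test of `phenotype ~ dosage`; markers with
  p < pval are kept (a threshold of exactly 1.0 keeps the full set,
  including zero-variance markers, whose p is set to 1).  The
  dosage-as-factor one-way ANOVA is a deliberate non-choice: the
  linear-dosage test is the standard additive SNP screen and has one
  df regardless of how many genotype classes segregate.
* **ANO+LD** — the composition: screen first, prune the survivors.

The ANOVA screen uses phenotypes, so inside cross-validation it re-runs
on each training fold by default ("fold-honest").  The whole-set
variant is exposed (`honest: False`) because the contrast is
instructive: selecting markers on data that includes the validation
lines inflates predictive ability through overfitting, and the package
reproduces that contrast in its acceptance suite.

## Training-set selection

**RANDOM** draws a uniform subset; the complement is the validation
set.  **OPTI** maximizes the mean coefficient of determination (CDmean)
of the unphenotyped lines: for the contrast c between an unselected
line and the mean of the unselected set,

```
CD(c) = c′(G − λ(Z′MZ + λG⁻¹)⁻¹)c / (c′Gc)
```

with Z the incidence of phenotyped (selected) lines, M the
within-training-set centring projector, and λ = σ²e/σ²g (default 1,
i.e. an assumed h² of 0.5 — supply the trait's actual ratio when
known; the CDmean-vs-random gains in the acceptance experiments use
λ matched to the simulated heritability).  The implementation is
verified against the mixed-model-equations prediction-error-variance
route on random kinships.

The optimizer is an exchange (drop-replacement) search: swap one
selected with one unselected line, accept iff mean CD strictly
increases.  After `n_stall` consecutive rejections the subset is a
local optimum of the single-swap neighbourhood, and the search restarts
from a fresh random subset — keeping the best subset seen — until the
`n_iter` proposal budget (default 3000) is spent.  Restarts matter:
single-swap local optima occur already on 8-line toys.

## Prediction methods

All fifteen methods implement one contract: `fit(tag, geno, pheno)` →
`FittedModel` → `predict_gebv(model, target)`; targets must carry the
training marker panel (any column order; rows aligned by line id).

* **GBLUP** — REML by spectral decomposition of G (profile restricted
  likelihood in log δ = log σ²e/σ²g, coarse grid of 61 points on
  [−6, 6] in log10 then bounded refinement).  Marker effects are
  back-solved (`β = W′G⁻¹ĝ/c`) so the model is scoreable as a dot
  product; PEV comes from the inverse coefficient matrix of the
  mixed-model equations.
* **EGBLUP** — two variance components with covariances `G` (scaled)
  and `G∘G` (elementwise square, unit diagonal), sampled by the kernel
  Gibbs sampler below.  New lines are scored by BLUP projection with
  the corresponding cross-kernels.
* **RR / LASSO / EN** — scikit-learn's coordinate-descent elastic net
  on standardized dosages; the penalty weight is chosen by 5-fold
  cross-validation *inside the training set* (never touching the outer
  validation fold).  Mixing parameter: 0 (ridge), 1 (LASSO), or
  `alpha_mix` (default 0.5).  A single-element grid bypasses CV and
  matches the closed-form ridge solution to 1e−8 (tested).
* **BRR / BL / BA / BB / BC** — single-site Gibbs samplers (numba-
  compiled) for `y = 1μ + Xβ + e` with, respectively: Gaussian prior
  with a common variance; double-exponential (exponential prior on
  per-marker variances, inverse-Gaussian conditional); scaled-t via
  per-marker scaled-inv-χ² variances; point mass at zero plus scaled-t
  slab; point mass plus Gaussian slab.  Hyperparameters follow the
  variance-partition rule: prior scales are set so the markers are
  expected a priori to explain R² = 0.5 of the phenotypic variance;
  all variance hyperpriors are scaled-inv-χ² with 5 df; the inclusion
  probability π of BB/BC gets a Beta(5, 5) prior (p₀ = 0.5, concentration
  10) and is updated.  Defaults n_iter = 5000, burn-in 1000, thin 5.
  Chains are seeded and bit-reproducible.  PEV is the posterior
  variance of each line's genetic value; σ²g is reported as the
  posterior mean of var(g) across lines.
* **RKHS / MRKHS** — Gaussian kernels
  `K_h = exp(−h·d²/mean(d²))` on squared Euclidean genotype distances
  (mean over off-diagonal entries), one variance component per
  bandwidth, sampled in each kernel's eigenbasis where the
  conditionals are independent Gaussians.  Defaults: single h = 1;
  multi-kernel ladder h ∈ {0.1, 0.5, 2.5}.
* **RF / SVM** — scikit-learn regression forest (500 trees, seeded) and
  ε-insensitive RBF support-vector regression on standardized dosages.
  Feature columns are put in a canonical (sorted) marker order first so
  predictions cannot depend on the incoming column order.  The SVM
  warns above 20,000 markers, where RBF-kernel SVR is known to degrade
  on this kind of data.
* **BRNN** — a single hidden layer of tanh units (default 2) trained
  for 20 epochs; each epoch runs a bounded L-BFGS minimization of
  `β·ED + α·EW` followed by MacKay evidence updates of (α, β) using the
  effective number of parameters `γ = Σ s²/(s² + α)` from the singular
  values of the scaled Jacobian.  Seeded initialization.

PEV (hence reliability) is reported only for the methods with an
explicit Gaussian model: GBLUP, EGBLUP, the Bayes family, RKHS.

## Cross-validation and metrics

Each replicate partitions the lines into `n_folds` near-equal random
folds (exact partition, sizes differing by ≤ 1); each fold is predicted
from a model trained on the rest, fold GEBV are merged, and the metrics
are computed on the merged vector — the *hold* predictive ability, not
a fold-by-fold average (a constructed two-fold counterexample in the
test suite shows they differ).  RMSEP is `√mean((GEBV − y)²)`.
Reliabilities in the per-individual table come from one final full-data
fit; negative values of `1 − PEV/σ²g` are clipped to zero and counted.
Defaults are 10 folds × 100 replicates; the test and acceptance suites
use 2–5 replicates, which is enough for the orderings they assert.
Imputation (genotype-only, no phenotype leakage) runs once up front;
phenotype-using reduction re-runs inside each training fold unless the
leaky mode is requested explicitly.

## The population simulator

The generator emulates the material of a closed elite breeding
program: a pool of `n_founders` (default 16) founder haplotypes with
per-marker allele frequencies uniform on (0.1, 0.9); lines come in
biparental families of `family_size` (default 4) whose parents are
drawn from the pool; each inbred line is a two-parent Markov mosaic
(switch probability `recomb_rate` = 0.02 per marker step, restarting
each chromosome) doubled to homozygosity — the genome of a recombinant
inbred line, dosages in {0, 2}.  Full sibs then share ≈ 0.5 of their
genome, half-sib families ≈ 0.25, and unrelated families are loosely
connected through the pool, giving the *variable* relatedness on which
kinship-based imputation and CDmean optimization rely.  (An earlier
all-lines-from-one-pool design produced uniform relatedness, under
which training-set choice is irrelevant and CDmean optimization merely
chases noise — a useful negative control, not a useful test bed.)

The trait: `n_qtl` (default 100) markers get N(0,1) additive effects on
centred dosages; an optional `epistasis_fraction` adds products of
centred dosage pairs scaled to the requested variance share.  Noise
variance is set from the realized TBV variance so the phenotype
heritability matches `h2_target` (default 0.6; realized h² is within
±0.05 of target at n = 2000 over seeds).  Defaults: 300 lines × 2000
markers on 21 chromosomes.

What the simulator does **not** emulate: genotyping error, non-random
(platform- or MAF-dependent) missingness, selection history and drift,
population substructure beyond the family/pool hierarchy, multiple
environments or G×E.  Passing tests therefore show the pipeline's
internal consistency and its qualitative orderings under idealized
random missingness and family structure — not field performance.

`mask_genotypes` masks a uniform random fraction of observed cells,
re-drawing (with a warning) cells whose loss would leave a marker or a
line with no observed call.

## Problem sizes in the test and acceptance suites

The orderings are asserted at desk scale, chosen so the full suite runs
in minutes on one core: imputation-method ordering at n = 300 lines ×
m = 2000 markers, 5 seeds, 60/80% masking; ANOVA-overfitting contrast
and cross-method concordance at n = 300 × m = 1000; training-size curve
at sizes {50, 100, 200, 400} from a 500-line population; CDmean
experiments at n = 200 × m = 800 with a 2000-proposal search budget;
cross-method concordance with 5000-iteration chains.  Expected
behaviour at these sizes was verified over independent seeds before the
suites were frozen.  One caveat is inherent to scale: the EM-vs-mean
imputation gap at extreme missingness grows with marker count (kinship
precision), so desk-scale gaps (≈ +0.02–0.04 predictive ability) are
smaller than what dense real panels show.

## Known limitations

* EMI assumes missingness is random; systematically missing markers
  (e.g. presence/absence variation) violate the conditional model.
* The CDmean criterion needs a sensible λ; with a badly misspecified
  variance ratio the optimized sets lose their advantage.
* BRNN is a small network trained with restrictive defaults (2 neurons,
  20 epochs) to keep runtime bounded; it is not a tuned deep model.
* No G×E modelling, no multi-trait selection, no pedigree-based
  relationships, no map-aware haplotype imputation — dedicated tools
  should be used upstream where those matter.
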