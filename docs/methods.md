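# Methods

This document specifies the statistical model, the simulation scheme, and the
numerical methods implemented in `markerh2`, together with the conventions
and known limitations a user should be aware of before interpreting results.

## 1. The question

The animal model estimates the additive genetic variance `σ²_A` (and hence
the narrow-sense heritability `h² = σ²_A / (σ²_A + σ²_e)`) from the
covariance of phenotypes among relatives. Classically the expected
relatedness comes from a pedigree. When no pedigree exists, pairwise
relatedness can instead be estimated from molecular markers. `markerh2`
quantifies, by simulation, the bias `E(ĥ² − h²)` and the sampling error
`E(ĥ² − E(ĥ²))²` of marker-based heritability estimation relative to the
pedigree-based estimator, in randomly mating and in partially selfing
populations.

## 2. Simulation model (`markerh2.simulator`)

* **Population.** `N` hermaphroditic diploid individuals, non-overlapping
  generations, constant size. Each offspring is produced by selfing with
  probability `S`; otherwise two *distinct* parents are drawn uniformly
  (forcing distinctness makes `S` exactly the realized selfing rate rather
  than `S + (1−S)/N`). Parents are sampled with replacement across
  offspring.
* **Genome.** `L_M` biallelic marker loci and `L_QTL` causal loci with
  `n_qtl_alleles` alleles each, all unlinked: each locus segregates
  independently (one uniformly chosen allele transmitted per parent per
  locus). No mutation after the founders.
* **Founders.** Allele frequencies per locus are drawn from a symmetric
  Dirichlet with concentration `theta` (default 0.2), the frequency-spectrum
  shape of mutation–drift equilibrium; loci whose founder draw is fixed for
  one allele are redrawn. Founder genotypes are formed by drawing two
  alleles per locus per individual from those frequencies.
* **Trait.** Purely additive: the genotypic value of individual *i* is the
  sum of the effects of its `2 L_QTL` causal alleles. Allelic effects are
  i.i.d. standard normal; only the environmental variance is tuned to hit the
  target heritability (fixing one scale loses no generality). Phenotype =
  genotypic value + `Normal(0, σ²_e)`.

### Heritability calibration at the analyzed generation

`calibrate_env_variance` implements `σ²_e = V_G (1 − h²)/h²`, so that
`V_G/(V_G + σ²_e) = h²` for whatever genotypic-value variance `V_G` it is
given. The `simulate` driver deliberately calibrates against the **final
(analyzed) generation's** realized genotypic variance, not the founder
generation's:

* Ten generations of selfing at `S = 0.9` inflate the genotypic variance by
  roughly `(1 + F)` (with `F = S/(2−S) ≈ 0.82`) relative to the founders,
  while drift erodes it slightly under random mating.
* If `σ²_e` were fixed from the founders, the *true* heritability of the
  analyzed generation would differ from the nominal target by up to ~0.13
  under selfing, and every estimator — including the pedigree-based gold
  standard — would appear biased by that amount. The comparison truth would
  no longer be the configured `target_h2`.
* Calibrating at the analyzed generation makes `target_h2` the actual
  heritability of the individuals being analyzed, so bias measures the
  estimator, not the calibration convention.

The founder-calibration behaviour remains available by calling
`calibrate_env_variance` on founder genotypic values directly.

## 3. Relatedness (`markerh2.relatedness`)

### Pedigree kinship

Standard kinship recursion in generation order, vectorized one generation at
a time (parents always belong to the previous generation):

* founders: `Φ(i,i) = 1/2`, `Φ(i,j) = 0`;
* `Φ(i,j) = [Φ(s_i,s_j) + Φ(s_i,d_j) + Φ(d_i,s_j) + Φ(d_i,d_j)]/4` for
  distinct non-founders of the same generation (computed against the parent
  generation matrix for mixed pairs);
* `Φ(i,i) = [1 + F_i]/2` with `F_i = Φ(sire_i, dam_i)`.

`pedigree_inbreeding` returns `F_i = Φ(sire_i, dam_i)`. Under selfing rate
`S` the population mean follows `F_{t+1} = (S/2)(1 + F_t)`, converging to the
equilibrium `F = S/(2−S)` (`equilibrium_inbreeding`).

### Marker kinship (Loiselle estimator)

For allele `a` of locus `l`, let `p_{il,a}` be the half-dosage of `a` in
individual `i` (0, ½ or 1 for diploids) and `p̄_{l,a}` the sample mean. The
estimator is

```
K_ij = [ Σ_{l,a} (p_{il,a} − p̄_{l,a})(p_{jl,a} − p̄_{l,a})  +  Σ_{l,a} p̄_{l,a}(1 − p̄_{l,a})/(n − 1) ]
       / Σ_{l,a} p̄_{l,a}(1 − p̄_{l,a})
```

It is referenced to the *sample* allele frequencies (no Hardy–Weinberg
assumption, robust to rare alleles) and supports any number of alleles per
locus, so the same code computes marker-, QTL- and (if desired) combined
kinship. Conventions:

* **Diagonal**: the same formula is applied with `i = j`; the diagonal is a
  homozygosity-weighted self-comparison, the natural marker analogue of
  `(1 + F_i)/2`.
* Monomorphic loci contribute zero weight and drop out; a matrix of only
  monomorphic loci is an error. `n_loci_used` records the polymorphic count.
* Because coefficients are centered on sample frequencies, the mean
  off-diagonal value in a sample of unrelated individuals is not 0 but
  `≈ (n+1)/(2n(n−1))` (centering contributes `−1/(2n)` per pair, the
  bias-correction term `+1/(n−1)`). Negative estimates for unrelated pairs
  are expected and meaningful; see truncation below.

### Covariance structures

The additive covariance among individuals is modeled as
`Cov(a_i, a_j) = 2 Φ_ij σ²_A / (1 + F)`:

* pedigree method: `Φ` from the pedigree, `F` = mean pedigree inbreeding;
* marker method: `Φ = K` (Loiselle), `F = S/(2−S)` from the known selfing
  rate (the pedigree is assumed unavailable);
* truncated marker method: element-wise `max(K, 0)` before the transform
  (`truncate_nonnegative`), the common practice of zeroing "negative
  relatedness".

The `1/(1+F)` factor converts the inflated genic variance of inbred
populations to the scale of `σ²_A` in the analyzed generation: for a fully
selfed line (`Φ_ii = 1`, `F = 1`) the diagonal of `G* = 2Φ/(1+F)` is 1.

`covariance_structure` finally projects `G*` to the nearest positive
semidefinite matrix by clipping negative eigenvalues at zero. Marker-based
`K` is not guaranteed PSD; REML requires a valid covariance. Eigenvalue
clipping is the minimal-change repair and leaves pedigree matrices (already
PSD) untouched.

## 4. REML animal model (`markerh2.animal_model`)

Model: `y = μ + a + e`, `a ~ N(0, σ²_A G*)`, `e ~ N(0, σ²_e I)`, with a
single fixed intercept.

* **Rotation.** `G* = U D Uᵀ` is eigendecomposed once; in the rotated basis
  `V = σ²_A D + σ²_e I` is diagonal, so each restricted-likelihood
  evaluation is `O(n)` (the FaST-LMM trick for a single random effect).
* **Profiling.** With `λ = σ²_A/σ²_e`, the residual variance has a closed
  form at the optimum (`σ̂² = RSS_λ/(n−1)`), leaving a one-dimensional
  profile restricted likelihood in `log λ`. It is maximized by a 64-point
  grid scan on `log λ ∈ [−12, 12]`, Brent refinement in the best bracket,
  and an explicit check of the `λ = 0` boundary. The fit is guaranteed never
  worse than the best grid point.
* **Restricted likelihood.** The REML criterion includes the
  `log|XᵀV⁻¹X|` term; at `G* = I` it reduces to the closed form
  `−½[(n−1)log 2π + (n−1)log σ̂² + RSS/σ̂²]`. Note that rescaling `y → √c y`
  shifts the restricted log-likelihood by `−(n−1)/2 · log c` (the
  contrast-space Jacobian) while leaving `ĥ²` unchanged.
* **Uncertainty.** `se_h2` comes from the numerical observed information
  (finite-difference curvature of the profile likelihood re-parameterized on
  the `h²` scale). Wald intervals on a boundary-constrained parameter
  undercover somewhat (about 90% observed for nominal 95% in our checks).
* **Diagnostics.** `boundary` flags `σ̂²_A = 0`; `identifiable` flags a flat
  profile (e.g. `G* = I`, where `σ²_A` and `σ²_e` are confounded).

## 5. Experiments (`markerh2.experiments`)

`run_cell` simulates `n_replicates` populations for one parameter
combination and fits all three methods to the *same* populations (paired
design). `run_grid` crosses selfing rates × heritabilities × panel sizes ×
population sizes, with an independent deterministic seed per cell
(`cell_seed`, a CRC32 hash of the cell coordinates and experiment seed).
Non-convergence is recorded per replicate, never fatal, and excluded from
summaries (the exclusion count is logged).

Performance measures: `bias` = mean `ĥ² − h²`; `sampling_error` = mean
squared deviation of `ĥ²` around its replicate mean, computed within a cell.
`paired_compare` wraps the Wilcoxon signed-rank test for method contrasts on
paired replicates; `kinship_regression` regresses one kinship matrix's
off-diagonals on another's (e.g. QTL kinship on marker kinship — a slope
near 1 means markers capture the realized relatedness at causal loci).

## 6. Default problem sizes

The package defaults (`N = 500`, 10 generations, `S ∈ {0, 0.9}`,
`L_QTL = 500` with 5 alleles, panels of 384–5000 SNPs, `h² ∈ {0.15, 0.3,
0.6}`, 20 replicates per cell) are the reference configuration of the
package's own simulation study; every one of them is a `SimulationConfig` /
`ExperimentGrid` field and can be changed freely. The full default grid
(48 cells × 20 replicates × 3 methods) runs in roughly 7 minutes on one CPU.

## 7. Known limitations

* **Unlinked loci only.** No linkage map, so identity disequilibrium between
  markers and QTLs is generated purely by non-random mating, not by linkage.
* **Additive traits only.** No dominance or epistasis; `σ²_A` is the only
  genetic component.
* **Single random effect.** The REML solver handles one relatedness matrix
  plus residual; no maternal, dominance or repeated-measures terms.
* **Equilibrium `F` for the marker method.** The marker method plugs in
  `F = S/(2−S)`, which assumes the selfing rate is known and the population
  is at inbreeding equilibrium; after only a few generations of selfing this
  overstates `F`.
* **Wald standard errors.** `se_h2` is a curvature-based approximation; for
  estimates near the boundary, likelihood-ratio or bootstrap intervals are
  preferable.
* **Marker-method attenuation.** With finite panels, Loiselle kinship is a
  noisy estimate of realized relatedness; regression attenuation propagates
  into `ĥ²` and shrinks as the panel grows. This is a property of the
  estimator being studied, not a numerical artifact; see
  `analysis/03_kinship_at_causal_loci.py` and `analysis/04_panel_size_sweep.py`.
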