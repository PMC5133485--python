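# Methods

## Model

For each of `n` unrelated individuals we observe `K` correlated continuous
phenotypes `Y_i = (Y_i1, …, Y_iK)'`, `m` covariates `X_i`, and the dosages
`G_i = (G_i1, …, G_iv)'` of `v` (typically rare) variants in a region.  The
joint model is the multivariate linear model

    Y_i = α₀ + (I_K ⊗ X_i') α + (I_K ⊗ G_i') β + ε_i ,
    ε_i ~ N_K(0, Σ_ε)   i.i.d. across individuals.

The stacked variant-effect vector `β` (phenotype-major) is treated as
random,

    β ~ N_{Kv}(0, Σ_β),    Σ_β = τ · R_ρ ⊗ W,

where `R_ρ = (1−ρ) I_K + ρ J_K` is exchangeable — the effects of the same
variant on two different phenotypes have common correlation `ρ`, the
effects of different variants are independent — and `W = diag(w_j²)` holds
per-variant weights `w_j = Beta(maf_j; a, b)` (default `(a, b) = (1, 25)`,
the usual rare-variant up-weighting; `(1, 1)` is unweighted).

The region-level null hypothesis is `H₀: β = 0`, equivalently `τ = 0`.

## Score statistic and its null law

With `r` the phenotype-major stacked residual vector of the covariate-only
null fit, and `V = Σ̂_ε ⊗ I_n`, the variance-component score statistic at a
given ρ is the quadratic form

    Q(ρ) = r' V⁻¹ (R_ρ ⊗ G W G') V⁻¹ r .

Because the design is identical across phenotypes, per-phenotype ordinary
least squares equals the multivariate GLS fit, and the residual covariance
is estimated as `Σ̂_ε = resid' resid / (n − m − 1)` (intercept counted;
unbiased under H₀).  Conditional on the null fit, `Q(ρ)` is distributed as
a mixture of independent 1-df chi-squares whose weights are the eigenvalues
of

    (R_ρ^{1/2} Σ̂_ε⁻¹ R_ρ^{1/2}) ⊗ (W^{1/2} G⊥' G⊥ W^{1/2}),

with `G⊥` the genotype matrix residualised against the null design.  The
Kronecker structure means only one `K × K` and one `v × v` symmetric
eigenproblem are solved per region; the `Kv` mixture weights are all outer
products of the two spectra.  `R_ρ^{1/2}` has the closed form
`√(1−ρ)(I − J/K) + √(1+(K−1)ρ) J/K`.

With `K = 1` the statistic and mixture reduce exactly (up to a common
scale, to which the tail probability is invariant) to univariate SKAT:
`Q = r'GWG'r/σ̂²` against the eigenvalues of `W^{1/2} G⊥' G⊥ W^{1/2}`.
This reduction is enforced by tests to 1e-8 relative.

## Tail probabilities of the chi-square mixture

`P(Σ λ_l χ²₁ > q)` is computed by numerical inversion of the
characteristic function (the Imhof integral):

* one weight: the exact scaled-chi-square tail;
* two weights: an exact smooth 1-D integral obtained by conditioning on
  the larger component (the oscillatory inversion integral is hard to
  certify at this dimension, the conditional form is not);
* three or more: adaptive quadrature of the Imhof integrand on `[0, U]`,
  with `U` chosen so that an integration-by-parts bound on the oscillatory
  tail (phase derivative ≥ q/4 beyond the chosen point) is below one tenth
  of the accuracy target, and a subdivision budget scaled to the number of
  oscillation periods.

Mixtures are normalised by their largest weight before inversion, which
makes the scale equivariance `p(cλ, cq) = p(λ, q)` hold to floating-point
reproduction and is what makes the K = 1 reduction exact in practice.
When the computed tail is comparable to its own error bound the inversion
is retried at a tighter tolerance (down to 1e-14); only beyond that is the
moment-matching approximation of Liu et al. (mean/variance/skewness
matched to a noncentral chi-square) substituted, and the result flagged.
Returned p-values are floored at the smallest positive double so that
−log10 p stays finite.  Eigenvalues below 1e-10 of the largest are
truncated as numerical null space.

## Data-adaptive ρ and the combined p-value

ρ is unknown, so `Q(ρ)` is evaluated on the grid
`{0, 0.1, …, 0.9, 0.99}` (ρ = 1 excluded to keep `R_ρ` positive definite;
0.99 stands in for perfectly correlated effects).  Each `p(ρ)` is computed
analytically as above; `min_p` is their minimum.  The distribution of that
minimum is calibrated by score resampling: `B` surrogate residual matrices
are drawn from `N(0, Σ̂_ε)` per row (`Σ̂_ε` held fixed — score-test logic
conditions on nuisance estimates; orthogonality to the design is implicit
because `G⊥` is used), and `Q(ρ)` is recomputed for every surrogate.
Within each ρ the surrogate sample defines an empirical p-scale (rank
transform) applied identically to the observed statistic; the minimum over
the grid is taken on that common scale and

    final_p = (1 + #{surrogate min ≤ observed min}) / (B + 1),

floored at `min_p` (the combined p-value cannot undercut the observed
minimum; the floor removes Monte Carlo undershoot).  The conservative
`grid-size × min_p` Bonferroni bound is reported alongside.  The empirical
rank transform was chosen over an approximate analytic p-scale because any
ρ-dependent approximation error distorts which grid point attains the
minimum and costs power; the rank scale is exact per ρ given B.  With a
single grid point, or with `K = 1` (where ρ has no effect), the resampling
step is skipped and `final_p = min_p`.

Defaults: `B = 1000` (p-value granularity ≈ 1e-3); the K = 2, v = 10,
n = 500 region costs roughly 0.1 s.

## Univariate comparison and multiple testing

Per-phenotype SKAT p-values are combined by Bonferroni over phenotypes,
`min(1, K · min_k p_k)` — for K = 2 the twice-the-minimum rule.  Scan-level
family-wise control is Bonferroni over regions, `α / n_tests`.  Q-Q data
pair the ordered observed p-values with uniform quantiles `i/(N+1)` on the
−log10 scale.

## Preprocessing conventions

* Phenotypes are natural-log transformed (base fixed and documented;
  results are not invariant to base through the linear model, only the
  fit's scale changes).
* Complete-case filtering removes samples missing any phenotype **or**
  covariate: the null regression needs a full design row for every
  retained sample.
* Carriers are counted on observed genotypes before imputation; a
  homozygote counts once.  The default filter keeps variants with ≥ 4
  carriers.
* Missing genotypes are mean-imputed with the expected dosage
  `2 × (observed alt-allele frequency)` — deterministic, so the allele
  frequency is conserved.  Internally allele frequencies are accumulated
  in exact rational arithmetic with a single final rounding; this makes
  the conservation bit-exact whenever the alt allele is the minor allele
  (always the case in the rare-variant regime).  When alt is the major
  allele the fold `1 − f` necessarily introduces a second rounding: the
  alt-allele frequency is still conserved bit-exactly, the folded MAF to
  within 1 ulp.
* `Σ̂_ε` is ridge-regularised (1e-8 × mean diagonal added) only if its
  condition number exceeds 1e12, so near-degenerate phenotype pairs fail
  soft; a singular matrix after regularisation is an error.

## Region construction

Gene regions come from glist annotations (1-based inclusive bounds; genes
without variants are dropped; overlapping genes may share variants).
Windows tile each chromosome with non-overlapping fixed-width (default
30 kb) intervals anchored at coordinate 1 — a deterministic, restart-free
tiling; a first-variant anchor is available as an option.  Windows
partition the occupied genome: every variant falls in exactly one window.
Single-variant "regions" are the variants passing the carrier filter.

## Synthetic data

The generator reproduces the statistical structure the analysis assumes:
by default n = 1851 unrelated samples; two phenotypes on the log
blood-pressure scale with residual correlation 0.542 and unit variances;
age ~ N(40, 10²) and sex ~ Bernoulli(0.5) covariates with small fixed
effects (intercepts ln 120 and ln 75, +0.002 per year of age, +0.03 for
male sex — typical log-mmHg magnitudes, chosen once); variant MAFs uniform
on [0.001, 0.05] with genotypes Binomial(2, MAF), so singletons and
doubletons are common at the lower end and the 4-carrier filter is
exercised.  Causal effects are drawn multivariate normal with common
cross-phenotype correlation `effect_corr` (a shared draw when
`effect_corr = 1`) and standard deviation `effect_size`; effects can be
restricted to a subset of phenotypes to emulate single-trait genetics.
Everything derives deterministically from one seed.

What the generator does **not** emulate: linkage disequilibrium between
variants (independent Binomial draws), population structure or
relatedness, genotype-calling error, and non-Gaussian phenotype tails.
Passing calibration and power checks on this generator therefore
demonstrates correctness of the statistics under their own assumptions,
not robustness to those real-data features.

## Calibration and power checks: problem sizes and findings

Type-I error is verified on 2000 replicate null regions (n = 500, v = 10,
K = 2, correlation 0.542, B = 500), with the empirical size of MURAT and
per-phenotype SKAT required to fall in [0.04, 0.06] at α = 0.05 and the
Q-Q points to track the diagonal within a 99% Kolmogorov band.  These
sizes keep the full suite comfortably inside a desktop run while making
the binomial bands meaningful.

Power ordering is checked at 500 replicates (B = 1000).  A finding worth
recording: with residual correlation +0.542 and **same-sign** effect
correlation (+0.9), the joint test and the twice-the-minimum univariate
combination are statistically indistinguishable at K = 2 and α = 0.05
(margin ≈ +0.01 ± 0.01 at 1200 replicates): same-sign effects project
mainly onto the high-variance phenotype-sum direction, and the adaptive
grid's multiplicity cost absorbs the remaining edge (a fixed ρ = 0.99 test
does beat the univariate combination by ~6 points there).  The joint
test's decisive advantage appears when effect and residual correlations
differ — the power demonstration therefore uses opposite-direction
pleiotropy (every variant affects both traits, effect correlation −0.9),
where MURAT's power is ~0.90 against ~0.58 for adjusted SKAT.  Conversely,
when only one trait carries the signal, that trait's own SKAT beats the
joint test — the joint analysis dilutes single-trait signal, exactly the
behaviour expected of pleiotropy-oriented tests.

## Known limitations

* The analytic minimum-p combination over the ρ grid used by the original
  method is not reproduced; the seeded resampling combination is the
  documented stand-in (module boundary allows an analytic drop-in).
* Unrelated samples only: no kinship, mixed models or population-structure
  adjustment.
* Continuous phenotypes only; no binary traits, no SKAT-O style
  burden/variance-component mixture for the univariate comparator.
* p-values from score resampling have granularity 1/(B+1); genome-wide
  thresholds (~1e-6) require the per-ρ analytic p-values (`min_p`,
  `bonferroni_p`), not `final_p`, or a much larger B.
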