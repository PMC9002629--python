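# Methods

## Design and data model

The unit of analysis is a balanced half-diallel trial: `p` parents, their
`p(p-1)/2` unordered F1 crosses (no reciprocals), and the selfed parents
themselves, giving `g = p(p+1)/2` entries grown in `r` complete blocks under
one or more irrigation regimes.  The default study shape is `p = 8`,
`r = 3`, two regimes (well-watered, water-deficit), hence 36 entries, 28
crosses and 216 plots per trait.  `PhenotypePanel` stores one row per
(entry, block, regime); construction validates completeness, uniqueness and
finiteness, and loudly rejects anything else — the closed-form ANOVA and
combining-ability algebra below assume exact balance, so imputation is
deliberately out of scope.  Cross labels are canonicalized by parent order
at the boundary, so `(P2, P1)` and `(P1, P2)` are the same entry everywhere
inside the package.

Each trait carries a direction flag (`higher-is-better` by default;
`lower-is-better` for plant height).  Directions are used only when
interpreting effect signs in reports, never in estimation.

## RCBD ANOVA and the genotype partition

Per trait and regime the model is the two-way fixed-effects fit
`y_gk = μ + genotype_g + block_k + ε_gk`.  Sums of squares come from the
standard balanced closed forms; the genotype SS is then split into
between-parents (df `p−1`), between-crosses (df `p(p−1)/2 − 1`) and the
single-df parents-vs-crosses contrast, obtained by subtraction
`SS_G − SS_P − SS_C` (algebraically equal to the group-mean contrast
`(m_P − m_C)²/(1/n_P + 1/n_C)`; a unit test asserts this).  Every
genotype-level source is tested against the residual mean square.  Each
regime is analysed separately — the two regimes are separate adjacent
experiments, and no pooled across-regime ANOVA is attempted.  Blocks are
kept in the model and reported even where published tables omit the row;
the residual df `(g−1)(r−1) = 70` matches the study layout either way.
Degenerate inputs (all observations equal) yield SS = 0, F reported as NaN
and p = 1 rather than an exception.

## Griffing method-2 model-1 combining ability

Estimation uses the classical closed forms on the symmetric entry-mean
matrix `x_ij` (see README for the formulas).  The parametrization is
saturated: with the constraints `Σ_i ĝ_i = 0` and, per array,
`Σ_j ŝ_ij + ŝ_ii = 0`, the decomposition is the exact least-squares
projection, and the saturation identity `x_ij = μ̂ + ĝ_i + ĝ_j + ŝ_ij`
(selfs: `x_ii = μ̂ + 2ĝ_i + ŝ_ii`) holds to machine precision on every
input.  The test suite checks the closed forms against an independent
constrained least-squares solver on random tables.

Model 1 (fixed effects) inference: the error term is the plot-error mean
square divided by `r` (putting it on the entry-mean scale) with the
plot-error df; GCA (df `p−1`) and SCA (df `p(p−1)/2`) mean squares are each
tested against it.  Effect variances are

```
Var(ĝ_i)  = σ'² (p−1)/(p(p+2))
Var(ŝ_ij) = σ'² (p²+p+2)/((p+1)(p+2))    (i ≠ j)
Var(ŝ_ii) = σ'² p(p−1)/((p+1)(p+2))
```

and `LSD_α = t_(α/2, df_error) · SE`, used to star individual effects at
0.05/0.01 with a strict inequality (an effect exactly at the LSD is not
significant).  Two deliberately separated alternatives are exposed but are
never the default: the SE of a *difference* `ĝ_i − ĝ_j`
(`√(2σ'²/(p+2))`, field `se_gi_diff`), and Baker's predictability ratio
`2MS_GCA/(2MS_GCA + MS_SCA)` alongside the default `MS_GCA/MS_SCA`.  Both
ratios are computed at full precision, never from rounded mean squares.
Self SCA effects `ŝ_ii` are computed and written to their own output file,
since published cross tables usually omit them.

## Tolerance indices and grouping

GMP, MP, YI and STI are computed from grain-yield entry means only, with
strictly positive yields required (GMP is undefined otherwise).  Useful
identities — `GMP² = Y_s·Y_p`, `mean(YI) = 1`, `GMP ≤ MP` (AM–GM), and STI
being a monotone transform of GMP — are asserted in tests.  Grouping uses
Ward-linkage agglomerative clustering on Euclidean distances of the four
z-scored index columns, cut at `k = 5` groups.  Linkage, standardization
and `k` are parameters of `ToleranceClassifier`; the choice of
Ward + z-scoring is the package's own default where no canonical convention
exists, and the standardization flag is recorded in the classifier.
Group letters are assigned by descending cluster mean of the standardized
index average (A = most tolerant), with ties broken by the
lexicographically smallest entry label; rows are processed in sorted-label
order so the grouping is invariant to input permutation.  The dendrogram
can be exported as newick with heights.

## Stress response and associations

Percent change per trait is `100·(stress − control)/control` on grand means
over all entries and blocks.  Correlations are Pearson `r` with two-sided
p-values on entry means, ordered for heatmap rendering by average-linkage
clustering of `1 − |r|`.  PCA is correlation-matrix PCA (columns z-scored),
so it is invariant to affine rescaling of any trait; zero-variance traits
are dropped with a warning.  Loadings are eigenvectors scaled by the square
root of the eigenvalues, so with all components retained
`L·Lᵀ` reproduces the trait correlation matrix (asserted in tests).  Sign
convention: each component's largest-magnitude loading is made positive,
making outputs deterministic.  Associations default to the water-deficit
regime, where trait relationships are interpreted; the regime is a
parameter.

## Synthetic trial generator

`simulate_trial` mirrors the fixed-effects model: per trait and regime, raw
GCA draws `~ N(0, σ²_gca)` are centered, and raw symmetric SCA draws
`~ N(0, σ²_sca)` are projected onto the pure-SCA constraint space by the
same closed-form decomposition the estimator uses.  **Truth is defined
post-projection**: the raw draws are not identifiable (a raw SCA matrix has
a GCA component), and using them as "truth" would make recovery ill-posed
and would break the null calibration of the GCA F test.  Entry means are
`μ_m + g_i + g_j + s_ij`; block effects are drawn and centered (so entry
means are exactly the noiseless truth when `σ_error = 0`), and plot error
is iid Gaussian.  `μ_m = μ · regime_effect` for post-control regimes, so a
`regime_effect` of 0.747 programs a 25.3% reduction; sigmas scale with the
regime effect by default, keeping coefficients of variation constant.  GCA
is correlated across regimes through a shared standard-normal vector
(default ρ = 0.8, a deliberately high but imperfect cross-regime stability).

The `paper_like_config` preset fixes `p = 8`, `r = 3`, two regimes and 18
traits whose regime effects reproduce the reported stress responses
(reductions of 5.5–31.4% for photosynthetic, agronomic and carbohydrate
traits; increases of 9.7–155.7% for proline, antioxidant enzymes, protein
and gluten).  Control-regime means are plausible trait-unit values (e.g.
30 g/plant grain yield, Fv/Fm 0.80, RWC 85%); genetic and environmental
spread uses fixed coefficients of variation (GCA 5%, SCA 4%, block 2%,
plot error 6% of the control mean), chosen once to give clearly significant
GCA and SCA tests at the study size, as in real trials of this kind.

What the generator does *not* emulate: epistasis, genotype-specific regime
interaction beyond regime-level scaling, non-normal residuals, spatial
field trends, missing plots, and trait–trait genetic correlations (traits
are generated independently; association tests construct coupled traits
explicitly).  Passing recovery tests therefore demonstrates correctness of
the estimators under the stated model, not robustness to those
complications.

## Verification and calibration

- Closed-form Griffing estimates match an independent constrained
  least-squares oracle to 1e−8 on random tables; RCBD SS match brute-force
  group-mean decompositions and a statsmodels OLS fit.
- With `σ_gca = 0` the GCA F test's empirical type-I error over 500 seeded
  replicates sits within two Monte-Carlo standard errors of the nominal
  0.05 (p-values are uniform under the null).
- `E[MS_GCA] = σ'² + (p+2)σ²_gca` at `σ_sca = 0`, checked by simulation.
- RMSE of `ĝ` shrinks like `1/√r` over `r ∈ {2, 3, 5, 10}`.
- Simulation sizes in tests (hundreds of 108–216-plot trials) were chosen
  to keep the suite fast while leaving Monte-Carlo bands tight enough to be
  informative.

## Numerical notes and limitations

- Entry-mean matrices are symmetrized (`(x + xᵀ)/2`) before decomposition
  to remove float-level asymmetry from summation order; asymmetry beyond
  1e−9 relative is an error.
- Subtraction-based SS (`P vs C`, residual) are clamped to zero within
  1e−9 of the total SS to avoid tiny negative values.
- CSV round-trips are bit-exact (`%.17g` on write, round-trip float parsing
  on read).
- Only complete balanced designs are supported; no reciprocal (full
  diallel) methods, no random-effects (model 2/3) variance components, no
  heterosis estimates, and no missing-plot estimation.  Supported alphas
  for starring are 0.05 and 0.01.
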