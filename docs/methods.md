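# Methods

`diallelgp` implements an across-population genomic-prediction analysis for a
perennial outbreeding crop: predicting both the mean genetic value of a
bi-parental cross (cross mean) and the within-cross deviations of its
offspring (Mendelian sampling) from genome-wide SNP dosages, with marker
effects trained either within the half-diallel itself, on half-sib families,
or on an external diversity panel. This note documents the models, the
synthetic-data generator, the numerical choices, and what the simulation
studies do and do not demonstrate.

## Phenotype model and genotypic values

Plot phenotypes from a multi-year randomized-complete-block trial are analyzed
with the linear mixed model

    y_ijkl = mu + G_i + C_j + B_k + Y_l + (B:Y)_kl + (G:Y)_il + (C:Y)_jl
             + x + y + x:y + (x:Y)_l + (y:Y)_l + e_ijkl

where G is the genotype effect nested in cross C, B and Y are fixed block and
year effects (with their interaction), and x, y are the field row and column
treated as categorical factors with i.i.d. random effects (no spatial kernel).
All underlined-in-the-field-model terms (G, C, the year interactions, the
spatial terms) are random with independent levels; there is no genomic
covariance in this model. Genotypic values used downstream are the BLUP sum
C + G ("total genotypic value"), scaled to unit sample variance per population
so traits are comparable.

Random-term selection (`drop_random_terms`) is backward elimination by REML
likelihood-ratio tests against the boundary null 0.5*chi2_0 + 0.5*chi2_1,
never dropping G or C. Fixed effects are always retained: selecting among
them changes no downstream quantity (only the BLUPs matter), so the package
does not implement a fixed-effect search.

### Estimation: EM-REML on the mixed-model equations

Variance components are estimated by EM iterations on Henderson's mixed-model
equations (ML is available with the usual n vs n-p denominators and the
conditional-variance trace taken from the random-effect block alone). Each
iteration performs one Cholesky factorization of the coefficient matrix, from
which the solution, the log-determinant (for the REML log-likelihood) and the
conditional-variance traces are all derived. Numerical safeguards, each of
which preserves the EM ascent property (the log-likelihood is checked on
every accepted step):

* components are floored at 1e-10 x var(y);
* Aitken extrapolation on log-components every 5 iterations, kept only when
  it increases the log-likelihood;
* a boundary test every 10 iterations: a component that has decreased for 10
  consecutive iterations is profiled at the floor and fixed there when that
  does not lower the log-likelihood (EM approaches a zero variance only
  geometrically, so this shortcut is what makes near-null terms converge in
  tens rather than thousands of iterations);
* convergence when the largest relative component change drops below `tol`
  (default 1e-6), or when the log-likelihood has gained less than
  1e-7 * (1 + |ll|) over 20 iterations ("plateau stop"). The plateau stop
  matters in tiny or nearly-confounded designs (e.g. within-cross refits)
  where the likelihood is flat along a ridge of component splits; the
  reported components are then one point on that ridge, at the optimum for
  every practical purpose.

The balanced one-way layout, where REML has the closed form
sigma_g = (MSB - MSW)/r and sigma_e = MSW, is the oracle pinning the
implementation (agreement to 1e-6).

## Heritability

Entry-mean broad-sense heritability is

    H2 = (sC2 + sG2) /
         (sC2 + sG2 + (sCY2 + sGY2 + sxY2 + syY2)/n_year
          + (sx2 + sy2 + sxy2 + se2)/(n_year * n_rep_year))

with n_year the mean number of years with data per genotype and n_rep_year
the mean number of replicates per genotype-year; dropped terms contribute
zero. Per-cross heritability refits the selected model inside one full-sib
family with every cross term removed and applies the same formula without the
cross components. In the pipeline, these per-cross refits also drop the
field-coordinate terms: a few dozen within-cross plots cannot identify them,
and retaining them only manufactures likelihood ridges (their variance folds
into the residual, which sits in the same divisor bucket).

The share of genetic variance between crosses is sC2/(sC2 + sG2).

## Marker-effect models

Ridge regression (RR) and LASSO minimize

    (1/2n) ||y - b0 - X beta||^2 + lambda * P(beta),

with P the squared L2/2 or L1 norm, by cyclic coordinate descent with
covariance (Gram) updates; the intercept is unpenalized and markers are
centered and unit-scaled with training-set statistics (zero-variance markers
get scale 0 and thus no effect). Convergence: largest coefficient change in a
sweep below 1e-7. For ridge, coordinate descent is warm-started at the exact
SVD solution — a cold start converges only linearly with rate ~ lambda, which
is hopeless at the small end of the grid — so the sweep acts as a stationarity
verification; the cold-start kernel is held to the dense closed form in the
test suite, and scikit-learn's solvers serve as an independent cross-check.

`lambda` is calibrated by 5-fold inner cross-validation on a log-spaced grid
from lambda_max (the smallest lambda zeroing all LASSO coefficients) down to
lambda_max * 1e-4 (default 100 points), each inner fold re-standardizing with
its own training statistics; the minimizing lambda is selected (not the
1-SE rule), ties resolving toward heavier shrinkage. Inside the CV the ridge
path is evaluated by the SVD closed form and the LASSO path by warm-started
pathwise descent.

Predictions are linear in dosages, so fractional (expected) genotypes are
valid inputs, and the prediction at a parental-average genotype equals the
segregation-weighted mean of the per-class predictions exactly.

## Scenarios and predictive ability

* **1a** random outer 10-fold CV over all offspring, replicated (default 10);
  each individual is predicted once per replicate and its predictions are
  averaged over replicates for the cross-mean modality.
* **1b** per focal cross and per parent, training on that parent's other
  crosses (3 in a 5-parent half-diallel); each cross is predicted twice and
  the two arms are reported separately.
* **2** training on the diversity panel (optionally a single subpopulation),
  validating on every cross.

PA is Pearson's correlation between observed scaled totals and predictions.
Within-cross (Mendelian) PA is computed per (cross, trait) cell; per-trait /
per-cross / overall summaries are means of cells. Cross-mean PA correlates
observed and predicted cross means: per trait across crosses, per cross
across traits, and pooled over all cells for the overall value. Cells with
fewer than 3 pairs or zero variance are reported missing, never zero. For
each cell both RR and LASSO are run and the better PA is kept ("best", ties
toward RR).

Cross means are predicted two ways — averaging predicted offspring values,
and predicting the parental-average genotype (d_p1 + d_p2)/2 directly — and
the two agree almost perfectly (pooled correlation above 0.98 in the
acceptance experiment), so the parental-genotype modality, which needs no
offspring genotypes, is the one used for ranking untested crosses. Ranking
all n(n-1)/2 pairs of a panel uses the linearity identity
pred(pair) = (pred(p1) + pred(p2))/2, with a per-trait additive bias
(mean of predicted minus observed cross means on the known crosses)
subtracted first.

## Training-set optimization

For a validation cross, candidate training sets of fixed size (default sizes
50-250) are scored by PEVmean, CDmean (both derived from the Gaussian
conditional variance PEV = A_VV - A_VT (A_TT + lambda_r I)^-1 A_TV on the
VanRaden relationship matrix, lambda_r = (1-h2)/h2 with default h2 = 0.5) or
MeanRel (mean TS-VS relationship). MeanRel is additive over TS members, so
its optimum is the exact top-k; PEV/CD use greedy forward construction with
incremental block-inverse updates followed by steepest-ascent single-swap
exchanges, best over restarts. The comparison baseline is 10 seeded uniform
random sets of the same size. The criterion definitions, not the search
metaheuristic, are the scientific content; the greedy-plus-exchange search
dominates every random baseline in all tested runs.

## What drives PA

The explanatory table has one row per (trait, cross): the proportion of
non-segregating markers (both parents homozygous, matching or not — either
way the offspring show zero variance at the locus), overall and per-cross H2,
the parents' additive relationship and their distance on the panel PCA plane,
and the cross-variance share; external-training scenarios add the mean TS-VS
relationship, and panel training adds the panel H2 and the subpopulation R^2
of the trait (one-way fixed-effect R^2 of panel genotypic values on
subpopulation). Forward-backward stepwise OLS under the Gaussian AIC
(predictors standardized, ties alphabetical, exact collinearity pruned up
front) selects the model; its R^2 is decomposed by lmg (uniform average of
sequential contributions over orderings, computed by subset enumeration) and
pmvd (proportional marginal variance decomposition: ordering weights
proportional to inverse products of the remaining-variance terms
R2_full - R2(first i), taken in the zero-denominator limit so that a
predictor with an exactly-zero coefficient receives an exactly-zero share).
Both schemes sum to the model R^2 and are enumerated exhaustively (at most
10 predictors).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure* the analysis assumes,
not any real genome:

* **Panel.** Balding-Nichols structure: per marker an ancestral frequency
  uniform on [maf_min, 1-maf_min], subpopulation frequencies
  Beta(p(1-F)/F, (1-p)(1-F)/F) with F = 0.05 (three subpopulations by
  default, mirroring a weakly structured outbreeding crop), haplotypes drawn
  independently per individual. Markers are therefore in linkage equilibrium
  within subpopulations — real panels retain short-range LD.
* **Meiosis.** Haldane model: per chromosome a Poisson number of crossovers
  with mean equal to the map length in Morgans, positions uniform in cM, no
  interference. The default map is 19 chromosomes of 75 cM.
* **Half-diallel.** All pairwise crosses of 5 panel members (4 from one
  subpopulation, 1 from another), default 65 offspring per cross at function
  level; the pipeline desk default uses 30.
* **Traits.** Additive QTL architectures (oligogenic <= 10 QTLs or polygenic
  >= 100), plus an explicit i.i.d. cross deviation: under pure additivity the
  fitted cross variance would be driven only by parent means, whereas the
  fitted quantity in real data also captures non-additive family effects.
  `orthogonalize_cross_means` projects QTL effects so expected cross means
  are equal, making the cross-variance share exactly tunable by
  `calibrate_cross_deviation` (pipeline default: shares spread 0.05-0.5
  across traits). The genetic scale is calibrated so the plug-in entry-mean
  H2 equals the target (defaults spread 0.49-0.91 across the trait suite);
  an unattainable target raises with the implied H2.
* **Phenotypes.** Fixed year/block shifts plus i.i.d. normal effects for
  every random model term at the architecture's sds
  (year_interaction_sd = 0.25, spatial_sd = 0.15, residual_sd = 0.5 by
  default, in units of the scaled genetic sd ~ 1); each genotype-block pair
  keeps one field position across years (perennial layout). Defaults are
  2 years x 2 blocks.

Consequences for interpretation: passing simulations show the machinery is
correct and that relatedness/LD mechanisms have the expected direction; they
do not estimate real-crop PA values. Two deliberate fidelity notes:

* In the scenario-ordering experiment the QTLs are excluded from the
  prediction marker set. Marker-QTL LD then exists within families (linkage)
  but not across the panel, which reproduces the mechanism that makes
  across-population prediction hardest (scenario ordering 1a > 1b > 2). The
  panel scenario's PA is near zero in this setting because the simulated
  panel has *no* marker-QTL LD at all; real panels retain some, so real
  across-population PA is low but not null. With QTLs left among the
  predictors, panel training is unrealistically easy.
* With only 10 crosses, the REML estimate of the cross-variance share is
  noticeably biased downward (~0.24 for a true 0.3 at desk scale): under the
  positivity constraint, variance leaks from the 10-level cross term into
  the 20-level cross:year term. This is a property of the design, visible in
  any software; the realized (true simulated) share is recovered within
  +-0.05.

## Problem sizes

Desk-scale defaults were chosen so that each study runs in minutes on one
core: recovery experiments use a fixed half-diallel of 10 x 20 offspring with
400 markers and 20 replicate architectures; the scenario-ordering experiment
a 120-member panel, 10 x 20 offspring, 400 markers (300 predictors after QTL
exclusion), ridge only, 10-fold CV with 2 replicates and a 30-point lambda
grid; the TS-optimization experiment a 150-member panel with sets of size 50
against 10 random baselines, 20 replicates. The full pipeline default
(`RunConfig`) simulates a 300-member panel, 800 markers, 10 x 30 offspring
and 5 traits. All sizes are configurable; the statistical conclusions above
were stable across the sizes tried.

## Known limitations

* No genomic covariance in the phenotype mixed model (i.i.d. genotype
  levels); GBLUP-style variance estimation is out of scope.
* No dominance or epistasis in either the generator's QTL model (the cross
  deviation is a family-level stand-in) or the prediction models.
* The panel generator has no within-subpopulation LD; conclusions about
  absolute across-population PA magnitudes cannot be read off it.
* PEV/CD are the plain conditional-variance forms without fixed-effect
  contrasts; an external optimizer's exact criterion may differ in that
  detail.
* pmvd is enumerated exhaustively and is limited to 10 predictors.
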