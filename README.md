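# diallelgp

Across-population genomic prediction for half-diallel mating designs:
predicting the **mean genetic value of a cross** and the **within-cross
(Mendelian-sampling) values of its offspring** from genome-wide SNP dosages,
in the setting typical of perennial outbreeding crops such as grapevine — a
diversity panel of a few hundred cultivars weakly structured into
subpopulations, and a half-diallel of bi-parental families bred from a handful
of elite parents.

The package is aimed at quantitative geneticists and breeders who want to
evaluate, on realistic synthetic data, how far marker-trained models carry
across populations, which factors drive predictive ability, and whether
optimizing the training set helps.

## What it computes

**Genotypic values.** Multi-year randomized-block phenotypes are analyzed
with a linear mixed model
`y = mu + G + C + B + Y + B:Y + G:Y + C:Y + x + y + x:y + x:Y + y:Y + e`
(genotype G nested in cross C; block B and year Y fixed; G, C, the field
row/column factors x, y and all their year interactions random with i.i.d.
levels), fitted by
EM-REML on Henderson's mixed-model equations. The BLUP sum C + G, scaled to
unit variance, is the "total genotypic value". Entry-mean broad-sense
heritability is

```
H2 = (sC2 + sG2) / (sC2 + sG2 + (sCY2 + sGY2 + sxY2 + syY2)/n_year
                    + (sx2 + sy2 + sxy2 + se2)/(n_year * n_rep_year))
```

**Marker models.** Ridge regression and LASSO,
`(1/2n)||y - b0 - X beta||^2 + lambda P(beta)`, solved by cyclic coordinate
descent with covariance updates; `lambda` calibrated by 5-fold inner
cross-validation.

**Scenarios.** 1a: outer 10-fold CV over the half-diallel (x10 replicates);
1b: training on each parent's half-sib crosses; 2: training on the diversity
panel (optionally one subpopulation). Predictive ability (PA) is Pearson's
correlation between observed and predicted genotypic values — per
(trait, cross) cell for Mendelian sampling, and over cross means (predicted
either by averaging offspring or directly at the parental-average genotype
`(d_p1 + d_p2)/2`) for the cross-mean component. All `n(n-1)/2` possible
panel crosses can be ranked by bias-corrected predicted mean.

**Training-set optimization.** PEVmean / CDmean (Gaussian conditional
variance on the VanRaden relationship matrix) and MeanRel criteria, greedy +
exchange search with seeded random baselines.

**PA determinants.** Stepwise-AIC regression of per-cell PA on
non-segregating-marker proportion, heritabilities, parent distances, the
cross-variance share and TS-VS relatedness, with lmg / pmvd decomposition of
the model R².

**Synthetic data.** A first-class generator (Balding-Nichols structured
panel, Haldane meiosis, calibrated trait architectures) reproduces the
statistical structure these analyses assume, so everything runs end-to-end
without external data. See `docs/methods.md` for the models and their limits.

## Worked example

```bash
python examples/03_prediction_scenarios.py
```

prints, for one simulated trait (H² = 0.9, 10 crosses × 25 offspring,
ridge regression):

```
scenario 1a  : Mendelian PA 0.98   cross-mean PA 0.94
scenario 1b  : Mendelian PA 0.74   cross-mean PA 0.47
scenario 2   : Mendelian PA 0.49   cross-mean PA 0.94
modality agreement (offspring-average vs parental genotype): r = 0.949
```

Within-diallel cross-validation (1a) predicts individuals best, half-sib
training (1b) is intermediate, and panel training (2) is hardest: Mendelian
PA tracks training-validation relatedness. The two ways of predicting a cross
mean agree closely, so untested crosses can be ranked from parental genotypes
alone (`examples/05_rank_all_crosses.py`). The other examples cover the
generator, the mixed model, training-set optimization, and the PA-determinant
regression.

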