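"""What drives predictive ability: regression of per-(trait, cross) PA on
cross- and trait-level covariates.

The explanatory table has one row per (trait, cross) with the within-cross
individual PA as response and, as predictors: the proportion of
non-segregating markers in the cross, overall and per-cross broad-sense
heritability, the distance between the cross parents (additive relationship
and PCA distance), and the cross-variance ratio; scenarios with an external
training set add the mean TS-VS additive relationship, and panel-trained
prediction adds the panel heritability and the subpopulation R^2 of the trait.

Model selection is forward-backward stepwise regression under AIC; the R^2 of
the selected model is decomposed into per-predictor shares with the averaging-
over-orderings scheme (lmg) and the proportional-marginal-variance
decomposition (pmvd), whose data-dependent ordering weights give exactly zero
share to predictors with zero coefficient.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "ImportanceResult",
    "COMMON_PREDICTORS",
    "SCENARIO_PREDICTORS",
    "assemble_table",
    "stepwise_aic",
    "relative_importance",
    "correlate_pa_with",
]

COMMON_PREDICTORS = [
    "prop_nonseg",        # proportion of non-segregating markers in the cross
    "h2_overall",         # overall broad-sense heritability of the trait
    "h2_cross",           # per-cross broad-sense heritability
    "parent_relationship",  # additive relationship between the two parents
    "parent_pca_distance",  # distance between parents on the panel PCA plane
    "cross_ratio",        # sigma_C^2 / (sigma_C^2 + sigma_G^2)
]
SCENARIO_PREDICTORS = {
    "1a": COMMON_PREDICTORS,
    "1b": COMMON_PREDICTORS + ["ts_vs_relationship"],
    "2": COMMON_PREDICTORS + ["ts_vs_relationship", "h2_panel", "subpop_r2"],
}


@dataclass
class ImportanceResult:
    selected_variables: list[str]
    coefficients: pd.Series
    r2: float
    shares: pd.Series  # per-variable share of R^2
    method: str  # "lmg" | "pmvd"


def assemble_table(pa_cells: pd.DataFrame, cross_stats: pd.DataFrame,
                   trait_stats: pd.DataFrame, scenario: str,
                   trait_cross_stats: pd.DataFrame | None = None,
                   min_rows: int = 15) -> pd.DataFrame:
    """Join per-cell PA with its candidate explanatory variables.

    ``pa_cells``: columns trait, cross, pa (one row per combination).
    ``cross_stats``: indexed by cross (prop_nonseg, parent_relationship,
    parent_pca_distance and, for scenario 1b/2, ts_vs_relationship when it is
    cross-specific). ``trait_stats``: indexed by trait (h2_overall,
    cross_ratio and, scenario 2, h2_panel and subpop_r2).
    ``trait_cross_stats``: optional (trait, cross)-keyed frame for h2_cross and
    trait-specific TS-VS relationships. Rows with any missing value are
    dropped (logged); fewer than ``min_rows`` complete rows raise.
    """
    scen_key = scenario.split("-")[0]
    predictors = SCENARIO_PREDICTORS[scen_key]
    df = pa_cells[["trait", "cross", "pa"]].copy()
    df = df.merge(cross_stats, left_on="cross", right_index=True, how="left",
                  suffixes=("", "_crossdup"))
    df = df.merge(trait_stats, left_on="trait", right_index=True, how="left",
                  suffixes=("", "_traitdup"))
    if trait_cross_stats is not None:
        df = df.merge(trait_cross_stats, on=["trait", "cross"], how="left",
                      suffixes=("", "_tcdup"))
    missing_cols = [c for c in predictors if c not in df.columns]
    if missing_cols:
        raise KeyError(f"explanatory variables missing: {missing_cols}")
    out = df[["trait", "cross", "pa"] + predictors]
    complete = out.dropna()
    n_drop = len(out) - len(complete)
    if n_drop:
        logger.info("assemble_table: dropped %d incomplete rows", n_drop)
    if len(complete) < min_rows:
        raise ValueError(
            f"only {len(complete)} complete rows (< {min_rows}); "
            "the regression would be unstable")
    return complete.reset_index(drop=True)


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    if X.shape[1] == 0:
        return 0.0
    Xi = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Xi, y, rcond=None)
    resid = y - Xi @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float(resid @ resid) / tss


def _aic(y: np.ndarray, X: np.ndarray) -> float:
    n = len(y)
    Xi = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Xi, y, rcond=None)
    rss = float(((y - Xi @ beta) ** 2).sum())
    k = Xi.shape[1] + 1  # + sigma^2
    return n * math.log(max(rss, 1e-300) / n) + 2 * k


def stepwise_aic(table: pd.DataFrame, response: str = "pa",
                 predictors: list[str] | None = None,
                 direction: str = "both") -> "sm.regression.linear_model.RegressionResultsWrapper":
    """Forward-backward stepwise OLS under the Gaussian AIC.

    Starts from the full model and alternates single-variable drops and adds
    until no move lowers the AIC. Predictors are standardized to unit variance
    before the search so AIC moves are scale-free; perfectly collinear
    predictors are removed up front (the later-listed one, logged). Ties break
    alphabetically, making the search deterministic and invariant to column
    order. Returns the fitted statsmodels OLS of the selected model (on
    standardized predictors; raw-scale coefficients are recoverable from the
    scale attributes attached to the result).
    """
    if predictors is None:
        predictors = [c for c in table.columns
                      if c not in (response, "trait", "cross")]
    y = table[response].to_numpy(dtype=float)
    Xraw = table[predictors].to_numpy(dtype=float)
    sds = Xraw.std(axis=0, ddof=1)
    if (sds == 0).any():
        const = [p for p, s in zip(predictors, sds) if s == 0]
        logger.info("removing constant predictors: %s", const)
        predictors = [p for p in predictors if p not in const]
        Xraw = table[predictors].to_numpy(dtype=float)
        sds = Xraw.std(axis=0, ddof=1)
    Xs = (Xraw - Xraw.mean(axis=0)) / sds
    # drop perfectly collinear columns (keep the earlier-listed)
    keep: list[int] = []
    for j in range(Xs.shape[1]):
        trial = Xs[:, keep + [j]]
        if np.linalg.matrix_rank(trial, tol=1e-10) == len(keep) + 1:
            keep.append(j)
        else:
            logger.info("removing collinear predictor %s", predictors[j])
    predictors = [predictors[j] for j in keep]
    Xs = Xs[:, keep]
    cols = {p: Xs[:, j] for j, p in enumerate(predictors)}

    def aic_of(subset: list[str]) -> float:
        X = np.column_stack([cols[p] for p in subset]) if subset \
            else np.empty((len(y), 0))
        return _aic(y, X)

    current = sorted(predictors)
    cur_aic = aic_of(current)
    while True:
        moves: list[tuple[float, str, str]] = []
        if direction in ("both", "backward"):
            for p in current:
                moves.append((aic_of([q for q in current if q != p]), "drop", p))
        if direction in ("both", "forward"):
            for p in sorted(set(predictors) - set(current)):
                moves.append((aic_of(sorted(current + [p])), "add", p))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[2]))
        best_aic, action, var = moves[0]
        if best_aic < cur_aic - 1e-10:
            current = [q for q in current if q != var] if action == "drop" \
                else sorted(current + [var])
            cur_aic = best_aic
        else:
            break
    X = np.column_stack([cols[p] for p in current]) if current \
        else np.empty((len(y), 0))
    Xdf = pd.DataFrame(X, columns=current)
    res = sm.OLS(y, sm.add_constant(Xdf, has_constant="add")).fit()
    res.selected_predictors = current
    res.predictor_sds = pd.Series(
        {p: float(table[p].std(ddof=1)) for p in current})
    res.model_aic = cur_aic
    return res


def relative_importance(table: pd.DataFrame, selected: list[str],
                        response: str = "pa", method: str = "pmvd"
                        ) -> ImportanceResult:
    """Decompose the model R^2 into per-predictor shares (lmg or pmvd).

    lmg averages each predictor's sequential R^2 increment uniformly over all
    orderings (computed by subset enumeration). pmvd weights orderings by the
    inverse products of the remaining-variance terms R^2(all) - R^2(first i),
    taken in the zero-denominator limit, so a predictor whose coefficient in
    the full model is exactly zero receives exactly zero share. Both schemes
    sum to the model R^2. At most 10 predictors (orderings are enumerated).
    """
    p = len(selected)
    if p > 10:
        raise ValueError("more than 10 predictors: ordering enumeration "
                         "infeasible (sampling of orderings not implemented)")
    y = table[response].to_numpy(dtype=float)
    Xall = table[selected].to_numpy(dtype=float)
    full_mask = (1 << p) - 1
    r2 = np.empty(1 << p)
    for mask in range(1 << p):
        idx = [j for j in range(p) if mask >> j & 1]
        r2[mask] = _ols_r2(y, Xall[:, idx])
    r2_full = r2[full_mask]

    if method == "lmg":
        shares = np.zeros(p)
        for j in range(p):
            for mask in range(1 << p):
                if mask >> j & 1:
                    continue
                s = bin(mask).count("1")
                w = math.factorial(s) * math.factorial(p - s - 1) / math.factorial(p)
                shares[j] += w * (r2[mask | (1 << j)] - r2[mask])
    elif method == "pmvd":
        if p == 1:
            shares = np.array([r2_full])
        else:
            entries = []  # (n_zero_denoms, weight, increments)
            for order in itertools.permutations(range(p)):
                mask = 0
                incs = np.zeros(p)
                denom_prod = 1.0
                n_zero = 0
                for i, j in enumerate(order):
                    incs[j] = r2[mask | (1 << j)] - r2[mask]
                    mask |= 1 << j
                    if i < p - 1:
                        d = r2_full - r2[mask]
                        if d <= 1e-12:
                            n_zero += 1
                        else:
                            denom_prod *= d
                entries.append((n_zero, 1.0 / denom_prod, incs))
            max_zero = max(e[0] for e in entries)
            tw = 0.0
            acc = np.zeros(p)
            for n_zero, w, incs in entries:
                if n_zero == max_zero:
                    tw += w
                    acc += w * incs
            shares = acc / tw
    else:
        raise ValueError("method must be 'lmg' or 'pmvd'")

    Xdf = pd.DataFrame(Xall, columns=selected)
    fit = sm.OLS(y, sm.add_constant(Xdf, has_constant="add")).fit()
    coefs = fit.params.drop("const")
    assert abs(shares.sum() - r2_full) < 1e-8
    return ImportanceResult(list(selected), coefs, float(r2_full),
                            pd.Series(shares, index=selected), method)


def correlate_pa_with(variable: np.ndarray, pa: np.ndarray) -> float:
    """Plain Pearson correlation for single-variable screens of PA."""
    v = np.asarray(variable, dtype=float)
    q = np.asarray(pa, dtype=float)
    ok = np.isfinite(v) & np.isfinite(q)
    v, q = v[ok], q[ok]
    if v.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(v) == 0 or np.std(q) == 0:
        return np.nan
    return float(np.corrcoef(v, q)[0, 1])
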