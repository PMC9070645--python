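"""Mixed-model analysis of multi-year field phenotypes.

Variance components and BLUPs come from an EM algorithm on Henderson's
mixed-model equations (ML or REML flavor), with every random term an i.i.d.
grouping factor. The module also provides backward elimination of random terms
by REML likelihood-ratio tests, entry-mean broad-sense heritability (overall
and per cross), the cross-variance ratio, BLUP scaling to unit variance, a
skewness-based transformation rule, and the subpopulation coefficient of
determination.

The heritability of genotype-entry means divides year-interaction components
by the mean number of years per genotype (n_year) and plot-level components
(spatial terms and the residual) by n_year times the mean number of replicates
per genotype-year (n_rep_year):

    H2 = (sC2 + sG2) / (sC2 + sG2 + (sCY2 + sGY2 + sxY2 + syY2)/n_year
         + (sx2 + sy2 + sxy2 + se2)/(n_year * n_rep_year))
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

logger = logging.getLogger(__name__)

__all__ = [
    "VarianceComponents",
    "GeneticValues",
    "MixedModelFit",
    "DEFAULT_FIXED_TERMS",
    "DEFAULT_RANDOM_TERMS",
    "select_transformation",
    "apply_transformation",
    "fit_mixed_model",
    "drop_random_terms",
    "heritability_overall",
    "heritability_per_cross",
    "cross_variance_ratio",
    "scale_genetic_values",
    "subpopulation_r2",
]

DEFAULT_FIXED_TERMS = ("block", "year", "block:year")
DEFAULT_RANDOM_TERMS = ("genotype", "cross", "genotype:year", "cross:year",
                        "x", "y", "x:y", "x:year", "y:year")

GENETIC_TERMS = ("genotype", "cross")


@dataclass
class VarianceComponents:
    """REML/ML variance estimates keyed by term name (incl. 'residual')."""

    components: dict[str, float]
    retained_terms: list[str]
    n_year: float
    n_rep_year: float
    method: str = "REML"

    def __getitem__(self, term: str) -> float:
        return self.components.get(term, 0.0)


@dataclass
class GeneticValues:
    """Per-genotype cross BLUP (C), within-cross BLUP (G) and total (C+G)."""

    values: pd.DataFrame  # index genotype, columns C, G, total
    scaled: bool = False
    scaling_factor: float = 1.0


@dataclass
class MixedModelFit:
    variance_components: VarianceComponents
    genetic_values: GeneticValues
    loglik: float
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    blups: dict[str, pd.Series] = field(default_factory=dict)
    fixed_effects: pd.Series | None = None


# ---------------------------------------------------------------------------
# transformation choice
# ---------------------------------------------------------------------------


def select_transformation(values: Sequence[float]) -> str:
    """Pick identity / sqrt / log by sample skewness (thresholds 1 and 2).

    A stand-in for an unnamed distributional check of raw data: |skew| <= 1
    keeps the identity; moderate right skew (1, 2] with non-negative data takes
    the square root; stronger skew takes the log (shifted if min <= 0). Falls
    back to identity with a warning when a transform is inapplicable.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 10:
        raise ValueError("need at least 10 finite values")
    skew = float(stats.skew(v, bias=False))
    logger.info("select_transformation: skewness=%.3f", skew)
    if abs(skew) <= 1.0:
        return "identity"
    if skew < 0:
        warnings.warn("left-skewed data: no transform applied")
        return "identity"
    if skew <= 2.0:
        if v.min() >= 0:
            return "sqrt"
        warnings.warn("negative values: sqrt inapplicable, keeping identity")
        return "identity"
    return "log"


def apply_transformation(values: Sequence[float], transform: str) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if transform == "identity":
        return v
    if transform == "sqrt":
        return np.sqrt(v)
    if transform == "log":
        shift = 0.0
        if np.nanmin(v) <= 0:
            shift = 1.0 - np.nanmin(v)
        return np.log(v + shift)
    raise ValueError(f"unknown transform {transform!r}")


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def _term_labels(records: pd.DataFrame, term: str) -> pd.Series:
    parts = term.split(":")
    lab = records[parts[0]].astype(str)
    for p in parts[1:]:
        lab = lab + "/" + records[p].astype(str)
    return lab


def _fixed_design(records: pd.DataFrame, fixed_terms: Sequence[str]
                  ) -> tuple[np.ndarray, list[str]]:
    n = len(records)
    cols = [np.ones(n)]
    names = ["intercept"]
    for term in fixed_terms:
        # treatment coding; interactions as products of the parts' dummies
        part_dummies = []
        for part in term.split(":"):
            lab = records[part].astype(str)
            levels = sorted(lab.unique())
            part_dummies.append([(lev, (lab == lev).to_numpy(dtype=float))
                                 for lev in levels[1:]])
        combos = part_dummies[0]
        for nxt in part_dummies[1:]:
            combos = [(f"{l1}:{l2}", c1 * c2) for l1, c1 in combos
                      for l2, c2 in nxt]
        for lev, col in combos:
            cols.append(col)
            names.append(f"{term}[{lev}]")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
        aliased = sorted(names[j] for j in piv[rank:])
        raise ValueError(f"singular fixed design; aliased columns: {aliased}")
    return X, names


def _random_design(records: pd.DataFrame, term: str
                   ) -> tuple[np.ndarray, list[str]]:
    lab = _term_labels(records, term)
    levels = sorted(lab.unique())
    idx = {lev: j for j, lev in enumerate(levels)}
    Z = np.zeros((len(records), len(levels)))
    Z[np.arange(len(records)), [idx[v] for v in lab]] = 1.0
    return Z, levels


# ---------------------------------------------------------------------------
# EM-(RE)ML on the mixed-model equations
# ---------------------------------------------------------------------------


def _neg2ll(method: str, n: int, p: int, quad: float, sigma_e: float,
            sigmas: np.ndarray, q_sizes: np.ndarray, logdet_A: float,
            logdet_ZtZ_D: float) -> float:
    if method == "REML":
        return ((n - p) * np.log(2 * np.pi)
                + (n - p - q_sizes.sum()) * np.log(sigma_e)
                + float(q_sizes @ np.log(sigmas)) + logdet_A + quad)
    return (n * np.log(2 * np.pi) + (n - q_sizes.sum()) * np.log(sigma_e)
            + float(q_sizes @ np.log(sigmas)) + logdet_ZtZ_D + quad)


def fit_mixed_model(records: pd.DataFrame,
                    fixed_terms: Sequence[str] = DEFAULT_FIXED_TERMS,
                    random_terms: Sequence[str] = DEFAULT_RANDOM_TERMS,
                    method: str = "REML", tol: float = 1e-6,
                    max_iter: int = 500, value_col: str = "value",
                    accelerate: bool = True) -> MixedModelFit:
    """EM estimation of variance components on Henderson's MME, with BLUPs.

    Every random term is an i.i.d. grouping factor (independent levels, no
    genomic covariance). Components are floored at 1e-10 times the phenotypic
    variance; convergence is declared when the max relative change of any
    component falls below ``tol``. Aitken extrapolation is attempted
    periodically and kept only when it does not decrease the log-likelihood
    (the EM likelihood ascent is asserted on every accepted step).
    """
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    records = records.reset_index(drop=True)
    y = records[value_col].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("phenotype values must be finite")
    n = len(y)
    X, fixed_names = _fixed_design(records, fixed_terms)
    p = X.shape[1]
    random_terms = list(random_terms)
    for term in list(fixed_terms) + random_terms:
        for part in term.split(":"):
            if part not in records.columns:
                raise KeyError(f"model term column {part!r} missing from records")
    Z_blocks, level_lists = [], []
    for term in random_terms:
        Z, levels = _random_design(records, term)
        Z_blocks.append(Z)
        level_lists.append(levels)
    q_sizes = np.array([Z.shape[1] for Z in Z_blocks], dtype=int)
    q = int(q_sizes.sum())
    W = np.concatenate([X] + Z_blocks, axis=1) if Z_blocks else X
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    var_y = float(np.var(y, ddof=1))
    floor = 1e-10 * var_y

    k_terms = len(random_terms)
    sigmas = np.full(k_terms, var_y / (k_terms + 1.0)) if k_terms else np.empty(0)
    sigma_e = var_y / (k_terms + 1.0)
    offsets = np.concatenate([[p], p + np.cumsum(q_sizes)]).astype(int)

    def assemble(sig, se):
        A = WtW.copy()
        for k in range(k_terms):
            sl = slice(offsets[k], offsets[k + 1])
            A[sl, sl] += np.eye(q_sizes[k]) * (se / sig[k])
        return A

    def em_step(sig, se):
        A = assemble(sig, se)
        L = linalg.cholesky(A, lower=True, check_finite=False)
        logdet_A = 2.0 * float(np.sum(np.log(np.diag(L))))
        sol = linalg.cho_solve((L, True), Wty, check_finite=False)
        quad = (yty - float(sol @ Wty)) / se
        new_se = (yty - float(sol @ Wty)) / (n - p if method == "REML" else n)
        new_se = max(new_se, floor)
        new_sig = np.empty_like(sig)
        logdet_ZtZ_D = 0.0
        if method == "REML" or k_terms == 0:
            if k_terms:
                # columns of A^-1 for the random-effect block, one solve
                Cu = linalg.cho_solve((L, True), _eye_u, check_finite=False)
            for k in range(k_terms):
                sl = slice(offsets[k], offsets[k + 1])
                uk = sol[sl]
                tr = float(np.trace(Cu[sl, offsets[k] - p:offsets[k + 1] - p]))
                new_sig[k] = (float(uk @ uk) + se * tr) / q_sizes[k]
        else:
            ZtZ_D = A[p:, p:]
            Lz = linalg.cholesky(ZtZ_D, lower=True, check_finite=False)
            logdet_ZtZ_D = 2.0 * float(np.sum(np.log(np.diag(Lz))))
            Cml = linalg.cho_solve((Lz, True), np.eye(q), check_finite=False)
            for k in range(k_terms):
                sl = slice(offsets[k] - p, offsets[k + 1] - p)
                uk = sol[offsets[k]:offsets[k + 1]]
                new_sig[k] = (float(uk @ uk) + se * np.trace(Cml[sl, sl])) / q_sizes[k]
        new_sig = np.maximum(new_sig, floor)
        ll = -0.5 * _neg2ll(method, n, p, quad, se, sig, q_sizes, logdet_A,
                            logdet_ZtZ_D)
        return new_sig, new_se, sol, ll

    _eye_u = np.zeros((p + q, q))
    _eye_u[p:, :] = np.eye(q)

    trace: list[float] = []
    history: list[np.ndarray] = []
    sol = np.zeros(p + q)
    converged = False
    it = 0
    decreasing = np.zeros(k_terms, dtype=int)
    for it in range(1, max_iter + 1):
        new_sig, new_se, sol, ll = em_step(sigmas, sigma_e)
        # boundary test for persistently-shrinking components: a component
        # decaying geometrically toward zero never satisfies the relative-
        # change criterion; if profiling it at the floor does not lower the
        # likelihood, jump there directly
        decreasing = np.where(new_sig < sigmas, decreasing + 1, 0)
        if trace and it % 10 == 0 and (decreasing >= 10).any():
            eligible = decreasing >= 10
            trials = [eligible]
            if eligible.sum() > 1:
                single = np.zeros(k_terms, dtype=bool)
                single[int(np.argmax(decreasing))] = True
                trials.append(single)
            jumped = False
            for mask in trials:
                cand_sig = np.where(mask, floor, new_sig)
                try:
                    nsig2, nse2, _, ll_b = em_step(cand_sig, new_se)
                except linalg.LinAlgError:
                    continue
                if ll_b >= trace[-1] - 1e-10 * (1.0 + abs(trace[-1])):
                    trace.append(max(ll_b, trace[-1]))
                    sigmas, sigma_e = nsig2, nse2
                    history = [np.log(np.maximum(
                        np.concatenate([sigmas, [sigma_e]]), floor))]
                    decreasing[:] = 0
                    jumped = True
                    break
            if jumped:
                continue
        if trace and ll < trace[-1] - 1e-6 * (1.0 + abs(trace[-1])):
            raise RuntimeError(
                f"EM log-likelihood decreased at iteration {it}: "
                f"{trace[-1]:.8f} -> {ll:.8f}")
        trace.append(ll)
        old = np.concatenate([sigmas, [sigma_e]])
        new = np.concatenate([new_sig, [new_se]])
        # components boxed at the near-zero floor do not gate convergence
        live = new > 1e-8 * var_y
        live[-1] = True
        rel = np.max(np.abs(new[live] - old[live]) / np.maximum(old[live], floor))
        sigmas, sigma_e = new_sig, new_se
        history.append(np.log(np.maximum(new, floor)))
        if rel < tol:
            converged = True
            break
        # plateau stop: the likelihood has been flat for 20 iterations, the
        # components are wandering a ridge at the optimum (common in tiny or
        # nearly-confounded designs)
        if len(trace) > 20 and (trace[-1] - trace[-21]) < 1e-7 * (1.0 + abs(trace[-1])):
            converged = True
            break
        # Aitken extrapolation on log-components, kept only if ll improves
        if accelerate and it % 5 == 0 and len(history) >= 3:
            t2, t1, t0 = history[-3], history[-2], history[-1]
            d1, d0 = t1 - t2, t0 - t1
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.where(np.abs(d1) > 1e-14, d0 / d1, 0.0)
            r = np.clip(r, 0.0, 0.995)
            theta = t0 + r / (1.0 - r) * d0
            cand = np.exp(theta)
            cand_sig, cand_se = np.maximum(cand[:-1], floor), max(cand[-1], floor)
            try:
                nsig, nse, sol, ll_cand = em_step(cand_sig, cand_se)
            except linalg.LinAlgError:
                ll_cand = -np.inf
            if ll_cand > trace[-1]:
                # jump to the extrapolated point and adopt its EM update
                trace.append(ll_cand)
                sigmas, sigma_e = nsig, nse
                history = [np.log(np.maximum(
                    np.concatenate([sigmas, [sigma_e]]), floor))]
    if not converged:
        raise RuntimeError(
            f"EM did not converge in {max_iter} iterations "
            f"(last 5 log-likelihoods: {[round(v, 6) for v in trace[-5:]]})")

    # final solve at converged components
    A = assemble(sigmas, sigma_e) if k_terms else WtW
    cf = linalg.cho_factor(A, lower=True, check_finite=False)
    sol = linalg.cho_solve(cf, Wty, check_finite=False)
    beta = pd.Series(sol[:p], index=fixed_names)
    blups: dict[str, pd.Series] = {}
    for k, term in enumerate(random_terms):
        sl = slice(offsets[k], offsets[k + 1])
        blups[term] = pd.Series(sol[sl], index=level_lists[k])

    components = {term: float(sigmas[k]) for k, term in enumerate(random_terms)}
    components["residual"] = float(sigma_e)

    # design-averaged divisors for entry-mean heritability
    if "year" in records.columns and "genotype" in records.columns:
        n_year = float(records.groupby("genotype")["year"].nunique().mean())
        n_rep_year = float(
            records.groupby(["genotype", "year"]).size().mean())
    else:
        n_year = 1.0
        n_rep_year = float(len(records)) / max(
            1, records["genotype"].nunique()) if "genotype" in records.columns \
            else 1.0
    vc = VarianceComponents(components, list(random_terms), n_year, n_rep_year,
                            method)

    genos = blups.get("genotype", pd.Series(dtype=float))
    g_ids = list(genos.index)
    c_blup = blups.get("cross", pd.Series(dtype=float))
    if "cross" in records.columns and records["cross"].notna().any():
        g2c = records.dropna(subset=["cross"]).drop_duplicates("genotype") \
            .set_index("genotype")["cross"]
        c_vals = np.array([c_blup.get(str(g2c.get(g)), 0.0) for g in g_ids])
    else:
        c_vals = np.zeros(len(g_ids))
    gv = pd.DataFrame({"C": c_vals, "G": genos.to_numpy(dtype=float)},
                      index=g_ids)
    gv["total"] = gv["C"] + gv["G"]
    return MixedModelFit(vc, GeneticValues(gv), trace[-1], trace, it, blups, beta)


def drop_random_terms(records: pd.DataFrame,
                      fixed_terms: Sequence[str] = DEFAULT_FIXED_TERMS,
                      random_terms: Sequence[str] = DEFAULT_RANDOM_TERMS,
                      alpha: float = 0.05,
                      protected: Sequence[str] = GENETIC_TERMS,
                      tol: float = 1e-6, max_iter: int = 500,
                      value_col: str = "value") -> list[str]:
    """Backward elimination of random terms by REML likelihood-ratio tests.

    Each candidate term is tested against the boundary null 0.5*chi2_0 +
    0.5*chi2_1; the term with the largest p >= alpha is dropped, and the search
    repeats until no droppable term remains. Genotype and cross are never
    dropped. Returns the retained random-term list (dropping order is
    deterministic given the data).
    """
    current = list(random_terms)
    fit_full = fit_mixed_model(records, fixed_terms, current, "REML", tol,
                               max_iter, value_col)
    while True:
        candidates = [t for t in current if t not in protected]
        if not candidates:
            return current
        pvals = {}
        reduced_fits = {}
        for term in candidates:
            reduced = [t for t in current if t != term]
            fit_red = fit_mixed_model(records, fixed_terms, reduced, "REML",
                                      tol, max_iter, value_col)
            lrt = max(0.0, 2.0 * (fit_full.loglik - fit_red.loglik))
            pvals[term] = 0.5 * stats.chi2.sf(lrt, 1) + (0.5 if lrt == 0 else 0.0)
            reduced_fits[term] = fit_red
        worst = max(sorted(pvals), key=lambda t: pvals[t])
        if pvals[worst] < alpha:
            return current
        logger.info("dropping random term %s (p=%.3f)", worst, pvals[worst])
        current = [t for t in current if t != worst]
        fit_full = reduced_fits[worst]


# ---------------------------------------------------------------------------
# heritability and derived quantities
# ---------------------------------------------------------------------------


def heritability_overall(vc: VarianceComponents) -> float:
    """Entry-mean broad-sense heritability from the fitted components.

    Numerator: genetic terms (cross + genotype). Year-interaction terms are
    divided by n_year; plot-level terms (spatial and residual) by
    n_year * n_rep_year. Dropped terms contribute zero.
    """
    if vc.n_year <= 0 or vc.n_rep_year <= 0:
        raise ValueError("n_year and n_rep_year must be positive")
    genetic = sum(vc[t] for t in GENETIC_TERMS)
    year_terms = sum(v for t, v in vc.components.items()
                     if ":year" in t and t != "residual")
    plot_terms = sum(v for t, v in vc.components.items()
                     if t != "residual" and ":year" not in t
                     and t not in GENETIC_TERMS)
    plot_terms += vc["residual"]
    total = genetic + year_terms / vc.n_year \
        + plot_terms / (vc.n_year * vc.n_rep_year)
    if total == 0:
        raise ValueError("all variance components are zero")
    return genetic / total


def heritability_per_cross(records_one_cross: pd.DataFrame,
                           retained_terms: Sequence[str],
                           fixed_terms: Sequence[str] = DEFAULT_FIXED_TERMS,
                           tol: float = 1e-6, max_iter: int = 500) -> float:
    """Within-cross entry-mean heritability.

    Refits the globally selected model inside one full-sib family with every
    cross-related term removed, then applies the heritability formula without
    the cross components.
    """
    if records_one_cross["genotype"].nunique() < 2:
        raise ValueError("need at least 2 genotypes in the cross")
    terms = [t for t in retained_terms if "cross" not in t]
    fit = fit_mixed_model(records_one_cross, fixed_terms, terms, "REML", tol,
                          max_iter)
    return heritability_overall(fit.variance_components)


def cross_variance_ratio(vc: VarianceComponents) -> float:
    """Share of genetic variance due to differences between crosses."""
    tot = vc["cross"] + vc["genotype"]
    if tot <= 0:
        raise ValueError("zero total genetic variance")
    return vc["cross"] / tot


def scale_genetic_values(gv: GeneticValues) -> GeneticValues:
    """Scale totals to unit sample variance (C and G by the same factor)."""
    totals = gv.values["total"].to_numpy(dtype=float)
    if len(totals) < 2:
        raise ValueError("need at least 2 genotypes to scale")
    sd = float(np.std(totals, ddof=1))
    if sd == 0:
        raise ValueError("zero variance in total genotypic values")
    scaled = gv.values / sd
    return GeneticValues(scaled, scaled=True, scaling_factor=1.0 / sd)


def subpopulation_r2(values: Sequence[float], subpops: Sequence[str]) -> float:
    """R^2 of the one-way fixed-effect fit of genotypic values on subpopulation."""
    df = pd.DataFrame({"g": np.asarray(values, dtype=float),
                       "p": list(subpops)})
    sizes = df.groupby("p").size()
    if len(sizes) < 2 or (sizes < 2).any():
        raise ValueError("need >= 2 subpopulations each with >= 2 members")
    grand = df["g"].mean()
    ss_tot = float(((df["g"] - grand) ** 2).sum())
    if ss_tot == 0:
        return 0.0
    means = df.groupby("p")["g"].transform("mean")
    ss_between = float(((means - grand) ** 2).sum())
    return ss_between / ss_tot
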