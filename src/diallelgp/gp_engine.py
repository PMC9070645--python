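"""Penalized marker-effect models: ridge (RR) and LASSO.

Both methods minimize (1/2n)||y - b0 - X beta||^2 + lambda * P(beta) with
P = 0.5*||beta||^2 (RR) or ||beta||_1 (LASSO), solved by cyclic coordinate
descent with covariance (Gram) updates; the intercept is unpenalized. Markers
are centered and unit-scaled with training-set statistics, and the shrinkage
lambda is calibrated by five-fold inner cross-validation on a log-spaced grid
descending from lambda_max (the smallest lambda that zeroes every LASSO
coefficient).

Predictions are linear in the dosages, so they accept fractional
(parental-average) genotypes; the prediction at a parental-average genotype is
exactly the segregation-weighted mean of the per-class predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._cd import cd_gram, cd_path
from .simdata import DosageMatrix

__all__ = [
    "MarkerEffectsModel",
    "standardize",
    "fit_penalized",
    "calibrate_lambda",
    "predict",
    "fit_marker_model",
]

CD_TOL = 1e-7
CD_MAX_SWEEPS = 100_000


@dataclass
class MarkerEffectsModel:
    """Intercept + per-marker additive effects on the standardized scale."""

    method: str  # "RR" | "LASSO"
    intercept: float
    effects: np.ndarray
    lam: float
    marker_means: np.ndarray
    marker_scales: np.ndarray  # 1/sd per marker; 0 for zero-variance markers
    marker_ids: list[str] | None = None
    trait_id: str | None = None
    training_ids: list[str] = field(default_factory=list)

    @property
    def n_zero(self) -> int:
        """Sparsity: count of exactly-zero effects (meaningful for LASSO)."""
        return int(np.sum(self.effects == 0.0))


def standardize(train_dosages: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center and unit-scale columns using training statistics only.

    Returns (standardized matrix, means, scales) where scales = 1/sd
    (population sd, ddof=0); zero-variance columns get scale 0, so their
    standardized values are identically 0 and they can carry no effect.
    """
    X = np.asarray(train_dosages, dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing dosages not allowed")
    means = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    scales = np.where(sd > 0, 1.0 / np.where(sd > 0, sd, 1.0), 0.0)
    return (X - means) * scales, means, scales


def _apply_standardization(X: np.ndarray, means: np.ndarray,
                           scales: np.ndarray) -> np.ndarray:
    return (np.asarray(X, dtype=float) - means) * scales


def fit_penalized(X: np.ndarray, y: np.ndarray, method: str, lam: float,
                  marker_ids: Sequence[str] | None = None,
                  training_ids: Sequence[str] | None = None,
                  trait_id: str | None = None,
                  _standardization: tuple[np.ndarray, np.ndarray] | None = None,
                  ) -> MarkerEffectsModel:
    """Fit one penalized model at a fixed lambda on a standardized matrix.

    ``X`` is expected column-standardized (as produced by :func:`standardize`);
    the intercept absorbs the response mean and is never penalized. Convergence
    is declared when the largest coefficient change in a sweep drops below 1e-7.
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    if method not in ("RR", "LASSO"):
        raise ValueError("method must be 'RR' or 'LASSO'")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y have different numbers of rows")
    if n < 10:
        raise ValueError("need at least 10 training observations")
    xbar = X.mean(axis=0)
    ybar = y.mean()
    Xc = X - xbar
    G = (Xc.T @ Xc) / n
    c = (Xc.T @ (y - ybar)) / n
    if method == "RR":
        # warm start at the exact SVD solution: coordinate descent then
        # verifies stationarity in a sweep or two even for tiny lambda,
        # where a cold start converges only linearly with rate ~ 1/lambda
        beta = _ridge_path_coefs(Xc, y - ybar, np.array([float(lam)]))[0]
    else:
        beta = np.zeros(p)
    sweeps, converged = cd_gram(G, c, float(lam), method == "LASSO", beta,
                                CD_TOL, CD_MAX_SWEEPS)
    if not converged:
        raise RuntimeError(
            f"coordinate descent did not converge in {sweeps} sweeps "
            f"(method={method}, lambda={lam:.4g}, p={p})")
    b0 = float(ybar - xbar @ beta)
    if _standardization is not None:
        means, scales = _standardization
    else:
        means = np.zeros(p)
        scales = np.ones(p)
    return MarkerEffectsModel(method, b0, beta, float(lam), means, scales,
                              list(marker_ids) if marker_ids is not None else None,
                              trait_id,
                              list(training_ids) if training_ids else [])


def _lambda_grid(Xs: np.ndarray, y: np.ndarray, grid_size: int) -> np.ndarray:
    n = len(y)
    yc = y - y.mean()
    Xc = Xs - Xs.mean(axis=0)
    lam_max = float(np.max(np.abs(Xc.T @ yc)) / n)
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * 1e-4, grid_size)


def _ridge_path_coefs(Xc: np.ndarray, yc: np.ndarray,
                      lambdas: np.ndarray) -> np.ndarray:
    """Exact ridge solutions along the grid via SVD (cross-checked against the
    coordinate-descent solver in the test suite)."""
    n = Xc.shape[0]
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    uty = U.T @ yc
    # beta(lam) = V diag(s / (s^2 + n*lam)) U'y
    factors = s[None, :] / (s[None, :] ** 2 + n * lambdas[:, None])
    return (factors * uty[None, :]) @ Vt


def _path_coefs(Xs: np.ndarray, y: np.ndarray, method: str,
                lambdas: np.ndarray) -> np.ndarray:
    """Coefficient path (and implied intercepts handled by the caller)."""
    n = Xs.shape[0]
    xbar = Xs.mean(axis=0)
    Xc = Xs - xbar
    yc = y - y.mean()
    if method == "RR":
        return _ridge_path_coefs(Xc, yc, lambdas)
    G = (Xc.T @ Xc) / n
    c = (Xc.T @ yc) / n
    betas, ok = cd_path(G, c, lambdas, True, CD_TOL, CD_MAX_SWEEPS)
    if not ok:
        raise RuntimeError("pathwise coordinate descent failed to converge")
    return betas


def calibrate_lambda(X: np.ndarray, y: np.ndarray, method: str, k: int = 5,
                     grid_size: int = 100, seed: int = 0
                     ) -> tuple[float, np.ndarray]:
    """Five-fold inner cross-validation of the shrinkage parameter.

    The grid is log-spaced from lambda_max down to lambda_max * 1e-4. ``X`` is
    the raw training dosage matrix: each inner fold re-standardizes with its
    own training statistics. Returns (selected lambda, mean CV-MSE per grid
    point); ties in CV error resolve toward the larger lambda.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} observations for {k}-fold CV")
    Xs_full, _, _ = standardize(X)
    lambdas = _lambda_grid(Xs_full, y, grid_size)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    sse = np.zeros(grid_size)
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        Xtr, means, scales = standardize(X[mask])
        ytr = y[mask]
        Xva = _apply_standardization(X[fold], means, scales)
        betas = _path_coefs(Xtr, ytr, method, lambdas)
        b0 = ytr.mean() - betas @ Xtr.mean(axis=0)
        pred = Xva @ betas.T + b0[None, :]
        sse += np.sum((y[fold][:, None] - pred) ** 2, axis=0)
    cv_mse = sse / n
    best = np.min(cv_mse)
    lam = float(np.max(lambdas[cv_mse == best]))  # ties -> larger lambda
    return lam, cv_mse


def predict(model: MarkerEffectsModel,
            dosages: "DosageMatrix | np.ndarray",
            marker_ids: Sequence[str] | None = None) -> np.ndarray:
    """b0 + Xs beta with the model's training standardization.

    Accepts fractional dosages (parental-average genotypes). When the model
    records marker ids, the input markers are aligned to them; missing markers
    raise with their ids listed.
    """
    if isinstance(dosages, DosageMatrix):
        marker_ids = dosages.marker_ids
        M = dosages.dosages
    else:
        M = np.asarray(dosages, dtype=float)
    if model.marker_ids is not None and marker_ids is not None:
        if list(marker_ids) != list(model.marker_ids):
            pos = {m: j for j, m in enumerate(marker_ids)}
            missing = [m for m in model.marker_ids if m not in pos]
            if missing:
                raise KeyError(f"markers missing from input: {missing[:20]}"
                               + ("..." if len(missing) > 20 else ""))
            M = M[:, [pos[m] for m in model.marker_ids]]
    if M.shape[1] != model.effects.size:
        raise ValueError("marker count mismatch with model effects")
    Xs = _apply_standardization(M, model.marker_means, model.marker_scales)
    return model.intercept + Xs @ model.effects


def fit_marker_model(train_dosages: np.ndarray, y: np.ndarray, method: str,
                     lam: float | None = None, k: int = 5,
                     grid_size: int = 100, seed: int = 0,
                     marker_ids: Sequence[str] | None = None,
                     training_ids: Sequence[str] | None = None,
                     trait_id: str | None = None) -> MarkerEffectsModel:
    """Standardize, calibrate lambda by inner CV (unless given), and fit."""
    X = np.asarray(train_dosages, dtype=float)
    if lam is None:
        lam, _ = calibrate_lambda(X, y, method, k=k, grid_size=grid_size,
                                  seed=seed)
    Xs, means, scales = standardize(X)
    return fit_penalized(Xs, np.asarray(y, dtype=float), method, lam,
                         marker_ids=marker_ids, training_ids=training_ids,
                         trait_id=trait_id, _standardization=(means, scales))
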