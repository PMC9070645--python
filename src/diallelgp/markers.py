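"""Genotype-matrix algebra.

Filters (MAF, missingness), marker-set intersection across populations,
expected (parental-average) offspring genotypes, segregation accounting,
the VanRaden realized additive relationship matrix, and PCA of the panel with
projection of external individuals onto its axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .simdata import DosageMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RelationshipMatrix",
    "PCAProjection",
    "filter_markers",
    "intersect_markers",
    "parental_average_genotype",
    "nonsegregating_proportion",
    "vanraden_A",
    "mean_relationship",
    "pca_project",
    "parent_axis_distance",
]


@dataclass
class RelationshipMatrix:
    """Realized additive relationships A = ZZ' / (2 sum p(1-p))."""

    individual_ids: list[str]
    values: np.ndarray
    scaling_constant: float
    freq_source: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.individual_ids),) * 2:
            raise ValueError("relationship matrix shape mismatch")
        if np.abs(v - v.T).max() > 1e-10:
            raise ValueError("relationship matrix is not symmetric")
        self.values = v

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        pos = {i: j for j, i in enumerate(self.individual_ids)}
        return np.array([pos[i] for i in ids], dtype=int)

    def submatrix(self, rows: Sequence[str], cols: Sequence[str]) -> np.ndarray:
        return self.values[np.ix_(self.index_of(rows), self.index_of(cols))]


@dataclass
class PCAProjection:
    """Panel-anchored PCA: centering means, orthonormal loadings, scores."""

    marker_means: np.ndarray
    loadings: np.ndarray  # (m, n_axes)
    scores: pd.DataFrame  # one row per individual, columns PC1..PCk
    explained_variance_ratio: np.ndarray

    def project(self, dosages: np.ndarray, ids: Sequence[str]) -> pd.DataFrame:
        sc = (np.asarray(dosages, dtype=float) - self.marker_means) @ self.loadings
        return pd.DataFrame(sc, index=list(ids), columns=self.scores.columns)


def filter_markers(d: DosageMatrix, maf_min: float = 0.05,
                   max_missing: float = 0.8,
                   dosages_with_missing: np.ndarray | None = None
                   ) -> DosageMatrix:
    """Retain markers with MAF >= maf_min and missingness <= max_missing.

    DosageMatrix itself carries no missing values; pre-imputation matrices with
    NaNs can be passed through ``dosages_with_missing`` (same shape), in which
    case frequencies are computed over non-missing calls. Marker order is
    preserved.
    """
    raw = d.dosages if dosages_with_missing is None else np.asarray(
        dosages_with_missing, dtype=float)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(raw, axis=0) / 2.0
        missing = np.mean(np.isnan(raw), axis=0)
    maf = np.minimum(freq, 1.0 - freq)
    keep = (maf >= maf_min) & (missing <= max_missing)
    if not keep.any():
        stricter = "maf" if (maf < maf_min).sum() >= (missing > max_missing).sum() \
            else "missingness"
        raise ValueError(f"all markers removed (binding filter: {stricter})")
    kept_ids = [m for m, k in zip(d.marker_ids, keep) if k]
    return d.subset_markers(kept_ids)


def intersect_markers(a: DosageMatrix, b: DosageMatrix
                      ) -> tuple[DosageMatrix, DosageMatrix]:
    """Restrict both matrices to their shared marker ids, identical column order."""
    shared = [m for m in a.marker_ids if m in set(b.marker_ids)]
    if not shared:
        raise ValueError("marker intersection is empty")
    return a.subset_markers(shared), b.subset_markers(shared)


def _check_parent_dosages(*vecs: np.ndarray) -> None:
    for v in vecs:
        if not np.isin(v, (0.0, 1.0, 2.0)).all():
            raise ValueError("parent dosages must be observed genotypes in {0,1,2}")


def parental_average_genotype(d_p1: np.ndarray, d_p2: np.ndarray) -> np.ndarray:
    """Expected offspring dosage per locus: (d_p1 + d_p2) / 2.

    This equals the segregation-probability-weighted mean over offspring
    genotype classes for every parental combination (e.g. 1 x 1 gives classes
    0/1/2 with probabilities 1/4, 1/2, 1/4, mean 1).
    """
    d1 = np.asarray(d_p1, dtype=float)
    d2 = np.asarray(d_p2, dtype=float)
    _check_parent_dosages(d1, d2)
    return (d1 + d2) / 2.0


def nonsegregating_proportion(d_p1: np.ndarray, d_p2: np.ndarray) -> float:
    """Proportion of loci where the cross produces no genetic variance.

    A locus is non-segregating when both parents are homozygous (dosage 0 or 2),
    whether matching (all offspring identical homozygotes) or opposite (all
    offspring heterozygous): either way the offspring dosage variance is zero.
    """
    d1 = np.asarray(d_p1, dtype=float)
    d2 = np.asarray(d_p2, dtype=float)
    _check_parent_dosages(d1, d2)
    homo = np.isin(d1, (0.0, 2.0)) & np.isin(d2, (0.0, 2.0))
    return float(homo.mean())


def vanraden_A(d: DosageMatrix, freq_individuals: Sequence[str] | str = "self"
               ) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix from allelic dosages.

    Columns are centered by 2p with allele frequencies p taken from
    ``freq_individuals`` (default: all individuals in the matrix); the
    denominator is 2 * sum p(1-p). Markers monomorphic among the frequency
    individuals contribute nothing to the denominator and are excluded (logged).
    """
    if isinstance(freq_individuals, str) and freq_individuals == "self":
        freq_rows = d.dosages
        source = "self"
    else:
        idx = [d.individual_ids.index(i) for i in freq_individuals]
        freq_rows = d.dosages[idx]
        source = f"{len(idx)} designated individuals"
    p = freq_rows.mean(axis=0) / 2.0
    keep = (p > 0.0) & (p < 1.0)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("vanraden_A: excluded %d monomorphic markers", n_drop)
    if not keep.any():
        raise ValueError("all markers monomorphic in the frequency individuals")
    Z = d.dosages[:, keep] - 2.0 * p[keep]
    c = 2.0 * np.sum(p[keep] * (1.0 - p[keep]))
    A = (Z @ Z.T) / c
    A = (A + A.T) / 2.0
    return RelationshipMatrix(list(d.individual_ids), A, c, source)


def mean_relationship(A: RelationshipMatrix, set1: Sequence[str],
                      set2: Sequence[str]) -> float:
    """Mean of A over all (i in set1, j in set2) pairs.

    When the two sets coincide, diagonal entries are excluded so the value
    reflects relatedness between distinct individuals.
    """
    if len(set1) == 0 or len(set2) == 0:
        raise ValueError("mean_relationship requires non-empty sets")
    i1, i2 = A.index_of(set1), A.index_of(set2)
    same = set(set1) == set(set2)
    if not same and set(set1) & set(set2):
        raise ValueError("overlapping sets are only allowed when identical")
    block = A.values[np.ix_(i1, i2)]
    if same:
        if len(set1) < 2:
            raise ValueError("identical singleton sets have no off-diagonal pairs")
        mask = i1[:, None] != i2[None, :]
        return float(block[mask].mean())
    return float(block.mean())


def pca_project(panel: DosageMatrix, others: DosageMatrix | None = None,
                n_axes: int = 2) -> PCAProjection:
    """PCA of the panel dosages (centered, unscaled); others projected onto it.

    Axes are computed from the panel only; external individuals (parents,
    progenies, parental-average genotypes) are centered with panel means and
    multiplied by the panel loadings. Explained-variance shares refer to the
    panel.
    """
    if others is not None and panel.marker_ids != others.marker_ids:
        raise ValueError("marker sets must be identical and aligned")
    X = panel.dosages
    means = X.mean(axis=0)
    Xc = X - means
    rank = np.linalg.matrix_rank(Xc)
    if n_axes > rank:
        logger.warning("n_axes=%d exceeds rank %d; truncating", n_axes, rank)
        n_axes = rank
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = Vt[:n_axes].T
    cols = [f"PC{k + 1}" for k in range(n_axes)]
    scores = pd.DataFrame(Xc @ loadings, index=list(panel.individual_ids),
                          columns=cols)
    evr = (s ** 2 / np.sum(s ** 2))[:n_axes]
    proj = PCAProjection(means, loadings, scores, evr)
    if others is not None:
        other_scores = proj.project(others.dosages, others.individual_ids)
        proj.scores = pd.concat([scores, other_scores])
    return proj


def parent_axis_distance(proj: PCAProjection, parent1: str, parent2: str,
                         axes: Sequence[int] = (1,)) -> float:
    """Distance between two projected parents on PC1 or the PC1-PC2 plane."""
    for p in (parent1, parent2):
        if p not in proj.scores.index:
            raise KeyError(f"parent {p} has no projected scores")
    cols = [f"PC{a}" for a in axes]
    delta = (proj.scores.loc[parent1, cols].to_numpy(dtype=float)
             - proj.scores.loc[parent2, cols].to_numpy(dtype=float))
    return float(np.sqrt(np.sum(delta ** 2)))
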