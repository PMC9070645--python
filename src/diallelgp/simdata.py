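"""Synthetic structured panels, half-diallel progenies and multi-year phenotypes.

The generator emulates the data layout of a perennial-crop genomic-prediction study:
a diversity panel of a few hundred highly heterozygous individuals weakly structured
into subpopulations, five of which serve as parents of a half-diallel (all pairwise
crosses, no selfs or reciprocals), and multi-year randomized-block phenotypes whose
variance structure matches the mixed model fitted downstream (genotype and cross
effects, year interactions, row/column field effects, residual).

Population structure follows the Balding-Nichols model: for each marker an ancestral
allele frequency p is drawn uniformly, each subpopulation's frequency from a
Beta(p(1-F)/F, (1-p)(1-F)/F) with differentiation parameter F (a priori FST), and
genotypes binomially. Meiosis uses a Haldane model (Poisson crossovers on the cM
scale, no interference).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._seeds import derive_rng

__all__ = [
    "DosageMatrix",
    "CrossDefinition",
    "TraitArchitecture",
    "make_population",
    "validate_population",
    "simulate_panel",
    "simulate_cross",
    "make_half_diallel",
    "simulate_phenotypes",
    "calibrate_cross_deviation",
    "orthogonalize_cross_means",
    "make_architecture",
    "default_trait_suite",
]

SUBPOP_LABELS = ("WW", "WE", "TE")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class DosageMatrix:
    """Individuals x markers alternate-allele dosages with a marker map.

    ``dosages`` holds real values in [0, 2]: integers {0,1,2} for observed
    individuals, fractional values for expected (parental-average) genotypes.
    ``marker_map`` is indexed by marker id with columns ``chrom``, ``pos_bp``,
    ``pos_cM``, sorted by (chrom, pos_bp). ``haplotypes`` (n, m, 2) stores phase
    when the individuals were simulated de novo; it is required for meiosis.
    """

    individual_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray
    marker_map: pd.DataFrame
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.individual_ids) or m != len(self.marker_ids):
            raise ValueError("dosage matrix shape does not match id lists")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        if len(set(self.marker_ids)) != m:
            raise ValueError("duplicate marker ids")
        if np.isnan(self.dosages).any():
            raise ValueError("missing dosages are not allowed in a DosageMatrix")
        if self.dosages.min() < -1e-12 or self.dosages.max() > 2 + 1e-12:
            raise ValueError("dosages must lie in [0, 2]")
        if list(self.marker_map.index) != list(self.marker_ids):
            raise ValueError("marker_map index must equal marker_ids")
        chrom = self.marker_map["chrom"].to_numpy()
        pos = self.marker_map["pos_bp"].to_numpy()
        cm = self.marker_map["pos_cM"].to_numpy()
        if (cm < 0).any():
            raise ValueError("pos_cM must be non-negative")
        for c in pd.unique(chrom):
            sel = chrom == c
            if not (np.diff(pos[sel]) > 0).all():
                raise ValueError(f"marker_map not sorted by pos_bp within {c}")
            if not (np.diff(cm[sel]) >= 0).all():
                raise ValueError(f"pos_cM not non-decreasing within {c}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def row(self, individual_id: str) -> np.ndarray:
        return self.dosages[self.individual_ids.index(individual_id)]

    def subset_individuals(self, ids: Sequence[str]) -> "DosageMatrix":
        idx = [self.individual_ids.index(i) for i in ids]
        hap = self.haplotypes[idx] if self.haplotypes is not None else None
        return DosageMatrix(list(ids), list(self.marker_ids), self.dosages[idx],
                            self.marker_map, hap)

    def subset_markers(self, ids: Sequence[str]) -> "DosageMatrix":
        pos = {m: j for j, m in enumerate(self.marker_ids)}
        idx = [pos[i] for i in ids]
        hap = self.haplotypes[:, idx] if self.haplotypes is not None else None
        return DosageMatrix(list(self.individual_ids), list(ids),
                            self.dosages[:, idx], self.marker_map.iloc[idx], hap)

    def allele_frequencies(self) -> np.ndarray:
        return self.dosages.mean(axis=0) / 2.0


@dataclass(frozen=True)
class CrossDefinition:
    cross_id: str
    parent1: str
    parent2: str
    n_offspring: int

    def __post_init__(self) -> None:
        if self.parent1 == self.parent2:
            raise ValueError("selfs are not allowed in a half-diallel")
        if self.n_offspring < 1:
            raise ValueError("n_offspring must be positive")


@dataclass
class TraitArchitecture:
    """Additive QTL architecture plus the non-genetic variance layers.

    ``qtl_effects`` are additive effects per alternate-allele copy. The
    non-genetic standard deviations feed i.i.d. normal effects for the design
    terms of the phenotype model: ``year_interaction_sd`` for genotype:year and
    cross:year, ``spatial_sd`` for row, column, row:column and the two
    spatial-by-year terms, ``residual_sd`` for the plot residual.
    """

    trait_id: str
    qtl_marker_ids: list[str]
    qtl_effects: np.ndarray
    architecture_class: str  # "polygenic" | "oligogenic"
    target_H2: float
    cross_deviation_sd: float = 0.0
    year_interaction_sd: float = 0.25
    spatial_sd: float = 0.15
    residual_sd: float = 0.5

    def __post_init__(self) -> None:
        self.qtl_effects = np.asarray(self.qtl_effects, dtype=float)
        if len(self.qtl_marker_ids) != self.qtl_effects.size:
            raise ValueError("qtl ids and effects differ in length")
        if not 0 < self.target_H2 <= 1:
            raise ValueError("target_H2 must be in (0, 1]")
        n_qtl = len(self.qtl_marker_ids)
        if self.architecture_class == "oligogenic" and n_qtl > 10:
            raise ValueError("oligogenic architecture allows at most 10 QTLs")
        if self.architecture_class == "polygenic" and n_qtl < 100:
            raise ValueError("polygenic architecture requires at least 100 QTLs")


def make_population(individual_ids: Sequence[str], role: str,
                    subpopulation: Sequence[str] | None = None,
                    cross_id: Sequence[str] | None = None,
                    parent1: Sequence[str] | None = None,
                    parent2: Sequence[str] | None = None) -> pd.DataFrame:
    """Population table: one row per individual with role and pedigree fields."""
    n = len(individual_ids)
    df = pd.DataFrame({
        "individual_id": list(individual_ids),
        "role": role,
        "subpopulation": list(subpopulation) if subpopulation is not None else [None] * n,
        "cross_id": list(cross_id) if cross_id is not None else [None] * n,
        "parent1": list(parent1) if parent1 is not None else [None] * n,
        "parent2": list(parent2) if parent2 is not None else [None] * n,
    })
    validate_population(df)
    return df


def validate_population(pop: pd.DataFrame) -> None:
    off = pop[pop["role"] == "offspring"]
    if off[["cross_id", "parent1", "parent2"]].isna().any().any():
        raise ValueError("offspring rows need cross_id, parent1 and parent2")
    panel = pop[pop["role"] == "panel"]
    if panel["subpopulation"].isna().any():
        raise ValueError("panel rows need a subpopulation label")
    for cid, grp in off.groupby("cross_id"):
        if grp["parent1"].nunique() != 1 or grp["parent2"].nunique() != 1:
            raise ValueError(f"cross {cid} has inconsistent parent assignment")


# ---------------------------------------------------------------------------
# genetic map helpers
# ---------------------------------------------------------------------------


def _build_map(n_markers: int, map_length_cM: Sequence[float],
               rng: np.random.Generator) -> pd.DataFrame:
    """Markers spread uniformly at random over chromosomes, cM proportional to bp."""
    n_chrom = len(map_length_cM)
    # allocate markers to chromosomes proportionally to map length, >= 2 each
    lengths = np.asarray(map_length_cM, dtype=float)
    alloc = np.maximum(2, np.round(n_markers * lengths / lengths.sum()).astype(int))
    while alloc.sum() > n_markers:
        alloc[np.argmax(alloc)] -= 1
    while alloc.sum() < n_markers:
        alloc[np.argmin(alloc)] += 1
    rows = []
    for c in range(n_chrom):
        cm = np.sort(rng.uniform(0.0, lengths[c], size=alloc[c]))
        bp = np.round(cm * 1e4).astype(np.int64)  # 100 kb per cM, synthetic scale
        bp = bp + np.arange(alloc[c])  # enforce strictly increasing bp
        for j in range(alloc[c]):
            rows.append((f"chr{c + 1:02d}", int(bp[j]), float(cm[j])))
    df = pd.DataFrame(rows, columns=["chrom", "pos_bp", "pos_cM"])
    df.index = [f"{c}_{p}" for c, p in zip(df["chrom"], df["pos_bp"])]
    return df


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def simulate_panel(n_individuals: int = 300, n_markers: int = 2000,
                   n_subpops: int = 3, fst: float = 0.05,
                   maf_min: float = 0.05,
                   subpop_sizes: Sequence[int] | None = None,
                   map_length_cM: Sequence[float] | None = None,
                   seed: int = 0) -> tuple[DosageMatrix, pd.DataFrame]:
    """Simulate a structured diversity panel under the Balding-Nichols model.

    Returns the dosage matrix (with phased haplotypes attached) and a
    population table assigning each individual to a subpopulation.
    """
    if not 0 <= fst < 1:
        raise ValueError("fst must lie in [0, 1)")
    if n_markers < 2:
        raise ValueError("need at least 2 markers")
    if n_subpops < 1:
        raise ValueError("need at least one subpopulation")
    if subpop_sizes is None:
        base = n_individuals // n_subpops
        subpop_sizes = [base] * n_subpops
        subpop_sizes[0] += n_individuals - base * n_subpops
    if sum(subpop_sizes) != n_individuals:
        raise ValueError("subpop_sizes must sum to n_individuals")
    if map_length_cM is None:
        map_length_cM = [75.0] * 19

    rng = derive_rng(seed, "panel")
    marker_map = _build_map(n_markers, map_length_cM, rng)
    m = len(marker_map)
    p_anc = rng.uniform(maf_min, 1.0 - maf_min, size=m)
    if fst == 0.0:
        p_sub = np.tile(p_anc, (n_subpops, 1))
    else:
        ratio = (1.0 - fst) / fst
        p_sub = rng.beta(p_anc * ratio, (1.0 - p_anc) * ratio, size=(n_subpops, m))
        p_sub = np.clip(p_sub, 1e-6, 1.0 - 1e-6)

    labels = [SUBPOP_LABELS[k] if k < len(SUBPOP_LABELS) else f"SP{k + 1}"
              for k in range(n_subpops)]
    hap = np.empty((n_individuals, m, 2), dtype=np.int8)
    subpop_col = []
    row = 0
    for k, size in enumerate(subpop_sizes):
        u = rng.random(size=(size, m, 2))
        hap[row:row + size] = (u < p_sub[k][None, :, None]).astype(np.int8)
        subpop_col.extend([labels[k]] * size)
        row += size
    ids = [f"P{i + 1:04d}" for i in range(n_individuals)]
    dm = DosageMatrix(ids, list(marker_map.index), hap.sum(axis=2).astype(float),
                      marker_map, haplotypes=hap)
    pop = make_population(ids, "panel", subpopulation=subpop_col)
    return dm, pop


def _gametes(haplotypes: np.ndarray, marker_map: pd.DataFrame, n: int,
             rng: np.random.Generator) -> np.ndarray:
    """Draw n recombinant gametes from one phased parent (Haldane model)."""
    m = haplotypes.shape[0]
    out = np.empty((n, m), dtype=np.int8)
    chrom = marker_map["chrom"].to_numpy()
    cm = marker_map["pos_cM"].to_numpy()
    for c in pd.unique(chrom):
        sel = np.flatnonzero(chrom == c)
        cm_c = cm[sel]
        length = cm_c[-1] - cm_c[0] if len(sel) > 1 else 0.0
        for g in range(n):
            k = rng.poisson(length / 100.0)  # crossovers ~ Poisson(Morgans)
            start = rng.integers(2)
            if k == 0:
                phase = np.full(len(sel), start)
            else:
                xo = np.sort(rng.uniform(cm_c[0], cm_c[-1], size=k))
                phase = (start + np.searchsorted(xo, cm_c, side="right")) % 2
            out[g, sel] = haplotypes[sel, :][np.arange(len(sel)), phase]
    return out


def simulate_cross(parent1: DosageMatrix, parent2: DosageMatrix,
                   n_offspring: int, seed: int = 0,
                   cross_id: str = "X", id_prefix: str | None = None
                   ) -> DosageMatrix:
    """Simulate a bi-parental cross by sampling one recombinant gamete per parent.

    Both parents must be single-individual DosageMatrix objects carrying phased
    haplotypes (as produced by :func:`simulate_panel`); crossover counts per
    chromosome are Poisson with mean equal to the map length in Morgans and
    crossover positions are uniform on the cM scale (Haldane, no interference).
    """
    for p in (parent1, parent2):
        if p.haplotypes is None:
            raise ValueError(
                "parents are unphased: provide haplotypes (simulate parents de novo "
                "with simulate_panel, or phase them before crossing)")
        if p.n_individuals != 1:
            raise ValueError("each parent must be a single-individual DosageMatrix")
    if parent1.marker_ids != parent2.marker_ids:
        raise ValueError("parents must share an identical marker set")
    rng = derive_rng(seed, f"cross:{cross_id}")
    g1 = _gametes(parent1.haplotypes[0], parent1.marker_map, n_offspring, rng)
    g2 = _gametes(parent2.haplotypes[0], parent2.marker_map, n_offspring, rng)
    hap = np.stack([g1, g2], axis=2)
    prefix = id_prefix or cross_id
    ids = [f"{prefix}_{i + 1:03d}" for i in range(n_offspring)]
    return DosageMatrix(ids, list(parent1.marker_ids),
                        (g1 + g2).astype(float), parent1.marker_map, haplotypes=hap)


def make_half_diallel(parents: DosageMatrix, n_offspring_per_cross: int = 65,
                      seed: int = 0) -> tuple[DosageMatrix, pd.DataFrame,
                                              list[CrossDefinition]]:
    """All pairwise crosses of a parent set (no selfs, no reciprocals).

    p parents give p(p-1)/2 crosses; 5 parents give the canonical 10 families.
    """
    ids = parents.individual_ids
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate parent ids")
    if len(ids) < 2:
        raise ValueError("need at least 2 parents")
    crosses: list[CrossDefinition] = []
    blocks: list[DosageMatrix] = []
    pop_rows: list[pd.DataFrame] = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            cid = f"{ids[a]}x{ids[b]}"
            crosses.append(CrossDefinition(cid, ids[a], ids[b],
                                           n_offspring_per_cross))
            off = simulate_cross(parents.subset_individuals([ids[a]]),
                                 parents.subset_individuals([ids[b]]),
                                 n_offspring_per_cross, seed=seed, cross_id=cid)
            blocks.append(off)
            pop_rows.append(make_population(off.individual_ids, "offspring",
                                            cross_id=[cid] * off.n_individuals,
                                            parent1=[ids[a]] * off.n_individuals,
                                            parent2=[ids[b]] * off.n_individuals))
    all_ids = [i for blk in blocks for i in blk.individual_ids]
    dosages = np.vstack([blk.dosages for blk in blocks])
    hap = np.vstack([blk.haplotypes for blk in blocks])
    dm = DosageMatrix(all_ids, list(parents.marker_ids), dosages,
                      parents.marker_map, haplotypes=hap)
    return dm, pd.concat(pop_rows, ignore_index=True), crosses


# ---------------------------------------------------------------------------
# trait architectures and phenotypes
# ---------------------------------------------------------------------------


def make_architecture(marker_ids: Sequence[str], trait_id: str,
                      architecture_class: str = "polygenic",
                      target_H2: float = 0.7, n_qtl: int | None = None,
                      cross_deviation_sd: float = 0.0,
                      year_interaction_sd: float = 0.25,
                      spatial_sd: float = 0.15, residual_sd: float = 0.5,
                      seed: int = 0) -> TraitArchitecture:
    """Draw a QTL architecture: random QTL subset, N(0,1) effects (rescaled later)."""
    rng = derive_rng(seed, f"arch:{trait_id}")
    if n_qtl is None:
        n_qtl = 5 if architecture_class == "oligogenic" else min(200, len(marker_ids))
    idx = rng.choice(len(marker_ids), size=n_qtl, replace=False)
    idx.sort()
    return TraitArchitecture(
        trait_id=trait_id,
        qtl_marker_ids=[marker_ids[i] for i in idx],
        qtl_effects=rng.normal(size=n_qtl),
        architecture_class=architecture_class,
        target_H2=target_H2,
        cross_deviation_sd=cross_deviation_sd,
        year_interaction_sd=year_interaction_sd,
        spatial_sd=spatial_sd,
        residual_sd=residual_sd,
    )


def default_trait_suite(marker_ids: Sequence[str], n_traits: int = 15,
                        seed: int = 0) -> list[TraitArchitecture]:
    """A suite of traits spanning the study conditions: per-trait broad-sense
    heritabilities spread over 0.49-0.91 and cross-effect shares of genetic
    variance from <10% up to ~50%, mixing polygenic and oligogenic classes."""
    rng = derive_rng(seed, "trait-suite")
    h2 = np.linspace(0.49, 0.91, n_traits)
    archs = []
    for t in range(n_traits):
        cls = "oligogenic" if t % 5 == 4 else "polygenic"
        archs.append(make_architecture(
            marker_ids, trait_id=f"trait{t + 1:02d}", architecture_class=cls,
            target_H2=float(h2[t]), seed=int(rng.integers(2 ** 31))))
    return archs


def _true_components(genotypes: DosageMatrix, pop: pd.DataFrame,
                     arch: TraitArchitecture) -> tuple[np.ndarray, float, float]:
    """Additive values and the (sigma_C^2, sigma_G^2) decomposition they imply.

    sigma_G^2 is the pooled within-cross variance of additive values (the whole-set
    variance when there are no crosses); sigma_C^2 is the variance of cross additive
    means plus the explicit cross-deviation variance.
    """
    pos = {m: j for j, m in enumerate(genotypes.marker_ids)}
    for q in arch.qtl_marker_ids:
        if q not in pos:
            raise ValueError(f"QTL marker {q} absent from the genotype matrix")
    idx = [pos[q] for q in arch.qtl_marker_ids]
    add = genotypes.dosages[:, idx] @ arch.qtl_effects
    cross = pop.set_index("individual_id").loc[genotypes.individual_ids, "cross_id"]
    if cross.notna().any():
        df = pd.DataFrame({"add": add, "cross": cross.to_numpy()})
        within = df.groupby("cross")["add"].var(ddof=1).mean()
        between = df.groupby("cross")["add"].mean().var(ddof=1)
        if np.isnan(between):  # single cross
            between = 0.0
        sigma_g = float(within)
        sigma_c = float(between) + arch.cross_deviation_sd ** 2
    else:
        sigma_g = float(np.var(add, ddof=1))
        sigma_c = 0.0
    return add, sigma_c, sigma_g


def orthogonalize_cross_means(arch: TraitArchitecture, parents: DosageMatrix,
                              crosses: Sequence[CrossDefinition]
                              ) -> TraitArchitecture:
    """Project QTL effects so expected cross additive means are all equal.

    The expected additive mean of a cross is linear in the effect vector (the
    parental-average genotype at the QTLs dotted with the effects); removing
    the component of the effects that differentiates those means makes the
    between-cross genetic variance come only from the explicit cross deviation,
    so :func:`calibrate_cross_deviation` can set the cross-variance share to
    any target. With far more QTLs than crosses the projection barely perturbs
    the within-cross architecture.
    """
    pos = {m: j for j, m in enumerate(parents.marker_ids)}
    idx = [pos[q] for q in arch.qtl_marker_ids]
    M = np.vstack([
        (parents.row(cr.parent1)[idx] + parents.row(cr.parent2)[idx]) / 2.0
        for cr in crosses])
    Mc = M - M.mean(axis=0)
    beta = arch.qtl_effects.astype(float)
    # remove the row-space component of Mc from beta (min-norm correction)
    coef, *_ = np.linalg.lstsq(Mc, Mc @ beta, rcond=None)
    beta = beta - coef
    resid = Mc @ beta
    if np.abs(resid).max() > 1e-8:
        raise RuntimeError("cross-mean orthogonalization failed")
    return replace(arch, qtl_effects=beta)


def calibrate_cross_deviation(genotypes: DosageMatrix, pop: pd.DataFrame,
                              arch: TraitArchitecture,
                              target_ratio: float,
                              clamp: bool = False) -> TraitArchitecture:
    """Set cross_deviation_sd so that sigma_C^2/(sigma_C^2+sigma_G^2) hits target_ratio.

    The additive part already contributes between-cross variance through parent
    mean differences; the explicit deviation tops it up. Raises if the additive
    between-cross variance alone already exceeds the target.
    """
    if not 0 <= target_ratio < 1:
        raise ValueError("target_ratio must be in [0, 1)")
    arch0 = replace(arch, cross_deviation_sd=0.0)
    _, sigma_c_add, sigma_g = _true_components(genotypes, pop, arch0)
    need = target_ratio / (1.0 - target_ratio) * sigma_g - sigma_c_add
    if need < 0 and clamp:
        # finite-family sampling of cross means sets a floor on the share;
        # settle for the closest achievable ratio (zero added deviation)
        return replace(arch, cross_deviation_sd=0.0)
    if need < 0:
        raise ValueError(
            f"additive between-cross variance alone gives ratio "
            f"{sigma_c_add / (sigma_c_add + sigma_g):.3f} > target {target_ratio}")
    return replace(arch, cross_deviation_sd=float(np.sqrt(need)))


def simulate_phenotypes(genotypes: DosageMatrix, pop: pd.DataFrame,
                        arch: TraitArchitecture, n_years: int = 2,
                        n_blocks: int = 2,
                        field_dims: tuple[int, int] | None = None,
                        seed: int = 0, year_effect_sd: float = 1.0,
                        block_effect_sd: float = 0.5) -> tuple[pd.DataFrame, dict]:
    """Multi-year randomized-block plot phenotypes for one trait.

    Plot value = mu + additive genetic value + cross deviation + year + block +
    genotype:year + cross:year + row + column + row:column + row:year +
    column:year effects + residual, every random term i.i.d. normal with the
    architecture's sd. Each genotype-block pair occupies a fixed field position
    across years (perennial layout). The genetic scale (QTL effects and the
    cross deviation jointly) is calibrated so that plugging the true variance
    components into the entry-mean heritability formula yields ``target_H2``.

    Returns the long-format record table and a dict of ground truth: per-genotype
    genetic values, true variance components, the plug-in H2 and the
    cross-variance ratio.
    """
    rng = derive_rng(seed, f"pheno:{arch.trait_id}")
    ids = genotypes.individual_ids
    n = len(ids)
    add, sigma_c, sigma_g = _true_components(genotypes, pop, arch)

    # calibrate genetic scale against the fixed non-genetic sds
    yi2 = arch.year_interaction_sd ** 2
    sp2 = arch.spatial_sd ** 2
    res2 = arch.residual_sd ** 2
    cross = pop.set_index("individual_id").loc[ids, "cross_id"].to_numpy()
    has_cross = pd.notna(cross).any()
    denom_extra = (2 * yi2 + 2 * sp2) / n_years if has_cross else (yi2 + 2 * sp2) / n_years
    denom_extra += (3 * sp2 + res2) / (n_years * n_blocks)
    sigma_gen = sigma_c + sigma_g
    if sigma_gen <= 0:
        raise ValueError("architecture has zero genetic variance")
    if denom_extra == 0.0:
        scale = 1.0
        implied = 1.0
        if arch.target_H2 < 1.0:
            raise ValueError(
                f"target_H2={arch.target_H2} unattainable: all non-genetic sds are "
                f"zero, implied H2 = 1.0")
    else:
        if arch.target_H2 >= 1.0:
            raise ValueError(
                "target_H2=1 unattainable with non-zero non-genetic sds; implied "
                f"H2 -> {sigma_gen / (sigma_gen + denom_extra):.3f} at scale 1")
        scale = np.sqrt(arch.target_H2 / (1 - arch.target_H2) * denom_extra / sigma_gen)
    add = add * scale
    sigma_c *= scale ** 2
    sigma_g *= scale ** 2
    cross_dev_sd = arch.cross_deviation_sd * scale

    cross_levels = pd.unique(cross[pd.notna(cross)])
    cross_dev = dict(zip(cross_levels,
                         rng.normal(0.0, cross_dev_sd, size=len(cross_levels))))
    g_true = add + np.array([cross_dev.get(c, 0.0) if pd.notna(c) else 0.0
                             for c in cross])

    # fixed effects (deterministic shifts; sds control their spread)
    year_eff = rng.normal(0.0, year_effect_sd, size=n_years) \
        if year_effect_sd > 0 else np.zeros(n_years)
    block_eff = rng.normal(0.0, block_effect_sd, size=n_blocks) \
        if block_effect_sd > 0 else np.zeros(n_blocks)

    # field layout: blocks stacked in rows, genotypes shuffled within block
    if field_dims is None:
        ncol = int(np.ceil(np.sqrt(n * n_blocks)))
        nrow = int(np.ceil(n * n_blocks / ncol))
    else:
        nrow, ncol = field_dims
        if nrow * ncol < n * n_blocks:
            raise ValueError("field_dims too small for all plots")
    row_eff = rng.normal(0.0, arch.spatial_sd, size=nrow)
    col_eff = rng.normal(0.0, arch.spatial_sd, size=ncol)
    pos_eff = rng.normal(0.0, arch.spatial_sd, size=(nrow, ncol))
    rowyear_eff = rng.normal(0.0, arch.spatial_sd, size=(nrow, n_years))
    colyear_eff = rng.normal(0.0, arch.spatial_sd, size=(ncol, n_years))
    gy_eff = rng.normal(0.0, arch.year_interaction_sd, size=(n, n_years))
    cy_eff = rng.normal(0.0, arch.year_interaction_sd,
                        size=(len(cross_levels), n_years)) if has_cross else None
    cross_index = {c: j for j, c in enumerate(cross_levels)}

    # assign plots to positions
    order = np.concatenate([rng.permutation(n) + b * n for b in range(n_blocks)])
    plot_row = np.empty(n * n_blocks, dtype=int)
    plot_col = np.empty(n * n_blocks, dtype=int)
    for slot, plot in enumerate(order):
        plot_row[plot] = slot // ncol
        plot_col[plot] = slot % ncol

    records = []
    for b in range(n_blocks):
        for i in range(n):
            plot = b * n + i
            r, ccol = plot_row[plot], plot_col[plot]
            for yv in range(n_years):
                val = (10.0 + g_true[i] + year_eff[yv] + block_eff[b]
                       + gy_eff[i, yv] + row_eff[r] + col_eff[ccol]
                       + pos_eff[r, ccol] + rowyear_eff[r, yv]
                       + colyear_eff[ccol, yv]
                       + rng.normal(0.0, arch.residual_sd))
                if has_cross and pd.notna(cross[i]):
                    val += cy_eff[cross_index[cross[i]], yv]
                records.append((ids[i], cross[i] if pd.notna(cross[i]) else None,
                                f"B{b + 1}", 2013 + yv, r + 1, ccol + 1,
                                arch.trait_id, val))
    rec = pd.DataFrame(records, columns=["genotype", "cross", "block", "year",
                                         "x", "y", "trait", "value"])

    components = {"cross": sigma_c, "genotype": sigma_g,
                  "cross:year": yi2 if has_cross else 0.0, "genotype:year": yi2,
                  "x:year": sp2, "y:year": sp2, "x": sp2, "y": sp2, "x:y": sp2,
                  "residual": res2}
    h2_plugin = (sigma_c + sigma_g) / (sigma_c + sigma_g + denom_extra)
    truth = {
        "genetic_values": pd.Series(g_true, index=ids),
        "additive_values": pd.Series(add, index=ids),
        "components": components,
        "h2_plugin": float(h2_plugin),
        "cross_ratio": float(sigma_c / (sigma_c + sigma_g)) if has_cross else 0.0,
        "n_year": n_years,
        "n_rep_year": n_blocks,
    }
    return rec, truth
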