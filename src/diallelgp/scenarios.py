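"""Training scenarios and predictive-ability (PA) assessment.

Three designs for predicting half-diallel offspring:

* **1a** - random outer 10-fold cross-validation over the whole half-diallel,
  replicated (default 10 times);
* **1b** - half-sib prediction: for each focal cross, train on the other
  crosses of each of its two parents in turn (each cross predicted twice);
* **2** - across-population prediction: train on the diversity panel (optionally
  one subpopulation only) and predict every half-diallel cross.

PA is the Pearson correlation between observed total genotypic values (scaled
BLUP sums) and predictions. The cross-mean component is evaluated with two
modalities - averaging predicted offspring values, and predicting the
parental-average genotype directly - which are identical up to model error and
empirically correlate above 0.98; the within-cross (Mendelian-sampling)
component is the per-cross correlation over individuals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .gp_engine import MarkerEffectsModel, fit_marker_model, predict
from .markers import parental_average_genotype
from .simdata import CrossDefinition, DosageMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "HalfDiallelData",
    "ScenarioResult",
    "run_scenario_1a",
    "run_scenario_1b",
    "run_scenario_2",
    "compute_pa",
    "best_method",
    "modality_correlation",
    "estimate_bias",
    "apply_bias",
    "predict_all_crosses",
]

PA_COLUMNS = ["scenario", "trait", "cross", "component", "method",
              "granularity", "pa", "se", "ts_parent"]


@dataclass
class HalfDiallelData:
    """Genotypes, pedigree and scaled total genotypic values of a half-diallel."""

    offspring: DosageMatrix
    parents: DosageMatrix
    pop: pd.DataFrame
    crosses: list[CrossDefinition]
    gv: pd.DataFrame  # columns: genotype, trait, total

    def cross_of(self) -> pd.Series:
        off = self.pop[self.pop["role"] == "offspring"]
        return off.set_index("individual_id")["cross_id"]

    def traits(self) -> list[str]:
        return sorted(self.gv["trait"].unique())


@dataclass
class ScenarioResult:
    scenario: str
    pa_table: pd.DataFrame
    cross_means: pd.DataFrame
    predictions: pd.DataFrame = field(default_factory=pd.DataFrame)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3:
        return np.nan
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def compute_pa(observed: np.ndarray, predicted: np.ndarray,
               keys: pd.DataFrame, granularity: str) -> pd.DataFrame:
    """Pearson PA at the requested grouping of (cross, trait)-keyed pairs.

    ``keys`` has one row per pair with columns ``cross`` and ``trait``.
    Groups with fewer than 3 pairs are dropped with a warning; zero-variance
    groups give a missing (NaN) PA, never 0.
    """
    df = keys.copy()
    df["obs"] = np.asarray(observed, dtype=float)
    df["pred"] = np.asarray(predicted, dtype=float)
    if granularity == "overall":
        groups = [(("all", "all"), df)]
    elif granularity == "per_trait":
        groups = [(("all", k), g) for k, g in df.groupby("trait")]
    elif granularity == "per_cross":
        groups = [((k, "all"), g) for k, g in df.groupby("cross")]
    elif granularity == "per_cell":
        groups = [(k, g) for k, g in df.groupby(["cross", "trait"])]
    else:
        raise ValueError(f"unknown granularity {granularity!r}")
    rows = []
    for key, g in groups:
        if len(g) < 3:
            warnings.warn(f"group {key} has fewer than 3 pairs; dropped")
            continue
        pa = _pearson(g["obs"].to_numpy(), g["pred"].to_numpy())
        if granularity == "overall":
            cross, trait = "all", "all"
        elif granularity == "per_trait":
            cross, trait = "all", key[1]
        elif granularity == "per_cross":
            cross, trait = key[0], "all"
        else:
            cross, trait = key
        rows.append({"cross": cross, "trait": trait, "granularity": granularity,
                     "pa": pa, "n": len(g)})
    return pd.DataFrame(rows)


def best_method(pa_rr: float, pa_lasso: float) -> tuple[str, float]:
    """Keep the larger PA of the two methods; ties (and missing) favor RR."""
    rr_missing = pa_rr is None or (isinstance(pa_rr, float) and np.isnan(pa_rr))
    la_missing = pa_lasso is None or (isinstance(pa_lasso, float) and np.isnan(pa_lasso))
    if rr_missing and la_missing:
        return "best", np.nan
    if rr_missing:
        return "LASSO", float(pa_lasso)
    if la_missing:
        return "RR", float(pa_rr)
    if pa_lasso > pa_rr:
        return "LASSO", float(pa_lasso)
    return "RR", float(pa_rr)


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------


def _gv_series(gv: pd.DataFrame, trait: str) -> pd.Series:
    sub = gv[gv["trait"] == trait]
    return sub.set_index("genotype")["total"]


def _parental_average_matrix(hd: HalfDiallelData) -> tuple[np.ndarray, list[str]]:
    """One expected-offspring (parental-average) dosage row per cross."""
    rows, ids = [], []
    for cr in hd.crosses:
        rows.append(parental_average_genotype(hd.parents.row(cr.parent1),
                                              hd.parents.row(cr.parent2)))
        ids.append(cr.cross_id)
    return np.vstack(rows), ids


def _observed_cross_means(hd: HalfDiallelData, trait: str) -> pd.Series:
    """Mean observed total genotypic value over phenotyped offspring per cross."""
    vals = _gv_series(hd.gv, trait)
    cross = hd.cross_of()
    common = vals.index.intersection(cross.index)
    df = pd.DataFrame({"total": vals.loc[common], "cross": cross.loc[common]})
    return df.groupby("cross")["total"].mean()


def _mendelian_rows(scenario: str, trait: str, method: str,
                    per_cross_pa: dict[str, float],
                    per_cross_se: dict[str, float] | None = None,
                    ts_parent: str | None = None) -> list[dict]:
    rows = []
    for cid, pa in per_cross_pa.items():
        rows.append({"scenario": scenario, "trait": trait, "cross": cid,
                     "component": "mendelian", "method": method,
                     "granularity": "per_cell", "pa": pa,
                     "se": (per_cross_se or {}).get(cid, np.nan),
                     "ts_parent": ts_parent})
    return rows


def _aggregate_mendelian(pa_rows: pd.DataFrame, scenario: str) -> pd.DataFrame:
    """per-trait / per-cross / overall Mendelian PA as means of per-cell values."""
    cells = pa_rows[(pa_rows["component"] == "mendelian")
                    & (pa_rows["granularity"] == "per_cell")]
    out = []
    for method, g in cells.groupby("method"):
        for trait, gt in g.groupby("trait"):
            out.append({"scenario": scenario, "trait": trait, "cross": "all",
                        "component": "mendelian", "method": method,
                        "granularity": "per_trait", "pa": gt["pa"].mean(),
                        "se": np.nan, "ts_parent": None})
        for cid, gc in g.groupby("cross"):
            out.append({"scenario": scenario, "trait": "all", "cross": cid,
                        "component": "mendelian", "method": method,
                        "granularity": "per_cross", "pa": gc["pa"].mean(),
                        "se": np.nan, "ts_parent": None})
        out.append({"scenario": scenario, "trait": "all", "cross": "all",
                    "component": "mendelian", "method": method,
                    "granularity": "overall", "pa": g["pa"].mean(),
                    "se": np.nan, "ts_parent": None})
    return pd.DataFrame(out, columns=PA_COLUMNS)


def _add_best_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-(trait, cross) best-of-methods rows (max PA, ties toward RR)."""
    out = []
    for (trait, cross, comp), g in cells.groupby(["trait", "cross", "component"]):
        by = g.set_index("method")["pa"]
        if "RR" not in by.index and "LASSO" not in by.index:
            continue
        label, pa = best_method(by.get("RR", np.nan), by.get("LASSO", np.nan))
        row = g.iloc[0].to_dict()
        row.update({"method": "best", "pa": pa,
                    "se": g.set_index("method")["se"].get(label, np.nan)})
        out.append(row)
    return pd.DataFrame(out, columns=cells.columns)


def _cross_mean_pa_rows(cross_means: pd.DataFrame, scenario: str,
                        pred_col: str = "pred_parental") -> pd.DataFrame:
    """Cross-mean PA at the three granularities from the cross-mean table.

    per-trait = correlation over crosses, per-cross = correlation over traits,
    overall = pooled correlation over all cells (definitional).
    """
    rows = []
    for method, g in cross_means.groupby("method"):
        keys = g[["cross", "trait"]].reset_index(drop=True)
        obs = g["observed"].to_numpy()
        pred = g[pred_col].to_numpy()
        for gran in ("per_trait", "per_cross", "overall"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                part = compute_pa(obs, pred, keys, gran)
            for _, r in part.iterrows():
                rows.append({"scenario": scenario, "trait": r["trait"],
                             "cross": r["cross"], "component": "cross_mean",
                             "method": method, "granularity": gran,
                             "pa": r["pa"], "se": np.nan, "ts_parent": None})
    df = pd.DataFrame(rows, columns=PA_COLUMNS)
    # best-of-methods per granularity entry
    out = [df]
    for (trait, cross, gran), g in df.groupby(["trait", "cross", "granularity"]):
        by = g.set_index("method")["pa"]
        label, pa = best_method(by.get("RR", np.nan), by.get("LASSO", np.nan))
        out.append(pd.DataFrame([{"scenario": scenario, "trait": trait,
                                  "cross": cross, "component": "cross_mean",
                                  "method": "best", "granularity": gran,
                                  "pa": pa, "se": np.nan, "ts_parent": None}]))
    return pd.concat(out, ignore_index=True)


def modality_correlation(cross_means: pd.DataFrame) -> float:
    """Correlation between the two cross-mean prediction modalities over cells."""
    g = cross_means.dropna(subset=["pred_offspring_avg", "pred_parental"])
    return _pearson(g["pred_offspring_avg"].to_numpy(),
                    g["pred_parental"].to_numpy())


# ---------------------------------------------------------------------------
# scenario 1a: whole half-diallel 10-fold CV
# ---------------------------------------------------------------------------


def run_scenario_1a(hd: HalfDiallelData, methods: Sequence[str] = ("RR", "LASSO"),
                    k: int = 10, reps: int = 10, seed: int = 0,
                    grid_size: int = 100) -> ScenarioResult:
    """Random outer k-fold cross-validation over the whole half-diallel.

    Per replicate, every offspring is predicted exactly once (90% train / 10%
    validate at k=10). Mendelian PA is computed per cross within each replicate
    and averaged, with its standard error over replicates. Cross-mean
    predictions use both modalities: offspring predictions averaged over
    replicates, and the parental-average genotype predicted by a model trained
    on all offspring.
    """
    cross_of = hd.cross_of()
    ids = [i for i in hd.offspring.individual_ids]
    X = hd.offspring.dosages
    n = len(ids)
    pam, pam_ids = _parental_average_matrix(hd)
    pa_rows: list[dict] = []
    cm_rows: list[dict] = []
    pred_rows: list[pd.DataFrame] = []
    for trait in hd.traits():
        y_ser = _gv_series(hd.gv, trait).reindex(ids)
        if y_ser.isna().any():
            raise ValueError(f"trait {trait}: some offspring lack genetic values")
        y = y_ser.to_numpy()
        obs_means = _observed_cross_means(hd, trait)
        for method in methods:
            preds = np.full((reps, n), np.nan)
            percross: dict[str, list[float]] = {}
            for rep in range(reps):
                rep_seed = derive_seed(seed, f"1a:{trait}:{method}:rep{rep}")
                rng = np.random.default_rng(rep_seed)
                perm = rng.permutation(n)
                for f, fold in enumerate(np.array_split(perm, k)):
                    mask = np.ones(n, dtype=bool)
                    mask[fold] = False
                    model = fit_marker_model(
                        X[mask], y[mask], method, grid_size=grid_size,
                        seed=derive_seed(rep_seed, f"fold{f}"))
                    preds[rep, fold] = model.intercept + (
                        (X[fold] - model.marker_means) * model.marker_scales
                    ) @ model.effects
                rep_df = pd.DataFrame({"pred": preds[rep], "obs": y,
                                       "cross": cross_of.reindex(ids).to_numpy()})
                for cid, g in rep_df.groupby("cross"):
                    if len(g) < 3:
                        logger.info("cross %s: <3 validation pairs in rep %d",
                                    cid, rep)
                        continue
                    percross.setdefault(cid, []).append(
                        _pearson(g["obs"].to_numpy(), g["pred"].to_numpy()))
            pc_pa = {c: float(np.nanmean(v)) for c, v in percross.items()}
            pc_se = {c: float(np.nanstd(v, ddof=1) / np.sqrt(len(v)))
                     if len(v) > 1 else np.nan for c, v in percross.items()}
            pa_rows += _mendelian_rows("1a", trait, method, pc_pa, pc_se)

            mean_pred = pd.Series(preds.mean(axis=0), index=ids)
            pred_rows.append(pd.DataFrame({
                "genotype": ids, "trait": trait, "method": method,
                "predicted": mean_pred.to_numpy()}))
            # cross-mean modality 1: averaged offspring predictions
            off_avg = pd.DataFrame({"pred": mean_pred,
                                    "cross": cross_of.reindex(ids)}) \
                .groupby("cross")["pred"].mean()
            # cross-mean modality 2: parental-average genotypes, model on all
            model_all = fit_marker_model(
                X, y, method, grid_size=grid_size,
                seed=derive_seed(seed, f"1a:{trait}:{method}:all"),
                marker_ids=hd.offspring.marker_ids)
            par_pred = pd.Series(predict(model_all, pam,
                                         hd.offspring.marker_ids),
                                 index=pam_ids)
            for cid in obs_means.index:
                cm_rows.append({"cross": cid, "trait": trait, "method": method,
                                "observed": obs_means[cid],
                                "pred_offspring_avg": off_avg.get(cid, np.nan),
                                "pred_parental": par_pred.get(cid, np.nan)})
    pa_df = pd.DataFrame(pa_rows, columns=PA_COLUMNS)
    cells = pa_df[pa_df["granularity"] == "per_cell"]
    pa_df = pd.concat([pa_df, _add_best_cells(cells)], ignore_index=True)
    pa_df = pd.concat([pa_df, _aggregate_mendelian(pa_df, "1a")],
                      ignore_index=True)
    cm_df = pd.DataFrame(cm_rows)
    pa_df = pd.concat([pa_df, _cross_mean_pa_rows(cm_df, "1a")],
                      ignore_index=True)
    pa_df["scenario"] = "1a"
    return ScenarioResult("1a", pa_df, cm_df,
                          pd.concat(pred_rows, ignore_index=True))


# ---------------------------------------------------------------------------
# scenario 1b: half-sib training
# ---------------------------------------------------------------------------


def run_scenario_1b(hd: HalfDiallelData, methods: Sequence[str] = ("RR", "LASSO"),
                    seed: int = 0, grid_size: int = 100) -> ScenarioResult:
    """Half-sib prediction: per focal cross, train on each parent's other crosses.

    In a 5-parent half-diallel each parent appears in 4 crosses, so the
    training set for a (cross, parent) pair is the parent's 3 other crosses and
    each cross is predicted twice (once per parent).
    """
    cross_of = hd.cross_of()
    ids = list(hd.offspring.individual_ids)
    X = hd.offspring.dosages
    cross_arr = cross_of.reindex(ids).to_numpy()
    pam, pam_ids = _parental_average_matrix(hd)
    pam_lookup = dict(zip(pam_ids, pam))
    pa_rows: list[dict] = []
    cm_rows: list[dict] = []
    by_parent: dict[str, list[str]] = {}
    for cr in hd.crosses:
        by_parent.setdefault(cr.parent1, []).append(cr.cross_id)
        by_parent.setdefault(cr.parent2, []).append(cr.cross_id)
    for trait in hd.traits():
        y = _gv_series(hd.gv, trait).reindex(ids).to_numpy()
        obs_means = _observed_cross_means(hd, trait)
        for cr in hd.crosses:
            vs_mask = cross_arr == cr.cross_id
            for parent in (cr.parent1, cr.parent2):
                ts_crosses = [c for c in by_parent[parent] if c != cr.cross_id]
                if not ts_crosses:
                    warnings.warn(f"parent {parent} has no other crosses; "
                                  f"skipping ({cr.cross_id})")
                    continue
                ts_mask = np.isin(cross_arr, ts_crosses)
                assert not (ts_mask & vs_mask).any()
                for method in methods:
                    model = fit_marker_model(
                        X[ts_mask], y[ts_mask], method, grid_size=grid_size,
                        seed=derive_seed(seed,
                                         f"1b:{trait}:{cr.cross_id}:{parent}:{method}"))
                    pred_vs = model.intercept + (
                        (X[vs_mask] - model.marker_means) * model.marker_scales
                    ) @ model.effects
                    pa = _pearson(y[vs_mask], pred_vs)
                    pa_rows += _mendelian_rows("1b", trait, method,
                                               {cr.cross_id: pa},
                                               ts_parent=parent)
                    par_row = pam_lookup[cr.cross_id]
                    par_pred = float(model.intercept + (
                        (par_row - model.marker_means) * model.marker_scales
                    ) @ model.effects)
                    cm_rows.append({"cross": cr.cross_id, "trait": trait,
                                    "method": method, "ts_parent": parent,
                                    "observed": obs_means[cr.cross_id],
                                    "pred_offspring_avg": float(pred_vs.mean()),
                                    "pred_parental": par_pred})
    pa_df = pd.DataFrame(pa_rows, columns=PA_COLUMNS)
    # best per (trait, cross, parent-arm)
    best_rows = []
    for (trait, cross, parent), g in pa_df.groupby(["trait", "cross", "ts_parent"]):
        by = g.set_index("method")["pa"]
        label, pa = best_method(by.get("RR", np.nan), by.get("LASSO", np.nan))
        best_rows.append({"scenario": "1b", "trait": trait, "cross": cross,
                          "component": "mendelian", "method": "best",
                          "granularity": "per_cell", "pa": pa, "se": np.nan,
                          "ts_parent": parent})
    pa_df = pd.concat([pa_df, pd.DataFrame(best_rows, columns=PA_COLUMNS)],
                      ignore_index=True)
    pa_df = pd.concat([pa_df, _aggregate_mendelian(pa_df, "1b")],
                      ignore_index=True)
    cm_df = pd.DataFrame(cm_rows)
    pa_df = pd.concat([pa_df, _cross_mean_pa_rows(cm_df, "1b")],
                      ignore_index=True)
    pa_df["scenario"] = "1b"
    return ScenarioResult("1b", pa_df, cm_df)


# ---------------------------------------------------------------------------
# scenario 2: panel training
# ---------------------------------------------------------------------------


def run_scenario_2(panel: DosageMatrix, panel_pop: pd.DataFrame,
                   panel_gv: pd.DataFrame, hd: HalfDiallelData,
                   methods: Sequence[str] = ("RR", "LASSO"),
                   ts_filter: str = "all", seed: int = 0,
                   grid_size: int = 100) -> ScenarioResult:
    """Across-population prediction: diversity panel as training set.

    One model per (trait, method) trained on the panel's scaled genotypic
    values; Mendelian PA per half-diallel cross, cross-mean PA via both
    modalities. ``ts_filter='one-subpopulation:WW'`` (or any label) restricts
    the training set to one subpopulation.
    """
    scen = "2"
    panel_ids = list(panel.individual_ids)
    if ts_filter != "all":
        label = ts_filter.split(":")[-1] if ":" in ts_filter else "WW"
        sub = panel_pop.set_index("individual_id")["subpopulation"]
        panel_ids = [i for i in panel_ids if sub.get(i) == label]
        scen = f"2-{label}"
    cross_of = hd.cross_of()
    off_ids = list(hd.offspring.individual_ids)
    cross_arr = cross_of.reindex(off_ids).to_numpy()
    pam, pam_ids = _parental_average_matrix(hd)
    panel_sub = panel.subset_individuals(panel_ids)
    pa_rows: list[dict] = []
    cm_rows: list[dict] = []
    pred_rows: list[pd.DataFrame] = []
    for trait in sorted(panel_gv["trait"].unique()):
        y_ser = _gv_series(panel_gv, trait).reindex(panel_ids)
        if y_ser.isna().all():
            warnings.warn(f"trait {trait}: no panel phenotypes; skipped")
            continue
        keep = y_ser.notna().to_numpy()
        y = y_ser.to_numpy()[keep]
        Xtr = panel_sub.dosages[keep]
        if trait not in hd.traits():
            warnings.warn(f"trait {trait}: absent from half-diallel values; skipped")
            continue
        y_off = _gv_series(hd.gv, trait).reindex(off_ids).to_numpy()
        obs_means = _observed_cross_means(hd, trait)
        for method in methods:
            model = fit_marker_model(
                Xtr, y, method, grid_size=grid_size,
                seed=derive_seed(seed, f"{scen}:{trait}:{method}"),
                marker_ids=panel.marker_ids)
            pred_off = predict(model, hd.offspring, hd.offspring.marker_ids)
            pred_rows.append(pd.DataFrame({"genotype": off_ids, "trait": trait,
                                           "method": method,
                                           "predicted": pred_off}))
            df = pd.DataFrame({"obs": y_off, "pred": pred_off,
                               "cross": cross_arr})
            pc_pa = {}
            for cid, g in df.groupby("cross"):
                if len(g) < 3:
                    continue
                pc_pa[cid] = _pearson(g["obs"].to_numpy(), g["pred"].to_numpy())
            pa_rows += _mendelian_rows(scen, trait, method, pc_pa)
            par_pred = pd.Series(predict(model, pam, hd.offspring.marker_ids),
                                 index=pam_ids)
            off_avg = df.groupby("cross")["pred"].mean()
            for cid in obs_means.index:
                cm_rows.append({"cross": cid, "trait": trait, "method": method,
                                "observed": obs_means[cid],
                                "pred_offspring_avg": off_avg.get(cid, np.nan),
                                "pred_parental": par_pred.get(cid, np.nan)})
    pa_df = pd.DataFrame(pa_rows, columns=PA_COLUMNS)
    cells = pa_df[pa_df["granularity"] == "per_cell"]
    pa_df = pd.concat([pa_df, _add_best_cells(cells)], ignore_index=True)
    pa_df = pd.concat([pa_df, _aggregate_mendelian(pa_df, scen)],
                      ignore_index=True)
    cm_df = pd.DataFrame(cm_rows)
    pa_df = pd.concat([pa_df, _cross_mean_pa_rows(cm_df, scen)],
                      ignore_index=True)
    pa_df["scenario"] = scen
    return ScenarioResult(scen, pa_df, cm_df,
                          pd.concat(pred_rows, ignore_index=True)
                          if pred_rows else pd.DataFrame())


# ---------------------------------------------------------------------------
# bias correction and all-pairs cross ranking
# ---------------------------------------------------------------------------


def estimate_bias(cross_means: pd.DataFrame,
                  pred_col: str = "pred_parental") -> pd.Series:
    """Per-trait bias of predicted cross means: mean over crosses of
    (predicted - observed). Subtracting it recenters predictions on the
    observed scale."""
    g = cross_means.dropna(subset=[pred_col, "observed"])
    counts = g.groupby("trait").size()
    if (counts < 2).any():
        warnings.warn("bias estimated from a single cross for some trait(s): "
                      "treat the correction with caution")
    if counts.empty:
        raise ValueError("no (observed, predicted) cross means available")
    return g.groupby("trait").apply(
        lambda d: (d[pred_col] - d["observed"]).mean(), include_groups=False)


def apply_bias(predictions: pd.Series | np.ndarray, bias: float) -> np.ndarray:
    """Subtract an estimated per-trait bias from predicted cross means."""
    return np.asarray(predictions, dtype=float) - float(bias)


def predict_all_crosses(panel: DosageMatrix, model: MarkerEffectsModel,
                        bias: float = 0.0) -> pd.DataFrame:
    """Rank every unordered parent pair of the panel by predicted cross mean.

    The prediction for a pair is the model value at the parental-average
    genotype; by linearity this equals the mean of the two parents' own
    predictions, which is how it is computed. n genotypes give n(n-1)/2 rows,
    sorted by corrected prediction (descending).
    """
    ind_pred = predict(model, panel, panel.marker_ids)
    ids = panel.individual_ids
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    pred = (ind_pred[iu] + ind_pred[ju]) / 2.0 - bias
    df = pd.DataFrame({"parent1": [ids[i] for i in iu],
                       "parent2": [ids[j] for j in ju],
                       "predicted_mean": pred})
    return df.sort_values("predicted_mean", ascending=False,
                          kind="mergesort").reset_index(drop=True)
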