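"""Reproduction experiments: Monte-Carlo studies exercising the whole stack.

These functions define the package's standard simulation experiments —
parameter recovery for heritability and the cross-variance share, the
relatedness ordering of the three training scenarios, agreement of the two
cross-mean prediction modalities, and the value of training-set optimization —
at desk-scale problem sizes chosen to run in minutes on one core. They are the
backbone of the acceptance checks and of the worked examples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .gp_engine import fit_marker_model, predict
from .markers import vanraden_A
from .phenomodel import (cross_variance_ratio, fit_mixed_model,
                         heritability_overall)
from .scenarios import (HalfDiallelData, modality_correlation, run_scenario_1a,
                        run_scenario_1b, run_scenario_2)
from .simdata import (DosageMatrix, calibrate_cross_deviation,
                      make_architecture, make_half_diallel,
                      orthogonalize_cross_means, simulate_panel,
                      simulate_phenotypes)
from .tsopt import optimize_ts, random_baseline

__all__ = [
    "h2_recovery_experiment",
    "scenario_ordering_experiment",
    "tsopt_pa_experiment",
]

RECOVERY_TERMS = ("genotype", "cross", "genotype:year", "cross:year")


def _small_diallel(seed: int, n_panel: int = 60, n_markers: int = 400,
                   n_offspring: int = 20, n_subpops: int = 2,
                   parent_pick: str = "same"):
    panel, pop = simulate_panel(n_panel, n_markers, n_subpops, fst=0.05,
                                map_length_cM=[80.0] * 10, seed=seed)
    ids = panel.individual_ids
    if parent_pick == "same":
        pidx = ids[:5]
    else:  # 4 from the first subpopulation, 1 from another
        sub = pop.set_index("individual_id")["subpopulation"]
        first = [i for i in ids if sub[i] == sub.iloc[0]]
        other = [i for i in ids if sub[i] != sub.iloc[0]]
        pidx = first[:4] + other[:1]
    parents = panel.subset_individuals(pidx)
    off, offpop, crosses = make_half_diallel(parents, n_offspring,
                                             seed=derive_seed(seed, "diallel"))
    return panel, pop, parents, off, offpop, crosses


def h2_recovery_experiment(n_seeds: int = 20,
                           targets: tuple[float, ...] = (0.5, 0.8),
                           target_ratio: float = 0.3,
                           seed: int = 0) -> dict:
    """Recover simulated heritability and cross-variance share by REML.

    For each replicate a fresh polygenic architecture is drawn on a fixed
    half-diallel (10 crosses x 20 offspring, 2 years x 2 blocks), its genetic
    scale calibrated to the target entry-mean H2 and its cross deviation to the
    target variance share; the generating model (genetic and year-interaction
    terms) is then refitted by EM-REML. Reports the mean REML H2 per target,
    the mean realized (true simulated) cross-variance ratio and its REML
    estimate.
    """
    panel, pop, parents, off, offpop, crosses = _small_diallel(
        derive_seed(seed, "h2rec:geno"))
    cross_of = offpop.set_index("individual_id")["cross_id"]
    out = {"targets": {}, "realized_ratio": None, "reml_ratio": None}
    realized_ratios, reml_ratios = [], []
    for target in targets:
        h2s = []
        for s in range(n_seeds):
            arch = make_architecture(
                panel.marker_ids, "t", "polygenic", target_H2=target,
                spatial_sd=0.0, seed=derive_seed(seed, f"arch:{target}:{s}"))
            arch = orthogonalize_cross_means(arch, parents, crosses)
            arch = calibrate_cross_deviation(off, offpop, arch, target_ratio)
            rec, truth = simulate_phenotypes(
                off, offpop, arch, 2, 2,
                seed=derive_seed(seed, f"pheno:{target}:{s}"))
            fit = fit_mixed_model(rec, random_terms=RECOVERY_TERMS, tol=1e-6)
            h2s.append(heritability_overall(fit.variance_components))
            reml_ratios.append(cross_variance_ratio(fit.variance_components))
            g = truth["genetic_values"]
            df = pd.DataFrame({"g": g, "c": cross_of.reindex(g.index)})
            between = df.groupby("c")["g"].mean().var(ddof=1)
            within = df.groupby("c")["g"].var(ddof=1).mean()
            realized_ratios.append(between / (between + within))
        out["targets"][target] = float(np.mean(h2s))
    out["realized_ratio"] = float(np.mean(realized_ratios))
    out["reml_ratio"] = float(np.mean(reml_ratios))
    return out


def _true_gv_frame(off: DosageMatrix, offpop: pd.DataFrame, arch, seed: int,
                   trait: str = "t") -> pd.DataFrame:
    rec, truth = simulate_phenotypes(off, offpop, arch, 2, 2, seed=seed)
    g = truth["genetic_values"]
    g = g / g.std(ddof=1)
    return pd.DataFrame({"genotype": g.index, "trait": trait,
                         "total": g.to_numpy()})


def scenario_ordering_experiment(n_seeds: int = 20, seed: int = 0,
                                 n_offspring: int = 20,
                                 grid_size: int = 30) -> dict:
    """Mean within-cross PA across the three training scenarios.

    Per replicate, a fresh trait is simulated on a fixed structured panel +
    half-diallel (parents drawn from the panel), scaled true genetic values
    stand in for BLUPs, and each scenario is run with ridge regression.
    Reports per-scenario mean Mendelian PA, the per-seed ordering counts, and
    the pooled correlation between the two cross-mean prediction modalities.
    """
    panel, pop, parents, off, offpop, crosses = _small_diallel(
        derive_seed(seed, "ord:geno"), n_panel=120, n_markers=400,
        n_offspring=n_offspring, n_subpops=3, parent_pick="structured")
    pa = {"1a": [], "1b": [], "2": []}
    modality_cells = []
    for s in range(n_seeds):
        arch = make_architecture(panel.marker_ids, "t", "polygenic",
                                 target_H2=0.9, n_qtl=100,
                                 seed=derive_seed(seed, f"ord:arch:{s}"))
        # predict from non-QTL markers only: marker-QTL LD then comes from
        # linkage within families but is absent across the panel, which is
        # what makes across-population prediction genuinely harder
        predictors = [m for m in panel.marker_ids
                      if m not in set(arch.qtl_marker_ids)]
        panel_p = panel.subset_markers(predictors)
        off_p = off.subset_markers(predictors)
        parents_p = parents.subset_markers(predictors)
        gv = _true_gv_frame(off, offpop, arch,
                            derive_seed(seed, f"ord:pheno:{s}"))
        hd = HalfDiallelData(off_p, parents_p, offpop, crosses, gv)
        sub_seed = derive_seed(seed, f"ord:run:{s}")
        r1a = run_scenario_1a(hd, methods=("RR",), k=10, reps=2,
                              seed=sub_seed, grid_size=grid_size)
        r1b = run_scenario_1b(hd, methods=("RR",), seed=sub_seed,
                              grid_size=grid_size)
        rec_p, truth_p = simulate_phenotypes(
            panel, pop, arch, 2, 2, seed=derive_seed(seed, f"ord:ppheno:{s}"))
        gp = truth_p["genetic_values"]
        gp = gp / gp.std(ddof=1)
        pgv = pd.DataFrame({"genotype": gp.index, "trait": "t",
                            "total": gp.to_numpy()})
        r2 = run_scenario_2(panel_p, pop, pgv, hd, methods=("RR",),
                            seed=sub_seed, grid_size=grid_size)
        for label, res in (("1a", r1a), ("1b", r1b), ("2", r2)):
            t = res.pa_table
            val = t[(t["component"] == "mendelian")
                    & (t["granularity"] == "overall")
                    & (t["method"] == "RR")]["pa"].iloc[0]
            pa[label].append(float(val))
        cm = r1a.cross_means.copy()
        cm["seed"] = s
        modality_cells.append(cm)
    cells = pd.concat(modality_cells, ignore_index=True)
    means = {k: float(np.mean(v)) for k, v in pa.items()}
    a, b, c = np.array(pa["1a"]), np.array(pa["1b"]), np.array(pa["2"])
    return {
        "mean_pa": means,
        "per_seed": pa,
        "frac_1a_ge_1b": float(np.mean(a >= b)),
        "frac_1b_ge_2": float(np.mean(b >= c)),
        "modality_correlation": float(modality_correlation(cells)),
    }


def tsopt_pa_experiment(n_seeds: int = 20, size: int = 50, seed: int = 0,
                        reps_random: int = 10) -> dict:
    """Cross-mean PA with MeanRel-optimized vs random training sets.

    On a structured panel holding a relatedness gradient to the half-diallel
    parents, each cross's training set of fixed size is either optimized by
    mean TS-VS relationship or sampled at random; a ridge model per TS predicts
    the cross mean via the parental-average genotype. Reports the mean per-seed
    cross-mean PA for both strategies.
    """
    panel, pop, parents, off, offpop, crosses = _small_diallel(
        derive_seed(seed, "ts:geno"), n_panel=150, n_markers=300,
        n_offspring=15, n_subpops=3, parent_pick="structured")
    cross_of = offpop.set_index("individual_id")["cross_id"]
    combined = DosageMatrix(
        panel.individual_ids + off.individual_ids, panel.marker_ids,
        np.vstack([panel.dosages, off.dosages]), panel.marker_map)
    A = vanraden_A(combined, freq_individuals=panel.individual_ids)
    pam = {cr.cross_id: (parents.row(cr.parent1) + parents.row(cr.parent2)) / 2
           for cr in crosses}
    pa_opt, pa_rand = [], []
    for s in range(n_seeds):
        arch = make_architecture(panel.marker_ids, "t", "polygenic",
                                 target_H2=0.9,
                                 seed=derive_seed(seed, f"ts:arch:{s}"))
        gv = _true_gv_frame(off, offpop, arch,
                            derive_seed(seed, f"ts:pheno:{s}"))
        obs = gv.set_index("genotype")["total"].groupby(cross_of).mean()
        rec_p, truth_p = simulate_phenotypes(
            panel, pop, arch, 2, 2, seed=derive_seed(seed, f"ts:ppheno:{s}"))
        gp = truth_p["genetic_values"]
        y_panel = (gp / gp.std(ddof=1)).reindex(panel.individual_ids)
        # one shared shrinkage level per replicate, calibrated on the panel
        lam_model = fit_marker_model(
            panel.dosages, y_panel.to_numpy(), "RR", grid_size=30,
            seed=derive_seed(seed, f"ts:lam:{s}"))
        lam = lam_model.lam
        preds_opt, preds_rand = {}, {}
        for cr in crosses:
            vs = [i for i in off.individual_ids if cross_of[i] == cr.cross_id]
            sel = optimize_ts(A, panel.individual_ids, vs, "MeanRel", size,
                              seed=derive_seed(seed, f"ts:opt:{s}"))
            idx = [panel.individual_ids.index(i) for i in sel.member_ids]
            model = fit_marker_model(panel.dosages[idx],
                                     y_panel.iloc[idx].to_numpy(), "RR",
                                     lam=lam)
            preds_opt[cr.cross_id] = float(
                predict(model, pam[cr.cross_id][None, :])[0])
            rand_preds = []
            baselines = random_baseline(
                panel.individual_ids, vs, size, reps=reps_random,
                seed=derive_seed(seed, f"ts:rand:{s}:{cr.cross_id}"))
            for b in baselines:
                idx = [panel.individual_ids.index(i) for i in b.member_ids]
                m = fit_marker_model(panel.dosages[idx],
                                     y_panel.iloc[idx].to_numpy(), "RR",
                                     lam=lam)
                rand_preds.append(float(predict(m, pam[cr.cross_id][None, :])[0]))
            preds_rand[cr.cross_id] = rand_preds
        order = [cr.cross_id for cr in crosses]
        obs_v = obs.reindex(order).to_numpy()
        pa_opt.append(float(np.corrcoef(
            obs_v, [preds_opt[c] for c in order])[0, 1]))
        per_rep = []
        for r in range(reps_random):
            per_rep.append(float(np.corrcoef(
                obs_v, [preds_rand[c][r] for c in order])[0, 1]))
        pa_rand.append(float(np.mean(per_rep)))
    return {"mean_pa_optimized": float(np.mean(pa_opt)),
            "mean_pa_random": float(np.mean(pa_rand)),
            "per_seed_opt": pa_opt, "per_seed_rand": pa_rand}
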