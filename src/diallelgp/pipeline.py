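"""End-to-end orchestration: simulate -> model -> predict -> optimize -> explain.

A :class:`RunConfig` (built in code or loaded from YAML) fully determines a
run: all randomness derives from the master seed and a stage label, so two
runs with the same config produce byte-identical result CSVs, and adding a
stage never perturbs earlier stages. Each stage writes tidy CSV artifacts into
the output directory and registers them in a machine-readable manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._seeds import derive_seed
from . import io as dio
from .determinants import assemble_table, relative_importance, stepwise_aic
from .gp_engine import fit_marker_model
from .markers import (mean_relationship, nonsegregating_proportion,
                      parent_axis_distance, pca_project, vanraden_A)
from .phenomodel import (DEFAULT_FIXED_TERMS, DEFAULT_RANDOM_TERMS,
                         apply_transformation, cross_variance_ratio,
                         drop_random_terms, fit_mixed_model,
                         heritability_overall, heritability_per_cross,
                         scale_genetic_values, select_transformation,
                         subpopulation_r2)
from .scenarios import (HalfDiallelData, estimate_bias, modality_correlation,
                        predict_all_crosses, run_scenario_1a, run_scenario_1b,
                        run_scenario_2)
from .simdata import (DosageMatrix, calibrate_cross_deviation,
                      default_trait_suite, make_half_diallel,
                      orthogonalize_cross_means, simulate_panel,
                      simulate_phenotypes)
from .tsopt import optimize_ts, random_baseline

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]


@dataclass
class RunConfig:
    """All parameters of a reproducible run."""

    seed: int = 1
    # simulation block (desk scale: full structure, runtime-friendly sizes)
    n_panel: int = 300
    n_markers: int = 800
    n_subpops: int = 3
    fst: float = 0.05
    maf_min: float = 0.05
    n_chromosomes: int = 19
    chrom_length_cM: float = 75.0
    n_parents: int = 5
    n_offspring_per_cross: int = 30
    n_traits: int = 5
    n_years: int = 2
    n_blocks: int = 2
    # analysis block
    scenarios: tuple[str, ...] = ("1a", "1b", "2")
    methods: tuple[str, ...] = ("RR", "LASSO")
    k_folds: int = 10
    cv_reps: int = 2
    grid_size: int = 50
    model_selection: bool = False
    selection_alpha: float = 0.05
    ts_criteria: tuple[str, ...] = ("PEVmean", "CDmean", "MeanRel")
    ts_sizes: tuple[int, ...] = (50, 100, 150)
    h2_for_lambda_ratio: float = 0.5
    run_tsopt: bool = True
    run_determinants: bool = True
    rank_all_crosses: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("scenarios", "methods", "ts_criteria", "ts_sizes"):
            if key in known and isinstance(known[key], list):
                known[key] = tuple(known[key])
        return cls(**known)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def validate_inputs(genotypes: DosageMatrix, pedigree: pd.DataFrame,
                    phenotypes: pd.DataFrame) -> dict[str, list[str]]:
    """Cross-reference checks on a genotype/pedigree/phenotype bundle.

    Returns {'errors': [...], 'warnings': [...]}; hard errors are conditions
    under which the pipeline cannot run (unresolvable ids, invalid dosages,
    inconsistent pedigree), warnings are recoverable oddities.
    """
    errors: list[str] = []
    warnings_: list[str] = []
    geno_ids = set(genotypes.individual_ids)
    if genotypes.dosages.min() < 0 or genotypes.dosages.max() > 2:
        bad = np.argwhere((genotypes.dosages < 0) | (genotypes.dosages > 2))
        i, j = bad[0]
        errors.append(
            f"dosage out of [0,2] at individual {genotypes.individual_ids[i]}, "
            f"marker {genotypes.marker_ids[j]} "
            f"(value {genotypes.dosages[i, j]})")
    for _, row in pedigree.iterrows():
        if row["parent1"] == row["parent2"]:
            errors.append(f"offspring {row['offspring']}: parent1 == parent2 "
                          f"({row['parent1']})")
    missing_off = sorted(set(pedigree["offspring"]) - geno_ids)[:20]
    if missing_off:
        errors.append(f"pedigree offspring without genotypes: {missing_off}")
    missing_par = sorted((set(pedigree["parent1"]) | set(pedigree["parent2"]))
                         - geno_ids)[:20]
    if missing_par:
        errors.append(f"pedigree parents without genotypes: {missing_par}")
    pheno_ids = set(phenotypes["genotype"].astype(str))
    unknown = sorted(pheno_ids - geno_ids)[:20]
    if unknown:
        errors.append(f"phenotyped ids without genotypes: {unknown}")
    if not np.isfinite(phenotypes["value"].to_numpy(dtype=float)).all():
        errors.append("non-finite phenotype values")
    ungenotyped = sorted(geno_ids - pheno_ids)
    if ungenotyped:
        warnings_.append(f"{len(ungenotyped)} genotyped individuals have no "
                         "phenotypes")
    return {"errors": errors, "warnings": warnings_}


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: RunConfig, out: Path, manifest: dict) -> dict[str, Any]:
    seed = cfg.seed
    panel, panel_pop = simulate_panel(
        cfg.n_panel, cfg.n_markers, cfg.n_subpops, cfg.fst, cfg.maf_min,
        map_length_cM=[cfg.chrom_length_cM] * cfg.n_chromosomes,
        seed=derive_seed(seed, "simulate:panel"))
    # parents: panel members, most from the first subpopulation and one from
    # another (mirrors a half-diallel bred mostly within one gene pool)
    sub = panel_pop.set_index("individual_id")["subpopulation"]
    first = [i for i in panel.individual_ids if sub[i] == sub.iloc[0]]
    other = [i for i in panel.individual_ids if sub[i] != sub.iloc[0]]
    n_main = max(1, cfg.n_parents - 1)
    parent_ids = first[:n_main] + other[:cfg.n_parents - n_main]
    parents = panel.subset_individuals(parent_ids)
    offspring, off_pop, crosses = make_half_diallel(
        parents, cfg.n_offspring_per_cross,
        seed=derive_seed(seed, "simulate:diallel"))
    archs = default_trait_suite(panel.marker_ids, cfg.n_traits,
                                seed=derive_seed(seed, "simulate:traits"))
    # cross-effect share of genetic variance spread over the study range
    shares = np.linspace(0.05, 0.5, max(1, cfg.n_traits))
    archs = [calibrate_cross_deviation(
        offspring, off_pop,
        orthogonalize_cross_means(arch, parents, crosses), float(share),
        clamp=True)
        for arch, share in zip(archs, shares)]
    pheno_hd, truth_hd = [], {}
    pheno_panel, truth_panel = [], {}
    for arch in archs:
        rec, tru = simulate_phenotypes(
            offspring, off_pop, arch, cfg.n_years, cfg.n_blocks,
            seed=derive_seed(seed, f"simulate:pheno-hd:{arch.trait_id}"))
        pheno_hd.append(rec)
        truth_hd[arch.trait_id] = tru
        rec_p, tru_p = simulate_phenotypes(
            panel, panel_pop, arch, cfg.n_years, cfg.n_blocks,
            seed=derive_seed(seed, f"simulate:pheno-panel:{arch.trait_id}"))
        pheno_panel.append(rec_p)
        truth_panel[arch.trait_id] = tru_p
    pheno_hd = pd.concat(pheno_hd, ignore_index=True)
    pheno_panel = pd.concat(pheno_panel, ignore_index=True)

    dio.write_dosage_csv(panel, out / "panel_dosages.csv",
                         out / "marker_map.csv")
    dio.write_dosage_csv(offspring, out / "offspring_dosages.csv")
    dio.write_pedigree_csv(off_pop, out / "pedigree.csv")
    dio.write_phenotypes_csv(pheno_hd, out / "phenotypes_halfdiallel.csv")
    dio.write_phenotypes_csv(pheno_panel, out / "phenotypes_panel.csv")
    panel_pop.to_csv(out / "panel_population.csv", index=False)
    manifest["artifacts"] += ["panel_dosages.csv", "marker_map.csv",
                              "offspring_dosages.csv", "pedigree.csv",
                              "phenotypes_halfdiallel.csv",
                              "phenotypes_panel.csv", "panel_population.csv"]
    return {"panel": panel, "panel_pop": panel_pop, "parents": parents,
            "offspring": offspring, "off_pop": off_pop, "crosses": crosses,
            "archs": archs, "pheno_hd": pheno_hd, "pheno_panel": pheno_panel,
            "truth_hd": truth_hd, "truth_panel": truth_panel}


def _fit_one_trait(records: pd.DataFrame, fixed_terms, random_terms,
                   model_selection: bool, alpha: float):
    vals = records["value"]
    transform = select_transformation(vals)
    rec = records.copy()
    rec["value"] = apply_transformation(vals.to_numpy(), transform)
    terms = list(random_terms)
    if model_selection:
        terms = drop_random_terms(rec, fixed_terms, terms, alpha)
    fit = fit_mixed_model(rec, fixed_terms, terms)
    return transform, terms, fit, rec


def _stage_fit_pheno(cfg: RunConfig, out: Path, manifest: dict,
                     sim: dict) -> dict[str, Any]:
    hd_rows, gv_rows, percross_rows = [], [], []
    panel_rows, gv_panel_rows = [], []
    panel_random = [t for t in DEFAULT_RANDOM_TERMS if "cross" not in t]
    for arch in sim["archs"]:
        t = arch.trait_id
        rec = sim["pheno_hd"][sim["pheno_hd"]["trait"] == t]
        transform, terms, fit, rec_t = _fit_one_trait(
            rec, DEFAULT_FIXED_TERMS, DEFAULT_RANDOM_TERMS,
            cfg.model_selection, cfg.selection_alpha)
        vc = fit.variance_components
        h2 = heritability_overall(vc)
        ratio = cross_variance_ratio(vc)
        gv = scale_genetic_values(fit.genetic_values)
        for g, row in gv.values.iterrows():
            gv_rows.append({"genotype": g, "trait": t, "C": row["C"],
                            "G": row["G"], "total": row["total"]})
        hd_rows.append({"trait": t, "transform": transform, "h2_overall": h2,
                        "cross_ratio": ratio,
                        **{f"vc_{k}": v for k, v in vc.components.items()}})
        # within a single cross the few dozen plots cannot identify the
        # field-coordinate terms; per-cross refits keep the genetic and
        # year-interaction structure only
        terms_pc = [t for t in terms if t.split(":")[0] not in ("x", "y")]
        for cid, crec in rec_t.groupby("cross"):
            try:
                h2c = heritability_per_cross(crec, terms_pc, DEFAULT_FIXED_TERMS)
            except (ValueError, RuntimeError) as exc:
                logger.warning("per-cross H2 failed for %s/%s: %s", t, cid, exc)
                h2c = np.nan
            percross_rows.append({"trait": t, "cross": cid, "h2_cross": h2c})

        # panel phenotypes: same trait, no cross terms
        rec_p = sim["pheno_panel"][sim["pheno_panel"]["trait"] == t]
        transform_p, terms_p, fit_p, _ = _fit_one_trait(
            rec_p.drop(columns=["cross"]), DEFAULT_FIXED_TERMS, panel_random,
            cfg.model_selection, cfg.selection_alpha)
        h2_panel = heritability_overall(fit_p.variance_components)
        gv_p = scale_genetic_values(fit_p.genetic_values)
        sub = sim["panel_pop"].set_index("individual_id")["subpopulation"]
        r2 = subpopulation_r2(gv_p.values["total"].to_numpy(),
                              sub.loc[gv_p.values.index].to_list())
        panel_rows.append({"trait": t, "transform": transform_p,
                           "h2_panel": h2_panel, "subpop_r2": r2})
        for g, row in gv_p.values.iterrows():
            gv_panel_rows.append({"genotype": g, "trait": t,
                                  "total": row["total"]})
    herit = pd.DataFrame(hd_rows)
    herit_cross = pd.DataFrame(percross_rows)
    herit_panel = pd.DataFrame(panel_rows)
    gv_hd = pd.DataFrame(gv_rows)
    gv_panel = pd.DataFrame(gv_panel_rows)
    herit.to_csv(out / "heritability_halfdiallel.csv", index=False)
    herit_cross.to_csv(out / "heritability_per_cross.csv", index=False)
    herit_panel.to_csv(out / "heritability_panel.csv", index=False)
    gv_hd.to_csv(out / "genetic_values_halfdiallel.csv", index=False)
    gv_panel.to_csv(out / "genetic_values_panel.csv", index=False)
    manifest["artifacts"] += ["heritability_halfdiallel.csv",
                              "heritability_per_cross.csv",
                              "heritability_panel.csv",
                              "genetic_values_halfdiallel.csv",
                              "genetic_values_panel.csv"]
    return {"herit": herit, "herit_cross": herit_cross,
            "herit_panel": herit_panel, "gv_hd": gv_hd, "gv_panel": gv_panel}


def _stage_scenarios(cfg: RunConfig, out: Path, manifest: dict, sim: dict,
                     pheno: dict) -> dict[str, Any]:
    hd = HalfDiallelData(sim["offspring"], sim["parents"], sim["off_pop"],
                         sim["crosses"], pheno["gv_hd"])
    results = {}
    pa_tables, cm_tables = [], []
    for scen in cfg.scenarios:
        seed = derive_seed(cfg.seed, f"scenario:{scen}")
        if scen == "1a":
            res = run_scenario_1a(hd, cfg.methods, cfg.k_folds, cfg.cv_reps,
                                  seed, cfg.grid_size)
        elif scen == "1b":
            if len(sim["crosses"]) < 3:
                logger.warning("scenario 1b skipped: no half-sib crosses "
                               "available with %d crosses", len(sim["crosses"]))
                continue
            res = run_scenario_1b(hd, cfg.methods, seed, cfg.grid_size)
        elif scen == "2":
            res = run_scenario_2(sim["panel"], sim["panel_pop"],
                                 pheno["gv_panel"], hd, cfg.methods, "all",
                                 seed, cfg.grid_size)
        elif scen.startswith("2-"):
            res = run_scenario_2(sim["panel"], sim["panel_pop"],
                                 pheno["gv_panel"], hd, cfg.methods,
                                 f"one-subpopulation:{scen.split('-')[1]}",
                                 seed, cfg.grid_size)
        else:
            raise ValueError(f"unknown scenario {scen!r}")
        results[scen] = res
        pa_tables.append(res.pa_table)
        cm = res.cross_means.copy()
        cm["scenario"] = res.scenario
        cm_tables.append(cm)
    if not results:
        logger.warning("no scenario produced results; nothing to write")
        return {"results": {}, "pa_all": pd.DataFrame(),
                "cm_all": pd.DataFrame()}
    pa_all = pd.concat(pa_tables, ignore_index=True)
    cm_all = pd.concat(cm_tables, ignore_index=True)
    pa_all.to_csv(out / "pa_results.csv", index=False)
    cm_all.to_csv(out / "cross_means.csv", index=False)
    manifest["artifacts"] += ["pa_results.csv", "cross_means.csv"]
    manifest["modality_correlation"] = {
        scen: float(modality_correlation(res.cross_means))
        for scen, res in results.items()}
    # all-pairs panel cross ranking with per-trait bias correction
    if cfg.rank_all_crosses and "2" in results:
        res2 = results["2"]
        bias = estimate_bias(res2.cross_means[res2.cross_means["method"]
                                              == cfg.methods[0]])
        first_trait = sorted(pheno["gv_panel"]["trait"].unique())[0]
        gvp = pheno["gv_panel"]
        y = gvp[gvp["trait"] == first_trait].set_index("genotype")["total"] \
            .reindex(sim["panel"].individual_ids)
        model = fit_marker_model(sim["panel"].dosages, y.to_numpy(),
                                 cfg.methods[0], grid_size=cfg.grid_size,
                                 seed=derive_seed(cfg.seed, "rank:model"),
                                 marker_ids=sim["panel"].marker_ids,
                                 trait_id=first_trait)
        ranking = predict_all_crosses(sim["panel"], model,
                                      bias=float(bias.get(first_trait, 0.0)))
        ranking.insert(0, "trait", first_trait)
        ranking.to_csv(out / "all_pairs_ranking.csv", index=False)
        manifest["artifacts"].append("all_pairs_ranking.csv")
    return {"results": results, "pa_all": pa_all, "cm_all": cm_all}


def _stage_tsopt(cfg: RunConfig, out: Path, manifest: dict, sim: dict) -> pd.DataFrame:
    lam_r = (1 - cfg.h2_for_lambda_ratio) / cfg.h2_for_lambda_ratio
    # A over panel + offspring with panel allele frequencies
    combined = DosageMatrix(
        sim["panel"].individual_ids + sim["offspring"].individual_ids,
        sim["panel"].marker_ids,
        np.vstack([sim["panel"].dosages, sim["offspring"].dosages]),
        sim["panel"].marker_map)
    A = vanraden_A(combined, freq_individuals=sim["panel"].individual_ids)
    cross_of = sim["off_pop"].set_index("individual_id")["cross_id"]
    rows = []
    for cr in sim["crosses"]:
        vs = [i for i in sim["offspring"].individual_ids
              if cross_of[i] == cr.cross_id]
        candidates = list(sim["panel"].individual_ids)
        for size in cfg.ts_sizes:
            if size > len(candidates):
                continue
            for crit in cfg.ts_criteria:
                sel = optimize_ts(A, candidates, vs, crit, size, restarts=1,
                                  seed=derive_seed(cfg.seed,
                                                   f"tsopt:{cr.cross_id}:{crit}:{size}"),
                                  lambda_ratio=lam_r)
                rows.append({"cross": cr.cross_id, "criterion": crit,
                             "size": size, "value": sel.criterion_value,
                             "members": ";".join(sel.member_ids)})
            base = random_baseline(candidates, vs, size, A, "MeanRel",
                                   reps=10,
                                   seed=derive_seed(cfg.seed,
                                                    f"tsopt:rand:{cr.cross_id}:{size}"),
                                   lambda_ratio=lam_r)
            vals = [b.criterion_value for b in base]
            rows.append({"cross": cr.cross_id, "criterion": "random-MeanRel",
                         "size": size, "value": float(np.mean(vals)),
                         "members": ""})
    df = pd.DataFrame(rows)
    df.to_csv(out / "ts_optimization.csv", index=False)
    manifest["artifacts"].append("ts_optimization.csv")
    return df


def _stage_determinants(cfg: RunConfig, out: Path, manifest: dict, sim: dict,
                        pheno: dict, scen: dict) -> dict[str, Any]:
    # cross-level covariates
    proj = pca_project(sim["panel"], sim["parents"], n_axes=2)
    A_panel = vanraden_A(sim["panel"])
    parent_pos = {p: sim["panel"].individual_ids.index(p)
                  for p in sim["parents"].individual_ids}
    cross_rows = {}
    for cr in sim["crosses"]:
        d1 = sim["parents"].row(cr.parent1)
        d2 = sim["parents"].row(cr.parent2)
        rel = A_panel.values[parent_pos[cr.parent1], parent_pos[cr.parent2]]
        cross_rows[cr.cross_id] = {
            "prop_nonseg": nonsegregating_proportion(d1, d2),
            "parent_relationship": rel,
            "parent_pca_distance": parent_axis_distance(proj, cr.parent1,
                                                        cr.parent2, (1, 2)),
        }
    cross_stats = pd.DataFrame(cross_rows).T
    trait_stats = pheno["herit"].set_index("trait")[["h2_overall",
                                                     "cross_ratio"]]
    trait_stats = trait_stats.join(
        pheno["herit_panel"].set_index("trait")[["h2_panel", "subpop_r2"]])
    tc_stats = pheno["herit_cross"]
    reports = {}
    for scen_name, res in scen["results"].items():
        cells = res.pa_table
        cells = cells[(cells["component"] == "mendelian")
                      & (cells["granularity"] == "per_cell")
                      & (cells["method"] == "best")]
        if scen_name == "1b":
            cells = cells.groupby(["trait", "cross"], as_index=False)["pa"].mean()
        cs = cross_stats.copy()
        scen_key = scen_name.split("-")[0]
        if scen_key in ("1b", "2"):
            # mean TS-VS additive relationship per cross
            cross_of = sim["off_pop"].set_index("individual_id")["cross_id"]
            combined = DosageMatrix(
                sim["panel"].individual_ids + sim["offspring"].individual_ids,
                sim["panel"].marker_ids,
                np.vstack([sim["panel"].dosages, sim["offspring"].dosages]),
                sim["panel"].marker_map)
            A_all = vanraden_A(combined,
                               freq_individuals=sim["panel"].individual_ids)
            tsvs = {}
            for cr in sim["crosses"]:
                vs = [i for i in sim["offspring"].individual_ids
                      if cross_of[i] == cr.cross_id]
                if scen_key == "2":
                    ts = list(sim["panel"].individual_ids)
                else:
                    ts = [i for i in sim["offspring"].individual_ids
                          if cross_of[i] != cr.cross_id
                          and (cr.parent1 in (cross_of[i].split("x"))
                               or cr.parent2 in (cross_of[i].split("x")))]
                tsvs[cr.cross_id] = mean_relationship(A_all, ts, vs)
            cs["ts_vs_relationship"] = pd.Series(tsvs)
        try:
            table = assemble_table(cells, cs, trait_stats, scen_key,
                                   trait_cross_stats=tc_stats)
        except ValueError as exc:
            logger.warning("determinants skipped for %s: %s", scen_name, exc)
            continue
        sel = stepwise_aic(table)
        report = {"scenario": scen_name, "selected": sel.selected_predictors,
                  "r2": float(sel.rsquared) if sel.selected_predictors else 0.0}
        if sel.selected_predictors:
            imp_pmvd = relative_importance(table, sel.selected_predictors,
                                           method="pmvd")
            imp_lmg = relative_importance(table, sel.selected_predictors,
                                          method="lmg")
            report["pmvd"] = imp_pmvd.shares.to_dict()
            report["lmg"] = imp_lmg.shares.to_dict()
        reports[scen_name] = report
        table.to_csv(out / f"explanatory_table_{scen_name}.csv", index=False)
        manifest["artifacts"].append(f"explanatory_table_{scen_name}.csv")
    (out / "determinants_report.json").write_text(
        json.dumps(reports, indent=2, default=float))
    manifest["artifacts"].append("determinants_report.json")
    return reports


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, Any]:
    """Execute the requested stages in dependency order; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"config": asdict(config),
                                "config_digest": config.digest(),
                                "version": __version__,
                                "seed": config.seed, "artifacts": []}
    stage = "simulate"
    try:
        sim = _stage_simulate(config, out, manifest)
        stage = "fit-pheno"
        pheno = _stage_fit_pheno(config, out, manifest, sim)
        stage = "scenarios"
        scen = _stage_scenarios(config, out, manifest, sim, pheno)
        if config.run_tsopt:
            stage = "optimize-ts"
            _stage_tsopt(config, out, manifest, sim)
        if config.run_determinants:
            stage = "explain-pa"
            _stage_determinants(config, out, manifest, sim, pheno, scen)
    except Exception as exc:
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    return manifest
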