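"""Train a ridge model on the panel, correct its cross-mean bias on the known
crosses, and rank every possible panel cross by predicted mean."""

import numpy as np
import pandas as pd

from diallelgp import simdata
from diallelgp.gp_engine import fit_marker_model
from diallelgp.scenarios import (HalfDiallelData, estimate_bias,
                                 predict_all_crosses, run_scenario_2)

panel, pop = simdata.simulate_panel(100, 300, 3, map_length_cM=[80.0] * 5,
                                    seed=41)
parents = panel.subset_individuals(panel.individual_ids[:5])
offspring, off_pop, crosses = simdata.make_half_diallel(parents, 20, seed=41)
arch = simdata.make_architecture(panel.marker_ids, "t", "polygenic",
                                 target_H2=0.9, seed=41)


def scaled_totals(genotypes, popframe, seed):
    _, truth = simdata.simulate_phenotypes(genotypes, popframe, arch, 2, 2,
                                           seed=seed)
    g = truth["genetic_values"]
    g = g / g.std(ddof=1)
    return pd.DataFrame({"genotype": g.index, "trait": "t",
                         "total": g.to_numpy()})


hd = HalfDiallelData(offspring, parents, off_pop, crosses,
                     scaled_totals(offspring, off_pop, 42))
panel_gv = scaled_totals(panel, pop, 43)
res2 = run_scenario_2(panel, pop, panel_gv, hd, methods=("RR",), seed=1,
                      grid_size=30)
bias = estimate_bias(res2.cross_means)["t"]
print(f"per-trait bias of predicted cross means: {bias:+.3f} "
      f"(subtracted from new predictions)")

y = panel_gv.set_index("genotype")["total"].reindex(panel.individual_ids)
model = fit_marker_model(panel.dosages, y.to_numpy(), "RR", grid_size=30,
                         seed=1, marker_ids=panel.marker_ids)
ranking = predict_all_crosses(panel, model, bias=bias)
print(f"{len(ranking)} candidate crosses ranked "
      f"({panel.n_individuals} x {panel.n_individuals - 1} / 2 pairs)")
print("top 5 predicted cross means:")
print(ranking.head(5).to_string(index=False))
# Each row is an untested pair of panel members with its bias-corrected
# predicted mean genetic value on the unit BLUP scale.
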