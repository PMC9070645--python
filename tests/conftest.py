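import numpy as np
import pandas as pd
import pytest

from diallelgp import simdata


@pytest.fixture(scope="session")
def small_panel():
    """Structured panel: 60 individuals, 3 subpops, 300 markers on 5 chromosomes."""
    return simdata.simulate_panel(n_individuals=60, n_markers=300, n_subpops=3,
                                  fst=0.05, seed=11, map_length_cM=[80.0] * 5)


@pytest.fixture(scope="session")
def small_diallel(small_panel):
    """5 parents from the panel crossed into a 10-family half-diallel."""
    panel, pop = small_panel
    parents = panel.subset_individuals(panel.individual_ids[:5])
    off, offpop, crosses = simdata.make_half_diallel(parents, 20, seed=7)
    return parents, off, offpop, crosses


@pytest.fixture(scope="session")
def simulated_trait(small_panel, small_diallel):
    """One calibrated polygenic trait with phenotypes and ground truth."""
    panel, _ = small_panel
    parents, off, offpop, crosses = small_diallel
    arch = simdata.make_architecture(panel.marker_ids, "t1", "polygenic",
                                     target_H2=0.8, seed=5)
    arch = simdata.orthogonalize_cross_means(arch, parents, crosses)
    arch = simdata.calibrate_cross_deviation(off, offpop, arch, 0.3)
    records, truth = simdata.simulate_phenotypes(off, offpop, arch, 2, 2,
                                                 seed=13)
    return arch, records, truth


@pytest.fixture(scope="session")
def scaled_true_gv(small_diallel, simulated_trait):
    """Scaled true genetic values in the tidy (genotype, trait, total) layout."""
    _, records, truth = simulated_trait
    g = truth["genetic_values"]
    g = g / g.std(ddof=1)
    return pd.DataFrame({"genotype": g.index, "trait": "t1",
                         "total": g.to_numpy()})
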