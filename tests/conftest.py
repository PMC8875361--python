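import numpy as np
import pandas as pd
import pytest

from sigreg import simulate


@pytest.fixture(scope="session")
def null_panel():
    """Truth-free default panel: 400 genes x 45 samples, seed 0."""
    cfg = simulate.SimulationConfig(n_genes=400, seed=0)
    return simulate.simulate_counts(cfg)


@pytest.fixture(scope="session")
def planted_panel():
    """Small planted panel: 10 genes per regulon class in the heat
    condition among 600 genes, at the study's effect size and design."""
    truth = simulate.plant_truth(n_per_class=10, effect_log2=2.0, condition="heat")
    cfg = simulate.SimulationConfig(n_genes=600, seed=7)
    counts, samples, sim_truth = simulate.simulate_counts(cfg, truth=truth)
    return counts, samples, sim_truth, truth
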