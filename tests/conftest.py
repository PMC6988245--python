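import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import dietexpr as dx

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """200-gene single-tissue dataset with planted diet effects."""
    cfg = dx.SimConfig(n_genes=200, tissues=("B",), pi_de=0.2, seed=1)
    return dx.simulate_counts(cfg)


@pytest.fixture(scope="session")
def full_design_sim():
    """Small full 3-diet x 3-tissue x 6-replicate dataset."""
    cfg = dx.SimConfig(n_genes=120, pi_de=0.2, seed=2)
    return dx.simulate_counts(cfg)


@pytest.fixture(scope="session")
def module_sim():
    """Planted-module world: 5 x 50-gene modules + 250 noise genes.

    Constant loading 0.53 maps to within-module expression correlation near
    0.7 given the NB measurement noise at mean counts ~128; no tissue
    effects, so correlation structure comes only from the planted factors.
    """
    cfg = dx.SimConfig(n_genes=500, pi_de=0.0, module_spec=((50, 0.53),) * 5,
                       baseline_logmean_mu=7.0, baseline_logmean_sigma=1.0,
                       tissue_effect_sd=0.0, batch_effect_sd=0.2, seed=7)
    counts, meta, truth = dx.simulate_counts(cfg)
    sf = dx.estimate_size_factors(counts)
    expr = dx.shifted_log_transform(counts, sf)
    info = dx.estimate_surrogate_variable(expr, meta)
    # batch-only correction: the planted factors ARE the signal here and a
    # surrogate variable would absorb the strongest module
    info = dx.DesignInfo(meta=info.meta, surrogate=info.surrogate * 0.0,
                         protected=info.protected, batch_col=info.batch_col)
    corrected = dx.remove_batch_effects(expr, info)
    return corrected, meta, truth
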