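import numpy as np
import pytest

from megblup.geno import compute_grm
from megblup.model import build_model, fit_reml
from megblup.simulate import SimulationConfig, simulate_population, simulate_phenotypes


@pytest.fixture(scope="session")
def sim600():
    """Default three-site simulated trial: 30 families x (8,4,8) = 600 trees."""
    cfg = SimulationConfig(seed=7)
    geno, ped = simulate_population(cfg)
    pheno, truth = simulate_phenotypes(geno, ped, cfg)
    grm = compute_grm(geno, blend_weight=0.01)
    return cfg, geno, ped, pheno, truth, grm


@pytest.fixture(scope="session")
def fitted600(sim600):
    """REML fit of the default simulated trial (shared across tests)."""
    cfg, geno, ped, pheno, truth, grm = sim600
    spec = build_model(pheno, grm, cfg.trait_name)
    vc = fit_reml(spec)
    return spec, vc


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
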