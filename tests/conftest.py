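import numpy as np
import pytest

from forkdyn import ElasticityModel, KineticParameters

# Published parameter sets of the two-term Arrhenius fork model,
# keyed by (protein, Mg2+ mM).  Concentrations are the measurement
# conditions (20 nM yeast, 50 nM human protein).
PARAM_TABLE = {
    ("yRPA", 1): dict(k_on_per_nM=34.2, k_off=233.0, dz_on=5.0, dz_off=1.8, F_unz=17.8, concentration=20.0),
    ("yRPA", 3): dict(k_on_per_nM=9.0, k_off=239.0, dz_on=3.3, dz_off=1.6, F_unz=18.2, concentration=20.0),
    ("yRPA", 10): dict(k_on_per_nM=18.2, k_off=336.0, dz_on=2.4, dz_off=1.8, F_unz=19.9, concentration=20.0),
    ("hRPA", 3): dict(k_on_per_nM=2.1, k_off=37.0, dz_on=1.6, dz_off=0.6, F_unz=18.2, concentration=50.0),
    ("hRPA", 5): dict(k_on_per_nM=3.2, k_off=109.0, dz_on=2.1, dz_off=1.1, F_unz=18.8, concentration=50.0),
    ("hRPA", 10): dict(k_on_per_nM=6.2, k_off=189.0, dz_on=2.5, dz_off=0.9, F_unz=19.9, concentration=50.0),
}

# Reported equilibrium forces (pN) for the same six conditions.
F_EQUI_TABLE = {
    ("yRPA", 1): 12.4,
    ("yRPA", 3): 12.4,
    ("yRPA", 10): 11.1,
    ("hRPA", 3): 11.8,
    ("hRPA", 5): 12.2,
    ("hRPA", 10): 14.5,
}


@pytest.fixture(scope="session")
def elasticity():
    return ElasticityModel()


@pytest.fixture(scope="session")
def yrpa3():
    """yRPA in 3 mM Mg2+ at 20 nM: the workhorse parameter set."""
    return KineticParameters(**PARAM_TABLE[("yRPA", 3)])


@pytest.fixture(scope="session")
def param_table():
    return {k: KineticParameters(**v) for k, v in PARAM_TABLE.items()}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
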