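import pytest
from hypothesis import HealthCheck, settings

from harediff.lineage_filter import FilterParams
from harediff.synthetic_data import SimConfig, simulate

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


#: Small, fast generator configuration for unit tests.
SMALL_SETS = {
    "glycolysis": ("HK1", "GPI", "PFKL", "ALDOA"),
    "krebs": ("ACO2", "CS", "SDHA"),
    "complex_IV_nuclear": ("COX4I1", "COX5B"),
    "complex_IV_mt": ("COXI", "COXII"),
}
SMALL_RATES = {
    "glycolysis": (0.008, 0.002),
    "krebs": (0.006, 0.002),
    "complex_IV_nuclear": (0.01, 0.006),
    "complex_IV_mt": (0.02, 0.002),
}


def small_config(seed: int = 0, **overrides) -> SimConfig:
    kwargs = dict(
        gene_sets=SMALL_SETS,
        rates=SMALL_RATES,
        cds_length_mean=600.0,
        cds_length_sd=120.0,
        cds_length_min=300,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def sim_small():
    return simulate(small_config(seed=11))


@pytest.fixture(scope="session")
def sim_default():
    return simulate(SimConfig(seed=11))


@pytest.fixture
def default_params():
    return FilterParams()
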