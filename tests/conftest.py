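import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from topophen.config import SyntheticConfig
from topophen import synthetic

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Compact landscape: 2 sites × 2 years, fast enough for every stage."""
    return SyntheticConfig(
        seed=11, n_sites=2, n_species_pool=10,
        site_richness_range=(4, 6),
        years={"2017": -0.5, "2018": 0.4},
    )


@pytest.fixture(scope="session")
def small_landscape(small_config) -> dict[str, pd.DataFrame]:
    return synthetic.simulate_landscape(small_config)


def noise_free_config(**kw) -> SyntheticConfig:
    """All stochastic components off: the analytically forced limit."""
    base = dict(
        seed=5, n_sites=2, n_species_pool=8,
        site_richness_range=(4, 4), turnover_fraction=0.0,
        temp_noise_sd_C=0.0, site_temp_sd_C=0.0,
        var_site=0.0, var_genotype=0.0, var_plot_noise=0.0,
        poisson_noise=False, survey_interval_days=1,
        years={"2017": 0.0},
    )
    base.update(kw)
    return SyntheticConfig(**base)
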