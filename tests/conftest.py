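import numpy as np
import pytest
from hypothesis import settings

from clockforge import GeneratorConfig, SpeciesDesign, generate_panel

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def cat_panel():
    """Small single-species panel with age, sex and marker probes."""
    config = GeneratorConfig(
        n_probes=500, n_age_probes=60, n_sex_probes=20, n_species_marker_probes=20,
        species={"cat": SpeciesDesign(n_samples=40, age_range=(0.2, 21.0),
                                      max_lifespan=30.0, maturity=1.0)},
        seed=11,
    )
    return config, generate_panel(config)


@pytest.fixture(scope="session")
def dual_panel():
    """Two-species panel (cat + human) for dual-species clocks."""
    config = GeneratorConfig(
        n_probes=800, n_age_probes=120, n_sex_probes=40, n_species_marker_probes=60,
        species={
            "cat": SpeciesDesign(n_samples=60, age_range=(0.2, 21.0),
                                 max_lifespan=30.0, maturity=1.0),
            "human": SpeciesDesign(n_samples=60, age_range=(0.0, 93.0),
                                   max_lifespan=122.0, maturity=15.0),
        },
        seed=3,
    )
    return config, generate_panel(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
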