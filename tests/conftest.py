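import logging

import pytest

from harmdw import SimulationConfig, load_registry, simulate_population

# calibration clipping for the extreme-RR condition is expected and noisy
logging.getLogger("harmdw").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def default_population():
    """One reference population under the default study conditions."""
    persons, manifest = simulate_population(SimulationConfig(n=20_000, seed=1))
    return persons, manifest


@pytest.fixture(scope="session")
def noiseless_single_condition():
    """Noiseless world: PG weight 0.46 plus one condition of weight 0.235.

    Exact algebraic identities hold here, so estimator oracles can assert
    to near machine precision.
    """
    from harmdw import ConditionSpec

    cfg = SimulationConfig(
        n=6_000,
        seed=11,
        noise_sigma=0.0,
        confounding_strength=0.5,
        category_dws={"LR": 0.14, "MR": 0.29, "PG": 0.46},
        conditions=[
            ConditionSpec(
                name="Alcohol abuse",
                community_prevalence=0.047,
                rr_pg=3.9,
                dw=0.235,
            )
        ],
    )
    persons, manifest = simulate_population(cfg)
    return persons, cfg
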