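from datetime import date, timedelta

import numpy as np
import pytest

from fowldna import simulate as sim


@pytest.fixture(scope="session")
def small_config():
    """A light study: default roster, reduced depth, fixed seed."""
    return sim.default_config(seed=7, read_depth_per_sample=30_000)


@pytest.fixture(scope="session")
def bundle(small_config):
    return sim.simulate_all(small_config)


def make_turnover_config(
    seed: int,
    n_species: int = 12,
    passage_width: float = 8.0,
    peak_spacing_days: int = 6,
    **overrides,
):
    """Species with staggered narrow passage pulses: strong week-to-week
    community turnover, the regime where temporal structure is identifiable."""
    start = date(2020, 9, 24)
    species = tuple(
        sim.SpeciesParams(
            f"Species s{i:02d}",
            "Anatini/Cairinini/Oxyura",
            start + timedelta(days=peak_spacing_days * i),
            passage_width,
            300 + 150 * i,
        )
        for i in range(n_species)
    )
    dates = tuple(start + timedelta(days=7 * k) for k in range(10))
    kwargs = dict(
        seed=seed,
        dates=dates,
        species=species,
        detection_prob=0.95,
        observer_dispersion=0.05,
        read_depth_per_sample=100_000,
        read_overdispersion=0.02,
        lag_kernel=(1.0, 0, 0, 0, 0, 0),
        contamination_rate=0.0,
    )
    kwargs.update(overrides)
    return sim.SimulationConfig(**kwargs)


def random_acgt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
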