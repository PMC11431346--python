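import numpy as np
import pandas as pd
import pytest

from socineq.ridit import GroupedDistribution, attach_scores
from socineq.simulate import SimulationDesign, generate


@pytest.fixture
def two_group_even() -> GroupedDistribution:
    """Two equal-share groups with prevalences 0.40 / 0.60."""
    return GroupedDistribution(("low", "high"), (0.5, 0.5), (0.40, 0.60))


@pytest.fixture
def scored_single_wave() -> pd.DataFrame:
    """Single-wave synthetic survey with ridit scores attached."""
    design = SimulationDesign(
        n=8000,
        shares={"2013": (0.25, 0.30, 0.30, 0.15)},
        truth={"2013": ("linear", 0.45, 0.30)},
        sex_effect=0.04,
        age_effects=(0.0, -0.03, 0.02, 0.05),
        n_psu=120,
        icc=0.02,
    )
    return attach_scores(generate(design, seed=42), "group")


@pytest.fixture
def scored_two_wave() -> pd.DataFrame:
    """Two waves with different shares and a designed SII decline."""
    design = SimulationDesign(
        n=6000,
        shares={"2013": (0.30, 0.30, 0.25, 0.15),
                "2019": (0.20, 0.25, 0.32, 0.23)},
        truth={"2013": ("linear", 0.45, 0.35),
               "2019": ("linear", 0.52, 0.20)},
        sex_effect=0.03,
        age_effects=(0.0, -0.02, 0.02, 0.04),
    )
    return attach_scores(generate(design, seed=7), "group", wave="wave")


def random_grouped_distribution(rng: np.random.Generator, k: int | None = None):
    """A random valid grouped distribution with prevalences bounded away
    from 0/1 (so identity- and log-link fits are well posed)."""
    k = k or rng.integers(2, 6)
    shares = rng.dirichlet(np.full(k, 2.0))
    while shares.min() < 0.02:
        shares = rng.dirichlet(np.full(k, 2.0))
    prev = rng.uniform(0.10, 0.90, size=k)
    labels = tuple(f"g{i}" for i in range(k))
    return GroupedDistribution(labels, tuple(shares), tuple(prev))
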