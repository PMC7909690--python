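import numpy as np
import pytest

from chreodkit import AgeGridSeries, SimulationConfig, simulate_population


def make_series(values: np.ndarray, ages=None, groups=None) -> AgeGridSeries:
    """Wrap a plain (individuals x ages) matrix as an AgeGridSeries."""
    values = np.asarray(values, dtype=float)
    n, T = values.shape
    if ages is None:
        ages = np.arange(T, dtype=float)
    return AgeGridSeries(
        values=values,
        grid_ages=np.asarray(ages, dtype=float),
        individual_ids=np.array([f"ind{i}" for i in range(n)]),
        group_labels=None if groups is None else np.asarray(groups),
    )


@pytest.fixture
def isogenic_series() -> AgeGridSeries:
    """Large isogenic AR(1) population (theta=0.4, unit innovations)."""
    cfg = SimulationConfig(
        n_individuals=5000,
        ages=np.arange(12.0),
        theta_t=0.4,
        var_eps_t=1.0,
        var_d0=1.0,
        seed=20240917,
    )
    _, truth = simulate_population(cfg)
    return make_series(truth.x_obs, ages=truth.ages)
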