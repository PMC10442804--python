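import numpy as np
import pytest

from dosestrat import CohortConfig, DVHCurve, generate_cohort, load_config


def linear_curve(d_max: float = 70.0, roi: str = "organ") -> DVHCurve:
    """v(d) = 1 - d/d_max on [0, d_max]: mean d_max/2, max dose d_max."""
    return DVHCurve(roi, np.array([0.0, d_max]), np.array([1.0, 0.0])).validate()


def uniform_curve(dose: float, roi: str = "organ") -> DVHCurve:
    """Whole organ receives exactly ``dose`` Gy (sharp falloff)."""
    if dose == 0:
        return DVHCurve(roi, np.array([0.0, 1e-9]), np.array([1.0, 0.0]))
    return DVHCurve(
        roi, np.array([0.0, dose, dose + 1e-9]), np.array([1.0, 1.0, 0.0])
    ).validate()


def random_piecewise_curve(rng: np.random.Generator, n_knots=None) -> DVHCurve:
    """A random valid piecewise-linear cumulative DVH."""
    k = int(n_knots or rng.integers(3, 12))
    doses = np.sort(rng.uniform(0.5, 80.0, size=k))
    doses = np.concatenate([[0.0], doses])
    drops = rng.random(k + 1)
    vols = 1.0 - np.cumsum(drops) / drops.sum() * rng.uniform(0.3, 1.0)
    vols = np.clip(np.concatenate([[1.0], vols[:-1] ]), 0.0, 1.0)
    vols = np.minimum.accumulate(vols)
    return DVHCurve("rand", doses, vols).validate()


@pytest.fixture(scope="session")
def config():
    return load_config()


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic 120-patient synthetic cohort, reused read-only."""
    return generate_cohort(CohortConfig(n_patients=120, seed=11))
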