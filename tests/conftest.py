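import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from retispec import synthetic

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A reduced cohort: short axis, few samples, cheap to generate."""
    return synthetic.CohortConfig(
        n_tbi_samples=3, n_control_samples=3, spectra_per_sample=8,
        axis_start=900.0, axis_stop=3300.0, axis_step=2.0, seed=42)


@pytest.fixture
def clean_config():
    """No baseline, noise, spikes or jitter: band structure only."""
    return synthetic.CohortConfig(
        n_tbi_samples=2, n_control_samples=2, spectra_per_sample=4,
        axis_start=900.0, axis_stop=3300.0, axis_step=2.0,
        baseline_amplitude=0.0, noise_sd=0.0, cosmic_ray_rate=0.0,
        band_jitter_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = synthetic.CohortConfig(
        n_tbi_samples=3, n_control_samples=3, spectra_per_sample=8,
        axis_start=900.0, axis_stop=3300.0, axis_step=2.0, seed=42)
    return synthetic.simulate_cohorts(cfg)


@pytest.fixture
def blob_data(rng):
    """Two spherical clusters ~10 noise-SD apart, separated in *direction*
    (not just magnitude) so a cosine-metric classifier can resolve them."""
    n, d = 60, 24
    mean_a = np.r_[np.full(d // 2, 8.0), np.full(d - d // 2, 1.0)]
    mean_b = mean_a[::-1]
    a = rng.normal(0.0, 1.0, (n, d)) + mean_a
    b = rng.normal(0.0, 1.0, (n, d)) + mean_b
    X = np.vstack([a, b])
    y = np.array(["a"] * n + ["b"] * n)
    return X, y
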