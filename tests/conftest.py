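import warnings

import numpy as np
import pytest

from panelflow import (
    ChromatogramSimSpec,
    CohortSimSpec,
    PipelineParams,
    make_demo_panel,
    simulate_chromatograms,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def demo_panel():
    return make_demo_panel(seed=0)


@pytest.fixture(scope="session")
def clean_batch(demo_panel):
    """Noise-free, jitter-free chromatogram batch with truth."""
    spec = ChromatogramSimSpec(panel=demo_panel, n_samples=6, n_blanks=1, seed=3)
    return simulate_chromatograms(spec)


@pytest.fixture(scope="session")
def noisy_batch(demo_panel):
    """Realistically noisy batch: 2% noise, RT jitter, drift, blank signal."""
    spec = ChromatogramSimSpec(
        panel=demo_panel, n_samples=8, n_blanks=2, noise_sd=0.02,
        rt_jitter_sd=0.03, drift_coefficient=0.2, blank_level=0.05, seed=7,
    )
    return simulate_chromatograms(spec)


@pytest.fixture(scope="session")
def cohort_pd_hc():
    """Two-group cohort at the default study sizes (HC 36 / PD 99)."""
    spec = CohortSimSpec(n_per_group={"HC": 36, "PD": 99}, seed=11)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def params():
    return PipelineParams()


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


def gaussian_trace(amplitude=100.0, sigma=0.10, center=4.20, dt=0.002,
                   span=5.0, noise_sd=0.0, seed=0, baseline=0.0):
    """Sampled Gaussian peak helper shared across tests."""
    rng = np.random.default_rng(seed)
    t = np.arange(center - span * sigma, center + span * sigma + dt / 2, dt)
    y = amplitude * np.exp(-0.5 * ((t - center) / sigma) ** 2) + baseline
    if noise_sd:
        y = y + rng.normal(0, noise_sd, t.size)
    return t, np.clip(y, 0, None)
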