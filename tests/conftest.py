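import numpy as np
import pytest

from spectyper import spectra as sp
from spectyper import synthetic as syn
from spectyper.pipeline import PipelineConfig, run_pipeline


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fingerprint(rng):
    """A 30-peak latent fingerprint with full occurrence (no dropout)."""
    return syn.make_fingerprint(30, rng, species="Bacillus testus",
                                occurrence_range=(1.0, 1.0))


@pytest.fixture
def quiet_noise():
    """Noise model with every stochastic term switched off."""
    return syn.NoiseModel(mz_jitter_sd=0.0, intensity_cv=0.0,
                          baseline_amplitude=0.0, noise_sd=0.0,
                          peak_width=3.0, peak_width_sd=0.0, seed=0)


@pytest.fixture
def default_noise():
    return syn.NoiseModel(seed=0)


def peaklist(mz, intensity=None):
    """Convenience constructor for hand-built peak lists."""
    mz = np.asarray(mz, float)
    if intensity is None:
        intensity = np.ones_like(mz)
    intensity = np.asarray(intensity, float)
    return sp.PeakList(mz, intensity / intensity.max())


@pytest.fixture(scope="session")
def pipeline_summary():
    """Full default-scenario pipeline run, shared across tests (fixed seed)."""
    return run_pipeline(PipelineConfig(seed=7))
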