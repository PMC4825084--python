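import numpy as np
import pytest

from aifx.phantom import PhantomSpec, generate_phantom
from aifx.pipeline import run_pipeline


@pytest.fixture(scope="session")
def default_phantom():
    """A default-condition phantom (noise, motion, shading all on)."""
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def clean_phantom():
    """A phantom with every corrupting factor switched off."""
    spec = PhantomSpec(seed=2, noise_sigma=0.0, motion_amplitude_px=0.0,
                       shading_coeffs=np.array([[1.0]]), baseline=0.0,
                       body_amp=0.0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def pipeline_result(default_phantom):
    """Full pipeline run on the default phantom."""
    series, _ = default_phantom
    return run_pipeline(series)
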