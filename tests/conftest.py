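import numpy as np
import pytest

from sorsid import simulate as sim
from sorsid.core import Spectrum, WavenumberAxis
from sorsid.pipeline import RunConfig, calibrate, run_demo


@pytest.fixture(scope="session")
def axis():
    return sim.DEFAULT_AXIS


@pytest.fixture()
def ramp_spectrum():
    x = np.linspace(400.0, 2000.0, 161)
    return Spectrum(WavenumberAxis(x), 0.5 * x + 3.0, {"sample": "ramp"})


@pytest.fixture(scope="session")
def calibration_labeled():
    """13 mock-fluid classes x 6 replicates at default noise (seed 0)."""
    classes = {f"C{i}": sim.CALIBRATION_CLASSES[f"C{i}"] for i in range(1, 14)}
    return sim.generate_calibration_set(classes, n_replicates=6, seed=0)


@pytest.fixture(scope="session")
def calibration_model(calibration_labeled):
    return calibrate(calibration_labeled, RunConfig())


@pytest.fixture(scope="session")
def demo_output():
    """Full synthetic survey: 13x6 calibration + 46-sample cohort, seed 0."""
    return run_demo(seed=0)
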