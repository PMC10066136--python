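import numpy as np
import pytest
from hypothesis import settings

import alps_reorient as ar
from alps_reorient.pipeline import EXPERIMENT_ACQUISITION

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_acq() -> ar.AcquisitionSpec:
    """Quarter-size grid, full 65-volume scheme."""
    return EXPERIMENT_ACQUISITION


@pytest.fixture(scope="session")
def small_template(small_acq):
    """Unrotated reference phantom on the quarter-size grid."""
    return ar.build_template(acquisition=small_acq)


@pytest.fixture(scope="session")
def gtab():
    return ar.generate_gradient_table(30, 1, 1000.0, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_spd_tensors(rng: np.random.Generator, n: int, scale: float = 0.25e-3) -> np.ndarray:
    """Random symmetric positive-definite 3x3 tensors.

    The default scale keeps eigenvalues in a physiological diffusivity range
    (~0.01-4 x 10^-3 mm^2/s) so simulated signals stay well above the
    log-clamp floor.
    """
    a = rng.standard_normal((n, 3, 3))
    spd = a @ np.swapaxes(a, -1, -2) + 0.05 * np.eye(3)
    return spd * scale
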