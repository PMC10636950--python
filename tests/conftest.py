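import numpy as np
import pytest

from mpq.core import ImageVolume
from mpq.dce import TumorMask
from mpq.synth import InputFunctionSpec, PhantomSpec, simulate_input_function


@pytest.fixture
def phantom_spec():
    """Default noiseless spherical phantom (515-voxel tumor)."""
    return PhantomSpec()


@pytest.fixture
def blood_curve():
    """Feng-type arterial input sampled densely over 60 minutes."""
    t = np.arange(0.0, 60.01, 0.05)
    return simulate_input_function(InputFunctionSpec(), t)


@pytest.fixture
def frame_schedule():
    from mpq.synth import default_frame_schedule

    return default_frame_schedule()


def volume(array, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(np.asarray(array, dtype=float), spacing)


def mask_of(array, spacing=(1.0, 1.0, 1.0)):
    return TumorMask(np.asarray(array, dtype=bool), spacing)
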