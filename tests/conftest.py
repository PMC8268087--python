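import numpy as np
import pytest

from ivdmech.models import IndentProfile, SLSParams
from ivdmech.synthetic import SyntheticIndentSpec, generate_indent_curve


@pytest.fixture(scope="session")
def default_profile():
    return IndentProfile()


@pytest.fixture(scope="session")
def af_control_params():
    """TS24 control annulus fibrosus parameter set (E_ins 24 kPa, f 0.74)."""
    return SLSParams.from_moduli(24.0, 0.74, 2.0)


@pytest.fixture(scope="session")
def clean_record(af_control_params):
    """Noise-free synthetic curve with a 1 s pre-contact baseline."""
    return generate_indent_curve(
        SyntheticIndentSpec(params=af_control_params, baseline_duration=1.0)
    )


def grating(angle_deg: float, shape=(256, 256), period: float = 12.0) -> np.ndarray:
    """Sinusoidal grating with stripes ALONG `angle_deg` (CCW from x, y up)."""
    yy, xx = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    a = np.radians(angle_deg)
    phase = 2 * np.pi / period * (-np.sin(a) * xx + np.cos(a) * (-yy))
    return 0.5 + 0.5 * np.cos(phase)
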