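import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # oracle_utils importable

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from gliometry import PhantomSpec, extract_lesions, make_phantom  # noqa: E402


@pytest.fixture(scope="session")
def sphere20():
    """Digital sphere, diameter 20 mm at 1 mm iso, plus its single lesion."""
    mask, gt = make_phantom(PhantomSpec(kind="sphere", radius_mm=10.0, shape=(32, 32, 32)))
    lesion = extract_lesions(mask)[0]
    return mask, lesion, gt


@pytest.fixture(scope="session")
def prolate_ellipsoid():
    """Prolate ellipsoid, semi-axes (10, 10, 30) mm, polar axis axial."""
    mask, gt = make_phantom(
        PhantomSpec(kind="ellipsoid", semi_axes_mm=(10, 10, 30), shape=(32, 32, 72))
    )
    lesion = extract_lesions(mask)[0]
    return mask, lesion, gt


@pytest.fixture
def rng():
    return np.random.default_rng(20230907)
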