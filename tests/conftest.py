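import numpy as np
import pytest

from dynrad.images import DynamicImage, Mask, ParametricImage
from dynrad.phantom import CohortConfig, simulate_cohort


SPACING = (2.0, 2.0, 2.0)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small two-center cohort with a planted dynamic effect, shared across
    tests that only read from it."""
    cfg = CohortConfig(n_per_center={"A": 8, "B": 6}, effect="dynamic",
                       effect_size=1.0)
    return simulate_cohort(cfg, seed=20240101)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_parametric(values, kind="TBR", spacing=SPACING):
    return ParametricImage(np.asarray(values, dtype=float), spacing, kind=kind)


def make_mask(values, spacing=SPACING, role="tumor"):
    return Mask(np.asarray(values, dtype=bool), spacing, role=role)


def make_dynamic(values, spacing=SPACING, frame_times=None):
    if frame_times is None:
        return DynamicImage(np.asarray(values, dtype=float), spacing)
    return DynamicImage(np.asarray(values, dtype=float), spacing, frame_times)
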