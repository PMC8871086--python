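import numpy as np
import pytest

from histoscar.fibers import OrientationField
from histoscar.synthetic import CLASS_COLLAGEN, SyntheticSpec, generate_image


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def single_fiber_mask(angle_deg: float, size: int = 128, seed: int = 2) -> np.ndarray:
    """Collagen mask of one long 3-px fiber at (approximately) angle_deg."""
    spec = SyntheticSpec(
        height=size, width=size, fiber_count=1,
        orientation_mean_deg=angle_deg, orientation_kappa=1e6,
        ellipse_count=0, nucleus_count=0, noise_sd=0.0, seed=seed,
    )
    _, gt = generate_image(spec)
    return gt.class_map == CLASS_COLLAGEN


def constant_field(theta_deg: float, shape=(96, 96)) -> OrientationField:
    return OrientationField(
        theta=np.full(shape, float(theta_deg)),
        valid=np.ones(shape, dtype=bool),
    )


def axial_diff_deg(a, b):
    """Smallest axial (mod 180) angular difference in degrees."""
    return np.abs((np.asarray(a) - np.asarray(b) + 90.0) % 180.0 - 90.0)
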