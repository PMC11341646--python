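import numpy as np
import pytest

from penna3d.core import MaskVolume, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cylinder_volume(
    shape=(40, 40, 60),
    spacing=(1.0, 1.0, 1.0),
    direction=(0.0, 0.0, 1.0),
    radius=2.0,
    amplitude=200.0,
    background=10.0,
):
    """Bright Gaussian-profile cylinder through the volume center.

    ``direction`` is the cylinder axis in *physical* (mm) coordinates;
    the returned tuple is (Volume, unit_direction).
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    sx, sy, sz = spacing
    xs = (np.arange(shape[0]) - (shape[0] - 1) / 2) * sx
    ys = (np.arange(shape[1]) - (shape[1] - 1) / 2) * sy
    zs = (np.arange(shape[2]) - (shape[2] - 1) / 2) * sz
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    along = pts @ d
    perp = pts - along[..., None] * d
    r2 = np.sum(perp ** 2, axis=-1)
    data = background + amplitude * np.exp(-r2 / (2 * radius ** 2))
    origin = np.array([xs[0], ys[0], zs[0]])
    return Volume(data, spacing, origin), d


def full_mask(vol) -> MaskVolume:
    return MaskVolume(np.ones(vol.shape, dtype=bool), vol.spacing, vol.origin, vol.axes)
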