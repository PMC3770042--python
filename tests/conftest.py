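"""Shared fixtures: canonical geometric images and coordinate-convention checks."""

from __future__ import annotations

import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def disk_mask(shape=(64, 64), center=(32.0, 32.0), radius=20.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    return (((yy - center[0]) ** 2 + (xx - center[1]) ** 2) <= radius**2).astype(np.uint8)


@pytest.fixture()
def disk():
    """Radius-20 disk mask in a 64x64 frame."""
    return disk_mask()


@pytest.fixture()
def disk_image(disk):
    """Bright disk (200) on dark background (20)."""
    return 20.0 + 180.0 * disk.astype(np.float64)


@pytest.fixture()
def clean_phantom():
    from liverseg import phantom

    spec = phantom.make_spec("clean", seed=7)
    return phantom.generate(spec)
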