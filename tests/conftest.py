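import numpy as np
import pytest

from tilagree.io_annotations import MaskStack, PointSets


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_stack(rng, n=4, h=48, w=48, p=0.5):
    masks = (rng.random((n, h, w)) < p).astype(np.uint8)
    return MaskStack(masks=masks, observer_ids=[f"o{i}" for i in range(n)],
                     image_id="rand")


@pytest.fixture
def small_stack(rng):
    return random_stack(rng)


@pytest.fixture
def blob_stack():
    """Four nearly identical masks: a centered disk whose radius differs by
    ≤ 2 px per observer, so all disagreement is boundary-localized."""
    h = w = 96
    yy, xx = np.mgrid[:h, :w]
    d = np.sqrt((xx - w / 2) ** 2 + (yy - h / 2) ** 2)
    radii = [30, 31, 32, 30.5]
    masks = np.stack([(d < r).astype(np.uint8) for r in radii])
    return MaskStack(masks=masks, observer_ids=list("abcd"), image_id="blob")


@pytest.fixture
def separated_points():
    """Perfect-agreement point sets on a coarse grid: every inter-cell
    distance (100 px) far exceeds twice the usual match radius."""
    xs, ys = np.meshgrid(np.arange(5) * 100.0 + 50, np.arange(5) * 100.0 + 50)
    base = np.column_stack([xs.ravel(), ys.ravel()])
    return PointSets(points=[base.copy() for _ in range(4)],
                     observer_ids=list("abcd"), image_id="grid")
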