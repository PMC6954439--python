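import numpy as np
import pytest

from mitoshape.segmentation import SegmentedObject


def obj_from_mask(mask, label=1, cell_id="cell"):
    """SegmentedObject from a binary mask (coordinates of set pixels)."""
    return SegmentedObject(label, np.argwhere(np.asarray(mask, bool)), cell_id=cell_id)


def disc_mask(radius_px, pad=5):
    side = int(2 * radius_px) + 2 * pad + 1
    c = side // 2
    yy, xx = np.mgrid[0:side, 0:side]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2


def random_polyomino(rng, n_pixels):
    """Random connected pixel set grown by 4-neighbour accretion."""
    pixels = {(0, 0)}
    frontier = [(0, 0)]
    while len(pixels) < n_pixels:
        r, c = frontier[rng.integers(len(frontier))]
        dr, dc = [(0, 1), (0, -1), (1, 0), (-1, 0)][rng.integers(4)]
        p = (r + dr, c + dc)
        if p not in pixels:
            pixels.add(p)
            frontier.append(p)
    coords = np.array(sorted(pixels))
    return coords - coords.min(axis=0)


def random_lattice_tree(rng, n_pixels):
    """Random 8-connected pixel tree: each new pixel touches only its parent.

    The resulting 1-px-wide arbour is its own skeleton up to thinning
    conventions, which makes geodesic lengths exactly computable.
    """
    pixels = {(0, 0)}
    order = [(0, 0)]
    attempts = 0
    while len(pixels) < n_pixels and attempts < 50 * n_pixels:
        attempts += 1
        r, c = order[rng.integers(len(order))]
        dr, dc = [(0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (1, -1), (-1, 1), (-1, -1)][rng.integers(8)]
        p = (r + dr, c + dc)
        if p in pixels:
            continue
        neighbours = sum(
            (p[0] + a, p[1] + b) in pixels
            for a in (-1, 0, 1) for b in (-1, 0, 1) if (a, b) != (0, 0)
        )
        if neighbours == 1:
            pixels.add(p)
            order.append(p)
    coords = np.array(sorted(pixels))
    mask_shape = coords.max(axis=0) - coords.min(axis=0) + 1
    mask = np.zeros(mask_shape, bool)
    shifted = coords - coords.min(axis=0)
    mask[shifted[:, 0], shifted[:, 1]] = True
    return mask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
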