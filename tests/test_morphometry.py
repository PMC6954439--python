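import math

import numpy as np
import pytest

from conftest import disc_mask, obj_from_mask, random_lattice_tree, random_polyomino
from mitoshape.morphometry import (
    ObjectFeatures,
    measure_basic,
    measure_object,
    midcrack_perimeter_px,
    min_feret,
    skeleton_extension,
    skeletonize_object,
    total_skeleton_length,
)

SQRT2 = math.sqrt(2)


def rotation_sweep_min_width(coords, step_deg=0.25):
    """Minimum projection width over a dense rotation sweep of pixel corners."""
    offsets = np.array([(-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5)])
    pts = (coords[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    angles = np.deg2rad(np.arange(0, 180, step_deg))
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    proj = pts @ dirs.T  # (n_points, n_angles)
    widths = proj.max(axis=0) - proj.min(axis=0)
    return widths.min()


def all_pairs_extension_oracle(skeleton, pixel_size):
    """Floyd–Warshall longest-shortest-path among skeleton endpoints."""
    coords = [tuple(p) for p in np.argwhere(skeleton)]
    index = {p: i for i, p in enumerate(coords)}
    n = len(coords)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    degree = np.zeros(n, int)
    for (r, c) in coords:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr, dc) == (0, 0):
                    continue
                q = (r + dr, c + dc)
                if q in index:
                    i, j = index[(r, c)], index[q]
                    dist[i, j] = (SQRT2 if dr and dc else 1.0) * pixel_size
                    degree[i] += 1
    for k in range(n):
        dist = np.minimum(dist, dist[:, k:k + 1] + dist[k:k + 1, :])
    endpoints = np.flatnonzero(degree == 1)
    nodes = endpoints if len(endpoints) >= 2 else np.arange(n)
    if len(nodes) < 2:
        return 0.0
    sub = dist[np.ix_(nodes, nodes)]
    return float(sub[np.isfinite(sub)].max())


class TestBasicFeatures:
    def test_square_area_and_solidity(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        f = measure_basic(obj_from_mask(mask), 0.1)
        assert f.A == pytest.approx(1.0)
        assert f.S == pytest.approx(1.0, abs=1e-6)
        assert f.AR == pytest.approx(1.0, abs=0.05)
        # reference value of the smoothed mid-crack estimator on a square
        assert f.C == pytest.approx(0.888, abs=0.02)
        assert f.r_eq == pytest.approx(math.sqrt(1.0 / math.pi))

    def test_disc_circularity_near_one(self):
        f = measure_basic(obj_from_mask(disc_mask(20.5)), 0.1)
        assert 0.90 <= f.C <= 1.00

    def test_single_pixel_conventions(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        f = measure_basic(obj_from_mask(mask), 0.1)
        assert (f.AR, f.S, f.C) == (1.0, 1.0, 1.0)
        assert f.A == pytest.approx(0.01)

    def test_rectangle_aspect_ratio(self):
        mask = np.zeros((40, 50), bool)
        mask[10:20, 10:40] = True  # 30 x 10
        f = measure_basic(obj_from_mask(mask), 0.1)
        assert f.AR == pytest.approx(3.0, rel=0.05)

    def test_thin_line_minor_axis_floored(self):
        mask = np.zeros((5, 30), bool)
        mask[2, 2:28] = True
        f = measure_basic(obj_from_mask(mask), 0.1)
        assert np.isfinite(f.AR) and f.AR > 5

    def test_circularity_clamped_for_tiny_objects(self):
        mask = np.zeros((4, 4), bool)
        mask[1:3, 1:3] = True
        f = measure_basic(obj_from_mask(mask), 0.1)
        assert f.C <= 1.0


class TestMinFeret:
    def test_rectangle_short_side(self):
        mask = np.zeros((40, 50), bool)
        mask[10:20, 10:40] = True
        assert min_feret(obj_from_mask(mask), 0.1) == pytest.approx(1.0, abs=0.1)

    def test_disc_diameter(self):
        assert min_feret(obj_from_mask(disc_mask(10.5)), 0.1) == pytest.approx(2.1, abs=0.1)

    def test_single_pixel_width_one(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        assert min_feret(obj_from_mask(mask), 0.1) == pytest.approx(0.1)

    def test_matches_rotation_sweep_oracle_on_random_polyominoes(self, rng):
        for _ in range(50):
            coords = random_polyomino(rng, int(rng.integers(3, 41)))
            got = min_feret(obj_from_mask_coords(coords), 1.0)
            want = rotation_sweep_min_width(coords.astype(float))
            assert got == pytest.approx(want, rel=0.01)

    def test_not_larger_than_max_feret(self, rng):
        from scipy.spatial.distance import pdist
        for _ in range(10):
            coords = random_polyomino(rng, 30)
            mle = min_feret(obj_from_mask_coords(coords), 1.0)
            offsets = np.array([(-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5)])
            pts = (coords[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
            max_feret = pdist(pts).max()
            assert mle <= max_feret + 1e-9


def obj_from_mask_coords(coords):
    from mitoshape.segmentation import SegmentedObject
    return SegmentedObject(1, coords)


class TestSkeletonExtension:
    def test_straight_line_weighted_length(self):
        mask = np.zeros((5, 115), bool)
        mask[2, 2:113] = True  # 111 px
        assert skeleton_extension(obj_from_mask(mask), 0.1) == pytest.approx(11.0)

    def test_y_shape_sums_two_longest_branches(self):
        # branches of 30, 40, 50 axial px from one junction -> E = 9.0 um
        mask = np.zeros((60, 80), bool)
        j = (55, 35)
        mask[j[0], j[1] - 30:j[1] + 1] = True      # west, 30 px
        mask[j[0], j[1]:j[1] + 41] = True          # east, 40 px
        mask[j[0] - 50:j[0] + 1, j[1]] = True      # north, 50 px
        assert skeleton_extension(obj_from_mask(mask), 0.1) == pytest.approx(9.0, abs=0.2)

    def test_ring_fallback_half_circumference(self):
        mask = np.zeros((12, 20), bool)
        mask[2, 2:18] = True
        mask[9, 2:18] = True
        mask[2:10, 2] = True
        mask[2:10, 17] = True  # rectangular ring, no endpoints
        obj = obj_from_mask(mask)
        got = skeleton_extension(obj, 0.1)
        skel = skeletonize_object(obj)
        want = all_pairs_extension_oracle(skel, 0.1)
        assert got == pytest.approx(want, abs=1e-9)
        cable = total_skeleton_length(obj, 0.1)
        assert got == pytest.approx(cable / 2, rel=0.2)

    def test_single_pixel_extension_zero(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        assert skeleton_extension(obj_from_mask(mask), 0.1) == 0.0

    def test_matches_all_pairs_oracle_on_random_trees(self, rng):
        for _ in range(50):
            mask = random_lattice_tree(rng, int(rng.integers(6, 60)))
            obj = obj_from_mask(mask)
            got = skeleton_extension(obj, 0.1)
            want = all_pairs_extension_oracle(skeletonize_object(obj), 0.1)
            assert got == pytest.approx(want, abs=1e-12)

    def test_extension_bounded_by_cable_length(self, rng):
        for _ in range(10):
            coords = random_polyomino(rng, 40)
            obj = obj_from_mask_coords(coords)
            assert skeleton_extension(obj, 0.1) <= total_skeleton_length(obj, 0.1) + 1e-9

    def test_staircase_path_exact_weighted_length(self):
        # alternating axial/diagonal steps; skeleton is the path itself
        pts = [(2, 2)]
        for i in range(10):
            r, c = pts[-1]
            pts.append((r, c + 1) if i % 2 == 0 else (r + 1, c + 1))
        mask = np.zeros((20, 20), bool)
        for r, c in pts:
            mask[r, c] = True
        expected = (5 * 1.0 + 5 * SQRT2) * 0.1
        assert skeleton_extension(obj_from_mask(mask), 0.1) == pytest.approx(expected)


class TestGeometricInvariances:
    def test_quarter_turn_leaves_blob_features_unchanged(self, rng):
        coords = random_polyomino(rng, 35)
        mask = np.zeros(tuple(coords.max(axis=0) + 1), bool)
        mask[coords[:, 0], coords[:, 1]] = True
        f0 = measure_object(obj_from_mask(mask), 0.1)
        f1 = measure_object(obj_from_mask(np.rot90(mask)), 0.1)
        assert f1.A == f0.A
        assert f1.S == pytest.approx(f0.S, abs=1e-9)
        assert f1.C == pytest.approx(f0.C, abs=1e-9)
        assert f1.AR == pytest.approx(f0.AR, rel=1e-6)
        assert f1.MLE == pytest.approx(f0.MLE, rel=1e-6)

    def test_quarter_turn_leaves_tube_extension_unchanged(self):
        # path-like fixture: thinning of a rotated capsule may differ by a
        # pixel or two at the caps, never more
        from mitoshape.synthgen import render_tube_mask
        mask = render_tube_mask(8.0, 0.5, 0.1)
        f0 = measure_object(obj_from_mask(mask), 0.1)
        f1 = measure_object(obj_from_mask(np.rot90(mask)), 0.1)
        assert f1.E == pytest.approx(f0.E, abs=0.3)
        assert f1.MLE == pytest.approx(f0.MLE, rel=1e-6)

    def test_mle_never_exceeds_max_feret_for_disc(self):
        f = measure_object(obj_from_mask(disc_mask(8.5)), 0.1)
        assert f.MLE <= 2 * 8.5 * 0.1 * 1.2


class TestObjectFeaturesInvariants:
    def test_r_eq_consistency_enforced(self):
        with pytest.raises(ValueError):
            ObjectFeatures(A=1.0, P=4.0, AR=1.0, C=0.9, S=1.0, r_eq=0.1)

    @pytest.mark.parametrize("kwargs", [
        dict(A=-1.0), dict(AR=0.5), dict(S=1.5), dict(C=0.0), dict(MLE=-2.0),
    ])
    def test_invalid_fields_rejected(self, kwargs):
        base = dict(A=1.0, P=4.0, AR=1.0, C=0.9, S=1.0,
                    r_eq=math.sqrt(1.0 / math.pi))
        base.update(kwargs)
        if "A" in kwargs:
            base["r_eq"] = 1.0
        with pytest.raises(ValueError):
            ObjectFeatures(**base)
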