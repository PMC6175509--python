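"""Contour rasterization, FWHM classification, depth field, wall layers."""

import numpy as np
import pytest
import trimesh

from scarmesh.contours import ContourSet
from scarmesh.mesh import TriMesh
from scarmesh.segmentation import (
    MID,
    OUTSIDE,
    SUBENDO,
    SUBEPI,
    fwhm_scar_mask,
    layer_labels,
    myocardium_mask_from_contours,
    transmural_depth_field,
)
from scarmesh.volume import BinaryMask, LGEVolume


def square(lo, hi):
    return np.array([[lo, lo], [hi, lo], [hi, hi], [lo, hi]], dtype=float)


class TestMyocardiumMask:
    def test_square_annulus_voxel_count(self):
        """10x10 epi minus 4x4 endo on a half-integer grid: 84 voxels."""
        affine = np.diag([1.0, 1.0, 1.0, 1.0])
        affine[:3, 3] = (0.5, 0.5, 0.0)  # centers at half-integers
        grid = LGEVolume(np.zeros((10, 10, 1)), (1.0, 1.0, 1.0), affine)
        cs = ContourSet()
        cs.add("lv_epi", 0, square(0.0, 10.0))
        cs.add("lv_endo", 0, square(3.0, 7.0))
        mask = myocardium_mask_from_contours(cs, grid)
        assert mask.count == 100 - 16

        # brute-force point-in-polygon oracle over all centers
        def inside(px, py, poly):
            n, c = len(poly), False
            for i in range(n):
                x1, y1 = poly[i]
                x2, y2 = poly[(i + 1) % n]
                if (y1 > py) != (y2 > py):
                    if px < (x2 - x1) * (py - y1) / (y2 - y1) + x1:
                        c = not c
            return c

        expected = np.zeros((10, 10), dtype=bool)
        for i in range(10):
            for j in range(10):
                px, py = i + 0.5, j + 0.5
                expected[i, j] = inside(px, py, square(0, 10)) and not inside(
                    px, py, square(3, 7)
                )
        np.testing.assert_array_equal(mask.data[:, :, 0], expected)

    def test_endo_equals_epi_gives_empty(self):
        grid = LGEVolume(np.zeros((10, 10, 1)), (1.0, 1.0, 1.0))
        cs = ContourSet()
        cs.add("lv_epi", 0, square(0.0, 9.0))
        cs.add("lv_endo", 0, square(0.0, 9.0))
        assert myocardium_mask_from_contours(cs, grid).count == 0

    def test_endo_outside_epi_warns(self):
        grid = LGEVolume(np.zeros((10, 10, 1)), (1.0, 1.0, 1.0))
        cs = ContourSet()
        cs.add("lv_epi", 0, square(0.0, 5.0))
        cs.add("lv_endo", 0, square(3.0, 8.0))
        with pytest.warns(UserWarning, match="not contained"):
            myocardium_mask_from_contours(cs, grid)

    def test_phantom_contours_recover_truth_mask(self, default_phantom):
        mask = myocardium_mask_from_contours(
            default_phantom.contours, default_phantom.volume
        )
        truth = default_phantom.myocardium_mask.data
        dice = 2 * np.sum(mask.data & truth) / (mask.data.sum() + truth.sum())
        assert dice > 0.95


class TestFWHM:
    def make(self, values):
        vol = LGEVolume(np.asarray(values, float).reshape(-1, 1, 1), (1, 1, 1))
        myo = BinaryMask(np.ones(vol.shape, dtype=bool), vol)
        return vol, myo

    def test_half_maximum_threshold(self):
        vol, myo = self.make([10, 10, 10, 10, 100])
        seg = fwhm_scar_mask(vol, myo)
        assert seg.reference_max == 100.0
        assert seg.threshold == 50.0
        assert seg.scar_mask.count == 1

    def test_uniform_intensities_all_scar_with_warning(self):
        vol, myo = self.make([5, 5, 5])
        with pytest.warns(UserWarning, match="degenerate"):
            seg = fwhm_scar_mask(vol, myo)
        assert seg.threshold == 2.5
        assert seg.scar_mask.count == 3

    def test_empty_myocardium_rejected(self):
        vol, myo = self.make([1, 2, 3])
        empty = BinaryMask(np.zeros(vol.shape, dtype=bool), vol)
        with pytest.raises(ValueError, match="empty"):
            fwhm_scar_mask(vol, empty)

    def test_matches_per_voxel_brute_force(self):
        """Vectorized mask equals an explicit per-voxel loop."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            shape = tuple(rng.integers(3, 9, 3))
            vol = LGEVolume(rng.random(shape) * 100, (1, 1, 1))
            myo = BinaryMask(rng.random(shape) < 0.6, vol)
            if myo.count == 0:
                continue
            seg = fwhm_scar_mask(vol, myo)
            ref = vol.data[myo.data].max()
            expected = np.zeros(shape, dtype=bool)
            for idx in np.ndindex(shape):
                expected[idx] = myo.data[idx] and vol.data[idx] > 0.5 * ref
            np.testing.assert_array_equal(seg.scar_mask.data, expected)

    def test_invariant_under_positive_rescaling(self):
        rng = np.random.default_rng(0)
        vol = LGEVolume(rng.random((6, 6, 6)) * 50, (1, 1, 1))
        myo = BinaryMask(rng.random((6, 6, 6)) < 0.5, vol)
        seg1 = fwhm_scar_mask(vol, myo)
        scaled = LGEVolume(vol.data * 3.7, (1, 1, 1))
        seg2 = fwhm_scar_mask(scaled, BinaryMask(myo.data, scaled))
        np.testing.assert_array_equal(seg1.scar_mask.data, seg2.scar_mask.data)
        assert seg2.threshold == pytest.approx(3.7 * seg1.threshold)

    def test_reference_region_overrides_myocardium(self):
        vol, myo = self.make([10, 10, 10, 10, 100])
        region = np.zeros(vol.shape, dtype=bool)
        region[0] = True  # reference restricted to a 10-intensity voxel
        seg = fwhm_scar_mask(vol, myo, reference_region=BinaryMask(region, vol))
        assert seg.threshold == 5.0
        assert seg.scar_mask.count == 5


class TestTransmuralDepth:
    def test_concentric_spheres_match_analytic(self, concentric_sphere_setup):
        s = concentric_sphere_setup
        depth = s["depth"]
        analytic = (s["radius"] - 20.0) / 10.0
        err = depth[s["myocardium"].data] - analytic.reshape(depth.shape)[
            s["myocardium"].data
        ]
        assert np.sqrt(np.mean(err**2)) < 0.02

    def test_monotone_along_ray(self, concentric_sphere_setup):
        s = concentric_sphere_setup
        depth = s["depth"]
        n = depth.shape[0]
        mid = (n - 1) // 2
        row = depth[:, mid, mid]
        vals = row[np.isfinite(row)]
        half = vals[len(vals) // 2:]  # outward leg of the +x ray
        assert np.all(np.diff(half) > -1e-6)

    def test_boundary_voxels_get_exact_depth(self):
        """Centers exactly on a surface get depth 0 (endo) or 1 (epi)."""
        endo = trimesh.creation.box(extents=(4.0, 4.0, 4.0))
        epi = trimesh.creation.box(extents=(12.0, 12.0, 12.0))
        endo_mesh = TriMesh(np.asarray(endo.vertices), np.asarray(endo.faces))
        epi_mesh = TriMesh(np.asarray(epi.vertices), np.asarray(epi.faces))
        n = 15
        affine = np.diag([1.0, 1.0, 1.0, 1.0])
        affine[:3, 3] = -(n - 1) / 2.0
        grid = LGEVolume(np.zeros((n, n, n)), (1.0, 1.0, 1.0), affine)
        mask = np.zeros((n, n, n), dtype=bool)
        on_endo = tuple(np.round(grid.world_to_index(np.array([2.0, 0.0, 0.0]))).astype(int))
        on_epi = tuple(np.round(grid.world_to_index(np.array([6.0, 0.0, 0.0]))).astype(int))
        mask[on_endo] = mask[on_epi] = True
        depth = transmural_depth_field(BinaryMask(mask, grid), endo_mesh, epi_mesh)
        assert depth[on_endo] == 0.0
        assert depth[on_epi] == 1.0


class TestLayerLabels:
    @pytest.mark.parametrize(
        "depth,expected",
        [(0.0, SUBENDO), (0.2, SUBENDO), (1 / 3, MID), (0.5, MID),
         (2 / 3, SUBEPI), (0.9, SUBEPI), (1.0, SUBEPI)],
    )
    def test_interval_membership(self, depth, expected):
        field = layer_labels(np.array([[[depth]]]))
        assert field.labels[0, 0, 0] == expected

    def test_nan_is_outside(self):
        field = layer_labels(np.array([[[np.nan]]]))
        assert field.labels[0, 0, 0] == OUTSIDE

    def test_layers_partition_myocardium(self, concentric_sphere_setup):
        s = concentric_sphere_setup
        field = layer_labels(s["depth"])
        labeled = field.labels != OUTSIDE
        np.testing.assert_array_equal(labeled, s["myocardium"].data)
        total = sum(field.mask(c).sum() for c in (SUBENDO, MID, SUBEPI))
        assert total == s["myocardium"].count

    def test_label_counts_match_analytic_shell_volumes(self, concentric_sphere_setup):
        s = concentric_sphere_setup
        field = layer_labels(s["depth"])
        a, b = 20.0, 30.0
        bounds = [a, a + (b - a) / 3, a + 2 * (b - a) / 3, b]
        n_myo = s["myocardium"].count
        for code, (r1, r2) in zip((SUBENDO, MID, SUBEPI), zip(bounds, bounds[1:])):
            analytic = (r2**3 - r1**3) / (b**3 - a**3)
            assert field.mask(code).sum() / n_myo == pytest.approx(analytic, abs=0.03)
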