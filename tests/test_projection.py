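"""Surface projection of subendocardial scar and texture baking."""

import numpy as np
import pytest

from scarmesh.projection import (
    bake_texture,
    disk_parametrize,
    project_scar,
    sample_texture,
    vertex_colors_from_map,
)
from scarmesh.segmentation import SUBENDO, layer_labels
from scarmesh.surface import clip_at_base
from scarmesh.volume import BinaryMask


@pytest.fixture(scope="module")
def sphere_projection_setup(concentric_sphere_setup):
    """Concentric-sphere shell with a 60-degree subendocardial blob."""
    s = concentric_sphere_setup
    layers = layer_labels(s["depth"])
    azim = np.degrees(np.arctan2(s["centers"][:, 1], s["centers"][:, 0]))
    r = s["radius"]
    shape = s["grid"].shape
    in_sector = (np.abs(azim) <= 30.0).reshape(shape)
    subendo_band = ((r >= 20.0) & (r <= 25.0)).reshape(shape)
    mid_epi_band = ((r > 25.0) & (r <= 30.0)).reshape(shape)
    myo = s["myocardium"].data
    return {
        **s,
        "layers": layers,
        "scar_subendo": BinaryMask(in_sector & subendo_band & myo, s["grid"]),
        "scar_deep": BinaryMask(in_sector & mid_epi_band & myo, s["grid"]),
        "scar_empty": BinaryMask(np.zeros(shape, dtype=bool), s["grid"]),
    }


class TestProjectScar:
    def test_empty_scar_gives_all_negative(self, sphere_projection_setup):
        s = sphere_projection_setup
        m = project_scar(s["endo"], s["scar_empty"], s["layers"])
        assert not m.vertex_scar.any()
        assert m.scar_area_fraction == 0.0

    def test_full_shell_scar_saturates(self, sphere_projection_setup):
        s = sphere_projection_setup
        full = BinaryMask(s["myocardium"].data, s["grid"])
        m = project_scar(s["endo"], full, s["layers"])
        assert m.vertex_scar.all()
        assert m.scar_area_fraction == pytest.approx(1.0)

    def test_sector_blob_area_matches_analytic(self, sphere_projection_setup):
        """60-degree azimuthal blob covers 1/6 of the endocardial sphere."""
        s = sphere_projection_setup
        graded = project_scar(s["endo"], s["scar_subendo"], s["layers"],
                              mode="graded")
        assert graded.scar_area_fraction == pytest.approx(60 / 360, abs=0.03)

    def test_deep_scar_never_reaches_surface(self, sphere_projection_setup):
        s = sphere_projection_setup
        m = project_scar(s["endo"], s["scar_deep"], s["layers"])
        assert m.scar_area_fraction == 0.0

    def test_layer_filter_is_exact(self, sphere_projection_setup):
        """Deleting all scar with depth >= 1/3 leaves the map bit-identical."""
        s = sphere_projection_setup
        both = BinaryMask(s["scar_subendo"].data | s["scar_deep"].data, s["grid"])
        with_deep = project_scar(s["endo"], both, s["layers"])
        filtered = BinaryMask(
            both.data & s["layers"].mask(SUBENDO), s["grid"]
        )
        without_deep = project_scar(s["endo"], filtered, s["layers"])
        np.testing.assert_array_equal(with_deep.vertex_scar,
                                      without_deep.vertex_scar)

    def test_monotone_in_blob_size(self, sphere_projection_setup):
        s = sphere_projection_setup
        azim = np.degrees(np.arctan2(s["centers"][:, 1], s["centers"][:, 0]))
        shape = s["grid"].shape
        r = s["radius"]
        band = ((r >= 20.0) & (r <= 25.0)).reshape(shape) & s["myocardium"].data
        prev = -1.0
        for half_width in (10.0, 30.0, 60.0):
            blob = BinaryMask(
                (np.abs(azim) <= half_width).reshape(shape) & band, s["grid"]
            )
            frac = project_scar(s["endo"], blob, s["layers"]).scar_area_fraction
            assert frac >= prev
            prev = frac

    def test_graded_threshold_matches_binary_away_from_boundary(
        self, sphere_projection_setup
    ):
        """Thresholded graded map equals binary except at the blob rim."""
        s = sphere_projection_setup
        binary = project_scar(s["endo"], s["scar_subendo"], s["layers"],
                              mode="binary")
        graded = project_scar(s["endo"], s["scar_subendo"], s["layers"],
                              mode="graded")
        azim = np.degrees(np.arctan2(s["endo"].vertices[:, 1],
                                     s["endo"].vertices[:, 0]))
        # the azimuthal blob boundary passes through the poles, so the
        # polar caps are boundary territory too — keep clear of them
        equatorial = np.abs(s["endo"].vertices[:, 2]) < 17.0
        interior = (np.abs(azim) < 20.0) & equatorial
        exterior = (np.abs(azim) > 45.0) & equatorial
        thresholded = graded.vertex_scar >= 0.5
        np.testing.assert_array_equal(thresholded[interior],
                                      binary.vertex_scar[interior])
        np.testing.assert_array_equal(thresholded[exterior],
                                      binary.vertex_scar[exterior])

    def test_invalid_radius_rejected(self, sphere_projection_setup):
        s = sphere_projection_setup
        with pytest.raises(ValueError, match="radius"):
            project_scar(s["endo"], s["scar_subendo"], s["layers"], radius=0.0)


class TestVertexColors:
    def test_all_negative_gives_uniform_remote(self, sphere_projection_setup):
        s = sphere_projection_setup
        m = project_scar(s["endo"], s["scar_empty"], s["layers"])
        colored = vertex_colors_from_map(m)
        assert len(np.unique(colored.vertex_colors, axis=0)) == 1

    def test_binary_map_has_two_colors(self, sphere_projection_setup):
        s = sphere_projection_setup
        m = project_scar(s["endo"], s["scar_subendo"], s["layers"])
        colored = vertex_colors_from_map(m)
        assert len(np.unique(colored.vertex_colors, axis=0)) == 2

    def test_graded_half_is_midpoint_color(self, sphere_projection_setup):
        from scarmesh.projection import SurfaceScarMap

        s = sphere_projection_setup
        vals = np.full(s["endo"].n_vertices, 0.5)
        m = SurfaceScarMap(s["endo"], vals, 0.0, mode="graded")
        colored = vertex_colors_from_map(
            m, scar_color=(1.0, 0.0, 0.0), remote_color=(0.0, 0.0, 0.0)
        )
        assert np.all(colored.vertex_colors[:, 0] == 128)


class TestTextureBaking:
    @pytest.fixture(scope="class")
    def clipped_setup(self, sphere_projection_setup):
        s = sphere_projection_setup
        cap = clip_at_base(s["endo"], (0.0, 0.0, 10.0))
        m = project_scar(cap, s["scar_subendo"], s["layers"])
        return {"cap": cap, "map": m}

    def test_uv_in_unit_square_no_flips(self, clipped_setup):
        cap = clipped_setup["cap"]
        uv = disk_parametrize(cap)
        assert uv.min() >= 0.0 and uv.max() <= 1.0
        tri = uv[cap.faces]
        e1, e2 = tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
        signed = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
        assert np.all(signed > 0)

    def test_uniform_map_gives_uniform_texture(self, clipped_setup):
        from scarmesh.projection import SurfaceScarMap

        cap = clipped_setup["cap"]
        m = SurfaceScarMap(cap, np.zeros(cap.n_vertices, dtype=bool), 0.0)
        tex, _ = bake_texture(m, resolution=128)
        assert len(np.unique(tex.reshape(-1, 4), axis=0)) == 1

    def test_sampling_reproduces_vertex_colors(self, clipped_setup):
        """Bilinear lookup at vertex UVs matches vertex colors.

        Vertices adjacent to the binary scar/remote color discontinuity
        are excluded: there the texel average legitimately mixes the two
        colors (interpolation tolerance of the round-trip).
        """
        m = clipped_setup["map"]
        tex, uv = bake_texture(m, resolution=1024)
        cols = vertex_colors_from_map(m).vertex_colors
        sampled = sample_texture(tex, uv)
        err = np.abs(sampled[:, :3] - cols[:, :3].astype(float)).max(axis=1)
        mesh = m.mesh
        flags = m.vertex_scar.astype(bool)
        mixed_edge = flags[mesh.faces].any(axis=1) & ~flags[mesh.faces].all(axis=1)
        near_boundary = np.zeros(mesh.n_vertices, dtype=bool)
        near_boundary[np.unique(mesh.faces[mixed_edge])] = True
        assert np.all(err[~near_boundary] <= 1.0 + 4.0)
        # and even at the discontinuity the majority are faithful
        assert np.mean(err <= 5.0) > 0.95

    def test_closed_mesh_rejected(self, sphere_projection_setup):
        s = sphere_projection_setup
        with pytest.raises(ValueError, match="closed"):
            disk_parametrize(s["endo"])
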