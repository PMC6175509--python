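"""Myocardium and scar segmentation.

Builds the myocardial mask from endo/epicardial contours, classifies
scar voxels by the full-width-at-half-maximum (FWHM) criterion — signal
intensity strictly greater than half of a reference maximum — computes
the transmural depth field (0 at the endocardium, 1 at the epicardium)
and partitions the wall into subendocardial, mid and subepicardial
thirds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from .contours import ContourSet
from .mesh import TriMesh
from .volume import BinaryMask, LGEVolume

# layer label codes
OUTSIDE, SUBENDO, MID, SUBEPI = 0, 1, 2, 3
LAYER_NAMES = {OUTSIDE: "outside", SUBENDO: "subendo", MID: "mid", SUBEPI: "subepi"}


@dataclass
class ScarSegmentation:
    """FWHM scar classification result.

    ``threshold`` is always half of ``reference_max``; ``transmural_depth``
    is filled in by :func:`transmural_depth_field` (NaN outside the
    myocardium) once the surfaces are available.
    """

    myocardium_mask: BinaryMask
    scar_mask: BinaryMask
    threshold: float
    reference_max: float
    transmural_depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.scar_mask.data & ~self.myocardium_mask.data):
            raise ValueError("scar mask must be a subset of the myocardium mask")


@dataclass
class LayerLabelField:
    """Per-voxel wall-layer labels (subendo / mid / subepi / outside)."""

    labels: np.ndarray

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code


# ---------------------------------------------------------------------------
# contour rasterization
# ---------------------------------------------------------------------------

def myocardium_mask_from_contours(
    contours: ContourSet,
    grid: LGEVolume,
    include_rv: bool = False,
) -> BinaryMask:
    """Rasterize contours to the myocardial mask.

    A voxel belongs to the mask iff its center lies inside the epicardial
    polygon of its slice and outside the endocardial polygon (points
    exactly on a polygon edge count as inside). Slices carrying only an
    epicardial contour (e.g. the apical cap) are filled entirely.
    """
    pairs = [("lv_endo", "lv_epi")] + ([("rv_endo", "rv_epi")] if include_rv else [])
    nx, ny, nz = grid.shape
    # in-plane world coordinates of voxel centers (axis-aligned affine)
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    mask = np.zeros(grid.shape, dtype=bool)
    for endo_label, epi_label in pairs:
        for k in contours.slices(epi_label):
            idx = np.stack(
                [ii.ravel(), jj.ravel(), np.full(ii.size, float(k))], axis=1
            )
            world = grid.index_to_world(idx)
            x, y = world[:, 0], world[:, 1]
            epi = contours.get(epi_label, k)
            endo = contours.get(endo_label, k)
            inside = _points_in_polygon(epi.points, x, y)
            if endo is not None:
                if not Polygon(epi.points).buffer(1e-9).covers(Polygon(endo.points)):
                    warnings.warn(
                        f"endo contour not contained in epi contour on slice {k}; "
                        "set difference still applied",
                        stacklevel=2,
                    )
                inside &= ~_points_in_polygon(endo.points, x, y)
            mask[:, :, k] |= inside.reshape(nx, ny)
    return BinaryMask(mask, grid)


def _points_in_polygon(polygon: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized point-in-polygon; boundary points count as inside."""
    poly = Polygon(np.asarray(polygon, dtype=float))
    shapely.prepare(poly)
    return shapely.intersects_xy(poly, x, y)


# ---------------------------------------------------------------------------
# FWHM scar classification
# ---------------------------------------------------------------------------

def fwhm_scar_mask(
    volume: LGEVolume,
    myocardium: BinaryMask,
    reference_region: BinaryMask | None = None,
    reference_percentile: float = 100.0,
) -> ScarSegmentation:
    """Classify scar as myocardial voxels above half the reference maximum.

    The reference maximum defaults to the plain maximum intensity over
    the myocardium; a user-supplied hyperenhanced ``reference_region``
    and a robust ``reference_percentile`` (default 100 = maximum) are
    optional. The comparison is strict (``intensity > threshold``), and
    the result is invariant under positive rescaling of the intensities.
    """
    if myocardium.count == 0:
        raise ValueError("myocardium mask is empty; cannot apply FWHM criterion")
    region = reference_region.data if reference_region is not None else myocardium.data
    if not np.any(region):
        raise ValueError("reference region is empty")
    ref_values = volume.data[region]
    reference_max = (
        float(ref_values.max())
        if reference_percentile >= 100.0
        else float(np.percentile(ref_values, reference_percentile))
    )
    threshold = 0.5 * reference_max
    scar = myocardium.data & (volume.data > threshold)
    if scar.sum() == myocardium.count:
        warnings.warn(
            "all myocardial voxels exceed the FWHM threshold "
            "(degenerate contrast); returning all-scar mask",
            stacklevel=2,
        )
    return ScarSegmentation(
        myocardium_mask=myocardium,
        scar_mask=BinaryMask(scar, volume),
        threshold=threshold,
        reference_max=reference_max,
    )


# ---------------------------------------------------------------------------
# transmural depth and wall layers
# ---------------------------------------------------------------------------

def _surface_sample_tree(mesh: TriMesh, target_edge: float) -> cKDTree:
    """KD-tree over a densified vertex sampling of a surface mesh.

    Midpoint subdivision until the longest edge is below ``target_edge``
    bounds the error of point-to-vertex distances as a stand-in for
    point-to-surface distances.
    """
    import trimesh as _trimesh

    verts = np.asarray(mesh.vertices, float)
    faces = np.asarray(mesh.faces)
    for _ in range(4):
        edges = verts[faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)]
        max_edge = np.linalg.norm(edges[:, 0] - edges[:, 1], axis=1).max()
        if max_edge <= target_edge:
            break
        verts, faces = _trimesh.remesh.subdivide(verts, faces)
    return cKDTree(verts)


def transmural_depth_field(
    myocardium: BinaryMask,
    endo_surface: TriMesh,
    epi_surface: TriMesh,
    target_edge: float | None = None,
) -> np.ndarray:
    """Two-distance transmural depth for every myocardial voxel center.

    depth(p) = d_endo(p) / (d_endo(p) + d_epi(p)) with unsigned Euclidean
    distances to the endo- and epicardial surfaces; 0 on the endocardium,
    1 on the epicardium, NaN outside the myocardium. Voxels where both
    distances vanish (touching surfaces) get depth 0 with a warning.
    """
    grid = myocardium.grid
    if target_edge is None:
        target_edge = 0.5 * min(grid.spacing)
    centers = grid.voxel_centers(myocardium.data)
    depth = np.full(grid.shape, np.nan)
    if len(centers) == 0:
        return depth
    d_endo = _surface_sample_tree(endo_surface, target_edge).query(centers, workers=-1)[0]
    d_epi = _surface_sample_tree(epi_surface, target_edge).query(centers, workers=-1)[0]
    total = d_endo + d_epi
    zero = total == 0.0
    if np.any(zero):
        warnings.warn(
            "endo and epi surfaces touch at some voxel centers; depth set to 0",
            stacklevel=2,
        )
    vals = np.where(zero, 0.0, d_endo / np.where(zero, 1.0, total))
    depth[myocardium.data] = vals
    return depth


def layer_labels(depth: np.ndarray) -> LayerLabelField:
    """Partition the wall into thirds of transmural depth.

    subendo = [0, 1/3), mid = [1/3, 2/3), subepi = [2/3, 1]; the
    intervals are half-open (closed at depth 1) so every myocardial
    voxel gets exactly one label.
    """
    labels = np.full(depth.shape, OUTSIDE, dtype=np.int8)
    valid = np.isfinite(depth)
    d = np.where(valid, depth, -1.0)
    labels[valid & (d < 1.0 / 3.0)] = SUBENDO
    labels[valid & (d >= 1.0 / 3.0) & (d < 2.0 / 3.0)] = MID
    labels[valid & (d >= 2.0 / 3.0)] = SUBEPI
    return LayerLabelField(labels=labels)
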