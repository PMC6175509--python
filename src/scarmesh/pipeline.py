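"""End-to-end pipeline: volume + contours -> layered holographic scene.

Chains the full framework: rasterize contours to the myocardial mask,
classify scar by FWHM, reconstruct endo/epicardial Poisson surfaces,
compute the transmural depth field and wall layers, render the
voxel-wise scar cube mesh, project subendocardial scar onto the
endocardial surface, compute the scar-burden metrics, and assemble the
transparency-blended scene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .contours import ContourSet
from .mesh import TriMesh
from .projection import SurfaceScarMap, project_scar, vertex_colors_from_map
from .scene import LayeredScene, ScarMetrics, assemble_scene, compute_metrics
from .segmentation import (
    LayerLabelField,
    ScarSegmentation,
    fwhm_scar_mask,
    layer_labels,
    myocardium_mask_from_contours,
    transmural_depth_field,
)
from .surface import (
    clip_at_base,
    clustering_decimation,
    contours_to_pointcloud,
    estimate_normals,
    poisson_reconstruct,
)
from .volume import BinaryMask, LGEVolume
from .voxelmesh import VoxelCubeMesh, deduplicate, mesh_statistics, voxels_to_cubemesh

log = logging.getLogger("scarmesh")


@dataclass
class PipelineConfig:
    """Tunable knobs of the full pipeline (mm units throughout).

    ``decimation_cell`` defaults to twice the in-plane voxel spacing;
    ``projection_radius`` to twice the largest spacing. The graded
    projection mode drives the metrics; set ``projection_mode`` to
    ``"binary"`` for the strict any-voxel-in-radius rule.
    """

    decimation_cell: float | None = None
    poisson_depth: int = 7
    normal_neighbors: int = 10
    projection_radius: float | None = None
    projection_mode: str = "graded"
    clip_base: bool = True
    style: dict | None = None
    reference_percentile: float = 100.0


@dataclass
class PipelineResult:
    segmentation: ScarSegmentation
    layers: LayerLabelField
    endo_mesh: TriMesh
    epi_mesh: TriMesh
    scar_cubemesh: VoxelCubeMesh
    scar_map: SurfaceScarMap
    metrics: ScarMetrics
    scene: LayeredScene
    scar_mesh_statistics: dict = field(default_factory=dict)


def reconstruct_surface(
    contours: ContourSet,
    grid: LGEVolume,
    surface: str,
    config: PipelineConfig | None = None,
) -> TriMesh:
    """Contours of one surface -> decimated, oriented, Poisson-meshed."""
    config = config or PipelineConfig()
    cell = config.decimation_cell or 2.0 * max(grid.spacing[0], grid.spacing[1])
    points = contours_to_pointcloud(contours, grid, surface)
    decimated = clustering_decimation(points, cell)
    cloud = estimate_normals(decimated, k=config.normal_neighbors)
    mesh = poisson_reconstruct(cloud, depth=config.poisson_depth)
    log.info(
        "surface %s: %d contour points -> %d decimated -> mesh V=%d F=%d",
        surface, len(points), len(decimated), mesh.n_vertices, mesh.n_faces,
    )
    return mesh


def run_pipeline(
    volume: LGEVolume,
    contours: ContourSet,
    config: PipelineConfig | None = None,
    myocardium: BinaryMask | None = None,
    scar: BinaryMask | None = None,
) -> PipelineResult:
    """Run the full framework on a volume and its contours.

    Precomputed ``myocardium`` / ``scar`` masks short-circuit the
    corresponding stages (the FWHM threshold report is then omitted).
    """
    config = config or PipelineConfig()

    if myocardium is None:
        myocardium = myocardium_mask_from_contours(contours, volume)
    if scar is None:
        seg = fwhm_scar_mask(
            volume, myocardium, reference_percentile=config.reference_percentile
        )
    else:
        seg = ScarSegmentation(
            myocardium_mask=myocardium, scar_mask=scar,
            threshold=float("nan"), reference_max=float("nan"),
        )
    log.info(
        "segmentation: %d myocardial voxels, %d scar voxels (threshold %.3g)",
        seg.myocardium_mask.count, seg.scar_mask.count, seg.threshold,
    )

    endo_mesh = reconstruct_surface(contours, volume, "lv_endo", config)
    epi_mesh = reconstruct_surface(contours, volume, "lv_epi", config)

    seg.transmural_depth = transmural_depth_field(
        seg.myocardium_mask, endo_mesh, epi_mesh
    )
    wall_layers = layer_labels(seg.transmural_depth)

    cubes = deduplicate(voxels_to_cubemesh(seg.scar_mask))
    stats = mesh_statistics(cubes)
    log.info(
        "scar cube mesh: V=%d F=%d volume=%.1f mm^3 components=%d",
        stats.n_vertices, stats.n_faces,
        stats.enclosed_volume_mm3, stats.n_components,
    )

    scar_map = project_scar(
        endo_mesh, seg.scar_mask, wall_layers,
        radius=config.projection_radius, mode=config.projection_mode,
    )
    metrics = compute_metrics(seg, wall_layers, scar_map)
    log.info(
        "metrics: scar %.1f%% of LV, endocardial share %.1f%%, surface %.1f%%",
        metrics.scar_volume_fraction_of_lv,
        metrics.endocardial_scar_fraction_of_total,
        metrics.endocardial_surface_scar_area_fraction,
    )

    endo_scene, epi_scene = endo_mesh, epi_mesh
    if config.clip_base:
        z_base = _basal_plane_z(contours, volume)
        endo_scene = clip_at_base(endo_mesh, (0.0, 0.0, z_base))
        epi_scene = clip_at_base(epi_mesh, (0.0, 0.0, z_base))
    endo_colored = vertex_colors_from_map(
        SurfaceScarMap(
            mesh=endo_scene,
            vertex_scar=_transfer_map(scar_map, endo_scene),
            scar_area_fraction=scar_map.scar_area_fraction,
            mode=scar_map.mode,
        )
    )
    scene = assemble_scene(
        {"epicardium": epi_scene, "endocardium": endo_colored},
        scar_mesh=cubes.mesh,
        style=config.style,
    )

    return PipelineResult(
        segmentation=seg,
        layers=wall_layers,
        endo_mesh=endo_mesh,
        epi_mesh=epi_mesh,
        scar_cubemesh=cubes,
        scar_map=scar_map,
        metrics=metrics,
        scene=scene,
        scar_mesh_statistics=stats.as_dict(),
    )


def _basal_plane_z(contours: ContourSet, volume: LGEVolume) -> float:
    """World z of the most basal (largest-z) contoured slice."""
    ks = contours.slices()
    zs = [
        volume.index_to_world(np.array([[0.0, 0.0, float(k)]]))[0][2] for k in ks
    ]
    return max(zs)


def _transfer_map(scar_map: SurfaceScarMap, target: TriMesh) -> np.ndarray:
    """Carry per-vertex scar values onto a clipped copy of the mesh."""
    from scipy.spatial import cKDTree

    tree = cKDTree(scar_map.mesh.vertices)
    _, idx = tree.query(target.vertices, workers=-1)
    return np.asarray(scar_map.vertex_scar)[idx]
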