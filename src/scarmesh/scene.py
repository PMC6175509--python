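"""Layered scene assembly, open-format export, and scar-burden metrics.

The reconstructed surfaces and the voxel-wise scar mesh are combined
into an ordered list of named layers, each with its own color and
opacity, mirroring the transparency-blended holographic model (default
style: epicardium alpha 0.2, endocardium 0.4, scar opaque). Scenes
export to glTF 2.0/GLB (transparent layers flagged alphaMode BLEND) and
OBJ+MTL (opacity in the ``d`` statement). Units are mm, +z toward the
cardiac base.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh

from .mesh import Material, TriMesh
from .projection import SurfaceScarMap
from .segmentation import SUBENDO, LayerLabelField, ScarSegmentation

#: default layer styles: name -> (RGB color, alpha)
DEFAULT_STYLE: dict[str, tuple[tuple[float, float, float], float]] = {
    "epicardium": ((0.70, 0.70, 0.70), 0.2),
    "endocardium": ((0.55, 0.27, 0.20), 0.4),
    "scar": ((1.00, 0.90, 0.10), 1.0),
}

SCENE_FORMATS = ("glb", "gltf", "obj")


@dataclass
class LayeredScene:
    """Ordered, named mesh layers with blending attributes.

    Layers are ``(name, mesh, color, alpha)`` tuples; order is preserved
    for blending. Units are mm with +z toward the cardiac base.
    """

    layers: list[tuple[str, TriMesh, tuple[float, float, float], float]]
    units: str = "mm"
    up_axis: str = "+z"

    def __post_init__(self) -> None:
        names = [name for name, *_ in self.layers]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate layer names in scene: {names}")
        for name, _, _, alpha in self.layers:
            if not 0.0 <= alpha <= 1.0:
                raise ValueError(f"layer {name!r} alpha {alpha} outside [0, 1]")

    def layer(self, name: str) -> tuple[str, TriMesh, tuple[float, float, float], float]:
        for entry in self.layers:
            if entry[0] == name:
                return entry
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [name for name, *_ in self.layers]


@dataclass
class ScarMetrics:
    """The three scar-burden percentages of the holographic model.

    * ``scar_volume_fraction_of_lv``: scar volume as % of LV myocardium;
    * ``endocardial_scar_fraction_of_total``: subendocardial share of
      the total scar volume, %; NaN when there is no scar;
    * ``endocardial_surface_scar_area_fraction``: % of the endocardial
      surface area covered by projected scar.
    """

    scar_volume_fraction_of_lv: float
    endocardial_scar_fraction_of_total: float
    endocardial_surface_scar_area_fraction: float
    note: str = ""

    def as_dict(self) -> dict:
        return {
            "scar_volume_fraction_of_lv": self.scar_volume_fraction_of_lv,
            "endocardial_scar_fraction_of_total": self.endocardial_scar_fraction_of_total,
            "endocardial_surface_scar_area_fraction": self.endocardial_surface_scar_area_fraction,
            "note": self.note,
        }


def assemble_scene(
    surfaces: dict[str, TriMesh],
    scar_mesh: TriMesh | None = None,
    style: dict[str, tuple[tuple[float, float, float], float]] | None = None,
) -> LayeredScene:
    """Combine surface and scar meshes into a transparency-blended scene.

    ``surfaces`` maps layer names (e.g. ``"endocardium"``,
    ``"epicardium"``) to meshes; the scar mesh, when given, becomes the
    ``"scar"`` layer. Styles default to :data:`DEFAULT_STYLE` (unknown
    names get opaque gray) and can be overridden per layer.
    """
    merged_style = dict(DEFAULT_STYLE)
    if style:
        merged_style.update(style)
    layers = []
    entries = list(surfaces.items())
    if scar_mesh is not None:
        entries.append(("scar", scar_mesh))
    for name, mesh in entries:
        color, alpha = merged_style.get(name, ((0.7, 0.7, 0.7), 1.0))
        layers.append((name, mesh, tuple(color), float(alpha)))
    return LayeredScene(layers=layers)


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

def export_scene(scene: LayeredScene, path, fmt: str | None = None) -> None:
    """Write the scene to GLB/glTF or OBJ+MTL, preserving color and alpha."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in SCENE_FORMATS:
        raise ValueError(
            f"unsupported scene format {fmt!r}; supported: {', '.join(SCENE_FORMATS)}"
        )
    if fmt in ("glb", "gltf"):
        _export_gltf(scene, path, fmt)
    else:
        _export_obj_scene(scene, path)


def _export_gltf(scene: LayeredScene, path: Path, fmt: str) -> None:
    tscene = _trimesh.Scene()
    for name, mesh, color, alpha in scene.layers:
        tm = mesh.to_trimesh()
        rgba = np.round(np.array([*color, alpha]) * 255).astype(np.uint8)
        material = _trimesh.visual.material.PBRMaterial(
            name=name,
            baseColorFactor=rgba,
            alphaMode="BLEND" if alpha < 1.0 else "OPAQUE",
            doubleSided=True,
        )
        if mesh.vertex_colors is not None:
            tm.visual = _trimesh.visual.TextureVisuals(material=material)
            tm.visual.vertex_attributes["color"] = mesh.vertex_colors.copy()
        else:
            tm.visual = _trimesh.visual.TextureVisuals(material=material)
        tscene.add_geometry(tm, node_name=name, geom_name=name)
    tscene.export(str(path), file_type=fmt)


def _export_obj_scene(scene: LayeredScene, path: Path) -> None:
    mtl_path = path.with_suffix(".mtl")
    with open(mtl_path, "w") as fh:
        for name, _, color, alpha in scene.layers:
            fh.write(f"newmtl {name}\n")
            fh.write("Kd {:.8f} {:.8f} {:.8f}\n".format(*color))
            fh.write(f"d {alpha:.8f}\n")
    with open(path, "w") as fh:
        fh.write(f"mtllib {mtl_path.name}\n")
        offset = 1
        for name, mesh, _, _ in scene.layers:
            fh.write(f"o {name}\nusemtl {name}\n")
            for x, y, z in mesh.vertices:
                fh.write(f"v {x:.8f} {y:.8f} {z:.8f}\n")
            for a, b, c in mesh.faces + offset:
                fh.write(f"f {a} {b} {c}\n")
            offset += mesh.n_vertices


def import_scene(path) -> LayeredScene:
    """Re-read a scene written by :func:`export_scene`."""
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt in ("glb", "gltf"):
        return _import_gltf(path)
    if fmt == "obj":
        return _import_obj_scene(path)
    raise ValueError(f"unsupported scene format {fmt!r}")


def _import_gltf(path: Path) -> LayeredScene:
    tscene = _trimesh.load(str(path), process=False)
    layers = []
    for name, tm in tscene.geometry.items():
        color, alpha = (0.7, 0.7, 0.7), 1.0
        vertex_colors = None
        material = getattr(tm.visual, "material", None)
        if material is not None and getattr(material, "baseColorFactor", None) is not None:
            rgba = np.asarray(material.baseColorFactor, dtype=float)
            if rgba.max() > 1.0:
                rgba = rgba / 255.0
            color, alpha = tuple(rgba[:3]), float(rgba[3])
        attr = getattr(tm.visual, "vertex_attributes", None)
        if attr and "color" in attr:
            vertex_colors = np.asarray(attr["color"], dtype=np.uint8)
        elif isinstance(tm.visual, _trimesh.visual.ColorVisuals) and tm.visual.kind == "vertex":
            vertex_colors = np.asarray(tm.visual.vertex_colors, dtype=np.uint8)
        mesh = TriMesh(
            np.asarray(tm.vertices), np.asarray(tm.faces),
            vertex_colors=vertex_colors,
            material=Material(color=color, alpha=alpha, name=str(name)),
        )
        layers.append((str(name), mesh, color, alpha))
    return LayeredScene(layers=layers)


def _import_obj_scene(path: Path) -> LayeredScene:
    from .io import _read_mtl

    mats: dict[str, Material] = {}
    groups: list[tuple[str, str, list[list[int]]]] = []  # (group, mtl, faces)
    vertices: list[list[float]] = []
    with open(path) as fh:
        current_group, current_mtl = "layer", ""
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "mtllib":
                mats = _read_mtl(path.parent / tok[1])
            elif tok[0] == "o" or tok[0] == "g":
                current_group = tok[1]
            elif tok[0] == "usemtl":
                current_mtl = tok[1]
                groups.append((current_group, current_mtl, []))
            elif tok[0] == "v":
                vertices.append([float(v) for v in tok[1:4]])
            elif tok[0] == "f":
                if not groups:
                    groups.append((current_group, current_mtl, []))
                groups[-1][2].append([int(t.split("/")[0]) - 1 for t in tok[1:4]])
    all_vertices = np.asarray(vertices)
    layers = []
    for group, mtl, faces in groups:
        if not faces:
            continue
        farr = np.asarray(faces, dtype=np.int64)
        used = np.unique(farr)
        remap = np.full(len(all_vertices), -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        mat = mats.get(mtl, Material(name=mtl or group))
        mesh = TriMesh(all_vertices[used], remap[farr], material=mat)
        layers.append((group, mesh, mat.color, mat.alpha))
    return LayeredScene(layers=layers)


# ---------------------------------------------------------------------------
# scar-burden metrics
# ---------------------------------------------------------------------------

def compute_metrics(
    seg: ScarSegmentation,
    layers: LayerLabelField,
    scar_map: SurfaceScarMap,
) -> ScarMetrics:
    """The three scar-burden percentages of the model.

    scar volume / LV myocardial volume, subendocardial scar / total
    scar, and projected scar area / endocardial surface area, each in
    percent. With no scar the endocardial share is undefined (NaN, with
    a note) and the other two are 0.
    """
    n_myo = seg.myocardium_mask.count
    n_scar = seg.scar_mask.count
    if n_myo == 0:
        raise ValueError("empty myocardium; metrics undefined")
    vol_pct = 100.0 * n_scar / n_myo
    note = ""
    if n_scar == 0:
        endo_pct = math.nan
        note = "no scar voxels; endocardial scar fraction is undefined"
    else:
        n_subendo_scar = int(np.sum(seg.scar_mask.data & layers.mask(SUBENDO)))
        endo_pct = 100.0 * n_subendo_scar / n_scar
    surf_pct = 100.0 * scar_map.scar_area_fraction
    if note:
        warnings.warn(note, stacklevel=2)
    return ScarMetrics(
        scar_volume_fraction_of_lv=vol_pct,
        endocardial_scar_fraction_of_total=endo_pct,
        endocardial_surface_scar_area_fraction=surf_pct,
        note=note,
    )
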