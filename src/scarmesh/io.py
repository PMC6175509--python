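"""Reading and writing of volumes, contours, masks and meshes.

Formats
-------
Volumes and masks
    NIfTI (``.nii`` / ``.nii.gz``) via nibabel; voxel spacing comes from
    the header zooms and world coordinates from the affine.
Contours
    A JSON document ``{"contours": [{"surface", "slice", "points"}]}``
    with in-plane coordinates in mm, or a CSV with columns
    ``surface,slice,x,y`` (points of one polygon listed consecutively).
Meshes
    PLY (binary little-endian, per-vertex uchar RGBA), OBJ+MTL (with the
    ``d`` opacity statement) and glTF 2.0 / GLB (``alphaMode`` BLEND for
    transparent layers).
"""

from __future__ import annotations

import csv
import json
import os
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh as _trimesh

from .contours import Contour, ContourSet
from .mesh import Material, TriMesh
from .volume import BinaryMask, LGEVolume

MESH_FORMATS = ("ply", "obj", "glb", "gltf")


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def read_volume(path: str | os.PathLike) -> LGEVolume:
    """Read a medical volume (NIfTI) into an :class:`LGEVolume`.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValueError
        If the file is not a readable volume or the data are not 3D.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several error types
        raise ValueError(f"unreadable volume file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {data.ndim}D data in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LGEVolume(data=np.asarray(data, dtype=float), spacing=spacing,
                     affine=np.asarray(img.affine, dtype=float))


def write_volume(volume: LGEVolume, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_mask(path: str | os.PathLike, grid: LGEVolume | None = None) -> BinaryMask:
    vol = read_volume(path)
    ref = grid if grid is not None else vol
    return BinaryMask(vol.data > 0.5, ref)


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.grid.affine)
    img.header.set_zooms(mask.grid.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# contours
# ---------------------------------------------------------------------------

def write_contours(contours: ContourSet, path: str | os.PathLike) -> None:
    """Write a contour set as JSON (or CSV when path ends in .csv)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["surface", "slice", "x", "y"])
            for c in contours:
                for x, y in c.points:
                    writer.writerow([c.surface, c.slice_index, repr(float(x)), repr(float(y))])
        return
    doc = {
        "contours": [
            {
                "surface": c.surface,
                "slice": c.slice_index,
                "points": [[float(x), float(y)] for x, y in c.points],
            }
            for c in contours
        ]
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_contours(path: str | os.PathLike) -> ContourSet:
    """Read a contour set from the JSON or CSV schema.

    Raises
    ------
    ValueError
        On a missing/unknown surface label or a polygon with < 3 points.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.suffix.lower() == ".csv":
        return _read_contours_csv(path)
    with open(path) as fh:
        doc = json.load(fh)
    cs = ContourSet()
    for rec in doc.get("contours", []):
        if "surface" not in rec:
            raise ValueError("contour record is missing the 'surface' field")
        if "slice" not in rec or "points" not in rec:
            raise ValueError("contour record needs 'slice' and 'points' fields")
        cs.contours.append(
            Contour(rec["surface"], int(rec["slice"]), np.asarray(rec["points"]))
        )
    return cs


def _read_contours_csv(path: Path) -> ContourSet:
    groups: dict[tuple[str, int], list[list[float]]] = {}
    order: list[tuple[str, int]] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            key = (row["surface"], int(row["slice"]))
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append([float(row["x"]), float(row["y"])])
    cs = ContourSet()
    for surface, sl in order:
        cs.contours.append(Contour(surface, sl, np.asarray(groups[(surface, sl)])))
    return cs


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in MESH_FORMATS:
        raise ValueError(
            f"unsupported mesh format {fmt!r}; supported formats: {', '.join(MESH_FORMATS)}"
        )
    return fmt


def write_mesh(mesh: TriMesh, path: str | os.PathLike, fmt: str | None = None) -> None:
    """Write a mesh; vertex colors and material alpha survive re-reading.

    PLY carries per-vertex RGBA (material alpha is baked into vertex
    alpha when no explicit vertex colors exist); OBJ writes an MTL
    side-file with ``Kd`` and ``d``; GLB uses a PBR material with
    ``alphaMode`` BLEND for alpha < 1.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "ply":
        tm = mesh.to_trimesh()
        if mesh.vertex_colors is None and mesh.material is not None:
            rgba = np.tile(mesh.material.rgba_uint8, (mesh.n_vertices, 1))
            tm.visual = _trimesh.visual.ColorVisuals(tm, vertex_colors=rgba)
        tm.export(str(path), file_type="ply", encoding="binary")
    elif fmt == "obj":
        _write_obj(mesh, path)
    else:
        from .scene import LayeredScene, export_scene

        mat = mesh.material or Material()
        scene = LayeredScene(layers=[(mat.name, mesh, mat.color, mat.alpha)])
        export_scene(scene, path, fmt)


def read_mesh(path: str | os.PathLike, fmt: str | None = None) -> TriMesh:
    """Read a single mesh written by :func:`write_mesh`."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "ply":
        tm = _trimesh.load(str(path), file_type="ply", process=False)
        return TriMesh.from_trimesh(tm)
    if fmt == "obj":
        return _read_obj(path)
    from .scene import import_scene

    scene = import_scene(path)
    name, mesh, color, alpha = scene.layers[0]
    mesh.material = Material(color=color, alpha=alpha, name=name)
    return mesh


def _write_obj(mesh: TriMesh, path: Path) -> None:
    """OBJ with an MTL side-file; ``d`` carries the layer opacity."""
    mat = mesh.material or Material()
    mtl_path = path.with_suffix(".mtl")
    with open(mtl_path, "w") as fh:
        fh.write(f"newmtl {mat.name}\n")
        fh.write("Kd {:.8f} {:.8f} {:.8f}\n".format(*mat.color))
        fh.write(f"d {mat.alpha:.8f}\n")
    with open(path, "w") as fh:
        fh.write(f"mtllib {mtl_path.name}\n")
        fh.write(f"usemtl {mat.name}\n")
        if mesh.vertex_colors is not None:
            vc = mesh.vertex_colors[:, :3] / 255.0
            for (x, y, z), (r, g, b) in zip(mesh.vertices, vc):
                fh.write(f"v {x:.8f} {y:.8f} {z:.8f} {r:.6f} {g:.6f} {b:.6f}\n")
        else:
            for x, y, z in mesh.vertices:
                fh.write(f"v {x:.8f} {y:.8f} {z:.8f}\n")
        for a, b, c in mesh.faces + 1:
            fh.write(f"f {a} {b} {c}\n")


def _read_obj(path: Path) -> TriMesh:
    vertices: list[list[float]] = []
    colors: list[list[float]] = []
    faces: list[list[int]] = []
    mtllib: str | None = None
    usemtl: str | None = None
    with open(path) as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "v":
                vertices.append([float(v) for v in tok[1:4]])
                if len(tok) >= 7:
                    colors.append([float(v) for v in tok[4:7]])
            elif tok[0] == "f":
                faces.append([int(t.split("/")[0]) - 1 for t in tok[1:4]])
            elif tok[0] == "mtllib":
                mtllib = tok[1]
            elif tok[0] == "usemtl":
                usemtl = tok[1]
    material = None
    if mtllib is not None:
        mats = _read_mtl(path.parent / mtllib)
        if usemtl in mats:
            material = mats[usemtl]
        elif mats:
            material = next(iter(mats.values()))
    vertex_colors = None
    if colors and len(colors) == len(vertices):
        vc = np.round(np.asarray(colors) * 255).astype(np.uint8)
        vertex_colors = np.concatenate(
            [vc, np.full((len(vc), 1), 255, np.uint8)], axis=1
        )
    return TriMesh(np.asarray(vertices), np.asarray(faces, dtype=np.int64),
                   vertex_colors=vertex_colors, material=material)


def _read_mtl(path: Path) -> dict[str, Material]:
    mats: dict[str, Material] = {}
    if not path.exists():
        return mats
    name, kd, d = None, (0.8, 0.8, 0.8), 1.0
    with open(path) as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "newmtl":
                if name is not None:
                    mats[name] = Material(color=kd, alpha=d, name=name)
                name, kd, d = tok[1], (0.8, 0.8, 0.8), 1.0
            elif tok[0] == "Kd":
                kd = tuple(float(v) for v in tok[1:4])  # type: ignore[assignment]
            elif tok[0] == "d":
                d = float(tok[1])
            elif tok[0] == "Tr":  # 1 - d convention
                d = 1.0 - float(tok[1])
    if name is not None:
        mats[name] = Material(color=kd, alpha=d, name=name)
    return mats
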