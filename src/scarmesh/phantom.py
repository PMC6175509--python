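"""Synthetic LGE phantoms: ellipsoidal-shell left ventricle with scar blobs.

The phantom emulates a short-axis 3D LGE acquisition: an ellipsoidal
myocardial shell (optionally with a crescent-shaped right ventricle),
bright scar regions of configurable angular and transmural extent, and
additive Gaussian noise. Scar blobs live in normalized shell coordinates
(azimuthal sector x transmural depth band starting at the endocardium),
so their transmural extent is exact by construction, and ground-truth
masks, contours and scar-burden fractions come with every phantom.

Ground-truth fractions are evaluated from the continuous geometry by
high-resolution numerical integration (a supersampled grid for volumes,
a dense parametric surface grid for areas), not from the voxelized
masks, so they can serve as an independent oracle for the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .contours import ContourSet
from .volume import BinaryMask, LGEVolume

SUBENDO_DEPTH_LIMIT = 1.0 / 3.0  # subendocardial band: depth in [0, 1/3)


@dataclass
class ScarBlob:
    """One scar region in normalized shell coordinates.

    ``center_azimuth_deg`` / ``azimuth_extent_deg`` select an angular
    sector around the long (z) axis; ``transmural_extent`` is the depth
    band [0, extent] measured from the endocardium (1.0 = transmural);
    ``z_range`` restricts the blob to normalized long-axis positions
    z / c_epi within the given interval.
    """

    center_azimuth_deg: float = 0.0
    azimuth_extent_deg: float = 100.0
    transmural_extent: float = 0.6
    z_range: tuple[float, float] = (-0.55, 0.55)

    def __post_init__(self) -> None:
        if not 0.0 < self.transmural_extent <= 1.0 + 1e-12:
            if self.transmural_extent > 1.0:
                warnings.warn(
                    "scar blob transmural extent > 1 extends outside the "
                    "myocardium; clipped to 1.0",
                    stacklevel=2,
                )
                self.transmural_extent = 1.0
            else:
                raise ValueError("transmural_extent must be in (0, 1]")
        lo, hi = self.z_range
        if lo < -1.0 or hi > 1.0:
            warnings.warn(
                "scar blob z_range extends outside the ventricle; clipped",
                stacklevel=2,
            )
            self.z_range = (max(lo, -1.0), min(hi, 1.0))


@dataclass
class PhantomSpec:
    """Geometry, scar pattern and intensity model of a synthetic study.

    Defaults describe a mid-sized left ventricle at the 1 mm isotropic
    in-vivo imaging regime: endo semi-axes 20x20x38 mm, epi 28x28x46 mm
    (8 mm wall), remote myocardium mean 30, scar mean 100, noise SD 2
    (arbitrary units) and one anterior scar blob covering roughly a tenth
    of the wall volume.
    """

    lv_endo_radii: tuple[float, float, float] = (20.0, 20.0, 38.0)
    lv_epi_radii: tuple[float, float, float] = (28.0, 28.0, 46.0)
    n_slices: int | None = None
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    scar_blobs: list[ScarBlob] = field(default_factory=lambda: [ScarBlob()])
    mu_remote: float = 30.0
    mu_scar: float = 100.0
    sigma_noise: float = 2.0
    rv_enabled: bool = False
    rv_center: tuple[float, float, float] = (24.0, 0.0, -4.0)
    rv_endo_radii: tuple[float, float, float] = (26.0, 22.0, 34.0)
    rv_epi_radii: tuple[float, float, float] = (30.0, 26.0, 38.0)
    margin_mm: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        endo = np.asarray(self.lv_endo_radii, float)
        epi = np.asarray(self.lv_epi_radii, float)
        if not np.all(endo < epi):
            raise ValueError("lv_endo_radii must be < lv_epi_radii componentwise")
        if not self.mu_scar > self.mu_remote:
            raise ValueError("mu_scar must exceed mu_remote")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be >= 0")

    @property
    def background_intensity(self) -> float:
        """Blood pool / air intensity; fixed below remote myocardium."""
        return self.mu_remote / 2.0


@dataclass
class PhantomTruth:
    """A generated phantom together with its analytic ground truth."""

    volume: LGEVolume
    contours: ContourSet
    myocardium_mask: BinaryMask
    scar_mask: BinaryMask
    true_scar_volume_fraction: float
    true_endocardial_scar_fraction: float
    true_surface_scar_area_fraction: float
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# continuous geometry
# ---------------------------------------------------------------------------

def _ellipsoid_level(points: np.ndarray, radii, center=(0.0, 0.0, 0.0)) -> np.ndarray:
    """sqrt((x/a)^2 + (y/b)^2 + (z/c)^2); 1 on the surface, <1 inside."""
    p = (points - np.asarray(center)) / np.asarray(radii, float)
    return np.linalg.norm(p, axis=-1)


def _lv_myocardium_indicator(points: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    e_en = _ellipsoid_level(points, spec.lv_endo_radii)
    e_ep = _ellipsoid_level(points, spec.lv_epi_radii)
    return (e_en >= 1.0) & (e_ep <= 1.0)


def _ray_depth(points: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Normalized transmural position along rays from the LV center.

    0 on the endocardial ellipsoid, 1 on the epicardial one. Exact for
    the blob construction; the package's two-distance depth agrees with
    it exactly for concentric spheres and closely for moderate aspect.
    """
    e_en = _ellipsoid_level(points, spec.lv_endo_radii)
    e_ep = _ellipsoid_level(points, spec.lv_epi_radii)
    denom = e_en - e_ep
    with np.errstate(divide="ignore", invalid="ignore"):
        t = e_ep * (e_en - 1.0) / np.where(denom > 0, denom, np.nan)
    return t


def _angle_in_sector(azimuth_deg: np.ndarray, blob: ScarBlob) -> np.ndarray:
    d = (azimuth_deg - blob.center_azimuth_deg + 180.0) % 360.0 - 180.0
    return np.abs(d) <= blob.azimuth_extent_deg / 2.0


def _scar_indicator(points: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Continuous-geometry scar membership (inside the myocardium)."""
    myo = _lv_myocardium_indicator(points, spec)
    if not spec.scar_blobs:
        return np.zeros(len(points), dtype=bool)
    t = _ray_depth(points, spec)
    azim = np.degrees(np.arctan2(points[:, 1], points[:, 0]))
    z_norm = points[:, 2] / spec.lv_epi_radii[2]
    scar = np.zeros(len(points), dtype=bool)
    for blob in spec.scar_blobs:
        lo, hi = blob.z_range
        sel = (
            _angle_in_sector(azim, blob)
            & (t <= blob.transmural_extent)
            & (z_norm >= lo)
            & (z_norm <= hi)
        )
        scar |= sel
    return scar & myo


def _rv_indicator(points: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Crescent RV: the RV shell minus the LV epicardial interior."""
    e_en = _ellipsoid_level(points, spec.rv_endo_radii, spec.rv_center)
    e_ep = _ellipsoid_level(points, spec.rv_epi_radii, spec.rv_center)
    lv_ep = _ellipsoid_level(points, spec.lv_epi_radii)
    return (e_en >= 1.0) & (e_ep <= 1.0) & (lv_ep > 1.0)


# ---------------------------------------------------------------------------
# grid construction
# ---------------------------------------------------------------------------

def phantom_grid(spec: PhantomSpec) -> LGEVolume:
    """Empty volume whose grid covers the epicardium plus a margin.

    The affine is diagonal (axis-aligned, positive spacing) with the LV
    center at world (0, 0, 0); voxel centers straddle the origin.
    """
    half = np.asarray(spec.lv_epi_radii, float) + spec.margin_mm
    if spec.rv_enabled:
        rv_half = np.abs(np.asarray(spec.rv_center)) + np.asarray(
            spec.rv_epi_radii, float
        ) + spec.margin_mm
        half = np.maximum(half, rv_half)
    spacing = np.asarray(spec.spacing, float)
    dims = np.maximum(np.ceil(2 * half / spacing).astype(int), 1)
    affine = np.diag([*spacing, 1.0])
    affine[:3, 3] = -(dims - 1) / 2.0 * spacing
    return LGEVolume(np.zeros(tuple(dims)), tuple(spacing), affine)


# ---------------------------------------------------------------------------
# ground-truth fractions
# ---------------------------------------------------------------------------

def _sample_ellipsoid_surface(radii, n_theta: int = 400, n_phi: int = 800) -> np.ndarray:
    """Dense point sampling of an ellipsoid surface (for distance oracles)."""
    a, b, c = radii
    theta = np.linspace(0.0, np.pi, n_theta)
    phi = np.linspace(0.0, 2 * np.pi, n_phi, endpoint=False)
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    pts = np.stack(
        [a * np.sin(tt) * np.cos(pp), b * np.sin(tt) * np.sin(pp), c * np.cos(tt)], -1
    )
    return pts.reshape(-1, 3)


def true_fractions(
    spec: PhantomSpec, fine_spacing: float | None = None
) -> tuple[float, float, float]:
    """Ground-truth scar fractions by numerical integration.

    Returns ``(scar_volume_fraction, endocardial_scar_fraction,
    surface_scar_area_fraction)`` as unitless fractions in [0, 1].

    * scar volume fraction: |scar| / |LV myocardium| on a fine grid;
    * endocardial fraction: share of scar with two-distance transmural
      depth < 1/3 (depth evaluated against densely sampled continuous
      endo/epi surfaces);
    * surface fraction: share of the continuous endocardial surface area
      whose shell column is scarred (blobs start at the endocardium, so
      this is the blob footprint), by parametric surface integration.
    """
    if fine_spacing is None:
        fine_spacing = min(spec.spacing) / 2.0
    half = np.asarray(spec.lv_epi_radii, float) + 1.0
    axes = [np.arange(-h, h + fine_spacing / 2, fine_spacing) for h in half]
    n_myo = 0
    n_scar = 0
    scar_pts: list[np.ndarray] = []
    # chunk over z planes to bound memory
    xy = np.stack(np.meshgrid(axes[0], axes[1], indexing="ij"), -1).reshape(-1, 2)
    for z in axes[2]:
        pts = np.concatenate([xy, np.full((len(xy), 1), z)], axis=1)
        myo = _lv_myocardium_indicator(pts, spec)
        scar = _scar_indicator(pts, spec)
        n_myo += int(myo.sum())
        n_scar += int(scar.sum())
        if scar.any():
            scar_pts.append(pts[scar])
    vol_frac = n_scar / n_myo if n_myo else 0.0

    if n_scar:
        pts = np.concatenate(scar_pts)
        endo_tree = cKDTree(_sample_ellipsoid_surface(spec.lv_endo_radii))
        epi_tree = cKDTree(_sample_ellipsoid_surface(spec.lv_epi_radii))
        d_en = endo_tree.query(pts, workers=-1)[0]
        d_ep = epi_tree.query(pts, workers=-1)[0]
        depth = d_en / (d_en + d_ep)
        endo_frac = float(np.mean(depth < SUBENDO_DEPTH_LIMIT))
    else:
        endo_frac = 0.0

    surf_frac = _surface_scar_fraction(spec)
    return float(vol_frac), float(endo_frac), float(surf_frac)


def _surface_scar_fraction(spec: PhantomSpec, n_theta: int = 1024, n_phi: int = 2048):
    """Endocardial-surface area fraction covered by scar blobs."""
    if not spec.scar_blobs:
        return 0.0
    a, b, c = spec.lv_endo_radii
    theta = (np.arange(n_theta) + 0.5) * np.pi / n_theta
    phi = (np.arange(n_phi) + 0.5) * 2 * np.pi / n_phi
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    # |r_theta x r_phi| for the standard ellipsoid parametrization
    st, ct = np.sin(tt), np.cos(tt)
    sp, cp = np.sin(pp), np.cos(pp)
    ex = b * c * st * st * cp
    ey = a * c * st * st * sp
    ez = a * b * st * ct
    dA = np.sqrt(ex**2 + ey**2 + ez**2)
    azim = np.degrees(np.arctan2(b * st * sp, a * st * cp))
    z_norm = (c * ct) / spec.lv_epi_radii[2]
    covered = np.zeros_like(dA, dtype=bool)
    for blob in spec.scar_blobs:
        lo, hi = blob.z_range
        covered |= (
            _angle_in_sector(azim, blob) & (z_norm >= lo) & (z_norm <= hi)
        )
    return float(dA[covered].sum() / dA.sum())


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_phantom(
    spec: PhantomSpec,
    contour_points: int = 64,
    compute_truth: bool = True,
) -> PhantomTruth:
    """Generate the phantom volume, contours, masks and truth fractions.

    Deterministic for a fixed seed; the masks and contours depend only
    on the geometry (not the noise seed).
    """
    grid = phantom_grid(spec)
    centers = grid.voxel_centers().reshape(-1, 3)
    myo = _lv_myocardium_indicator(centers, spec)
    scar = _scar_indicator(centers, spec)
    shape = grid.shape
    myo_mask = myo.reshape(shape)
    scar_mask = scar.reshape(shape)

    intensity = np.full(shape, spec.background_intensity)
    intensity[myo_mask] = spec.mu_remote
    if spec.rv_enabled:
        rv = _rv_indicator(centers, spec).reshape(shape)
        intensity[rv] = spec.mu_remote
    intensity[scar_mask] = spec.mu_scar
    rng = np.random.default_rng(spec.seed)
    if spec.sigma_noise > 0:
        intensity = intensity + rng.normal(0.0, spec.sigma_noise, size=shape)

    volume = LGEVolume(intensity, grid.spacing, grid.affine)
    contours = contours_from_phantom(spec, volume, n_points=contour_points)

    if compute_truth:
        vol_frac, endo_frac, surf_frac = true_fractions(spec)
    else:
        vol_frac = endo_frac = surf_frac = float("nan")

    return PhantomTruth(
        volume=volume,
        contours=contours,
        myocardium_mask=BinaryMask(myo_mask, volume),
        scar_mask=BinaryMask(scar_mask, volume),
        true_scar_volume_fraction=vol_frac,
        true_endocardial_scar_fraction=endo_frac,
        true_surface_scar_area_fraction=surf_frac,
        spec=spec,
    )


def contours_from_phantom(
    spec: PhantomSpec, grid: LGEVolume, n_points: int = 64
) -> ContourSet:
    """Discretized elliptical cross-sections of the shell on each slice.

    Each slice plane that intersects an ellipsoid yields one ordered,
    counter-clockwise polygon of ``n_points`` points for that surface;
    slices beyond the ellipsoid extent emit nothing. When
    ``spec.n_slices`` is set, only the most central that-many slices are
    contoured (emulating a restricted manual-delineation stack).
    """
    if n_points < 32:
        raise ValueError("contours need n_points >= 32")
    cs = ContourSet()
    nz = grid.shape[2]
    z_of = lambda k: grid.index_to_world(np.array([[0.0, 0.0, float(k)]]))[0][2]
    surfaces = [("lv_endo", spec.lv_endo_radii, (0.0, 0.0, 0.0)),
                ("lv_epi", spec.lv_epi_radii, (0.0, 0.0, 0.0))]
    if spec.rv_enabled:
        surfaces += [("rv_endo", spec.rv_endo_radii, spec.rv_center),
                     ("rv_epi", spec.rv_epi_radii, spec.rv_center)]

    ks = np.arange(nz)
    if spec.n_slices is not None and spec.n_slices < nz:
        mid = nz // 2
        half = spec.n_slices // 2
        ks = ks[max(0, mid - half): mid - half + spec.n_slices]

    phi = 2 * np.pi * np.arange(n_points) / n_points
    for k in ks:
        z = z_of(int(k))
        for label, radii, center in surfaces:
            a, b, c = radii
            u = (z - center[2]) / c
            if abs(u) >= 1.0:
                continue
            shrink = np.sqrt(1.0 - u * u)
            ax, by = a * shrink, b * shrink
            if min(ax, by) < 0.5:  # skip degenerate near-pole slivers
                continue
            pts = np.stack(
                [center[0] + ax * np.cos(phi), center[1] + by * np.sin(phi)], -1
            )
            cs.add(label, int(k), pts)
    return cs
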