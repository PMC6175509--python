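# Methods

`scarmesh` builds a layered 3D model of myocardial scar from a 3D
late-gadolinium-enhancement (LGE) cardiovascular MR volume and manually
delineated endo/epicardial contours. This note documents the model, its
assumptions, the tunable parameters, the synthetic phantom used for
validation, and the numerical choices made where the design was open.

## Pipeline overview

1. **Myocardial mask.** Per-slice endo/epicardial polygons are
   rasterized: a voxel belongs to the myocardium iff its center lies
   inside the epicardial polygon and outside the endocardial one.
   Point-in-polygon queries go through shapely; points exactly on a
   polygon edge count as inside, which makes grid-aligned fixtures
   deterministic. Slices carrying only an epicardial contour (the
   apical cap) are filled entirely.
2. **FWHM scar classification.** Scar = myocardial voxels with signal
   intensity strictly greater than half of a reference maximum
   (full-width at half-maximum criterion). The reference defaults to
   the plain maximum over the myocardium — the most literal reading —
   with two options for common practice: a user-supplied hyperenhanced
   reference region, and a robust percentile (default 100 = max). The
   classification is invariant under positive rescaling of intensities.
3. **Surface reconstruction.** Contours of each surface are merged into
   a point cloud (in-plane mm + slice position), decimated on a uniform
   3D grid (one centroid per occupied cell), given outward normals
   estimated from the 10 nearest neighbors, and meshed with Poisson
   surface reconstruction.
4. **Transmural depth and wall layers.** For each myocardial voxel
   center `p`, depth(p) = d_endo / (d_endo + d_epi) with unsigned
   Euclidean distances to the two surfaces; the wall partitions into
   subendocardial [0, 1/3), mid [1/3, 2/3) and subepicardial [2/3, 1]
   layers. The intervals are half-open with depth 1 closed — an
   explicit tie-break so every voxel gets exactly one label.
5. **Voxel-wise scar mesh.** Every scar voxel becomes an axis-aligned
   cuboid of the native voxel size (12 outward-wound triangles) centered
   on the voxel's world position. Duplicate vertices are welded on the
   voxel-corner lattice and coincident faces (interior walls between
   adjacent cubes) are removed in both copies, leaving the boundary
   shell. A `keep_one_duplicate` switch retains single copies instead.
6. **Endocardial scar projection.** Scar voxels in the subendocardial
   layer are projected onto the endocardial mesh by radius search:
   binary mode marks a vertex when any subendocardial scar voxel center
   is within the radius; graded mode assigns the scar fraction among
   subendocardial voxel centers within the radius. The per-vertex map
   becomes vertex colors, or is baked to a texture on a Tutte (uniform
   harmonic) disk parametrization of the basally opened surface.
7. **Scene assembly and export.** Layers (epicardium, endocardium,
   scar) carry color and opacity and export to glTF 2.0/GLB
   (`alphaMode` BLEND for transparent layers), OBJ+MTL (opacity in the
   `d` statement) and PLY (per-vertex RGBA). Units are mm, +z toward
   the cardiac base.

## Scar-burden metrics

* scar volume fraction = |scar| / |LV myocardium| x 100;
* endocardial scar fraction = |scar in subendocardial layer| / |scar| x 100
  (undefined/NaN when there is no scar);
* surface scar area fraction = projected scar area / endocardial
  surface area x 100, where a face's scar share is the mean of its
  three vertex values (mixed-face rule).

The pipeline computes the surface metric from the *graded* projection:
at a blob boundary the binary any-voxel-in-radius rule dilates the
footprint by roughly the search radius, while the graded fraction
crosses 0.5 at the true boundary, making the area estimate unbiased to
first order. The binary rule remains the default of `project_scar`
itself, matching its plain contract; `PipelineConfig.projection_mode`
selects the mode. A consequence worth noting: thresholding the graded
map at 0.5 agrees with the binary map away from blob boundaries but not
within one search radius of them — the two rules are genuinely
different estimators there.

## Poisson reconstruction on a regular grid

The classic screened-Poisson formulation solves for a smoothed
indicator function chi with lap(chi) = div(V) on an adaptive octree,
where V is the splatted field of oriented samples. At ventricular scale
an adaptive data structure buys little, so the solver here uses a
regular grid: trilinear splatting of the normals, Gaussian smoothing of
the vector field (sigma = 1.2 cells, playing the role of the B-spline
kernel), central-difference divergence, and a spectral (FFT) solve of
the periodic Poisson problem with the zero mode projected out. The
`depth` parameter bounds the grid as in the octree setting: the longest
padded bounding-box extent is divided into 2^depth cells (default
depth 7, i.e. cells of roughly 0.9 mm for a 90 mm ventricle plus 25 %
padding). The surface is the marching-cubes isosurface at the median
chi value of the samples; the largest connected component is kept and
oriented outward (positive enclosed volume). The reconstruction is
deterministic for a fixed cloud and parameters.

Measured on a 20 mm sphere cloud (2000 points, depth 7): two-sided
Hausdorff distance below 0.25 mm, watertight, Euler characteristic 2.
On the ellipsoidal phantom shells at 1 mm spacing both surfaces stay
within one voxel of the true ellipsoids.

Normal orientation uses the usual two-stage heuristic: per-point
normals from the smallest-eigenvalue eigenvector of the neighborhood
covariance, sign consistency propagated along a minimum spanning tree
of the neighbor graph (edge cost 1 - |n_i . n_j|), then whole
components flipped to point away from the cloud centroid. For planar
(degenerate) clouds the centroid score vanishes and a reproducible
axis-based sign is chosen instead.

## Transmural depth: two-distance ratio

Depth is the ratio d_endo / (d_endo + d_epi) rather than a Laplacian
transmural coordinate: the ratio is simple, exact for concentric
shells, and accurate to well under the layer width for ventricular
aspect ratios; Laplacian depth is noted as a possible extension.
Distances are evaluated against a midpoint-subdivided vertex sampling
of each surface (subdivision until the longest edge is below half the
smallest voxel spacing, at most 4 rounds), so the point-to-vertex
distance approximates point-to-surface distance with error below half
the sampling gap. On a concentric-sphere phantom (20/30 mm, 1 mm grid)
the RMS depth error is about 0.002.

## The synthetic phantom

The phantom emulates the imaging setting the tool targets: a short-axis
stack of an ellipsoidal-shell LV with a bright scar region and additive
Gaussian noise, with ground-truth masks, contours and fractions.

* **Geometry.** Endocardial semi-axes 20x20x38 mm, epicardial
  28x28x46 mm (8 mm wall, ~9 cm long axis — a mid-sized ventricle);
  optional crescent RV (an offset ellipsoidal shell minus the LV
  epicardial interior) for visualization realism, excluded from
  metrics. The grid is axis-aligned, LV-centered, with a 6 mm margin;
  default spacing 1.0 mm isotropic (the in-vivo regime), down to
  0.4x0.4x0.5 mm for the ex-vivo regime.
* **Scar blobs** live in normalized shell coordinates: an azimuthal
  sector around the long axis, a transmural band [0, extent] measured
  from the endocardium along rays from the LV center (exact by
  construction), and a normalized long-axis range. The default blob
  (100 deg sector, transmural extent 0.6, central half of the long
  axis) yields a scar burden near 10 % of LV myocardium, matching the
  scale of infarcts this kind of model is built for.
* **Intensities.** Remote myocardium mean 30, scar mean 100, additive
  Gaussian noise SD 2 (arbitrary units); background (blood pool, air)
  fixed at half the remote mean so the FWHM reference inside the
  myocardium is unaffected. Masks and contours depend only on the
  geometry, never on the noise seed; the same seed is bit-reproducible.
* **Ground truth** comes from the continuous geometry by numerical
  integration, not from the voxelized masks: volume fractions on a
  supersampled grid (half the voxel spacing), the endocardial share
  using the same two-distance depth definition as the pipeline
  (evaluated against densely sampled true ellipsoid surfaces), and the
  surface footprint by parametric surface integration.

What the phantom does **not** emulate: trabeculation and papillary
muscles, partial-volume intensity blending (voxels take the intensity
of the region containing their center), Rician noise statistics, coil
shading, motion artifacts, and irregular scar morphology. Passing
recovery tests therefore demonstrate the correctness of the geometry
and metric computations under known truth — not segmentation robustness
on clinical images.

## Numerical choices and degenerate inputs

* Voxel indices are 0-based; a voxel's world position is its center;
  cuboids span +/- spacing/2 about it.
* Decimation cell defaults to twice the in-plane spacing; the
  projection radius to twice the largest spacing.
* Vertex welding uses exact integer lattice keys for voxel meshes
  (volume conservation is exact in integer arithmetic: enclosed volume
  = voxel count x voxel volume, bit-for-bit) and a quantization
  tolerance (default 1e-6 mm) for generic meshes.
* Voxel shells with diagonally edge-touching cubes contain edges
  bounded by four faces: the shell is *closed* (every edge bounds an
  even number of faces; enclosed volume exact) though not strictly
  2-manifold. Mesh statistics report this closedness; reconstructed
  Poisson surfaces are held to the strict every-edge-two-faces
  standard.
* Basal clipping removes faces whose centroid lies above the plane (by
  default the plane of the most basal contoured slice); a plane missing
  the mesh entirely is a warning no-op. On a full symmetric phantom the
  contoured range covers the whole shell, so there is nothing to clip.
* FWHM on a uniform-intensity myocardium classifies everything as scar
  (threshold is half the maximum) and warns about degenerate contrast.
  An empty myocardium is an error.
* Texture baking: Tutte embeddings with a convex (circular) boundary
  are provably fold-free for triangulated disks; texels outside the
  disk take the nearest vertex color so bilinear lookups at rim
  vertices stay faithful. Bilinear texel averaging at a binary
  scar/remote color discontinuity mixes the two colors — the
  interpolation tolerance of the round-trip.

## Problem sizes

Validation uses 1 mm phantoms (~90x90x100 voxel grids, ~8.7 x 10^4
myocardial voxels), sphere clouds of 2000–3000 points, reconstruction
depth 7, and a single 0.5 mm phantom for the fine-resolution recovery
check; recovery is exercised across scar burdens of roughly 5–40 % and
transmural extents 0.3–1.0.

## Known limitations

* The FWHM reference choice (global max vs. seeded region) is a config
  option; clinical LGE often uses seeded or percentile references.
* Radius-search projection is robust to small mesh/mask misalignment
  but not a ray-casting projection along surface normals; the latter is
  a documented alternative interpretation, not yet implemented.
* The regular-grid Poisson solver holds the whole grid in memory
  (2^(3*depth) cells); depth 9+ at fine spacing would favor an octree.
* RV myocardium is carried through contours and intensities but not
  included in scar quantification.
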