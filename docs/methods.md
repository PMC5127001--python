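# Methods

## Sensor and frustum model

The depth camera is modelled as a pinhole sensor: a grid of
`n_cols × n_rows` rays spanning full angles `h_fov × v_fov` (defaults
512 × 424 over 70° × 60°). Pixel ray directions in the sensor frame are
`(u, v, 1)` with `u, v` spaced uniformly on the image plane, so the
theoretical spacing of measurements at range *r* is
`2 r tan(fov/2) / n_pixels` — 1.4 mm at 0.5 m and 10.9 mm at 4.0 m for
the default sensor.

**Range limits apply to sensor-frame depth (z), not Euclidean ray
length.** This matches how a depth image works — each pixel stores z, and
a flat target filling the frame at depth 3.75 m returns all 217,088
pixels even though corner rays are 5.06 m long — and it makes the viewing
volume a true truncated pyramid: four angular side planes plus planar
near/far caps. Frustum containment, canopy-top clipping and the boundary
mesh used for artefact distances all share this convention. The world
frame is Z-up, metres everywhere; a nadir pose maps the boresight to
world −Z so point elevations are plain world z.

Clipping to the canopy-top field of view keeps points whose sensor-frame
lateral coordinates fall inside the **closed** FOV rectangle evaluated at
the sensor-to-highest-plant depth; the closed rectangle means ties on the
boundary never silently drop canopy-top points. In the campaign workflow
the "highest plant" is resolved per frame (the tallest plant actually
inside that frame's view), since a plot-wide maximum would needlessly
narrow the windows of frames over short vegetation.

## Pre-processing

The chain per frame is fixed: clip to top FOV → crop to the area of
interest (closed box) → statistical outlier removal. The SOR filter
computes each point's mean Euclidean distance to its k = 5 exact nearest
neighbours (KD-tree) and removes points strictly above
`mean + multiplier · SD` of those distances (multiplier 1.0). A literal
variant thresholding on `multiplier · SD` alone exists behind a config
switch (`sor_literal`) for comparison; on fine, evenly spaced clouds it
removes nearly everything, which is why the mean-anchored form is the
default. Exact (not approximate) neighbours are required so results are
reproducible bit for bit.

Tie-point registration is the closed-form Kabsch/Horn solution (SVD of
the centred cross-covariance; rotation via `scipy` `align_vectors`),
with the SD of residual 3D distances reported. Collinear tie-point sets
are rejected (rotation not unique).

## Height models

Rasters use half-open cells `[x0+i·s, x0+(i+1)·s)` anchored at the AOI
lower-left corner so every CHM variant (single frames, combinations,
reference) is co-registered by construction; points exactly on the AOI
max edge are assigned to the last cell so each point maps to exactly one
cell. DSM = per-cell max, DTM = per-cell min, no interpolation — a cell
is only as good as its actual canopy-top and ground samples, which is the
point of the method. CHM = DSM − DTM; empty cells are nodata and nodata
propagates. Border trimming masks the outermost ring (default 1) rather
than shrinking the array, keeping rasters aligned; it is applied to the
CHM. The 0.25 m default cell size is matched to maize plant spacing
(seamless coverage without multiple plant tips per cell).

## Accuracy assessment

For a difference raster (test − reference; positive where the test model
is higher) the report contains RMSE, mean, SD; mean/SD excluding blunders
(|Δh| > 3·RMSE); the signed median (q50); the 68.3 % and 95 % quantiles
of |Δh|; NMAD = 1.4826·MAD; the squared Pearson correlation of the normal
Q–Q scatter (sorted standardised differences against normal quantiles at
plotting positions (i−0.5)/n, reported as NaN for zero-spread samples);
and the cell-level OLS of test on reference. Quantiles interpolate
linearly between order statistics. NMAD and the quantiles are robust to
blunders below their breakdown point; RMSE and SD are not — both
behaviours are exercised in the tests.

## Individual plant heights

A canopy local maximum is a point strictly higher than every other point
within a **horizontal** disc of radius 0.125 m (ties broken by first
index). The neighbourhood radius reuses the protocol's 0.125 m
min-extraction/matching radius, a choice this package makes explicit
because only those two radii are prescribed by the protocol. Scenario 1 pairs each local
maximum with the lowest point in its disc and discards heights below
0.50 m; scenario 2 takes the z-range of the disc around each known
position, reporting empty discs as missing rather than dropping them.
Matching to a reference cloud takes the nearest reference local maximum
within 0.125 m; unmatched observations are counted. One plant may yield
several observations across overlapping frames — the comparison
statistics operate on observation pairs, not plants.

The local-maxima search uses a coarse-grid prefilter (cell size
radius/√2: any point that is not its cell's running maximum has a
higher-or-earlier point within one radius) followed by an exact disc
check of the surviving candidates, so it is exact but near-linear.

## Synthetic test bench

The generator emulates one concrete field setup: a 2.5 m × 8.0 m planar plot
of 52 plants on a jittered 13 × 4 grid (longitudinal spacing 0.58 m,
transverse 0.46 m, Gaussian position jitter SD 2 cm), plant heights
increasing linearly from 0.55 m (south) to 2.41 m (north) with 6 cm
jitter, clipped to the range. Eight nadir camera poses at 3.75 m height
march along the long axis; five virtual laser-scanner positions at 3.5 m
height, 1 m outside the plot corners and mid-edge, provide the merged
reference cloud.

Plants are stylised, not botanical: an octagonal stem prism
(radius 15 mm), ten alternating arched leaf blades (tapering triangle
strips, length scaling with plant height), and an apex spike tapering
from 10 mm to a flat cap of radius `tip_radius` (default 2.5 mm) whose
elevation is exactly the plant's true height. This morphology creates the
three things the method is sensitive to: occlusion, canopy gaps through
which nadir rays reach the ground, and fine tips that a pixel grid
under-samples — the mechanism of systematic crop height underestimation.
Coarsening `tip_radius` monotonically shrinks that bias, which the tests
exploit.

Rendering is first-surface ray casting: terrain plane analytically,
plant triangles via Möller–Trumbore with two-level axis-aligned
bounding-box culling (per plant, then per part), bitwise reproducible
given the seeds. Noise is applied **along the ray**: measured range =
true range − bias(range) + N(0, sd(range)²), with sd interpolating
0.001 m @ 0.8 m → 0.003 m @ 4.0 m and bias 0.005 m @ 0.8 m →
0.024 m @ 4.0 m (range underestimation growing with distance, the
default sign). Looking down, the farther ground is lifted more than the
nearer canopy, so the bias alone already depresses the CHM slightly;
tip under-sampling adds the rest.

Artefacts per frame are drawn as `round(N(count_mean, count_sd))`,
clipped at zero, with lighting presets (night 50 (7.4), diffuse
195 (14.4), away-from-sun 202 (10.1), into-sun 218 (13.4)); 85 % are
placed within 2 cm of the frustum boundary faces (area-weighted) and the
rest uniformly in the frustum volume, reproducing small median but large
maximum/SD boundary distances. The into-sun mode adds a loosely
parameterised sun-direction column that is illustrative only and excluded
from quantitative checks.

The virtual laser scanner casts a spherical az/el grid windowed to the
plot, with Gaussian range noise (SD 3 mm). Its angular-step default is
the real device's 0.029° (2.5 mm spacing at 5 m); the default *campaign*
renders at 0.10°–0.06° — the package's chosen trade of reference density
against rendering cost — which at 4–9 m viewing distance still samples
finer than the depth camera's pixel footprint, preserving the reference's
advantage on fine canopy structure.

**What the bench does not emulate:** leaf-level botanical detail,
radiometric/intensity effects, multipath and flying-pixel physics, wind
movement, lens distortion, and real TLS beam divergence. Passing tests
therefore demonstrate the correctness of the geometry, filtering,
rasterisation and statistics, and the qualitative sensor physics
(underestimation via fine tips and range bias; single-frame vs combined
coverage) — not calibrated absolute error magnitudes for any real crop.

## Numerical and design choices

* RANSAC plane fit: 3-point samples, inlier threshold 0.01 m (sensor
  noise scale), 500 iterations, explicit seed, total-least-squares
  refinement on the consensus set, normal canonically oriented towards
  +z. Hand-rolled because a regression-form RANSAC cannot represent
  vertical planes.
* Degenerate inputs fail loudly (`DomainError`): < 3 plane points,
  collinear tie points, ≤ k points for SOR, < 2 cells/pairs for
  statistics, inverted AOI bounds, empty merges.
* Zero-spread samples: Q–Q R² is NaN (undefined), reported as missing
  rather than 0 or 1.
* Point-to-frustum distances triangulate the boundary (12 triangles) and
  use exact point-triangle distances, vectorised over points.
* The campaign fixes the analysis grid to the AOI at 0.25 m regardless of
  data extent, so all 11 CHM variants share one grid.

## Parameters that matter

| parameter | default | unit | role |
| --- | --- | --- | --- |
| `cell_size` | 0.25 | m | CHM raster cell |
| `sor_k`, `sor_multiplier` | 5, 1.0 | – | outlier filter neighbourhood/threshold |
| `plant_radius` | 0.125 | m | local-maximum / min-extraction / matching disc |
| `min_plant_height` | 0.500 | m | scenario-1 plausibility floor |
| `blunder_factor` | 3 | ×RMSE | gross-error cut |
| `trim_rings` | 1 | cells | CHM border mask |
| `tip_radius` | 0.0025 | m | apex fineness → underestimation strength |
| noise anchors | see above | m | TOF precision/accuracy vs range |

## Known limitations

* The per-frame canopy-top range uses ground truth in the synthetic
  campaign; on real data it must come from field knowledge or a robust
  upper quantile of the cloud.
* Scenario-1 heights conflate neighbouring plants when spacing < 2×
  search radius; the bench's 0.46 m minimum spacing avoids this by
  construction.
* The TLS sampler shares the ray-casting engine with the camera, so it is
  an independent *viewpoint*, not an independent *implementation*; format
  and statistics oracles in the tests are independent reimplementations.
* LAS I/O is not provided; ASCII XYZ and PLY (ascii/binary) cover the
  exchange needs at double precision.
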