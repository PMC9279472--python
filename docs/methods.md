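# Methods

## The measurement model

The quantity of interest is the **subchondral cortical distance (SCD)**: at
an in-plane location (x, y) of the joint frame, the vertical (parallel to
the tibial long axis) distance between the femoral and the lateral-tibial
subchondral bone surfaces. SCD deliberately includes cartilage plus joint
space — it is the 3D analog of the joint-space width read off a stress
radiograph, and it requires only bone segmentations, which are far more
robust to delineate than cartilage surfaces.

Processing of one segmented scan:

1. **Joint frame.** z = first principal component of the combined tibial
   voxel cloud (oriented craniocaudally), x = scanner ML axis
   orthogonalized against z with +x lateral (laterality is an input flag;
   the sign convention follows left knees, where lateral = +scanner-x),
   y = z × x. Origin: centroid of the lateral condyle's top-surface voxels.
   The frame is rigid, so all distances are preserved. If the two leading
   eigenvalues are within 5% the axis is ambiguous (symmetric phantoms);
   this warns rather than fails.
2. **Height fields.** All femoral and lateral-tibial voxel centers are
   mapped into the frame and binned onto an (x, y) raster at the volume's
   in-plane spacing. Per column, t = highest tibial voxel, f = lowest
   femoral voxel *strictly above t* (so posterior femoral cortex below the
   joint line can never capture a column — "coordinate hull" semantics).
   Surface positions are taken at voxel *boundaries* (± half a z voxel from
   the extreme centers): two slabs separated by a whole number of voxels
   then measure their exact nominal gap, and a zero gap measures zero.
   Columns on unsegmented coronal slices (2D acquisitions leave interslice
   gaps) are bridged by linear interpolation along y and flagged.
3. **Measurement grid.** A regular lattice, 3.5 mm mediolateral × 3.3 mm
   anteroposterior, covers the bounding box of the **baseline**
   (intact-unloaded) lateral-condyle footprint, centered so margins are
   symmetric (floor(extent/spacing)+1 points per axis). The same grid — the
   tibia is the fixed body of the frame — is reused for all conditions and
   configurations of a specimen; no image registration is performed.
4. **Lateral exclusion.** Grid points lateral of
   `lateral_extreme − 0.10 × transepicondylar diameter` are masked (reason
   `lateral-10%`): the epicondylar flank curves away from the joint line
   and produces spuriously long vertical distances. The diameter is the
   femur's extent along frame-x over its distal 40% (by z) — the distal
   restriction keeps the shaft out of the measurement; the threshold is a
   convention of this implementation.
5. **SCD map.** f and t are sampled at each retained grid point by bilinear
   interpolation of the height fields (nearest-column sampling is available
   as a sensitivity option); points whose stencil touches a column lacking
   either surface are masked (`invalid-column`). `SCD_compmean` is the
   arithmetic mean over retained points. The retained count is logged per
   run (98 per specimen at the default phantom geometry).
6. **Manual-site analogs.** Six named sites mimic a radiologist's 2D
   measurements: ml1/ml2/ml3 on the mid-coronal line at 25/50/75% of the ML
   extent from the lateral edge (lateral → medial), ap1/ap2/ap3 on the
   mid-sagittal line at 25/50/75% of the AP extent from the anterior edge.
   The real anteroposterior landmarks are meniscus-based; with no meniscus
   segmented, fractional positions of the condyle footprint are used as a
   documented proxy. Their mean is the `SCD_manmean` analog, and each site
   is also matched to its nearest retained grid point (ties broken toward
   smaller x, then smaller y).
7. **Loading-difference maps.** Per condition,
   |SCD_loaded − SCD_unloaded| point-by-point on the intersection of
   retained sets; specimen-averaged maps require each point in ≥ 50% of
   specimens (configurable). Signed means obey the exact identity
   mean(Δ) = compmean(loaded) − compmean(unloaded) on a common retained set.

## Statistics

* **Reader agreement**: ICC(1,1) — one-way random effects, single measures
  ("single scorings, not adjusted") — computed from the variance-component
  form; the two-way random single-measures form ICC(2,1) is an option.
  Zero total variance is reported as undefined, not as a number.
* **RM-ANOVA**: two within-subject factors (condition × configuration) via
  `statsmodels.AnovaRM`; all-constant input short-circuits to F = 0, p = 1.
  Sphericity is addressed by reporting Greenhouse–Geisser corrected
  p-values (ε from the double-centered covariance of orthonormalized
  effect contrasts) alongside the uncorrected ones; 2-level factors have
  ε = 1 identically.
* **Post-hocs**: Tukey pairwise condition comparisons within each
  configuration, using the one-way repeated-measures error term
  (condition × subject MS) and the studentized-range distribution — the
  multiplicity-adjusted p-values a GraphPad-style analysis reports.
* **Contrasts**: condition-vs-intact differences of group means per
  configuration, reported at full precision and at the 0.1 mm display
  rounding. In pipeline mode group means average per-specimen values; fed
  the packaged printed-means fixture they reproduce the published
  arithmetic exactly (printed means are already rounded, so six-site means
  recomputed from printed cells can differ from the printed summary row by
  up to 0.05 mm — e.g. 7.75 vs a printed 7.8).

## The phantom generator

Phantoms stand in for the cadaveric scans. Each is two voxelized "bones":
a tibia (wide plateau slab, split into medial/lateral labels at its ML
midline, on a narrow distal shaft) and a femur (distal block whose
undersurface floats `gap_mm` above the plateau, on a proximal shaft). The
shafts exist so each bone has a dominant craniocaudal principal axis, as a
long bone does; they are far from the joint and never affect column gaps.

* **Flat plate** (condyle radius ∞): every column's gap equals the nominal
  gap — the exact oracle for the measurement chain.
* **Wedge**: gap varies linearly from the medial to the lateral tibial
  edge; the linear coefficients ship in the volume metadata.
* **Knee-like**: a cylindrical sagittal condyle (radius default 30 mm, a
  mid-range adult femoral condyle) curves the femoral surface along y;
  **loading is a rigid rotation of the femur** about a hinge line at the
  medial tibial edge (re-voxelized through the exact inverse rotation), so
  the gap increase at signed in-plane distance s from the hinge line is
  `s·tan(angle)` to first order. An optional in-plane hinge tilt (a
  posteromedial→anterolateral axis) reproduces the posterolaterally
  dominant opening pattern of a rotationally unstable joint.

Voxelization uses the center-in-region rule with bone surfaces aligned to
voxel boundaries: requested gaps quantize to the nearest z-voxel boundary
(reported in metadata), so all ground-truth comparisons carry a one-voxel
tolerance. Label disjointness and femur-above-tibia ordering are asserted
on every emitted volume; a rotation that would drive the femur into the
tibia raises a collision error rather than emitting an invalid volume.

**Synthetic studies** mirror the experimental design: n = 10 specimens,
five ordered conditions (intact → +LCL → +PT → +PFL → +ACL), two
configurations. Per specimen a baseline gap is drawn (SD `noise_sd_mm`,
default 1.0 mm); each acquisition adds independent jitter
(`measurement_noise_mm`, default 0.3 mm — repositioning variability, and
the reason recovered contrasts have non-degenerate standard errors).
Unloaded volumes add the per-condition drift (defaults 0/0.2/0.3/0.4/0.9 mm,
the published unloaded progression); loaded volumes rotate the femur by the
angle whose mean opening over the *retained measurement region* equals
`load_effect_mm` (2.1 mm, the published intact loading response) plus the
per-condition increment (defaults 0/1.3/1.7/2.2/2.6 mm). That target
centroid is predicted from the phantom geometry by replicating the grid
arithmetic on voxel centers — using the naive footprint midpoint instead
biases large openings by ~0.3 mm. The truth table records the injected gap
parameters; the condylar sag adds a constant geometric offset to absolute
`SCD_compmean` values (≈ +3.2 mm at the defaults) that cancels in every
contrast, which is why recovery is asserted on contrasts.

### What the phantoms do *not* emulate

No MR signal formation, noise, bias fields or chemical-shift artifacts; no
cartilage or meniscus labels; no soft-tissue deformation (loading is purely
rigid); no segmentation error beyond voxel quantization; anatomy is
idealized (flat plateau, cylindrical condyle). Passing phantom tests
therefore demonstrates the correctness of the geometry, measurement and
statistics code under known truth — not robustness to real segmentation
variability or scanner physics.

## Defaults and problem sizes

| Parameter | Default | Why |
|---|---|---|
| voxel spacing | 0.5 mm isotropic | clinical-MRI-like scale; coronal interslice gaps available via `slice_gap_pattern` |
| phantom volume | 144 × 96 × 176 voxels (72 × 48 × 88 mm) | holds both bones plus up to ~20 mm gaps and 5–6° rotations |
| femur / tibia width | 64 / 68 mm | scaled-down adult transepicondylar proportions |
| grid spacing | 3.5 mm ML × 3.3 mm AP | the study grid |
| exclusion fraction | 0.10 | the lateral-10% rule |
| condyle radius | 30 mm (knee-like) | mid-range sagittal condylar curvature |
| study design | n=10, openings 0/1.3/1.7/2.2/2.6 mm over a 2.1 mm load effect, noise 1.0 mm | the published design magnitudes |

At these sizes a volume voxelizes in ~0.2 s and measures in ~0.3 s; the
full 100-volume study runs in ~15 s, the complete test suite in under a
minute, and `scripts/acceptance.py` in about a minute. The unit-test
phantoms shrink the field of view to 48 × 32 × 66 mm.

## Numerical choices

* Quantization tolerance: one z voxel for any single surface; the flat
  plate is exact because its gaps are voxel multiples.
* Bilinear interpolation propagates NaN from any stencil cell —
  conservative masking near footprint edges (points become
  `invalid-column` rather than extrapolated).
* Nearest-grid-point ties break toward smaller x, then smaller y;
  all-equal RM-ANOVA input returns F = 0, p = 1; zero-variance ICC is
  undefined by report.
* Principal-axis near-degeneracy (eigenvalue ratio < 1.05) warns;
  planar/collinear tibiae raise.
* Determinism: every stochastic element flows from explicit integer seeds;
  regeneration and reruns are bit-identical.

## Known limitations

* The transepicondylar axis is operationalized as the frame ML axis over
  the distal 40% of the femur — a deterministic surrogate, not an
  epicondyle detector.
* The AP manual sites are fractional-position proxies for meniscus
  landmarks.
* Grid transfer across configurations assumes the tibia is the fixed body;
  scans where the tibia itself moves relative to its own axis between
  acquisitions would need registration, which is out of scope.
* Real-data effects (segmentation error, artifacts, anatomical variation)
  are outside what the synthetic validation can certify.
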