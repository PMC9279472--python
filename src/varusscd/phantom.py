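"""Voxelized femorotibial phantoms with analytically known joint gaps.

The study's raw material — cadaveric stress-MRI segmentations — cannot ship
with the package, so every downstream operation is validated on synthetic
bone geometries built here. A phantom is two "bones" on a voxel grid:

* a tibia made of a wide plateau slab (split into medial and lateral labels
  at its mediolateral midline) on top of a narrow distal shaft, and
* a femur whose distal surface floats ``gap_mm`` above the tibial plateau,
  optionally curved sagittally (cylindrical condyle of radius
  ``condyle_radius_mm``), carried by a proximal shaft.

The shafts give each bone a dominant craniocaudal principal axis, as a real
long bone has, so the joint-frame construction behaves as it does on knees;
they sit far from the joint line and never alter per-column gaps.

Varus loading is modeled as a rigid rotation of the femur about a medial
hinge line before re-voxelization: at in-plane signed distance ``s`` from the
hinge line the vertical gap grows by ``s * tan(angle)``. All geometry is
voxelized by the voxel-center-in-region rule with surfaces aligned to voxel
boundaries, so a gap that is a multiple of the z voxel size is realized
exactly and arbitrary gaps are realized to the nearest boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .errors import CollisionError, ParameterError, SizingError
from .volume_io import FEMUR, LATERAL_TIBIA, MEDIAL_TIBIA, LabelVolume

_EPS = 1e-6

#: the study's five graded ligament-deficiency conditions, intact first
CONDITIONS = ("intact", "LCL", "LCL+PT", "LCL+PT+PFL", "LCL+PT+PFL+ACL")
CONFIGURATIONS = ("UL", "LO")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a single synthetic joint.

    Lengths in mm; the volume's world origin is half a voxel inside the
    array corner so voxel *boundaries* lie on integer multiples of spacing.
    """

    volume_shape: tuple[int, int, int] = (144, 96, 176)
    spacing_mm: tuple[float, float, float] = (0.5, 0.5, 0.5)
    femur_width_mm: float = 64.0          # transepicondylar-diameter analog
    tibia_width_mm: float = 68.0
    condyle_radius_mm: float = math.inf   # sagittal curvature; inf = flat
    gap_mm: float = 8.0                   # vertical joint gap at condyle apex
    varus_angle_deg: float = 0.0          # rigid femur rotation (0 = unloaded)
    hinge_offset_mm: float | None = None  # world x of hinge line; None = medial tibia edge
    hinge_tilt_deg: float = 0.0           # in-plane tilt of hinge line (0 = pure AP)
    joint_z_mm: float = 46.0              # tibial plateau top surface
    plateau_thickness_mm: float = 6.0
    shaft_width_mm: float = 28.0
    slice_gap_pattern: tuple[int, ...] = ()  # unsegmented coronal (AP) slice indices
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing_mm):
            raise ParameterError(f"spacing must be positive, got {self.spacing_mm}")
        if self.gap_mm < 0:
            raise ParameterError(f"gap_mm must be >= 0, got {self.gap_mm}")
        if not abs(self.varus_angle_deg) < 10:
            raise ParameterError("varus_angle_deg must stay small (< 10 deg)")

    # -- derived world geometry (mm) ---------------------------------------
    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.volume_shape, self.spacing_mm))

    @property
    def x_center(self) -> float:
        return self.extent_mm[0] / 2.0

    @property
    def tibia_x_range(self) -> tuple[float, float]:
        return (self.x_center - self.tibia_width_mm / 2,
                self.x_center + self.tibia_width_mm / 2)

    @property
    def femur_x_range(self) -> tuple[float, float]:
        return (self.x_center - self.femur_width_mm / 2,
                self.x_center + self.femur_width_mm / 2)

    @property
    def y_range(self) -> tuple[float, float]:
        return (1.0, self.extent_mm[1] - 1.0)

    @property
    def y_center(self) -> float:
        return self.extent_mm[1] / 2.0

    @property
    def hinge_x(self) -> float:
        return self.tibia_x_range[0] if self.hinge_offset_mm is None else self.hinge_offset_mm

    def sag_mm(self, y) -> np.ndarray:
        """Sagittal condyle drop-off: surface height above the apex at AP
        position y (0 at the AP center, grows toward the margins)."""
        r = self.condyle_radius_mm
        dy = np.abs(np.asarray(y, dtype=float) - self.y_center)
        if not np.isfinite(r):
            return np.zeros_like(dy)
        return r - np.sqrt(np.maximum(r * r - np.minimum(dy, r) ** 2, 0.0))

    @property
    def max_sag_mm(self) -> float:
        half_ap = (self.y_range[1] - self.y_range[0]) / 2.0
        return float(self.sag_mm(self.y_center + half_ap))

    @property
    def condyle_top_z(self) -> float:
        return self.joint_z_mm + self.gap_mm + self.max_sag_mm + 4.0


def _check_fit(spec: PhantomSpec, extra_gap: float = 0.0) -> None:
    sx, sy, sz = spec.extent_mm
    need_z = spec.condyle_top_z + extra_gap + 2.0
    if need_z > sz - 1.0:
        raise SizingError(
            f"volume z extent {sz} mm cannot hold plateau at {spec.joint_z_mm} mm "
            f"plus gap {spec.gap_mm + extra_gap} mm plus femur")
    if spec.tibia_width_mm > sx - 2.0 or spec.femur_width_mm > sx - 2.0:
        raise SizingError(f"volume x extent {sx} mm too small for bone widths")
    if spec.joint_z_mm - spec.plateau_thickness_mm < 2.0:
        raise SizingError("no room for tibial shaft below the plateau")


def _rotation_about_hinge(spec: PhantomSpec):
    """(R, hinge_point) rotating the femur rigidly about the hinge line.

    The hinge line passes through ``(hinge_x, y_center, joint_z + gap)`` with
    in-plane direction ``(sin tilt, cos tilt, 0)``; positive varus angle lifts
    the lateral (+x) side. Returns None for a zero angle.
    """
    theta = math.radians(spec.varus_angle_deg)
    if theta == 0.0:
        return None
    phi = math.radians(spec.hinge_tilt_deg)
    axis = np.array([math.sin(phi), math.cos(phi), 0.0])
    # Rodrigues; rotation by -theta about +y lifts +x (small-angle dz = +x*theta)
    a = -theta
    k = axis
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    R = np.eye(3) + math.sin(a) * K + (1 - math.cos(a)) * (K @ K)
    hinge = np.array([spec.hinge_x, spec.y_center, spec.joint_z_mm + spec.gap_mm])
    return R, hinge


def hinge_gap_increase(spec: PhantomSpec, x, y) -> np.ndarray:
    """Analytic first-order vertical gap increase at (x, y) under the hinge
    rotation: ``tan(angle) * s`` with s the signed in-plane distance from the
    hinge line (positive lateral of it)."""
    theta = math.radians(spec.varus_angle_deg)
    phi = math.radians(spec.hinge_tilt_deg)
    s = (math.cos(phi) * (np.asarray(x, float) - spec.hinge_x)
         - math.sin(phi) * (np.asarray(y, float) - spec.y_center))
    return math.tan(theta) * s


def analytic_gap(spec: PhantomSpec, x, y) -> np.ndarray:
    """Ground-truth vertical gap of the knee-like phantom at column (x, y)."""
    base = spec.gap_mm + spec.sag_mm(y)
    return base + hinge_gap_increase(spec, x, y)


# -- voxelization core ------------------------------------------------------

def _centers(spec: PhantomSpec):
    return tuple(
        (np.arange(n) + 0.5) * s
        for n, s in zip(spec.volume_shape, spec.spacing_mm)
    )


def _femur_low_z(spec: PhantomSpec, x, y, gap_fn) -> np.ndarray:
    """Continuous femoral undersurface before any rotation."""
    return spec.joint_z_mm + gap_fn(np.asarray(x, float), np.asarray(y, float))


def _voxelize(spec: PhantomSpec, gap_fn) -> LabelVolume:
    """Voxelize tibia + femur, femur optionally rotated about the hinge.

    ``gap_fn(x, y)`` is the continuous unloaded gap profile (>= 0) between
    the flat tibial plateau top and the femoral undersurface.
    """
    xc, yc, zc = _centers(spec)
    nx, ny, nz = spec.volume_shape
    labels = np.zeros(spec.volume_shape, dtype=np.int16)

    tx0, tx1 = spec.tibia_x_range
    y0, y1 = spec.y_range
    zt = spec.joint_z_mm
    in_tx = (xc >= tx0 - _EPS) & (xc <= tx1 + _EPS)
    in_y = (yc >= y0 - _EPS) & (yc <= y1 + _EPS)

    # tibia: plateau slab + distal shaft
    plateau_z = (zc >= zt - spec.plateau_thickness_mm - _EPS) & (zc <= zt + _EPS)
    sx0 = spec.x_center - spec.shaft_width_mm / 2
    sx1 = spec.x_center + spec.shaft_width_mm / 2
    sy0 = spec.y_center - spec.shaft_width_mm / 2
    sy1 = spec.y_center + spec.shaft_width_mm / 2
    in_sx = (xc >= sx0 - _EPS) & (xc <= sx1 + _EPS)
    in_sy = (yc >= sy0 - _EPS) & (yc <= sy1 + _EPS)
    shaft_z = (zc >= 0.5 - _EPS) & (zc < zt - spec.plateau_thickness_mm - _EPS)

    tibia = (in_tx[:, None, None] & in_y[None, :, None] & plateau_z[None, None, :]) | \
            (in_sx[:, None, None] & in_sy[None, :, None] & shaft_z[None, None, :])
    lateral = xc >= spec.x_center - _EPS
    labels[tibia & lateral[:, None, None]] = LATERAL_TIBIA
    labels[tibia & ~lateral[:, None, None]] = MEDIAL_TIBIA

    # femur: condyle block above gap_fn + proximal shaft, possibly rotated
    fx0, fx1 = spec.femur_x_range
    z_top = spec.extent_mm[2] - 0.5
    zct = spec.condyle_top_z
    rot = _rotation_about_hinge(spec)

    def member(qx, qy, qz):
        in_fx = (qx >= fx0 - _EPS) & (qx <= fx1 + _EPS)
        in_fy = (qy >= y0 - _EPS) & (qy <= y1 + _EPS)
        low = _femur_low_z(spec, qx, qy, gap_fn)
        condyle = in_fx & in_fy & (qz >= low - _EPS) & (qz <= zct + _EPS)
        fsx = (qx >= sx0 - _EPS) & (qx <= sx1 + _EPS)
        fsy = (qy >= sy0 - _EPS) & (qy <= sy1 + _EPS)
        shaft = fsx & fsy & (qz > zct + _EPS) & (qz <= z_top + _EPS)
        return condyle | shaft

    if rot is None:
        gx, gy = np.meshgrid(xc, yc, indexing="ij")
        low2d = _femur_low_z(spec, gx, gy, gap_fn)  # (nx, ny)
        in_fx = (xc >= fx0 - _EPS) & (xc <= fx1 + _EPS)
        femur = (in_fx[:, None, None] & in_y[None, :, None]
                 & (zc[None, None, :] >= low2d[:, :, None] - _EPS)
                 & (zc[None, None, :] <= zct + _EPS))
        femur |= (in_sx[:, None, None] & in_sy[None, :, None]
                  & (zc[None, None, :] > zct + _EPS)[...]
                  & (zc[None, None, :] <= z_top + _EPS))
    else:
        R, hinge = rot
        # only voxels above the plateau can be femur after a small rotation
        k0 = int(np.searchsorted(zc, zt - 2.0))
        sub = np.stack(np.meshgrid(xc, yc, zc[k0:], indexing="ij"), axis=-1)
        q = (sub.reshape(-1, 3) - hinge) @ R + hinge  # R is orthonormal: R^-1 = R.T; rows@R == R.T@cols
        inside = member(q[:, 0], q[:, 1], q[:, 2]).reshape(nx, ny, nz - k0)
        femur = np.zeros(spec.volume_shape, dtype=bool)
        femur[:, :, k0:] = inside

    if (labels != 0)[femur].any():
        raise CollisionError(
            "femur rotation drives the femur into the tibia; reduce the varus "
            "angle or move the hinge medially")
    labels[femur] = FEMUR

    # z-ordering check: femur strictly above tibia in every shared column
    tib = (labels == MEDIAL_TIBIA) | (labels == LATERAL_TIBIA)
    fem = labels == FEMUR
    both = tib.any(axis=2) & fem.any(axis=2)
    if both.any():
        t_top = np.where(tib.any(axis=2), nz - 1 - np.argmax(tib[:, :, ::-1], axis=2), -1)
        f_bot = np.where(fem.any(axis=2), np.argmax(fem, axis=2), nz)
        if (f_bot[both] <= t_top[both]).any():
            raise CollisionError("femur label reaches below the tibial surface")

    for j in spec.slice_gap_pattern:
        labels[:, int(j), :] = 0

    origin = tuple(s / 2.0 for s in spec.spacing_mm)
    meta = {"phantom": _spec_meta(spec)}
    return LabelVolume(labels, spec.spacing_mm, origin, meta=meta)


def _spec_meta(spec: PhantomSpec) -> dict:
    d = asdict(spec)
    d["condyle_radius_mm"] = (None if not np.isfinite(spec.condyle_radius_mm)
                              else spec.condyle_radius_mm)
    d["hinge_x_mm"] = spec.hinge_x
    return d


# -- brute-force column scan (also used to report realized gaps) ------------

def column_gaps(volume: LabelVolume) -> np.ndarray:
    """Per-(x, y)-column vertical gap between the tibial top and femoral
    bottom *voxel boundaries*, NaN where either bone is absent.

    Vectorized but definitionally a per-column scan of the emitted labels;
    the tests re-derive the same quantity with explicit loops.
    """
    vox = volume.voxels
    nz = vox.shape[2]
    dz = volume.spacing_mm[2]
    tib = (vox == MEDIAL_TIBIA) | (vox == LATERAL_TIBIA)
    fem = vox == FEMUR
    has_t = tib.any(axis=2)
    has_f = fem.any(axis=2)
    t_top = nz - 1 - np.argmax(tib[:, :, ::-1], axis=2)
    ks = np.arange(nz)[None, None, :]
    fem_above = fem & (ks > t_top[:, :, None])
    has_fa = fem_above.any(axis=2)
    f_bot = np.argmax(fem_above, axis=2)
    gaps = np.full(vox.shape[:2], np.nan)
    ok = has_t & has_f & has_fa
    gaps[ok] = (f_bot[ok] - t_top[ok] - 1) * dz
    return gaps


# -- public generators ------------------------------------------------------

def generate_flat_plate(spec: PhantomSpec) -> LabelVolume:
    """Two parallel axis-aligned slabs separated by ``gap_mm`` everywhere.

    The oracle geometry for SCD validation: every column's gap equals the
    (voxel-quantized) requested gap. The realized gap, obtained by a
    brute-force column scan of the emitted volume, is stored under
    ``meta['realized_gap_mm']``.
    """
    if np.isfinite(spec.condyle_radius_mm):
        raise ParameterError("flat plate requires condyle_radius_mm = inf")
    if spec.varus_angle_deg != 0.0:
        raise ParameterError("flat plate is an unloaded geometry; use "
                             "generate_knee_like for varus rotation")
    _check_fit(spec)
    vol = _voxelize(spec, lambda x, y: np.full_like(np.asarray(x, float), spec.gap_mm))
    realized = column_gaps(vol)
    vol.meta["realized_gap_mm"] = float(np.nanmedian(realized))
    return vol


def generate_wedge(spec: PhantomSpec, gap_lateral_mm: float,
                   gap_medial_mm: float) -> LabelVolume:
    """Gap varying linearly along x from the medial to the lateral tibial edge.

    Ground-truth coefficients are stored in ``meta['wedge']`` as
    ``gap(x) = intercept + slope * x`` (world mm).
    """
    if gap_lateral_mm < 0 or gap_medial_mm < 0:
        raise ParameterError("wedge gaps must be >= 0")
    tx0, tx1 = spec.tibia_x_range
    slope = (gap_lateral_mm - gap_medial_mm) / (tx1 - tx0)
    intercept = gap_medial_mm - slope * tx0

    def gap_fn(x, y):
        return np.maximum(intercept + slope * np.asarray(x, float), 0.0)

    spec = replace(spec, gap_mm=max(gap_lateral_mm, gap_medial_mm))
    _check_fit(spec)
    vol = _voxelize(spec, gap_fn)
    vol.meta["wedge"] = {"intercept_mm": intercept, "slope": slope,
                         "gap_medial_mm": gap_medial_mm,
                         "gap_lateral_mm": gap_lateral_mm}
    return vol


def generate_knee_like(spec: PhantomSpec) -> LabelVolume:
    """Curved-condyle joint, optionally varus-loaded about a medial hinge.

    The unloaded surface is ``joint_z + gap + sag(y)``; loading rigidly
    rotates the femur about the hinge line before re-voxelization, so the
    analytic gap-increase field (:func:`hinge_gap_increase`) is exact to
    first order in the angle.
    """
    corners = [(spec.femur_x_range[1], spec.y_range[0]),
               (spec.femur_x_range[1], spec.y_range[1])]
    max_extra = max(abs(float(hinge_gap_increase(spec, x, y))) for x, y in corners)
    _check_fit(spec, extra_gap=max_extra)

    def gap_fn(x, y):
        return spec.gap_mm + spec.sag_mm(y)

    vol = _voxelize(spec, gap_fn)
    vol.meta["knee_like"] = True
    return vol


# -- whole synthetic studies ------------------------------------------------

@dataclass(frozen=True)
class StudyDesign:
    """Design of a synthetic loading study mirroring the cadaveric experiment:
    n specimens, five graded deficiency conditions, two configurations.

    ``opening_increment_mm[c]`` is the extra lateral opening of condition c's
    loaded configuration beyond the intact loaded joint; ``load_effect_mm`` is
    the intact loaded-vs-unloaded opening. ``unloaded_drift_mm[c]`` is the
    small condition-dependent unloaded gap increase. ``noise_sd_mm`` scatters
    per-specimen baseline gaps; ``measurement_noise_mm`` jitters every
    acquisition independently (repositioning variability).
    """

    n_specimens: int = 10
    conditions: tuple[str, ...] = CONDITIONS
    configurations: tuple[str, ...] = CONFIGURATIONS
    opening_increment_mm: tuple[float, ...] = (0.0, 1.3, 1.7, 2.2, 2.6)
    unloaded_drift_mm: tuple[float, ...] = (0.0, 0.2, 0.3, 0.4, 0.9)
    load_effect_mm: float = 2.1
    noise_sd_mm: float = 1.0
    measurement_noise_mm: float = 0.3
    seed: int = 0

    def __post_init__(self):
        inc = self.opening_increment_mm
        if len(inc) != len(self.conditions) or len(self.unloaded_drift_mm) != len(self.conditions):
            raise ParameterError("per-condition increments must match condition count")
        if any(i < 0 for i in inc) or any(d < 0 for d in self.unloaded_drift_mm):
            raise ParameterError("increments must be >= 0")
        if any(b < a - 1e-12 for a, b in zip(inc, inc[1:])):
            raise ParameterError("opening increments must be non-decreasing "
                                 "across the ordered conditions")


def retained_centroid_x(spec: PhantomSpec, exclusion_fraction: float = 0.10,
                        grid_spacing_ml: float = 3.5) -> float:
    """Mediolateral centroid of the retained measurement-grid points,
    predicted from the phantom geometry alone.

    Mirrors the downstream grid arithmetic on voxel-center positions — the
    centered lattice over the lateral-condyle footprint, the lateral cut at
    ``lateral extreme - fraction * transepicondylar diameter`` — so that a
    hinge angle chosen against this centroid injects its nominal mean
    opening into what the pipeline actually averages.
    """
    sx = spec.spacing_mm[0]
    fp_lo = spec.x_center + sx / 2.0          # medialmost lateral-tibia center
    fp_hi = spec.tibia_x_range[1] - sx / 2.0  # lateralmost center
    extent = fp_hi - fp_lo
    n = int(extent / grid_spacing_ml + 1e-9) + 1
    start = fp_lo + (extent - (n - 1) * grid_spacing_ml) / 2.0
    pts = start + grid_spacing_ml * np.arange(n)
    fem_lat = spec.femur_x_range[1] - sx / 2.0
    fem_med = spec.femur_x_range[0] + sx / 2.0
    cut = fem_lat - exclusion_fraction * (fem_lat - fem_med)
    retained = pts[(pts <= cut) & (pts <= fem_lat)]
    if retained.size == 0:
        raise ParameterError("exclusion rule leaves no measurable grid column")
    return float(retained.mean())


def varus_angle_for_opening(spec: PhantomSpec, opening_mm: float,
                            exclusion_fraction: float = 0.10) -> float:
    """Hinge angle (deg) whose mean gap increase over the retained lateral
    measurement region equals ``opening_mm``."""
    lever = retained_centroid_x(spec, exclusion_fraction) - spec.hinge_x
    if lever <= 0:
        raise ParameterError("hinge must lie medial of the measurement region")
    return math.degrees(math.atan2(opening_mm, lever))


def generate_study(design: StudyDesign, base: PhantomSpec):
    """Generate the full synthetic study: one volume per specimen x condition
    x configuration, plus the ground-truth intended-gap table.

    Returns ``(volumes, truth)`` where ``volumes`` maps
    ``(specimen, condition, configuration)`` to a LabelVolume and ``truth``
    is a long-format DataFrame with the injected gap structure.
    """
    rng = np.random.default_rng(design.seed)
    volumes: dict[tuple[str, str, str], LabelVolume] = {}
    rows = []
    for s in range(design.n_specimens):
        sid = f"S{s + 1:02d}"
        g_s = base.gap_mm + rng.normal(0.0, design.noise_sd_mm)
        g_s = max(g_s, 1.0)
        for c, cond in enumerate(design.conditions):
            for config in design.configurations:
                jitter = rng.normal(0.0, design.measurement_noise_mm)
                if config == "UL":
                    gap = g_s + design.unloaded_drift_mm[c] + jitter
                    spec_v = replace(base, gap_mm=gap, varus_angle_deg=0.0)
                    opening = 0.0
                else:
                    gap = g_s + jitter
                    opening = design.load_effect_mm + design.opening_increment_mm[c]
                    angle = varus_angle_for_opening(base, opening)
                    spec_v = replace(base, gap_mm=gap, varus_angle_deg=angle)
                vol = generate_knee_like(spec_v)
                vol.meta["provenance"] = {"specimen": sid, "condition": cond,
                                          "configuration": config}
                volumes[(sid, cond, config)] = vol
                rows.append({"specimen": sid, "condition": cond,
                             "configuration": config,
                             "true_base_gap_mm": gap,
                             "true_opening_mm": opening,
                             "true_mean_gap_mm": gap + opening})
    truth = pd.DataFrame(rows)
    return volumes, truth
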