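"""Grid-based subchondral cortical distance (SCD) measurements.

The measurement grid is a regular lattice (defaults 3.5 mm mediolateral x
3.3 mm anteroposterior) laid over the *baseline* (intact, unloaded) lateral
condyle footprint and centered in its bounding box. The same grid — same
points, same exclusion mask — is reused for every other condition and
configuration of the specimen, so per-point values are longitudinally
comparable without any image registration (the tibia is the fixed body of
the joint frame).

Grid points over the lateralmost 10% of the femur's transepicondylar
diameter are excluded up front: the epicondylar flank curves away from the
joint line and would produce spuriously large vertical distances.

Six manual-measurement analogs are provided: three mediolateral sites on the
mid-coronal line at 25/50/75% of the ML extent from the lateral edge
(ml1..ml3, lateral to medial) and three anteroposterior sites on the
mid-sagittal line at 25/50/75% of the AP extent from the anterior edge
(ap1..ap3, anterior to posterior). The AP sites are fractional-position
proxies for the meniscus landmarks a radiologist would use (no meniscus is
segmented here).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .errors import MeasurementDomainError
from .frame import JointFrame, TransepicondylarResult
from .surfaces import SurfaceField

SPACING_ML_MM = 3.5
SPACING_AP_MM = 3.3
EXCLUSION_FRACTION = 0.10

REASON_LATERAL = "lateral-10%"
REASON_INVALID = "invalid-column"

SITE_NAMES = ("ml1", "ml2", "ml3", "ap1", "ap2", "ap3")


@dataclass
class MeasurementGrid:
    """Regular measurement lattice anchored to the baseline footprint."""

    xs: np.ndarray              # (n_ml,) frame mm
    ys: np.ndarray              # (n_ap,)
    spacing_ml: float
    spacing_ap: float
    retained: np.ndarray        # (n_ml, n_ap) bool
    reasons: np.ndarray         # (n_ml, n_ap) object, '' when retained
    anchor_box: tuple[float, float, float, float]  # x0, x1, y0, y1

    @property
    def n_points(self) -> int:
        return self.xs.size * self.ys.size

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    def points(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.xs, self.ys, indexing="ij")

    def copy(self) -> "MeasurementGrid":
        return MeasurementGrid(self.xs.copy(), self.ys.copy(),
                               self.spacing_ml, self.spacing_ap,
                               self.retained.copy(), self.reasons.copy(),
                               self.anchor_box)


@dataclass
class SCDMap:
    """Per-grid-point SCD values (mm) for one specimen/condition/configuration."""

    grid: MeasurementGrid
    values: np.ndarray          # (n_ml, n_ap), NaN at masked points
    retained: np.ndarray        # bool, subset of grid.retained
    reasons: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    def to_table(self) -> pd.DataFrame:
        gx, gy = self.grid.points()
        df = pd.DataFrame({
            "x": gx.ravel(), "y": gy.ravel(),
            "scd_mm": self.values.ravel(),
            "retained": self.retained.ravel(),
            "mask_reason": self.reasons.ravel(),
        })
        for k, v in self.provenance.items():
            df[k] = v
        return df


@dataclass
class ManualSites:
    """The six named manual-measurement locations in frame coordinates."""

    coords: dict[str, tuple[float, float]]


def build_grid(baseline_surfaces: SurfaceField,
               spacing_ap: float = SPACING_AP_MM,
               spacing_ml: float = SPACING_ML_MM) -> MeasurementGrid:
    """Lay the regular grid over the baseline lateral-condyle bounding box.

    Per axis the point count is floor(extent / spacing) + 1 and the lattice
    is centered so the box margins are symmetric. Rebuilt from the same
    baseline, the grid is bit-identical (anchor stability).
    """
    fp = baseline_surfaces.footprint
    if not fp.any():
        raise MeasurementDomainError("baseline footprint is empty")
    xs_fp = baseline_surfaces.xs[fp.any(axis=1)]
    ys_fp = baseline_surfaces.ys[fp.any(axis=0)]
    x0, x1 = float(xs_fp.min()), float(xs_fp.max())
    y0, y1 = float(ys_fp.min()), float(ys_fp.max())

    def axis_points(lo, hi, spacing):
        extent = hi - lo
        n = int(np.floor(extent / spacing + 1e-9)) + 1
        start = lo + (extent - (n - 1) * spacing) / 2.0
        return start + np.arange(n) * spacing

    gx = axis_points(x0, x1, spacing_ml)
    gy = axis_points(y0, y1, spacing_ap)
    if gx.size == 1 or gy.size == 1:
        warnings.warn("footprint smaller than one grid spacing; "
                      "grid degenerates to a single row/point", stacklevel=2)
    shape = (gx.size, gy.size)
    return MeasurementGrid(xs=gx, ys=gy, spacing_ml=spacing_ml,
                           spacing_ap=spacing_ap,
                           retained=np.ones(shape, dtype=bool),
                           reasons=np.full(shape, "", dtype=object),
                           anchor_box=(x0, x1, y0, y1))


def apply_lateral_exclusion(grid: MeasurementGrid,
                            te: TransepicondylarResult,
                            fraction: float = EXCLUSION_FRACTION) -> MeasurementGrid:
    """Mask grid points over the lateralmost ``fraction`` of the femur's
    transepicondylar diameter. Other masks are left untouched."""
    if te.diameter_mm <= 0:
        raise ValueError("transepicondylar diameter must be positive")
    out = grid.copy()
    cut = te.lateral_extreme_mm - fraction * te.diameter_mm
    lateral = out.xs > cut
    sel = lateral[:, None] & out.retained
    out.retained[sel] = False
    out.reasons[sel] = REASON_LATERAL
    return out


def _interpolators(surfaces: SurfaceField, method: str = "linear"):
    kw = dict(method=method, bounds_error=False, fill_value=np.nan)
    f_masked = np.where(surfaces.valid, surfaces.femur_height, np.nan)
    t_masked = np.where(surfaces.valid, surfaces.tibia_height, np.nan)
    it = RegularGridInterpolator((surfaces.xs, surfaces.ys), t_masked, **kw)
    if_ = RegularGridInterpolator((surfaces.xs, surfaces.ys), f_masked, **kw)
    return it, if_


def compute_scd_map(surfaces: SurfaceField, grid: MeasurementGrid,
                    provenance: dict | None = None,
                    method: str = "linear") -> SCDMap:
    """Sample f - t at every retained grid point (bilinear by default;
    ``method='nearest'`` snaps to the nearest column for sensitivity checks).

    A point whose interpolation stencil touches an invalid column is masked
    with reason 'invalid-column'. All retained values are >= 0.
    """
    it, if_ = _interpolators(surfaces, method=method)
    gx, gy = grid.points()
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    t = it(pts).reshape(gx.shape)
    f = if_(pts).reshape(gx.shape)
    scd = f - t

    retained = grid.retained & ~np.isnan(scd)
    reasons = grid.reasons.copy()
    newly = grid.retained & np.isnan(scd)
    reasons[newly] = REASON_INVALID
    if not retained.any():
        raise MeasurementDomainError("every grid point falls on an invalid column")
    values = np.where(retained, np.maximum(scd, 0.0), np.nan)
    return SCDMap(grid=grid, values=values, retained=retained,
                  reasons=reasons, provenance=dict(provenance or {}))


def scd_compmean(scd_map: SCDMap) -> float:
    """Mean SCD over all retained grid points (the per-joint summary)."""
    if scd_map.n_retained == 0:
        raise MeasurementDomainError("SCD map has no retained points")
    return float(np.nanmean(scd_map.values[scd_map.retained]))


def manual_sites(surfaces: SurfaceField) -> ManualSites:
    """Place the six manual-measurement sites on the lateral footprint.

    ml1..ml3 sit on the mid-coronal (constant-y) line at 25/50/75% of the ML
    extent from the *lateral* (+x) edge; ap1..ap3 on the mid-sagittal
    (constant-x) line at 25/50/75% of the AP extent from the anterior (+y)
    edge.
    """
    fp = surfaces.footprint
    if not fp.any():
        raise MeasurementDomainError("empty footprint")
    xs_fp = surfaces.xs[fp.any(axis=1)]
    ys_fp = surfaces.ys[fp.any(axis=0)]
    x0, x1 = float(xs_fp.min()), float(xs_fp.max())
    y0, y1 = float(ys_fp.min()), float(ys_fp.max())
    ymid = (y0 + y1) / 2.0
    xmid = (x0 + x1) / 2.0
    ext_x, ext_y = x1 - x0, y1 - y0
    coords = {
        "ml1": (x1 - 0.25 * ext_x, ymid),
        "ml2": (x1 - 0.50 * ext_x, ymid),
        "ml3": (x1 - 0.75 * ext_x, ymid),
        "ap1": (xmid, y1 - 0.25 * ext_y),
        "ap2": (xmid, y1 - 0.50 * ext_y),
        "ap3": (xmid, y1 - 0.75 * ext_y),
    }
    return ManualSites(coords=coords)


def manual_site_scd(surfaces: SurfaceField,
                    frame: JointFrame | None = None) -> tuple[dict, float, ManualSites]:
    """SCD at the six manual sites plus their mean (the manmean analog).

    Sites landing on invalid columns fall back to the nearest valid column
    and are flagged in the returned dict as ``<site>_flagged``.
    """
    sites = manual_sites(surfaces)
    it, if_ = _interpolators(surfaces)
    values: dict[str, float] = {}
    gxx, gyy = np.meshgrid(surfaces.xs, surfaces.ys, indexing="ij")
    vx = gxx[surfaces.valid]
    vy = gyy[surfaces.valid]
    vt = surfaces.tibia_height[surfaces.valid]
    vf = surfaces.femur_height[surfaces.valid]
    for name, (x, y) in sites.coords.items():
        t = float(it([[x, y]])[0])
        f = float(if_([[x, y]])[0])
        if np.isnan(t) or np.isnan(f):
            d2 = (vx - x) ** 2 + (vy - y) ** 2
            k = int(np.argmin(d2))
            t, f = float(vt[k]), float(vf[k])
            values[f"{name}_flagged"] = True
        values[name] = max(f - t, 0.0)
    mean = float(np.mean([values[n] for n in SITE_NAMES]))
    return values, mean, sites


def nearest_grid_to_sites(grid: MeasurementGrid,
                          sites: ManualSites) -> dict[str, dict]:
    """Retained grid point closest to each manual site (Euclidean), ties
    broken toward smaller x then smaller y."""
    if grid.n_retained == 0:
        raise MeasurementDomainError("grid has no retained points")
    gx, gy = grid.points()
    px = gx[grid.retained]
    py = gy[grid.retained]
    mapping: dict[str, dict] = {}
    for name, (x, y) in sites.coords.items():
        d2 = (px - x) ** 2 + (py - y) ** 2
        best = np.min(d2)
        tied = np.flatnonzero(d2 <= best + 1e-12)
        # deterministic tie-break: smallest x, then smallest y
        order = np.lexsort((py[tied], px[tied]))
        k = tied[order[0]]
        mapping[name] = {"x": float(px[k]), "y": float(py[k]),
                         "distance_mm": float(np.sqrt(d2[k]))}
    return mapping
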