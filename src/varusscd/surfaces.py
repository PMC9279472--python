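"""Opposing subchondral surface height fields over the lateral compartment.

For every (x, y) column of the joint frame, the tibial height ``t`` is the
top of the highest lateral-tibial voxel and the femoral height ``f`` is the
bottom of the lowest femoral voxel *above* the tibia (so posterior femoral
cortex below the joint line can never capture a column). Surface positions
are taken at voxel boundaries — half a voxel beyond the extreme voxel
centers — so parallel plates separated by a whole number of voxels measure
their exact nominal gap.

The vertical distance f - t is the subchondral cortical distance (SCD): it
deliberately spans cartilage plus joint space, mirroring how joint-space
width is read off radiographs.

Columns on unsegmented coronal slices (interslice gaps of a 2D acquisition)
are filled by linear interpolation along y from the nearest segmented
slices and flagged as interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MeasurementDomainError
from .frame import JointFrame
from .volume_io import FEMUR, LATERAL_TIBIA, LabelVolume


@dataclass
class SurfaceField:
    """Paired femoral/tibial height fields on a regular frame-(x, y) raster.

    ``tibia_height[i, j]`` / ``femur_height[i, j]`` are frame-z surface
    positions (mm) of the column centered at ``(xs[i], ys[j])``; NaN where a
    surface is absent. ``valid`` marks columns with both surfaces;
    ``interpolated`` marks columns bridged across interslice gaps.
    """

    xs: np.ndarray
    ys: np.ndarray
    tibia_height: np.ndarray
    femur_height: np.ndarray
    valid: np.ndarray
    interpolated: np.ndarray
    cell_mm: tuple[float, float]

    @property
    def footprint(self) -> np.ndarray:
        """Cells over the lateral tibial condyle (tibial surface present)."""
        return ~np.isnan(self.tibia_height)

    def to_table(self) -> pd.DataFrame:
        gx, gy = np.meshgrid(self.xs, self.ys, indexing="ij")
        return pd.DataFrame({
            "x": gx.ravel(), "y": gy.ravel(),
            "t": self.tibia_height.ravel(), "f": self.femur_height.ravel(),
            "valid": self.valid.ravel(),
            "interpolated": self.interpolated.ravel(),
        })


def _bin_extreme(qxy, qz, x0, y0, nx, ny, cell, mode) -> np.ndarray:
    """Per-raster-cell max (mode=+1) or min (mode=-1) of qz."""
    ix = np.round((qxy[:, 0] - x0) / cell[0]).astype(int)
    iy = np.round((qxy[:, 1] - y0) / cell[1]).astype(int)
    keep = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    ix, iy, qz = ix[keep], iy[keep], qz[keep]
    out = np.full((nx, ny), -np.inf if mode > 0 else np.inf)
    flat = ix * ny + iy
    if mode > 0:
        np.maximum.at(out.ravel(), flat, qz)
    else:
        np.minimum.at(out.ravel(), flat, qz)
    out[~np.isfinite(out)] = np.nan
    return out


def _fill_slice_gaps(height: np.ndarray, empty_rows: np.ndarray) -> np.ndarray:
    """Linear interpolation along y across globally empty rows."""
    filled = height.copy()
    ny = height.shape[1]
    segmented = np.flatnonzero(~empty_rows)
    for j in np.flatnonzero(empty_rows):
        lo = segmented[segmented < j]
        hi = segmented[segmented > j]
        if lo.size == 0 or hi.size == 0:
            continue  # gap at the margin: nothing to bridge
        j0, j1 = lo[-1], hi[0]
        w = (j - j0) / (j1 - j0)
        both = ~np.isnan(height[:, j0]) & ~np.isnan(height[:, j1])
        filled[both, j] = (1 - w) * height[both, j0] + w * height[both, j1]
    return filled


def extract_surfaces(volume: LabelVolume, frame: JointFrame) -> SurfaceField:
    """Extract the lateral-compartment height fields in frame coordinates.

    Voxel centers are mapped into the frame and binned onto a raster at the
    volume's in-plane spacing over the lateral tibial footprint; per column,
    t = highest lateral-tibia center (+dz/2), f = lowest femoral center above
    the tibia (-dz/2).
    """
    sx, sy, dz = volume.spacing_mm
    tib_pts = frame.to_frame(volume.label_points(LATERAL_TIBIA))
    fem_pts = frame.to_frame(volume.label_points(FEMUR))
    if tib_pts.shape[0] == 0:
        raise MeasurementDomainError("no lateral tibia voxels")

    # anchor the raster on the transformed voxel centers so that, for a
    # near-axis-aligned frame, every center lands on a cell center exactly
    x0 = float(min(tib_pts[:, 0].min(),
                   fem_pts[:, 0].min() if fem_pts.size else np.inf))
    y0 = float(tib_pts[:, 1].min())
    x1 = tib_pts[:, 0].max()
    y1 = tib_pts[:, 1].max()
    nx = int(np.round((x1 - x0) / sx)) + 1
    ny = int(np.round((y1 - y0) / sy)) + 1
    xs = x0 + np.arange(nx) * sx
    ys = y0 + np.arange(ny) * sy

    t = _bin_extreme(tib_pts[:, :2], tib_pts[:, 2], x0, y0, nx, ny, (sx, sy), +1)

    # femur restricted to strictly above the tibial surface in its column
    f = np.full((nx, ny), np.nan)
    if fem_pts.shape[0]:
        ix = np.round((fem_pts[:, 0] - x0) / sx).astype(int)
        iy = np.round((fem_pts[:, 1] - y0) / sy).astype(int)
        keep = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        ix, iy, fz = ix[keep], iy[keep], fem_pts[keep, 2]
        t_here = t[ix, iy]
        above = ~np.isnan(t_here) & (fz > t_here + 1e-9)
        f = _bin_extreme(np.column_stack([ix[above] * sx + x0, iy[above] * sy + y0]),
                         fz[above], x0, y0, nx, ny, (sx, sy), -1)

    # surfaces at voxel boundaries
    t = t + dz / 2.0
    f = f - dz / 2.0

    # bridge interslice gaps: rows with no tibia anywhere, between segmented rows
    empty_rows = np.isnan(t).all(axis=0)
    interpolated = np.zeros_like(t, dtype=bool)
    if empty_rows.any() and not empty_rows.all():
        t_f = _fill_slice_gaps(t, empty_rows)
        f_f = _fill_slice_gaps(f, empty_rows)
        interpolated = np.isnan(t) & ~np.isnan(t_f)
        t, f = t_f, f_f

    valid = ~np.isnan(t) & ~np.isnan(f)
    if not valid.any():
        raise MeasurementDomainError(
            "no column has both a tibial and a femoral surface")
    bad = valid & (f < t - 1e-6)
    if bad.any():
        raise MeasurementDomainError(
            f"{int(bad.sum())} columns show femur below tibia (interpenetration)")
    return SurfaceField(xs=xs, ys=ys, tibia_height=t, femur_height=f,
                        valid=valid, interpolated=interpolated, cell_mm=(sx, sy))
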