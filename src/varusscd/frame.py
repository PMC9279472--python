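"""Joint-specific Cartesian coordinate frames.

Each segmented joint is measured in its own right-handed frame: z runs
craniocaudally along the tibial long axis (first principal component of the
tibial voxel cloud), x mediolaterally (+x lateral), y anteroposteriorly
(y = z cross x). The origin sits at the centroid of the lateral tibial
condyle's top surface, so grid coordinates are comparable across the
conditions and configurations of one specimen.

The transepicondylar measurement — the femur's maximum extent along the
frame's ML axis over its distal portion — feeds the lateral grid-exclusion
rule (the lateralmost 10% of that diameter is dropped to keep measurements
off the curved epicondylar flank).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import FrameError, ValidationError
from .volume_io import FEMUR, LATERAL_TIBIA, MEDIAL_TIBIA, LabelVolume

#: eigenvalue ratio below which the tibial principal axis is ambiguous
DEGENERACY_RATIO = 1.05
#: fraction of the femur's z range (from its distal end) holding the epicondyles
DISTAL_FEMUR_FRACTION = 0.40


@dataclass(frozen=True)
class JointFrame:
    """Right-handed orthonormal joint frame (axes are rows of a rotation)."""

    origin_mm: np.ndarray
    x_axis: np.ndarray  # mediolateral, +x lateral
    y_axis: np.ndarray  # anteroposterior
    z_axis: np.ndarray  # craniocaudal, along the tibial axis

    @property
    def rotation(self) -> np.ndarray:
        """World->frame rotation matrix (rows = frame axes in world coords)."""
        return np.stack([self.x_axis, self.y_axis, self.z_axis])

    def to_frame(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world-mm points (N, 3) into frame coordinates."""
        return (np.atleast_2d(points_mm) - self.origin_mm) @ self.rotation.T

    def to_world(self, points_frame: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points_frame) @ self.rotation + self.origin_mm

    def validate(self) -> None:
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise FrameError("frame axes are not orthonormal")
        if np.linalg.det(R) < 0:
            raise FrameError("frame is left-handed")

    def as_dict(self) -> dict:
        return {"origin_mm": self.origin_mm.tolist(),
                "x_axis": self.x_axis.tolist(),
                "y_axis": self.y_axis.tolist(),
                "z_axis": self.z_axis.tolist()}


@dataclass(frozen=True)
class TransepicondylarResult:
    """Femoral ML extent along the frame's x axis over the distal femur."""

    axis_direction: np.ndarray
    diameter_mm: float
    lateral_extreme_mm: float   # frame-x of the lateralmost distal femur voxel
    medial_extreme_mm: float
    n_components: int = 1


def tibial_axis(volume: LabelVolume) -> np.ndarray:
    """Unit vector of the tibial long axis: the largest-variance principal
    direction of the combined medial+lateral tibial voxel cloud, oriented
    toward the scanner's +z.

    Warns (does not fail) when the leading two eigenvalues are within
    ``DEGENERACY_RATIO`` of each other — a symmetric phantom tie case.
    """
    tib = (volume.voxels == MEDIAL_TIBIA) | (volume.voxels == LATERAL_TIBIA)
    pts = volume.coords_of(np.argwhere(tib))
    if pts.shape[0] < 3:
        raise FrameError("tibia has fewer than 3 voxels")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / pts.shape[0]
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[0] < 1e-9 * max(evals[2], 1e-12):
        raise FrameError("tibial voxel cloud is planar or collinear; "
                         "no well-defined bone axis")
    if evals[2] / evals[1] < DEGENERACY_RATIO:
        warnings.warn("tibial principal axis is near-degenerate "
                      f"(eigenvalue ratio {evals[2] / evals[1]:.3f})",
                      stacklevel=2)
    axis = evecs[:, 2]
    if axis[2] < 0:
        axis = -axis
    return axis


def build_frame(volume: LabelVolume, laterality: str = "left") -> JointFrame:
    """Construct the joint frame from a segmented volume.

    z: tibial principal axis; x: scanner ML axis orthogonalized against z,
    sign chosen so +x points lateral (for the ``laterality`` given, with the
    package's phantoms and left knees lateral = +scanner-x); y = z cross x.
    Origin: centroid of the lateral condyle's top-surface voxels.
    """
    if laterality not in ("left", "right"):
        raise ValueError(f"laterality must be 'left' or 'right', got {laterality!r}")
    z = tibial_axis(volume)
    ml = np.array([1.0, 0.0, 0.0])
    x = ml - (ml @ z) * z
    nrm = np.linalg.norm(x)
    if nrm < 1e-6:
        raise FrameError("tibial axis is parallel to the scanner ML axis")
    x = x / nrm
    if laterality == "right":
        x = -x
    y = np.cross(z, x)

    lat = volume.voxels == LATERAL_TIBIA
    if not lat.any():
        raise ValidationError("volume has no lateral tibia label")
    # top surface: per (i, j) column, the highest lateral-tibia voxel
    nz = volume.voxels.shape[2]
    has = lat.any(axis=2)
    top_k = nz - 1 - np.argmax(lat[:, :, ::-1], axis=2)
    ii, jj = np.nonzero(has)
    idx = np.column_stack([ii, jj, top_k[ii, jj]])
    origin = volume.coords_of(idx).mean(axis=0)

    fr = JointFrame(origin_mm=origin, x_axis=x, y_axis=y, z_axis=z)
    fr.validate()
    return fr


def transepicondylar_axis(volume: LabelVolume,
                          frame: JointFrame) -> TransepicondylarResult:
    """Femoral maximum diameter along the frame ML axis, distal femur only.

    The epicondyles live in the distal ``DISTAL_FEMUR_FRACTION`` of the femur
    (by frame z); restricting to it keeps the shaft out of the measurement.
    Disconnected femur labels are measured jointly but flagged with a warning.
    """
    fem_idx = np.argwhere(volume.voxels == FEMUR)
    if fem_idx.shape[0] == 0:
        raise ValidationError("volume has no femur label")
    pts = frame.to_frame(volume.coords_of(fem_idx))
    zmin, zmax = pts[:, 2].min(), pts[:, 2].max()
    distal = pts[pts[:, 2] <= zmin + DISTAL_FEMUR_FRACTION * (zmax - zmin)]
    xs = distal[:, 0]
    diameter = float(xs.max() - xs.min())

    from scipy import ndimage
    _, n_comp = ndimage.label(volume.voxels == FEMUR)
    if n_comp > 1:
        warnings.warn(f"femur label has {n_comp} disconnected components; "
                      "diameter measured across all of them", stacklevel=2)
    return TransepicondylarResult(axis_direction=frame.x_axis,
                                  diameter_mm=diameter,
                                  lateral_extreme_mm=float(xs.max()),
                                  medial_extreme_mm=float(xs.min()),
                                  n_components=int(n_comp))
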