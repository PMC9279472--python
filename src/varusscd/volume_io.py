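"""Reading, writing and outline extraction for multi-label segmentation volumes.

A :class:`LabelVolume` is the package's in-memory form of a manually segmented
knee: a 3D integer array with one label per voxel (0 background, 1 femur,
2 medial tibia, 3 lateral tibia), millimetre voxel spacing, and a world origin.
Array axes are, in order, mediolateral (x), anteroposterior (y) and
craniocaudal (z); files whose headers encode a different orientation are
reoriented to this canonical order at load time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: canonical label integers
BACKGROUND, FEMUR, MEDIAL_TIBIA, LATERAL_TIBIA = 0, 1, 2, 3

DEFAULT_LABEL_MAP = {1: "femur", 2: "medial_tibia", 3: "lateral_tibia"}
ROLE_TO_LABEL = {"femur": FEMUR, "medial_tibia": MEDIAL_TIBIA,
                 "lateral_tibia": LATERAL_TIBIA}
#: roles that must be present for downstream measurement
REQUIRED_ROLES = ("femur", "lateral_tibia")


@dataclass
class LabelVolume:
    """Multi-label segmentation volume on a regular voxel grid.

    ``voxels[i, j, k]`` is the label of the voxel whose *center* sits at
    ``origin_mm + (i, j, k) * spacing_mm`` (world mm, axes ML/AP/CC).
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_codes: tuple[str, str, str] = ("R", "A", "S")
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise FormatError(f"expected a 3D volume, got {self.voxels.ndim}D")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise FormatError(f"expected integer labels, got {self.voxels.dtype}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValidationError(f"voxel spacing must be positive, got {self.spacing_mm}")

    # -- coordinate helpers -------------------------------------------------
    def axis_coords(self, axis: int) -> np.ndarray:
        """World-mm coordinates of voxel centers along one array axis."""
        n = self.voxels.shape[axis]
        return self.origin_mm[axis] + np.arange(n) * self.spacing_mm[axis]

    def coords_of(self, idx: np.ndarray) -> np.ndarray:
        """World-mm centers of an (N, 3) array of voxel indices."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin_mm) + idx * np.asarray(self.spacing_mm)

    def label_points(self, label: int) -> np.ndarray:
        """(N, 3) world-mm centers of all voxels carrying ``label``."""
        return self.coords_of(np.argwhere(self.voxels == label))

    def validate(self) -> None:
        present = set(np.unique(self.voxels).tolist())
        for role in REQUIRED_ROLES:
            if ROLE_TO_LABEL[role] not in present:
                raise ValidationError(f"volume has no voxels for required role {role!r}")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing_mm)
        aff[:3, 3] = self.origin_mm
        return aff


def read_labels(path, label_map: dict[int, str] | None = None) -> LabelVolume:
    """Load a NIfTI label volume, reorient to canonical ML/AP/CC axis order.

    ``label_map`` maps file label integers to roles ('femur', 'medial_tibia',
    'lateral_tibia'); integers outside the map are reported once via a warning
    and treated as background.
    """
    label_map = dict(label_map or DEFAULT_LABEL_MAP)
    img = nib.load(str(path))
    if img.ndim != 3:
        raise FormatError(f"{path}: expected 3D volume, got {img.ndim}D")
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if np.allclose(data, np.round(data)):
            data = np.round(data).astype(np.int16)
        else:
            raise FormatError(f"{path}: voxel values are not integer labels")

    known = set(label_map) | {BACKGROUND}
    present = set(np.unique(data).tolist())
    stray = sorted(present - known)
    if stray:
        warnings.warn(f"{path}: unknown labels {stray} treated as background",
                      stacklevel=2)
    # remap file integers onto the canonical {1,2,3}, stray -> 0
    out = np.zeros_like(data, dtype=np.int16)
    for file_label, role in label_map.items():
        out[data == file_label] = ROLE_TO_LABEL[role]

    aff = img.affine
    spacing = tuple(float(s) for s in nib.affines.voxel_sizes(aff))
    origin = tuple(float(o) for o in aff[:3, 3])
    vol = LabelVolume(out, spacing, origin,
                      axis_codes=tuple(nib.orientations.aff2axcodes(aff)))
    vol.validate()
    return vol


def write_labels(volume: LabelVolume, path) -> None:
    """Write a LabelVolume as NIfTI so that ``read_labels`` round-trips it."""
    img = nib.Nifti1Image(volume.voxels.astype(np.int16), volume.affine)
    try:
        nib.save(img, str(path))
    except OSError as exc:  # surface the offending path
        raise OSError(f"failed to write label volume to {path}: {exc}") from exc


# -- outlines ---------------------------------------------------------------

def boundary_mask(label_mask: np.ndarray) -> np.ndarray:
    """Voxels of a binary mask with >= 1 face neighbor outside the mask.

    Face connectivity (6-neighborhood); volume borders count as outside.
    """
    padded = np.pad(label_mask, 1, constant_values=False)
    interior = np.ones_like(label_mask, dtype=bool)
    for axis in range(3):
        lo = np.take(padded, range(0, label_mask.shape[axis]), axis=axis)
        hi = np.take(padded, range(2, label_mask.shape[axis] + 2), axis=axis)
        # crop the padding on the other two axes
        sl = [slice(1, -1)] * 3
        sl[axis] = slice(None)
        interior &= lo[tuple(sl)] & hi[tuple(sl)]
    return label_mask & ~interior


def extract_outlines(volume: LabelVolume) -> pd.DataFrame:
    """Per-coronal-slice boundary voxels of every label, in world mm.

    Returns a tidy frame with columns (slice, label, x, y, z): one row per
    boundary voxel, where ``slice`` is the coronal (AP) slice index. A label
    absent from a slice simply contributes no rows.
    """
    rows = []
    for label in (FEMUR, MEDIAL_TIBIA, LATERAL_TIBIA):
        mask = volume.voxels == label
        if not mask.any():
            continue
        edge = boundary_mask(mask)
        idx = np.argwhere(edge)
        pts = volume.coords_of(idx)
        rows.append(pd.DataFrame({
            "slice": idx[:, 1], "label": label,
            "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2],
        }))
    if not rows:
        return pd.DataFrame(columns=["slice", "label", "x", "y", "z"])
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["label", "slice", "x", "z"], kind="stable",
                           ignore_index=True)
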