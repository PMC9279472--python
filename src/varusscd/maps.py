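"""Loading-difference maps of the lateral compartment.

For each condition, the per-grid-point |SCD_loaded - SCD_unloaded| shows
*where* the compartment opens under varus load; averaged across specimens it
is the study's heat-map figure. Because every map of a specimen shares the
baseline-anchored grid, differences are computed point-by-point on the
intersection of retained points with no resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PairingError
from .scd import MeasurementGrid, SCDMap


@dataclass
class DifferenceMap:
    """Per-point SCD difference (mm) between two configurations.

    ``values`` holds |loaded - unloaded| (or the signed difference when
    ``signed=True``), NaN off the retained intersection.
    """

    grid: MeasurementGrid
    values: np.ndarray
    retained: np.ndarray
    condition: str
    provenance: str = "specimen"
    signed: bool = False
    support: np.ndarray | None = None  # specimen count per point, for averages

    def to_table(self) -> pd.DataFrame:
        gx, gy = self.grid.points()
        df = pd.DataFrame({
            "x": gx.ravel(), "y": gy.ravel(),
            "diff_mm": self.values.ravel(),
            "retained": self.retained.ravel(),
        })
        df["condition"] = self.condition
        df["provenance"] = self.provenance
        return df


def _same_grid(a: MeasurementGrid, b: MeasurementGrid) -> bool:
    return (a.xs.shape == b.xs.shape and a.ys.shape == b.ys.shape
            and np.allclose(a.xs, b.xs) and np.allclose(a.ys, b.ys))


def difference_map(loaded: SCDMap, unloaded: SCDMap,
                   signed: bool = False) -> DifferenceMap:
    """Per-point (absolute) loaded-vs-unloaded SCD difference.

    Both maps must come from the same specimen and condition and share the
    baseline grid; points retained in only one configuration are dropped.
    """
    if not _same_grid(loaded.grid, unloaded.grid):
        raise PairingError("loaded and unloaded maps use different grids")
    for key in ("specimen", "condition"):
        a = loaded.provenance.get(key)
        b = unloaded.provenance.get(key)
        if a is not None and b is not None and a != b:
            raise PairingError(f"maps disagree on {key}: {a!r} vs {b!r}")
    retained = loaded.retained & unloaded.retained
    diff = loaded.values - unloaded.values
    if not signed:
        diff = np.abs(diff)
    values = np.where(retained, diff, np.nan)
    return DifferenceMap(grid=loaded.grid, values=values, retained=retained,
                         condition=str(loaded.provenance.get("condition", "")),
                         provenance=str(loaded.provenance.get("specimen", "")),
                         signed=signed)


def average_maps(diff_maps: list[DifferenceMap], condition: str | None = None,
                 min_support: float = 0.5) -> DifferenceMap:
    """Point-wise mean across specimens.

    Points missing in some specimens are averaged over the available ones,
    but only where at least ``min_support`` of the specimens contribute.
    """
    if not diff_maps:
        raise PairingError("no maps to average")
    first = diff_maps[0]
    for m in diff_maps[1:]:
        if not _same_grid(m.grid, first.grid):
            raise PairingError("maps share no common grid topology")
        if condition is None and m.condition != first.condition:
            raise PairingError("maps mix conditions; pass condition explicitly")
    stack = np.stack([m.values for m in diff_maps])
    support = np.sum(~np.isnan(stack), axis=0)
    need = max(1, int(np.ceil(min_support * len(diff_maps))))
    retained = support >= need
    total = np.nansum(stack, axis=0)
    mean = np.where(retained, total / np.maximum(support, 1), np.nan)
    return DifferenceMap(grid=first.grid, values=mean, retained=retained,
                         condition=condition or first.condition,
                         provenance="mean-of-specimens",
                         signed=first.signed, support=support)


def render_heatmap(diff_map: DifferenceMap, path, vmax: float | None = None,
                   vmin: float = 0.0) -> pd.DataFrame:
    """Write the heat map as PNG (axial x-y layout, ML on the horizontal
    axis, anterior up) plus the underlying CSV grid next to it.

    Returns the CSV table. Color limits default to 0..data max.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = str(path)
    if diff_map.retained.sum() == 0:
        raise PairingError("cannot render an empty difference map")
    data = diff_map.values.T  # rows = y (AP), cols = x (ML)
    if vmax is None:
        vmax = float(np.nanmax(data))
        if vmax <= vmin:
            vmax = vmin + 1e-6
    fig, ax = plt.subplots(figsize=(5, 4))
    extent = (diff_map.grid.xs[0], diff_map.grid.xs[-1],
              diff_map.grid.ys[0], diff_map.grid.ys[-1])
    im = ax.imshow(data, origin="lower", extent=extent, vmin=vmin, vmax=vmax,
                   cmap="inferno", aspect="equal", interpolation="nearest")
    ax.set_xlabel("mediolateral x (mm, lateral →)")
    ax.set_ylabel("anteroposterior y (mm, anterior ↑)")
    kind = "signed" if diff_map.signed else "absolute"
    ax.set_title(f"{diff_map.condition}: {kind} loading difference "
                 f"({diff_map.provenance})")
    fig.colorbar(im, ax=ax, label="|Δ SCD| (mm)" if not diff_map.signed
                 else "Δ SCD (mm)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)

    table = diff_map.to_table()
    csv_path = path.rsplit(".", 1)[0] + ".csv"
    table.to_csv(csv_path, index=False)
    return table
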