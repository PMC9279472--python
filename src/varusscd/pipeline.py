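"""End-to-end study runs: phantom generation -> measurement -> maps -> stats.

A :class:`RunConfig` describes either a synthetic study design or a manifest
of segmentation files on disk; :func:`run_study` turns it into a
deterministic output directory of SCD tables, loading-difference maps, heat
maps, a statistics report and a machine-readable run manifest. Reruns with
the same config and seed are value-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ValidationError
from .frame import build_frame, transepicondylar_axis
from .maps import average_maps, difference_map, render_heatmap
from .phantom import (CONDITIONS, CONFIGURATIONS, PhantomSpec, StudyDesign,
                      generate_study)
from .scd import (EXCLUSION_FRACTION, SPACING_AP_MM, SPACING_ML_MM,
                  apply_lateral_exclusion, build_grid, compute_scd_map,
                  manual_site_scd, manual_sites, nearest_grid_to_sites,
                  scd_compmean)
from .stats import (condition_contrasts, contrasts_to_frame,
                    headline_contrasts, load_table1, rm_anova,
                    validate_study_table)
from .surfaces import extract_surfaces
from .volume_io import read_labels

log = logging.getLogger("varusscd")

BASELINE = (CONDITIONS[0], CONFIGURATIONS[0])  # intact, unloaded


@dataclass
class RunConfig:
    """Everything needed to reproduce a study run.

    Exactly one of ``manifest`` (mapping "specimen|condition|configuration"
    -> volume path) or ``design`` (synthetic study) must be set. All paper
    constants — grid spacings, the 10% lateral exclusion, the condition
    order — live here as overridable defaults.
    """

    design: StudyDesign | None = None
    manifest: dict[str, str] | None = None
    base_spec: PhantomSpec = field(default_factory=PhantomSpec)
    spacing_ml_mm: float = SPACING_ML_MM
    spacing_ap_mm: float = SPACING_AP_MM
    exclusion_fraction: float = EXCLUSION_FRACTION
    interpolation: str = "linear"
    laterality: str = "left"
    output_dir: str = "varusscd_run"
    seed: int = 0
    log_level: str = "WARNING"

    def __post_init__(self):
        if (self.design is None) == (self.manifest is None):
            raise ValidationError("exactly one of design/manifest must be set")
        if not (0.0 <= self.exclusion_fraction <= 0.5):
            raise ValidationError("exclusion fraction must lie in [0, 0.5]")
        if self.spacing_ml_mm <= 0 or self.spacing_ap_mm <= 0:
            raise ValidationError("grid spacings must be positive")
        if self.interpolation not in ("linear", "nearest"):
            raise ValidationError("interpolation must be 'linear' or 'nearest'")

    # -- JSON round trip ----------------------------------------------------
    def to_json(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                d = dataclasses.asdict(obj)
                d["__type__"] = type(obj).__name__
                return d
            raise TypeError(type(obj))
        d = dataclasses.asdict(self)
        if self.design is not None:
            d["design"]["__type__"] = "StudyDesign"
        d["base_spec"]["__type__"] = "PhantomSpec"
        if math.isinf(d["base_spec"]["condyle_radius_mm"]):
            d["base_spec"]["condyle_radius_mm"] = "inf"  # JSON has no inf
        return json.dumps(d, indent=2, sort_keys=True, default=enc,
                          allow_nan=False)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)

        def mk(klass, payload):
            if payload is None:
                return None
            payload = dict(payload)
            payload.pop("__type__", None)
            if payload.get("condyle_radius_mm") == "inf":
                payload["condyle_radius_mm"] = math.inf
            for k, v in payload.items():
                if isinstance(v, list):
                    payload[k] = tuple(tuple(x) if isinstance(x, list) else x
                                       for x in v) if any(
                        isinstance(x, list) for x in v) else tuple(v)
            return klass(**payload)

        d["design"] = mk(StudyDesign, d.get("design"))
        d["base_spec"] = mk(PhantomSpec, d.get("base_spec"))
        return cls(**d)


def measure_specimen(volumes: dict[tuple[str, str], "LabelVolume"],
                     config: RunConfig, specimen: str):
    """Measure one specimen's volumes against its intact-unloaded baseline.

    The joint frame and measurement grid (including the lateral exclusion)
    are built once from the baseline and reused for every condition and
    configuration — the tibia is the fixed body, so no registration is
    needed. Returns (scd_maps, site_rows, grid, mask_log).
    """
    baseline = volumes[BASELINE]
    frame = build_frame(baseline, laterality=config.laterality)
    te = transepicondylar_axis(baseline, frame)
    surf0 = extract_surfaces(baseline, frame)
    grid = build_grid(surf0, spacing_ap=config.spacing_ap_mm,
                      spacing_ml=config.spacing_ml_mm)
    grid = apply_lateral_exclusion(grid, te, config.exclusion_fraction)

    sites = manual_sites(surf0)
    site_map = nearest_grid_to_sites(grid, sites)

    scd_maps = {}
    rows = []
    for (cond, cfg), vol in volumes.items():
        surf = extract_surfaces(vol, frame)
        prov = {"specimen": specimen, "condition": cond, "configuration": cfg}
        smap = compute_scd_map(surf, grid, provenance=prov,
                               method=config.interpolation)
        scd_maps[(cond, cfg)] = smap
        site_vals, site_mean, _ = manual_site_scd(surf)
        base_row = dict(specimen=specimen, condition=cond, configuration=cfg,
                        source="computational")
        rows.append({**base_row, "measure": "compmean",
                     "value_mm": scd_compmean(smap)})
        rows.append({**base_row, "measure": "manmean", "value_mm": site_mean})
        for name in ("ml1", "ml2", "ml3", "ap1", "ap2", "ap3"):
            rows.append({**base_row, "measure": name,
                         "value_mm": site_vals[name]})
        log.info("%s %s/%s: %d retained grid points, compmean %.2f mm",
                 specimen, cond, cfg, smap.n_retained, scd_compmean(smap))

    gx, gy = grid.points()
    mask_log = pd.DataFrame({
        "specimen": specimen, "x": gx.ravel(), "y": gy.ravel(),
        "retained": grid.retained.ravel(), "reason": grid.reasons.ravel(),
    })
    return scd_maps, rows, grid, mask_log, site_map


def _collect_volumes(config: RunConfig):
    """(volumes keyed by (specimen, condition, configuration), truth|None)."""
    if config.design is not None:
        return generate_study(config.design, config.base_spec)
    volumes = {}
    for key, path in config.manifest.items():
        spec, cond, cfg = key.split("|")
        volumes[(spec, cond, cfg)] = read_labels(path)
    return volumes, None


def run_study(config: RunConfig) -> dict:
    """Execute a full study run; returns a summary dict of output paths and
    headline numbers. See the package README for the directory layout."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    (out / "maps").mkdir(parents=True, exist_ok=True)

    volumes, truth = _collect_volumes(config)
    specimens = sorted({k[0] for k in volumes})
    conditions = list(dict.fromkeys(k[1] for k in volumes))

    all_rows, mask_logs = [], []
    diff_by_condition: dict[str, list] = {c: [] for c in conditions}
    retained_counts = []
    for sid in specimens:
        vols = {(c, g): v for (s, c, g), v in volumes.items() if s == sid}
        try:
            scd_maps, rows, grid, mask_log, _ = measure_specimen(
                vols, config, sid)
        except Exception as exc:
            raise type(exc)(f"measurement stage failed for specimen {sid}: "
                            f"{exc}") from exc
        all_rows.extend(rows)
        mask_logs.append(mask_log)
        retained_counts.append(grid.n_retained)
        for cond in conditions:
            if (cond, "LO") in scd_maps and (cond, "UL") in scd_maps:
                diff_by_condition[cond].append(
                    difference_map(scd_maps[(cond, "LO")],
                                   scd_maps[(cond, "UL")]))

    table = pd.DataFrame(all_rows)[["specimen", "condition", "configuration",
                                    "measure", "source", "value_mm"]]
    validate_study_table(table)
    table = table.sort_values(["specimen", "condition", "configuration",
                               "measure"], ignore_index=True)
    table.to_csv(out / "scd_long.csv", index=False)
    pd.concat(mask_logs, ignore_index=True).to_csv(
        out / "grid_mask_log.csv", index=False)

    heatmap_paths = []
    for cond, dmaps in diff_by_condition.items():
        if not dmaps:
            continue
        mean_map = average_maps(dmaps, condition=cond)
        safe = cond.replace("+", "-")
        png = out / "maps" / f"{safe}_abs_diff.png"
        render_heatmap(mean_map, png)
        heatmap_paths.append(str(png))

    # statistics report
    anova = rm_anova(table, "compmean")
    anova.effects.to_csv(out / "anova_compmean.csv", index=False)
    anova.posthoc.to_csv(out / "tukey_compmean.csv", index=False)
    contrasts = contrasts_to_frame(condition_contrasts(table, "compmean"))
    contrasts.to_csv(out / "contrasts_compmean.csv", index=False)
    if truth is not None:
        truth.to_csv(out / "ground_truth.csv", index=False)

    manifest = {
        "config": json.loads(config.to_json()),
        "seed": config.seed,
        "package_version": __version__,
        "python": platform.python_version(),
        "n_specimens": len(specimens),
        "retained_grid_points": {
            "mean": float(np.mean(retained_counts)),
            "sd": float(np.std(retained_counts, ddof=1)) if len(retained_counts) > 1 else 0.0,
        },
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
    return {"output_dir": str(out), "table": table, "anova": anova,
            "contrasts": contrasts, "truth": truth,
            "heatmaps": heatmap_paths,
            "retained_grid_points": manifest["retained_grid_points"]}


def reproduce_table1_contrasts(fixture: pd.DataFrame | None = None) -> pd.DataFrame:
    """The headline opening contrasts recomputed from the packaged printed
    group means: loaded condition-vs-intact openings for both measurement
    methods plus the unloaded intact-vs-fully-deficient drift (0.1 mm
    display rounding alongside full precision)."""
    df = load_table1() if fixture is None else fixture
    required = {"method", "measure", "condition", "configuration", "mean_mm"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"fixture is corrupt: columns {sorted(required - set(df.columns))} missing")
    return headline_contrasts(df)
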