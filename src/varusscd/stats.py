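"""Statistical layer of the loading study.

Long-format study tables (specimen x condition x configuration x measure)
feed three analyses mirroring how such cadaveric loading experiments are
reported:

* repeated-measures two-way ANOVA (condition x configuration, both within
  subject) with Tukey post-hoc pairwise comparisons of conditions within
  each configuration, p-values reported both uncorrected and
  Greenhouse-Geisser corrected;
* two-reader agreement via the one-way random-effects, single-measures
  intraclass correlation coefficient, ICC(1,1) ("single scorings, not
  adjusted"), with the two-way random form available as an option;
* condition-vs-intact group-mean contrasts per configuration — the
  "additional lateral compartment opening" numbers — at full precision and
  at 0.1 mm display rounding.

A packaged fixture (``data/table1_means.csv``) transcribes the printed
group means of the study's summary table so the headline contrast
arithmetic is reproducible without any imaging data.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import studentized_range

from .errors import DesignError, PairingError

STUDY_COLUMNS = ("specimen", "condition", "configuration", "measure",
                 "source", "value_mm")
SITE_MEASURES = ("ml1", "ml2", "ml3", "ap1", "ap2", "ap3")


# -- study table ------------------------------------------------------------

def validate_study_table(table: pd.DataFrame,
                         conditions: tuple[str, ...] | None = None) -> None:
    missing = [c for c in STUDY_COLUMNS if c not in table.columns]
    if missing:
        raise DesignError(f"study table lacks columns {missing}")
    keys = ["specimen", "condition", "configuration", "measure", "source"]
    dup = table.duplicated(subset=keys)
    if dup.any():
        raise DesignError(f"{int(dup.sum())} duplicate study-table keys")
    if (table["value_mm"] < 0).any():
        raise DesignError("negative SCD values in study table")
    if conditions is not None:
        bad = set(table["condition"]) - set(conditions)
        if bad:
            raise DesignError(f"unknown conditions {sorted(bad)}")


def pool_readers(reader1: pd.DataFrame, reader2: pd.DataFrame) -> pd.DataFrame:
    """Average the two readers' site measurements key-by-key and append the
    per-joint six-site mean as measure 'manmean' (source 'pooled')."""
    keys = ["specimen", "condition", "configuration", "measure"]
    a = reader1.set_index(keys)["value_mm"]
    b = reader2.set_index(keys)["value_mm"]
    only_a = a.index.difference(b.index)
    only_b = b.index.difference(a.index)
    if len(only_a) or len(only_b):
        offenders = list(only_a[:5]) + list(only_b[:5])
        raise PairingError(f"reader tables do not match; e.g. {offenders}")
    pooled = ((a + b.reindex(a.index)) / 2.0).reset_index()
    pooled["source"] = "pooled"

    sites = pooled[pooled["measure"].isin(SITE_MEASURES)]
    manmean = (sites.groupby(["specimen", "condition", "configuration"],
                             as_index=False)["value_mm"].mean())
    manmean["measure"] = "manmean"
    manmean["source"] = "pooled"
    out = pd.concat([pooled, manmean], ignore_index=True)
    return out[list(STUDY_COLUMNS)]


# -- inter-reader agreement -------------------------------------------------

@dataclass(frozen=True)
class ICCResult:
    value: float
    form: str
    n: int
    defined: bool
    note: str = ""


def icc_two_readers(reader1, reader2, form: str = "one-way") -> ICCResult:
    """Intraclass correlation between two readers' single measurements.

    ``form='one-way'`` is ICC(1,1) — one-way random effects, single
    measures, absolute agreement. ``form='two-way'`` is ICC(2,1). With zero
    total variance the coefficient is undefined and reported as such.
    """
    x = np.asarray(reader1, dtype=float)
    y = np.asarray(reader2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("readers must be equal-length 1D score vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    data = np.column_stack([x, y])  # targets x raters, k = 2
    k = 2
    grand = data.mean()
    if np.allclose(data, grand, atol=1e-12):
        return ICCResult(np.nan, form, n, defined=False,
                         note="zero total variance; ICC undefined")
    target_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    ss_targets = k * np.sum((target_means - grand) ** 2)
    ms_targets = ss_targets / (n - 1)

    if form == "one-way":
        ss_within = np.sum((data - target_means[:, None]) ** 2)
        ms_within = ss_within / (n * (k - 1))
        denom = ms_targets + (k - 1) * ms_within
        value = (ms_targets - ms_within) / denom if denom > 0 else np.nan
    elif form == "two-way":
        ss_raters = n * np.sum((rater_means - grand) ** 2)
        ms_raters = ss_raters / (k - 1)
        ss_err = (np.sum((data - grand) ** 2) - ss_targets - ss_raters)
        ms_err = ss_err / ((n - 1) * (k - 1))
        denom = (ms_targets + (k - 1) * ms_err
                 + k * (ms_raters - ms_err) / n)
        value = (ms_targets - ms_err) / denom if denom > 0 else np.nan
    else:
        raise ValueError(f"unknown ICC form {form!r}")
    return ICCResult(float(value), form, n, defined=np.isfinite(value))


def synthetic_readers(n: int, between_sd: float = 1.4,
                      within_sd: float = 0.15, mean: float = 9.0,
                      seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Two synthetic readers scoring the same targets: shared per-target
    signal (SD ``between_sd``) plus independent per-reading noise
    (SD ``within_sd``) — the variance structure behind an ICC near
    between^2 / (between^2 + within^2)."""
    rng = np.random.default_rng(seed)
    truth = mean + rng.normal(0.0, between_sd, size=n)
    r1 = truth + rng.normal(0.0, within_sd, size=n)
    r2 = truth + rng.normal(0.0, within_sd, size=n)
    return r1, r2


# -- repeated-measures ANOVA ------------------------------------------------

@dataclass
class AnovaResult:
    """Two-way within-subject ANOVA effects and Tukey post-hocs."""

    effects: pd.DataFrame       # Source, F, df1, df2, p_unc, eps_gg, p_gg
    posthoc: pd.DataFrame       # configuration, condition pairs, q, p_tukey
    n_subjects: int
    measure: str


def _gg_epsilon(cell_matrix: np.ndarray, C: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon for the effect spanned by orthonormal
    cell contrasts C (cells x df), from subjects-by-cells scores."""
    Y = cell_matrix @ C
    S = np.cov(Y, rowvar=False)
    S = np.atleast_2d(S)
    df = C.shape[1]
    tr = np.trace(S)
    denom = df * np.sum(S * S)
    if denom <= 0:
        return 1.0
    return float(min(1.0, max(1.0 / df, tr * tr / denom)))


def _effect_contrasts(k: int) -> np.ndarray:
    """Orthonormal contrasts spanning the (k-1)-dim effect space."""
    basis = np.eye(k) - 1.0 / k
    q, _ = np.linalg.qr(basis)
    return q[:, : k - 1]


def rm_anova(table: pd.DataFrame, measure: str,
             source: str | None = None) -> AnovaResult:
    """Two-way repeated-measures ANOVA of one measure across the full
    condition x configuration design, with Tukey post-hocs.

    The design must be complete and crossed: every specimen must contribute
    exactly one value per (condition, configuration) cell. Sphericity is
    handled by reporting Greenhouse-Geisser corrected p-values alongside the
    uncorrected ones (2-level factors have epsilon = 1 by construction).
    """
    df = table[table["measure"] == measure]
    if source is not None:
        df = df[df["source"] == source]
    elif df["source"].nunique() > 1:
        # prefer the pooled/computational value when several sources coexist
        for pref in ("pooled", "computational"):
            if (df["source"] == pref).any():
                df = df[df["source"] == pref]
                break
    if df.empty:
        raise DesignError(f"no rows for measure {measure!r}")

    conditions = list(pd.unique(df["condition"]))
    configs = list(pd.unique(df["configuration"]))
    wide = df.pivot_table(index="specimen", columns=["condition", "configuration"],
                          values="value_mm", aggfunc="first")
    full_cols = pd.MultiIndex.from_product([conditions, configs])
    wide = wide.reindex(columns=full_cols)
    if wide.isna().any().any():
        gaps = [c for c in full_cols if wide[c].isna().any()]
        raise DesignError(f"incomplete design; missing cells {gaps[:6]}")
    n = wide.shape[0]
    a, b = len(conditions), len(configs)

    cells = wide.to_numpy(dtype=float)  # subjects x (a*b), condition-major
    if np.allclose(cells, cells.mean(), atol=1e-12):
        effects = pd.DataFrame({
            "Source": ["condition", "configuration", "condition:configuration"],
            "F": 0.0, "df1": [a - 1, b - 1, (a - 1) * (b - 1)],
            "df2": [(a - 1) * (n - 1), (b - 1) * (n - 1), (a - 1) * (b - 1) * (n - 1)],
            "p_unc": 1.0, "eps_gg": 1.0, "p_gg": 1.0,
        })
        posthoc = _tukey_posthoc(df, conditions, configs)
        return AnovaResult(effects, posthoc, n, measure)

    from statsmodels.stats.anova import AnovaRM
    long = df.rename(columns={"value_mm": "value"})
    fit = AnovaRM(long, depvar="value", subject="specimen",
                  within=["condition", "configuration"]).fit()
    tab = fit.anova_table

    Ca = _effect_contrasts(a)
    Cb = _effect_contrasts(b)
    ones_a = np.full((a, 1), 1 / np.sqrt(a))
    ones_b = np.full((b, 1), 1 / np.sqrt(b))
    eps = {
        "condition": _gg_epsilon(cells, np.kron(Ca, ones_b)),
        "configuration": _gg_epsilon(cells, np.kron(ones_a, Cb)),
        "condition:configuration": _gg_epsilon(cells, np.kron(Ca, Cb)),
    }
    from scipy.stats import f as fdist
    rows = []
    for source_name in tab.index:
        F = float(tab.loc[source_name, "F Value"])
        d1 = float(tab.loc[source_name, "Num DF"])
        d2 = float(tab.loc[source_name, "Den DF"])
        p_unc = float(tab.loc[source_name, "Pr > F"])
        e = eps.get(source_name, 1.0)
        p_gg = float(fdist.sf(F, e * d1, e * d2)) if np.isfinite(F) else np.nan
        rows.append({"Source": source_name, "F": F, "df1": d1, "df2": d2,
                     "p_unc": p_unc, "eps_gg": e, "p_gg": p_gg})
    effects = pd.DataFrame(rows)
    posthoc = _tukey_posthoc(df, conditions, configs)
    return AnovaResult(effects, posthoc, n, measure)


def _tukey_posthoc(df: pd.DataFrame, conditions, configs) -> pd.DataFrame:
    """Tukey pairwise condition comparisons within each configuration.

    Uses the one-way repeated-measures error term (condition x subject) of
    that configuration and the studentized-range distribution, i.e. the
    multiplicity-adjusted p-values a GraphPad-style RM Tukey reports.
    """
    rows = []
    k = len(conditions)
    for cfg in configs:
        sub = df[df["configuration"] == cfg]
        wide = sub.pivot_table(index="specimen", columns="condition",
                               values="value_mm", aggfunc="first")[conditions]
        W = wide.to_numpy(dtype=float)
        n = W.shape[0]
        m_subj = W.mean(axis=1, keepdims=True)
        m_cond = W.mean(axis=0, keepdims=True)
        resid = W - m_subj - m_cond + W.mean()
        df_err = (n - 1) * (k - 1)
        ms_err = float(np.sum(resid ** 2) / df_err) if df_err > 0 else 0.0
        se = np.sqrt(ms_err / n)
        for i in range(k):
            for j in range(i + 1, k):
                diff = float(m_cond[0, j] - m_cond[0, i])
                if se > 0:
                    q = abs(diff) / se
                    p = float(studentized_range.sf(q, k, df_err))
                else:
                    q, p = (0.0, 1.0) if abs(diff) < 1e-12 else (np.inf, 0.0)
                rows.append({"configuration": cfg,
                             "condition_a": conditions[j],
                             "condition_b": conditions[i],
                             "diff_mm": diff, "q": q, "p_tukey": min(p, 1.0)})
    return pd.DataFrame(rows)


# -- contrasts --------------------------------------------------------------

@dataclass(frozen=True)
class ContrastResult:
    measure: str
    configuration: str
    condition_a: str
    condition_b: str
    diff_mm: float

    @property
    def diff_rounded(self) -> float:
        return round(self.diff_mm, 1)


def condition_contrasts(table: pd.DataFrame, measure: str,
                        baseline: str = "intact",
                        value_col: str = "value_mm") -> list[ContrastResult]:
    """Per-configuration differences of each condition's group mean against
    the intact baseline (positive = more opening than intact).

    In pipeline mode the group mean averages per-specimen values at full
    precision; fed a printed-means fixture (one row per group) it reproduces
    the published arithmetic exactly.
    """
    df = table[table["measure"] == measure] if "measure" in table.columns else table
    if df.empty:
        raise DesignError(f"no rows for measure {measure!r}")
    means = df.groupby(["condition", "configuration"])[value_col].mean()
    out: list[ContrastResult] = []
    for (cond, cfg), m in means.items():
        base = means.get((baseline, cfg))
        if base is None:
            raise DesignError(f"missing baseline group ({baseline}, {cfg})")
        out.append(ContrastResult(measure=measure, configuration=cfg,
                                  condition_a=cond, condition_b=baseline,
                                  diff_mm=float(m - base)))
    return out


def contrasts_to_frame(contrasts: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "measure": c.measure, "configuration": c.configuration,
        "condition": c.condition_a, "baseline": c.condition_b,
        "diff_mm": c.diff_mm, "diff_rounded_mm": c.diff_rounded,
    } for c in contrasts])


# -- packaged fixture -------------------------------------------------------

def load_table1() -> pd.DataFrame:
    """The packaged transcription of the study's printed group means."""
    ref = importlib.resources.files("varusscd.data").joinpath("table1_means.csv")
    with ref.open("r") as fh:
        return pd.read_csv(fh)


def headline_contrasts(table1: pd.DataFrame | None = None) -> pd.DataFrame:
    """The study's headline opening contrasts from the printed group means.

    For each method's summary measure (manual manmean / computational
    compmean): loaded condition-vs-intact openings and the unloaded
    intact-vs-fully-deficient drift, rounded as printed (0.1 mm).
    """
    df = load_table1() if table1 is None else table1
    rows = []
    for method, measure in (("manual", "manmean"), ("computational", "compmean")):
        sub = df[(df["method"] == method) & (df["measure"] == measure)]
        contrasts = condition_contrasts(sub.assign(measure=measure), measure,
                                        value_col="mean_mm")
        for c in contrasts:
            if c.condition_a == c.condition_b:
                continue
            rows.append({"method": method, "measure": measure,
                         "configuration": c.configuration,
                         "condition": c.condition_a,
                         "diff_mm": c.diff_mm,
                         "diff_rounded_mm": c.diff_rounded})
    return pd.DataFrame(rows)


# -- power ------------------------------------------------------------------

def simulate_configuration_power(n_reps: int = 200, effect_mm: float = 2.0,
                                 noise_sd: float = 0.5, n_subjects: int = 10,
                                 alpha: float = 0.01, seed: int = 0,
                                 conditions=("c1", "c2", "c3", "c4", "c5")) -> float:
    """Fraction of simulated studies whose configuration main effect reaches
    ``p < alpha``: subject random intercepts (SD 1), a pure loading effect of
    ``effect_mm`` and i.i.d. measurement noise."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        rows = []
        subj_fx = rng.normal(8.0, 1.0, size=n_subjects)
        for s in range(n_subjects):
            for cond in conditions:
                for cfg, load in (("UL", 0.0), ("LO", effect_mm)):
                    rows.append({"specimen": f"S{s}", "condition": cond,
                                 "configuration": cfg, "measure": "m",
                                 "source": "sim",
                                 "value_mm": subj_fx[s] + load
                                 + rng.normal(0.0, noise_sd)})
        res = rm_anova(pd.DataFrame(rows), "m")
        p = res.effects.loc[res.effects["Source"] == "configuration",
                            "p_unc"].item()
        hits += p < alpha
    return hits / n_reps
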