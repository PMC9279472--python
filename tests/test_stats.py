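"""Reader pooling, ICC, repeated-measures ANOVA and contrasts."""

import numpy as np
import pandas as pd
import pytest

from varusscd import (DesignError, PairingError, condition_contrasts,
                      headline_contrasts, icc_two_readers, load_table1,
                      pool_readers, rm_anova, synthetic_readers)
from varusscd.stats import SITE_MEASURES


def reader_table(values: dict, source="reader1"):
    """values: {(specimen, condition, configuration, measure): value}"""
    rows = [dict(specimen=s, condition=c, configuration=g, measure=m,
                 source=source, value_mm=v)
            for (s, c, g, m), v in values.items()]
    return pd.DataFrame(rows)


INTACT_UL_SITES = dict(ml1=6.6, ml2=6.6, ml3=7.0, ap1=10.5, ap2=6.8, ap3=9.0)


class TestPoolReaders:
    def base_values(self, offset=0.0):
        return {("S1", "intact", "UL", m): v + offset
                for m, v in INTACT_UL_SITES.items()}

    def test_identical_readers_pool_to_themselves(self):
        r = reader_table(self.base_values())
        pooled = pool_readers(r, r)
        sites = pooled[pooled["measure"].isin(SITE_MEASURES)]
        for m, v in INTACT_UL_SITES.items():
            assert sites.loc[sites["measure"] == m, "value_mm"].item() == v

    def test_pooled_value_is_the_mean_and_symmetric(self):
        r1 = reader_table(self.base_values())
        r2 = reader_table(self.base_values(offset=2.0))
        a = pool_readers(r1, r2).sort_values("measure", ignore_index=True)
        b = pool_readers(r2, r1).sort_values("measure", ignore_index=True)
        assert a["value_mm"].equals(b["value_mm"])
        m = a.loc[a["measure"] == "ml1", "value_mm"].item()
        assert m == pytest.approx(6.6 + 1.0)

    def test_six_site_mean_matches_printed_intact_row(self):
        # the published intact-unloaded manual sites average to 7.75 mm,
        # printed as 7.8 after rounding
        r = reader_table(self.base_values())
        pooled = pool_readers(r, r)
        manmean = pooled.loc[pooled["measure"] == "manmean", "value_mm"].item()
        assert manmean == pytest.approx(7.75)

    def test_unmatched_keys_raise_with_offenders(self):
        r1 = reader_table(self.base_values())
        r2 = reader_table({k: v for k, v in self.base_values().items()
                           if k[3] != "ap3"})
        with pytest.raises(PairingError, match="ap3"):
            pool_readers(r1, r2)


class TestICC:
    def test_duplicated_readers_give_one(self):
        r1, _ = synthetic_readers(50, seed=0)
        assert icc_two_readers(r1, r1).value == pytest.approx(1.0)

    def test_independent_noise_gives_near_zero(self):
        rng = np.random.default_rng(1)
        res = icc_two_readers(rng.normal(size=10_000),
                              rng.normal(size=10_000))
        assert abs(res.value) < 0.05

    def test_high_agreement_variance_structure(self):
        # between-target SD 1.4, within-pair SD 0.15: expected ICC about
        # 1.96 / (1.96 + 0.0225) ~ 0.989
        vals = [icc_two_readers(*synthetic_readers(60, seed=s)).value
                for s in range(8)]
        assert np.mean(vals) == pytest.approx(0.98, abs=0.02)

    def test_shift_invariance(self):
        r1, r2 = synthetic_readers(40, seed=2)
        a = icc_two_readers(r1, r2).value
        b = icc_two_readers(r1 + 5.0, r2 + 5.0).value
        assert a == pytest.approx(b, abs=1e-12)

    def test_zero_variance_reported_undefined(self):
        res = icc_two_readers([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert not res.defined and np.isnan(res.value)

    def test_matches_pingouin_both_forms(self):
        pg = pytest.importorskip("pingouin")
        r1, r2 = synthetic_readers(80, seed=3)
        df = pd.DataFrame({"t": np.repeat(np.arange(80), 2),
                           "r": np.tile([0, 1], 80),
                           "s": np.column_stack([r1, r2]).ravel()})
        ref = pg.intraclass_corr(df, targets="t", raters="r", ratings="s")
        # rows are ordered ICC1, ICC2, ICC3, ... (labels vary by version)
        icc1 = ref["ICC"].iloc[0]
        icc2 = ref["ICC"].iloc[1]
        assert icc_two_readers(r1, r2).value == pytest.approx(icc1, abs=1e-9)
        assert icc_two_readers(r1, r2, form="two-way").value == \
            pytest.approx(icc2, abs=1e-9)


def study_frame(n=4, conditions=("A", "B"), configs=("UL", "LO"),
                effect_cond=0.5, effect_cfg=1.2, noise=0.4, seed=42):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n):
        for ci, c in enumerate(conditions):
            for gi, g in enumerate(configs):
                rows.append(dict(specimen=f"S{s}", condition=c,
                                 configuration=g, measure="m", source="x",
                                 value_mm=float(8 + effect_cond * ci
                                                + effect_cfg * gi
                                                + rng.normal(0, noise))))
    return pd.DataFrame(rows)


def hand_rm_anova_f(table):
    """Independent sum-of-squares oracle for the two-way within design."""
    wide = table.pivot_table(index="specimen",
                             columns=["condition", "configuration"],
                             values="value_mm")
    conditions = sorted({c for c, _ in wide.columns})
    configs = sorted({g for _, g in wide.columns})
    wide = wide[pd.MultiIndex.from_product([conditions, configs])]
    n, a, b = wide.shape[0], len(conditions), len(configs)
    cells = wide.to_numpy().reshape(n, a, b)
    gm = cells.mean()
    mA = cells.mean(axis=(0, 2))
    mB = cells.mean(axis=(0, 1))
    mS = cells.mean(axis=(1, 2))
    mAB = cells.mean(axis=0)
    mSA = cells.mean(axis=2)
    mSB = cells.mean(axis=1)
    ssA = n * b * np.sum((mA - gm) ** 2)
    ssB = n * a * np.sum((mB - gm) ** 2)
    ssAB = n * np.sum((mAB - mA[:, None] - mB[None, :] + gm) ** 2)
    ssSA = b * np.sum((mSA - mS[:, None] - mA[None, :] + gm) ** 2)
    ssSB = a * np.sum((mSB - mS[:, None] - mB[None, :] + gm) ** 2)
    ssSAB = np.sum((cells - mSA[:, :, None] - mSB[:, None, :]
                    - mAB[None, :, :] + mS[:, None, None]
                    + mA[None, :, None] + mB[None, None, :] - gm) ** 2)
    FA = (ssA / (a - 1)) / (ssSA / ((n - 1) * (a - 1)))
    FB = (ssB / (b - 1)) / (ssSB / ((n - 1) * (b - 1)))
    FAB = (ssAB / ((a - 1) * (b - 1))) / (ssSAB / ((n - 1) * (a - 1) * (b - 1)))
    return {"condition": FA, "configuration": FB,
            "condition:configuration": FAB}


class TestRMAnova:
    def test_f_statistics_match_hand_sum_of_squares(self):
        table = study_frame()
        res = rm_anova(table, "m")
        oracle = hand_rm_anova_f(table)
        for _, row in res.effects.iterrows():
            assert row["F"] == pytest.approx(oracle[row["Source"]], abs=1e-9)

    def test_constant_data_gives_null_result(self):
        table = study_frame()
        table["value_mm"] = 5.0
        res = rm_anova(table, "m")
        assert (res.effects["F"] == 0).all()
        assert (res.effects["p_unc"] == 1).all()
        assert (res.posthoc["p_tukey"] == 1).all()

    def test_f_invariant_to_unit_rescaling(self):
        table = study_frame(seed=7)
        a = rm_anova(table, "m").effects
        table2 = table.copy()
        table2["value_mm"] = table2["value_mm"] / 10.0  # mm -> cm
        b = rm_anova(table2, "m").effects
        np.testing.assert_allclose(a["F"], b["F"], rtol=1e-9)

    def test_p_invariant_to_specimen_relabeling(self):
        table = study_frame(seed=8)
        relabeled = table.copy()
        relabeled["specimen"] = relabeled["specimen"].map(
            {"S0": "Z9", "S1": "Z3", "S2": "Z1", "S3": "Z0"})
        np.testing.assert_allclose(rm_anova(table, "m").effects["p_unc"],
                                   rm_anova(relabeled, "m").effects["p_unc"],
                                   rtol=1e-9)

    def test_missing_cell_raises_naming_gap(self):
        table = study_frame()
        table = table[~((table.specimen == "S2") & (table.condition == "B")
                        & (table.configuration == "LO"))]
        with pytest.raises(DesignError, match="missing cells"):
            rm_anova(table, "m")

    def test_gg_epsilon_bounds_and_corrected_p(self):
        table = study_frame(n=6, conditions=("A", "B", "C"), seed=11)
        res = rm_anova(table, "m")
        for _, row in res.effects.iterrows():
            assert 1.0 / row["df1"] - 1e-12 <= row["eps_gg"] <= 1.0
            if row["F"] >= 1.0:
                # sphericity correction can only weaken real effects
                assert row["p_gg"] >= row["p_unc"] - 1e-12

    def test_tukey_p_monotone_in_q(self):
        table = study_frame(n=8, conditions=("A", "B", "C", "D"), seed=13)
        ph = rm_anova(table, "m").posthoc
        for _, grp in ph.groupby("configuration"):
            g = grp.sort_values("q")
            assert (np.diff(g["p_tukey"]) <= 1e-12).all()


class TestContrasts:
    def test_intact_vs_intact_is_zero_and_antisymmetry(self):
        table = study_frame(conditions=("intact", "B"))
        cons = condition_contrasts(table, "m")
        zero = [c for c in cons if c.condition_a == "intact"]
        assert all(c.diff_mm == pytest.approx(0.0) for c in zero)
        swapped = condition_contrasts(table, "m", baseline="B")
        for c in cons:
            if c.condition_a != "B":
                continue
            mate = next(s for s in swapped
                        if s.condition_a == "intact"
                        and s.configuration == c.configuration)
            assert c.diff_mm == pytest.approx(-mate.diff_mm)

    def test_missing_baseline_group_raises(self):
        table = study_frame(conditions=("A", "B"))
        with pytest.raises(DesignError):
            condition_contrasts(table, "m", baseline="intact")


class TestTable1Fixture:
    def test_fixture_contains_full_design(self):
        df = load_table1()
        assert len(df) == 140  # 2 methods x 7 measures x 5 conditions x 2 configs
        assert set(df["configuration"]) == {"UL", "LO"}
        assert df["mean_mm"].between(6, 16).all()

    def test_loaded_lcl_contrast_manual(self):
        rep = headline_contrasts()
        row = rep[(rep.method == "manual") & (rep.configuration == "LO")
                  & (rep.condition == "LCL")]
        assert row["diff_rounded_mm"].item() == pytest.approx(1.3)

    def test_loaded_full_deficiency_contrast_computational(self):
        rep = headline_contrasts()
        row = rep[(rep.method == "computational") & (rep.configuration == "LO")
                  & (rep.condition == "LCL+PT+PFL+ACL")]
        assert row["diff_rounded_mm"].item() == pytest.approx(2.7)
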