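import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qoctga.synthetic_cohort import CohortConfig, simulate_growth_table
from qoctga.trial_endpoints import (
    baseline_compare,
    build_long_table,
    fit_lsmeans,
    percent_reduction,
    sqrt_change,
)


class TestSqrtChange:
    @pytest.mark.parametrize(
        "area_t, area_0, expected",
        [(7.00, 7.00, 0.0), (4.00, 1.00, 1.0), (0.0, 0.0, 0.0), (1.0, 4.0, -1.0)],
    )
    def test_arithmetic(self, area_t, area_0, expected):
        assert sqrt_change(area_t, area_0) == pytest.approx(expected)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            sqrt_change(-1.0, 0.0)


class TestPercentReduction:
    def test_published_growth_means_give_45_and_27_percent(self):
        # 12-month mean √area change: treated monthly 0.151 mm, every other
        # month 0.202 mm, sham 0.277 mm
        assert percent_reduction(0.151, 0.277) == 45
        assert percent_reduction(0.202, 0.277) == 27

    def test_identity_is_zero(self):
        assert percent_reduction(0.3, 0.3) == 0

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        active=st.floats(0.01, 10), sham=st.floats(0.01, 10), scale=st.floats(0.1, 10)
    )
    def test_scale_invariance(self, active, sham, scale):
        assert percent_reduction(active, sham) == percent_reduction(
            active * scale, sham * scale
        )

    def test_nonpositive_sham_rejected(self):
        with pytest.raises(ValueError):
            percent_reduction(0.1, 0.0)


def _areas_frame():
    rows = []
    for eye, arm in [("a", "SHAM"), ("b", "PM")]:
        for month, area in [(0, 4.0), (12, 6.25)]:
            rows.append((eye, arm, month, "RORA", area))
    return pd.DataFrame(rows, columns=["eye_id", "arm", "visit_month", "feature", "area_mm2"])


class TestLongTable:
    def test_columns_and_change(self):
        table = build_long_table(_areas_frame())
        assert (table.loc[table.visit_month == 0, "sqrt_change_mm"] == 0).all()
        follow = table[table.visit_month == 12]
        assert follow.sqrt_change_mm.to_numpy() == pytest.approx([0.5, 0.5])
        assert (table.baseline_area_mm2 == 4.0).all()

    def test_missing_baseline_rejected(self):
        frame = _areas_frame()
        frame = frame[~((frame.eye_id == "b") & (frame.visit_month == 0))]
        with pytest.raises(ValueError, match="baseline"):
            build_long_table(frame)

    def test_duplicate_rows_rejected(self):
        frame = pd.concat([_areas_frame()] * 2)
        with pytest.raises(ValueError, match="duplicate"):
            build_long_table(frame)


def _sim_table(seed=0, n=25, effects=None, **kw):
    cfg = CohortConfig(
        n_per_arm={"SHAM": n, "PM": n, "PEOM": n},
        arm_effect=effects or {"SHAM": 1.0, "PM": 0.545, "PEOM": 0.729},
        rng_seed=seed,
        **kw,
    )
    return build_long_table(simulate_growth_table(cfg))


class TestMixedModel:
    def test_single_arm_errors(self):
        table = _sim_table()
        with pytest.raises(ValueError, match="single arm"):
            fit_lsmeans(table[table.arm == "SHAM"])

    def test_empty_cell_named(self):
        table = _sim_table()
        drop = (table.arm == "PM") & (table.visit_month == 12)
        with pytest.raises(ValueError, match="PM × month 12"):
            fit_lsmeans(table[~drop])

    def test_lsmeans_track_raw_cell_means_in_balanced_null(self):
        # with no baseline effect on growth and balanced arms, LS means
        # approach the raw arm×visit means of the response
        table = _sim_table(seed=4, n=80, effects={"SHAM": 1.0, "PM": 1.0, "PEOM": 1.0})
        res = fit_lsmeans(table)
        raw = (
            table[table.visit_month > 0]
            .groupby(["arm", "visit_month"])
            .sqrt_change_mm.mean()
        )
        for _, row in res.lsmeans.iterrows():
            assert row.estimate == pytest.approx(
                raw[(row.arm, row.visit_month)], abs=0.02
            )

    def test_treatment_effect_detected_and_sign_correct(self):
        table = _sim_table(seed=11, n=60)
        res = fit_lsmeans(table)
        pm12 = res.contrasts[(res.contrasts.arm == "PM") & (res.contrasts.visit_month == 12)]
        assert float(pm12.estimate.iloc[0]) < 0
        assert float(pm12.p.iloc[0]) < 0.05

    def test_ci_brackets_estimate_and_p_in_unit_interval(self):
        res = fit_lsmeans(_sim_table(seed=2))
        assert (res.lsmeans.ci_low <= res.lsmeans.estimate).all()
        assert (res.lsmeans.estimate <= res.lsmeans.ci_high).all()
        assert ((res.contrasts.p > 0) & (res.contrasts.p <= 1)).all()

    def test_missing_visits_handled_by_likelihood(self):
        table = _sim_table(seed=3, n=40)
        # drop month-18 rows for a third of the eyes
        eyes = table.eye_id.unique()[::3]
        table = table[~(table.eye_id.isin(eyes) & (table.visit_month == 18))]
        res = fit_lsmeans(table)
        n18 = res.lsmeans[res.lsmeans.visit_month == 18].n.sum()
        n12 = res.lsmeans[res.lsmeans.visit_month == 12].n.sum()
        assert n18 < n12


class TestBaselineCompare:
    def test_identical_samples_give_maximal_p(self):
        table = _sim_table(seed=6)
        # copy SHAM baselines into PM so the samples coincide exactly
        base = table[table.visit_month == 0]
        sham = base[base.arm == "SHAM"].copy()
        pm = sham.copy()
        pm["arm"] = "PM"
        pm["eye_id"] = pm.eye_id + "-copy"
        merged = pd.concat([sham, pm])
        assert baseline_compare(merged, "RORA", ("PM", "SHAM")) > 0.9

    def test_shifted_arms_detected(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(60):
            rows.append((f"s{i}", "SHAM", 0, "RORA", 7 + rng.normal(0, 1)))
            rows.append((f"p{i}", "PM", 0, "RORA", 10 + rng.normal(0, 1)))  # +3 SD
        table = pd.DataFrame(rows, columns=["eye_id", "arm", "visit_month", "feature", "area_mm2"])
        assert baseline_compare(table, "RORA", ("PM", "SHAM")) < 0.001

    def test_empty_arm_rejected(self):
        table = _sim_table()
        with pytest.raises(ValueError, match="empty arm"):
            baseline_compare(table[table.arm != "PM"], "RORA", ("PM", "SHAM"))

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(12)
        reject = 0
        reps = 300
        for _ in range(reps):
            rows = []
            for i in range(30):
                rows.append((f"s{i}", "SHAM", 0, "RORA", rng.lognormal(1.9, 0.5)))
                rows.append((f"p{i}", "PM", 0, "RORA", rng.lognormal(1.9, 0.5)))
            table = pd.DataFrame(
                rows, columns=["eye_id", "arm", "visit_month", "feature", "area_mm2"]
            )
            reject += baseline_compare(table, "RORA", ("PM", "SHAM")) < 0.05
        assert 0.02 <= reject / reps <= 0.09
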