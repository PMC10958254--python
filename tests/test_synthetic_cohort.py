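import hashlib
import json

import numpy as np
import pandas as pd
import pytest

from qoctga.io_formats import read_volume
from qoctga.synthetic_cohort import (
    CohortConfig,
    TruncatedGeometric,
    TruncatedNormal,
    simulate_cohort,
    simulate_growth_table,
    write_cohort,
)

from conftest import small_config


class TestConfigValidation:
    def test_sham_multiplier_must_be_one(self):
        with pytest.raises(ValueError, match="SHAM"):
            CohortConfig(arm_effect={"SHAM": 0.9, "PM": 0.5, "PEOM": 0.7})

    def test_visits_must_start_at_zero(self):
        with pytest.raises(ValueError, match="visit_months"):
            CohortConfig(visit_months=(2, 6, 12))

    def test_agreement_bounded(self):
        with pytest.raises(ValueError, match="htr_agreement"):
            CohortConfig(htr_agreement=1.2)


def test_truncated_geometric_hits_target_mean():
    dist = TruncatedGeometric(mean=3.14, max_k=12)
    p = dist.probabilities()
    assert p.sum() == pytest.approx(1.0)
    assert (p * np.arange(1, 13)).sum() == pytest.approx(3.14, abs=1e-6)


def test_truncated_normal_respects_bounds():
    rng = np.random.default_rng(0)
    d = TruncatedNormal(2.6, 0.6, 1.26, 4.07)
    xs = [d.sample(rng) for _ in range(500)]
    assert min(xs) >= 1.26 and max(xs) <= 4.07
    assert np.mean(xs) == pytest.approx(2.6, abs=0.1)


class TestSimulation:
    def test_empty_cohort(self):
        groups, truth = simulate_cohort(small_config(n_per_arm={}))
        assert groups == [] and truth.table.empty

    def test_degenerate_halo_gives_identical_features(self):
        cfg = small_config(prd_halo_mm=0.0, htr_agreement=1.0)
        _, truth = simulate_cohort(cfg)
        t = truth.table
        assert np.array_equal(t.area_PRD, t.area_RPE_LOSS)
        assert np.array_equal(t.area_HTR, t.area_RPE_LOSS)
        assert (t.area_PRD_ISOLATED == 0).all()

    def test_growth_law_matches_analytic_target(self):
        # sham eye, baseline √area 2.0 mm, growth 0.277 mm/yr: at month 12
        # the rendered mask must measure √area 2.277 mm up to pixelisation
        cfg = small_config(
            n_per_arm={"SHAM": 1},
            grid_px=(600, 600),
            baseline_sqrt_area_dist=TruncatedNormal(2.0, 0.0, 2.0, 2.0),
            growth_cv=0.0,
            visit_months=(0, 12),
        )
        _, truth = simulate_cohort(cfg)
        row = truth.table[truth.table.visit_month == 12].iloc[0]
        px = cfg.px_mm
        perim = 2 * np.sqrt(np.pi) * 2.277  # upper bound for a multifocal outline
        tol_area = 2 * perim * px
        assert row.area_RPE_LOSS == pytest.approx(2.277**2, abs=tol_area)

    def test_rora_equals_rpe_loss_without_htr_noise(self, clean_cohort):
        _, _, truth = clean_cohort
        t = truth.table
        assert np.array_equal(t.area_RORA, t.area_RPE_LOSS)
        assert np.allclose(t.area_PRD_ISOLATED, t.area_PRD - t.area_RPE_LOSS)

    def test_prd_contains_rpe_loss_in_rendered_masks(self, tiny_cohort):
        groups, _ = tiny_cohort
        for group in groups:
            by_feature = {v.feature: v.masks for v in group}
            assert not (by_feature["RPE_LOSS"] & ~by_feature["PRD"]).any()

    def test_identical_seed_is_bitwise_identical(self):
        cfg = small_config(n_per_arm={"SHAM": 1, "PM": 1})
        g1, t1 = simulate_cohort(cfg)
        g2, t2 = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(t1.table, t2.table)
        for a, b in zip(g1, g2):
            for va, vb in zip(a, b):
                assert np.array_equal(va.masks, vb.masks)

    def test_different_seed_differs(self):
        g1, t1 = simulate_cohort(small_config(rng_seed=1))
        g2, t2 = simulate_cohort(small_config(rng_seed=2))
        assert not t1.table.area_RPE_LOSS.equals(t2.table.area_RPE_LOSS)

    def test_oversized_baseline_rejected(self):
        cfg = small_config(
            baseline_sqrt_area_dist=TruncatedNormal(5.9, 0.0, 5.9, 5.9),
        )
        with pytest.raises(ValueError, match="outgrow|exceeds"):
            simulate_cohort(cfg)

    def test_focality_never_increases_as_lesion_grows(self, tiny_cohort):
        _, truth = tiny_cohort
        for _, eye in truth.table.groupby("eye_id"):
            foc = eye.sort_values("visit_month").focality.to_numpy()
            assert (np.diff(foc) <= 0).all()

    def test_per_eye_growth_regression_recovers_configured_rate(self):
        cfg = small_config(n_per_arm={"SHAM": 2, "PM": 2}, grid_px=(300, 300))
        _, truth = simulate_cohort(cfg)
        for _, eye in truth.table.groupby("eye_id"):
            t = eye.visit_month.to_numpy() / 12
            s = np.sqrt(eye.area_RPE_LOSS.to_numpy())
            slope = np.polyfit(t, s, 1)[0]
            assert slope == pytest.approx(eye.growth_rate_mm_per_year.iloc[0], rel=0.05)


class TestWriteCohort:
    def test_empty_cohort_manifest(self, tmp_path):
        groups, truth = simulate_cohort(small_config(n_per_arm={}))
        manifest = write_cohort(groups, truth, tmp_path)
        data = json.loads(manifest.read_text())
        assert data["n_volumes"] == 0

    def test_checksums_verify_and_masks_round_trip(self, tmp_path, tiny_cohort):
        groups, truth = tiny_cohort
        manifest = write_cohort(groups, truth, tmp_path)
        data = json.loads(manifest.read_text())
        volumes = {v.meta.acquisition_id + v.feature: v for g in groups for v in g}
        n_checked = 0
        for entry in data["files"]:
            path = tmp_path / entry["file"]
            assert hashlib.sha256(path.read_bytes()).hexdigest() == entry["sha256"]
            if entry["file"].endswith(".tif"):
                vol = read_volume(path)
                orig = volumes[vol.meta.acquisition_id + vol.feature]
                assert np.array_equal(vol.masks, orig.masks)
                n_checked += 1
        assert n_checked == len(groups) * 3

    def test_existing_manifest_requires_overwrite(self, tmp_path, tiny_cohort):
        groups, truth = tiny_cohort
        write_cohort(groups, truth, tmp_path)
        with pytest.raises(FileExistsError):
            write_cohort(groups, truth, tmp_path)
        write_cohort(groups, truth, tmp_path, overwrite=True)


def test_growth_table_recovers_arm_rates():
    cfg = CohortConfig(
        n_per_arm={"SHAM": 200, "PM": 200},
        arm_effect={"SHAM": 1.0, "PM": 0.55},
        growth_cv=0.3,
        rng_seed=8,
    )
    table = simulate_growth_table(cfg)
    assert set(table.columns) >= {"eye_id", "arm", "visit_month", "feature", "area_mm2"}
    for arm, mult in [("SHAM", 1.0), ("PM", 0.55)]:
        t = table[table.arm == arm].pivot(index="eye_id", columns="visit_month", values="area_mm2")
        growth = np.sqrt(t[12]) - np.sqrt(t[0])
        assert growth.mean() == pytest.approx(0.277 * mult, abs=3 * growth.std() / np.sqrt(len(t)))
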