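"""Synthetic trial generator: determinism, defaults, degenerate limits,
injection machinery, and equivalence of the fast panel path."""

import numpy as np
import pandas as pd
import pytest

from movecoda import (
    TrialConfig,
    generate_trial,
    inject_effect,
    null_interaction_config,
    simulate_coordinate_panel,
)
from movecoda.balances import ilr
from movecoda.composition import closure, compositional_mean
from movecoda.preprocess import (
    PART_COLS,
    aggregate_subject_timepoint,
    filter_valid_days,
)


def csv_bytes(df):
    return df.to_csv(index=False, float_format="%.10g")


class TestDeterminismAndDefaults:
    def test_identical_seed_identical_output(self):
        cfg = TrialConfig(seed=42)
        t1, t2 = generate_trial(cfg), generate_trial(cfg)
        assert csv_bytes(t1.days) == csv_bytes(t2.days)
        assert csv_bytes(t1.subjects) == csv_bytes(t2.subjects)

    def test_different_seed_differs(self):
        assert csv_bytes(generate_trial(TrialConfig(seed=1)).days) != csv_bytes(
            generate_trial(TrialConfig(seed=2)).days
        )

    def test_default_cohort_composition(self):
        t = generate_trial(TrialConfig(seed=0))
        assert len(t.subjects) == 231
        assert t.subjects["group"].value_counts()["intervention"] == 117
        assert t.subjects["group"].value_counts()["control"] == 114
        frac_women = (t.subjects["gender"] == "woman").mean()
        assert 0.75 < frac_women < 0.91
        assert abs(t.subjects["age"].mean() - 65.2) < 0.5

    def test_day_records_satisfy_invariants(self):
        t = generate_trial(TrialConfig(seed=3))
        days = t.days.dropna()
        assert (days["waking_wear_min"] <= days["day_length_min"]).all()
        assert (days[list(PART_COLS)].le(days["day_length_min"], axis=0)).all().all()
        assert (days[list(PART_COLS)] > 0).all().all()
        counts = t.days.groupby(["subject_id", "timepoint"]).size()
        assert counts.between(7, 8).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrialConfig(invalid_day_rate=1.5).validate()
        with pytest.raises(ValueError):
            TrialConfig(sublimit_low=0.6).validate()
        with pytest.raises(ValueError):
            TrialConfig(n_control=0).validate()


class TestDegenerateAndConsistency:
    def test_zero_noise_recovers_configured_means(self):
        cfg = TrialConfig(
            n_intervention=4, n_control=4, subject_sd=(0, 0, 0), slope_sd=(0, 0, 0),
            day_sd=(0, 0, 0), invalid_day_rate=0, missing_rate=0, sublimit_rate=0, seed=1,
        )
        t = generate_trial(cfg)
        agg = aggregate_subject_timepoint(t.days).merge(t.subjects, on="subject_id")
        for (g, tp), target in cfg.mean_compositions.items():
            cell = agg[(agg.group == g) & (agg.timepoint == tp)][list(PART_COLS)].to_numpy()
            assert np.allclose(cell, closure(np.asarray(target), 1440.0), rtol=1e-9)

    def test_large_cohort_means_converge(self):
        # variability reduced so the 1% tolerance is ~4 Monte-Carlo SDs
        cfg = TrialConfig(
            n_intervention=2500, n_control=2500,
            subject_sd=(0.15, 0.12, 0.05), slope_sd=(0.005, 0.005, 0.005),
            day_sd=(0.2, 0.2, 0.1),
            invalid_day_rate=0, missing_rate=0, sublimit_rate=0, seed=7,
        )
        t = generate_trial(cfg)
        agg = aggregate_subject_timepoint(t.days).merge(t.subjects, on="subject_id")
        for (g, tp), target in cfg.mean_compositions.items():
            cell = agg[(agg.group == g) & (agg.timepoint == tp)][list(PART_COLS)].to_numpy()
            m = compositional_mean(cell, 1440.0)
            assert np.all(np.abs(m - closure(np.asarray(target), 1440.0)) / m < 0.01)

    def test_invalid_days_fail_wear_rule(self):
        cfg = TrialConfig(invalid_day_rate=0.2, missing_rate=0, sublimit_rate=0, seed=5)
        t = generate_trial(cfg)
        kept, removed = filter_valid_days(t.days)
        assert removed > 0
        assert (kept["waking_wear_min"] >= 600.0).all()
        dropped = t.days[~t.days.index.isin(kept.index)]
        assert (dropped["waking_wear_min"] < 600.0).all()

    def test_sublimit_injection_lands_below_screen(self):
        cfg = TrialConfig(sublimit_rate=0.08, invalid_day_rate=0, missing_rate=0, seed=13)
        t = generate_trial(cfg)
        hit = t.truth.corrupted.query("kind == 'sublimit_mvpa'")
        assert len(hit) > 0
        agg = aggregate_subject_timepoint(t.days).set_index(["subject_id", "timepoint"])
        for _, rec in hit.iterrows():
            v = agg.loc[(rec.subject_id, rec.timepoint), "mvpa_min"]
            assert 0.0 < v < 0.5
            assert rec.true_value >= 0.5  # pre-injection truth retained

    def test_missing_injection_blanks_one_part(self):
        cfg = TrialConfig(missing_rate=0.05, invalid_day_rate=0, sublimit_rate=0, seed=17)
        t = generate_trial(cfg)
        miss = t.truth.corrupted.query("kind == 'missing'")
        assert len(miss) > 0
        for _, rec in miss.iterrows():
            block = t.days[(t.days.subject_id == rec.subject_id) & (t.days.timepoint == rec.timepoint)]
            assert block[rec.part].isna().all()
            other = [c for c in PART_COLS if c != rec.part]
            assert block[other].notna().all().all()


class TestEffectInjection:
    def test_zero_beta_is_identity(self):
        cfg = TrialConfig(seed=1)
        c0, c1 = cfg.cell_coords(), inject_effect(cfg, 2, 0.0).cell_coords()
        assert all(np.allclose(c0[cell], c1[cell]) for cell in c0)

    def test_injection_moves_only_target_coordinate(self):
        cfg = null_interaction_config(seed=1)
        cfg2 = inject_effect(cfg, 2, 0.04)
        c0, c1 = cfg.cell_coords(), cfg2.cell_coords()
        for cell in c0:
            delta = c1[cell] - c0[cell]
            assert delta[0] == pytest.approx(0.0, abs=1e-12)
            assert delta[2] == pytest.approx(0.0, abs=1e-12)  # SED:sleep untouched
            expected = 0.04 * 6.0 if cell == ("intervention", "m6") else 0.0
            assert delta[1] == pytest.approx(expected, abs=1e-12)

    def test_truth_fixed_effects(self):
        cfg = null_interaction_config(seed=1)
        fx = cfg.true_fixed_effects()
        for k in (1, 2, 3):
            assert fx[f"z{k}"]["Group*Time"] == pytest.approx(0.0, abs=1e-12)
        beta = 0.02
        fx2 = inject_effect(cfg, 2, beta).true_fixed_effects()
        assert fx2["z2"]["Group*Time"] == pytest.approx(beta, abs=1e-12)
        assert fx2["z1"]["Group*Time"] == pytest.approx(0.0, abs=1e-12)

    def test_bad_coordinate_rejected(self):
        with pytest.raises(ValueError):
            inject_effect(TrialConfig(), 5, 0.1)


class TestPanelPath:
    def test_panel_matches_day_level_route_in_distribution(self):
        """The analysis-resolution shortcut must match generate+aggregate."""
        cfg = TrialConfig(
            n_intervention=600, n_control=600, invalid_day_rate=0,
            missing_rate=0, sublimit_rate=0, seed=23,
        )
        t = generate_trial(cfg)
        agg = aggregate_subject_timepoint(t.days).merge(t.subjects, on="subject_id")
        z_days = ilr(closure(agg[list(PART_COLS)].to_numpy()))
        panel = simulate_coordinate_panel(cfg, 2, np.random.default_rng(23))
        merged = agg[["subject_id", "timepoint"]].copy()
        for tp in ("baseline", "m6"):
            a = z_days[(agg["timepoint"] == tp).to_numpy(), 1]
            b = panel.loc[panel.timepoint == tp, "z"].to_numpy()
            # same mean and spread up to Monte-Carlo error at n=1200
            assert abs(a.mean() - b.mean()) < 4 * np.sqrt(a.var() / len(a) + b.var() / len(b))
            assert abs(a.std() / b.std() - 1.0) < 0.1

    def test_panel_row_count_and_schema(self):
        cfg = TrialConfig(n_intervention=20, n_control=20, seed=2)
        panel = simulate_coordinate_panel(cfg, 1)
        assert len(panel) == 80
        assert set(panel.columns) == {"subject_id", "group", "gender", "age", "timepoint", "time", "z"}
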