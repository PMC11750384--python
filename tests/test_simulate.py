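"""Generator contracts: design conservation, determinism, RT model."""

import numpy as np
import pandas as pd
import pydantic
import pytest

from facespace import SimulationConfig, simulate_battery, simulate_dataset, simulate_fdt
from facespace.learning import forward_rt


def _go(trials):
    return trials[trials["stimulus_category"] == "upright_face"]


class TestDesign:
    def test_trial_and_category_counts(self, small_data, small_config):
        cfg = small_config
        for _, g in small_data.trials.groupby("participant_id"):
            assert len(g) == cfg.n_trials
            counts = g["stimulus_category"].value_counts()
            assert counts["upright_face"] == cfg.n_go_trials
            assert counts["inverted_face"] == cfg.n_inverted
            assert counts["chair"] == cfg.n_chairs

    def test_full_design_counts(self):
        """Default design: 576 trials = 480 upright + 48 inverted + 48 chairs."""
        trials, _ = simulate_fdt(SimulationConfig(n_participants=1, seed=5))
        assert len(trials) == 576
        counts = trials["stimulus_category"].value_counts()
        assert counts.to_dict() == {
            "upright_face": 480,
            "inverted_face": 48,
            "chair": 48,
        }
        assert trials["block"].min() == 1 and trials["block"].max() == 11

    def test_occurrence_and_angle_structure(self, small_data, small_config):
        cfg = small_config
        per_angle = cfg.n_occurrences // cfg.n_viewing_angles
        for (_, _), g in _go(small_data.trials).groupby(
            ["participant_id", "identity_id"]
        ):
            occ = np.sort(g["occurrence"].to_numpy(int))
            assert (occ == np.arange(1, cfg.n_occurrences + 1)).all()
            angle_counts = g.groupby("viewing_angle").size()
            assert (angle_counts == per_angle).all()
            assert len(angle_counts) == cfg.n_viewing_angles
            assert g["typicality"].nunique() == 1

    def test_half_identities_each_typicality(self, small_data):
        typ = (
            _go(small_data.trials)
            .groupby("identity_id")["typicality"]
            .first()
        )
        assert (typ == "typical").sum() == (typ == "distinctive").sum()

    def test_rt_present_iff_go_response(self, small_data):
        t = small_data.trials
        assert t.loc[t["responded"] == "go", "rt_ms"].notna().all()
        assert t.loc[t["responded"] == "nogo", "rt_ms"].isna().all()


class TestDeterminism:
    def test_identical_seed_identical_tables(self, small_config):
        a = simulate_dataset(small_config)
        b = simulate_dataset(small_config)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        pd.testing.assert_frame_equal(a.battery, b.battery)
        pd.testing.assert_frame_equal(a.ground_truth, b.ground_truth)

    def test_battery_consistent_across_entry_points(self, small_config):
        full = simulate_dataset(small_config)
        battery_only = simulate_battery(small_config)
        pd.testing.assert_frame_equal(full.battery, battery_only)

    def test_different_seed_differs(self, small_config):
        a = simulate_dataset(small_config)
        b = simulate_dataset(small_config.model_copy(update={"seed": 999}))
        assert not a.trials["rt_ms"].equals(b.trials["rt_ms"])


class TestRTModel:
    def test_degenerate_all_flat(self):
        cfg = SimulationConfig(
            n_participants=2,
            n_occurrences=10,
            n_inverted=12,
            n_chairs=12,
            trial_noise_sd=0.0,
            typicality_offset=0.0,
            gender_rt_offset=0.0,
            alpha_typical_mean=0.0,
            alpha_distinctive_mean=0.0,
            alpha_between_sd=0.0,
            baseline_rt_between_sd=0.0,
            seed=1,
        )
        trials, _ = simulate_fdt(cfg)
        hits = _go(trials).dropna(subset=["rt_ms"])
        assert np.allclose(hits["rt_ms"], cfg.baseline_rt_mean)

    def test_offset_is_exact_condition_difference(self):
        cfg = SimulationConfig(
            n_participants=3,
            n_occurrences=10,
            n_inverted=12,
            n_chairs=12,
            trial_noise_sd=0.0,
            typicality_offset=10.0,
            alpha_typical_mean=0.0,
            alpha_distinctive_mean=0.0,
            alpha_between_sd=0.0,
            baseline_rt_between_sd=0.0,
            gender_rt_offset=0.0,
            seed=2,
        )
        trials, _ = simulate_fdt(cfg)
        hits = _go(trials).dropna(subset=["rt_ms"])
        means = hits.groupby("typicality")["rt_ms"].mean()
        assert means["distinctive"] - means["typical"] == pytest.approx(
            10.0, abs=1e-9
        )

    def test_noise_free_rts_follow_learning_curve(self):
        """Occurrence 1 anchors RT0; later occurrences sit on the curve."""
        cfg = SimulationConfig(
            n_participants=2,
            n_occurrences=10,
            n_inverted=12,
            n_chairs=12,
            trial_noise_sd=0.0,
            typicality_offset=0.0,
            gender_rt_offset=0.0,
            hit_rate_target=1.0,
            seed=3,
        )
        trials, truth = simulate_fdt(cfg)
        hits = _go(trials)
        key = truth.set_index(["participant_id", "identity_id"])
        for (pid, ident), g in hits.groupby(["participant_id", "identity_id"]):
            row = key.loc[(pid, ident)]
            rt0, alpha = row["true_rt0"], row["true_alpha"]
            g = g.sort_values("occurrence")
            rts = g["rt_ms"].to_numpy(float)
            occ = g["occurrence"].to_numpy(int)
            assert rts[0] == pytest.approx(rt0, abs=1e-9)
            expected = forward_rt(rt0, alpha, occ[1:], rt_inf=cfg.rt_asymptote)
            np.testing.assert_allclose(rts[1:], expected, rtol=1e-12)

    def test_hit_and_fa_rates_near_targets(self, small_data, small_config):
        t = small_data.trials
        go = _go(t)
        nogo = t[t["stimulus_category"] != "upright_face"]
        assert (go["responded"] == "go").mean() == pytest.approx(
            small_config.hit_rate_target, abs=0.02
        )
        assert (nogo["responded"] == "go").mean() == pytest.approx(
            small_config.fa_rate_target, abs=0.05
        )


class TestBattery:
    def test_degenerate_zero_sd_hits_means(self):
        cfg = SimulationConfig(
            n_participants=4, battery_sds=(0.0, 0.0, 0.0, 0.0), seed=4
        )
        battery = simulate_battery(cfg)
        for test, mean in zip(
            ("cfmt_plus", "ybt", "gfmt2_s", "jbfft"), cfg.battery_means
        ):
            assert np.allclose(battery[test], mean)

    def test_independent_tests_uncorrelated(self):
        eye = tuple(tuple(float(i == j) for j in range(4)) for i in range(4))
        cfg = SimulationConfig(
            n_participants=5000, battery_corr=eye, seed=6
        )
        corr = simulate_battery(cfg)[
            ["cfmt_plus", "ybt", "gfmt2_s", "jbfft"]
        ].corr()
        off = corr.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_default_correlations_recovered(self):
        cfg = SimulationConfig(n_participants=5000, seed=7)
        corr = simulate_battery(cfg)[
            ["cfmt_plus", "ybt", "gfmt2_s", "jbfft"]
        ].corr()
        target = np.asarray(cfg.battery_corr)
        assert np.abs(corr.to_numpy() - target).max() < 0.05

    def test_scores_within_legal_ranges(self, small_data):
        b = small_data.battery
        assert b["cfmt_plus"].between(0, 102).all()
        assert b["ybt"].between(0, 35).all()
        assert b["gfmt2_s"].between(0, 40).all()
        assert b["jbfft"].between(0, 1).all()

    def test_missingness_leaves_one_test(self):
        cfg = SimulationConfig(
            n_participants=40, battery_missing_rate=0.5, seed=8
        )
        b = simulate_battery(cfg)
        n_present = b[["cfmt_plus", "ybt", "gfmt2_s", "jbfft"]].notna().sum(
            axis=1
        )
        assert (n_present >= 1).all()
        assert b.isna().any().any()


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("hit_rate_target", 1.5),
            ("trial_noise_sd", -1.0),
            ("n_participants", 0),
            ("alpha_typical_mean", -0.1),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(pydantic.ValidationError) as exc:
            SimulationConfig(**{field: value})
        assert field in str(exc.value)

    def test_asymptote_must_undercut_baseline(self):
        with pytest.raises(pydantic.ValidationError, match="rt_asymptote"):
            SimulationConfig(baseline_rt_mean=150.0)

    def test_non_psd_correlation_rejected(self):
        bad = (
            (1.0, 0.99, -0.99, 0.0),
            (0.99, 1.0, 0.99, 0.0),
            (-0.99, 0.99, 1.0, 0.0),
            (0.0, 0.0, 0.0, 1.0),
        )
        with pytest.raises(pydantic.ValidationError, match="battery_corr"):
            SimulationConfig(battery_corr=bad)
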