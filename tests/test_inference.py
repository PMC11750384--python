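"""Typicality contrasts, Bayes factors, rank tests, correlations, models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from facespace import (
    SimulationConfig,
    aggregate_score,
    battery_correlations,
    bic_bayes_factor,
    filter_rts,
    fit_alpha_model,
    fit_rt_model,
    group_compare_rank,
    simulate_dataset,
    typicality_contrast,
)
from facespace.learning import learning_rate_table


def _paired_hits(typical, distinctive):
    rows = []
    for i, (t, d) in enumerate(zip(typical, distinctive)):
        rows += [
            {
                "participant_id": f"p{i}",
                "typicality": "typical",
                "rt_ms": t,
            },
            {
                "participant_id": f"p{i}",
                "typicality": "distinctive",
                "rt_ms": d,
            },
        ]
    return pd.DataFrame(rows)


class TestTypicalityContrast:
    def test_hand_computed_paired_stats(self):
        # paired differences [2, 0, 4, -2]
        res = typicality_contrast(
            _paired_hits([10, 10, 10, 10], [12, 10, 14, 8])
        )
        assert res.mean_diff_ms == pytest.approx(1.0)
        assert res.sd_diff_ms == pytest.approx(2.582, abs=1e-3)
        assert res.cohens_d == pytest.approx(0.387, abs=1e-3)
        assert res.t == pytest.approx(0.775, abs=1e-3)
        assert res.df == 3
        assert res.d_ci_low < res.cohens_d < res.d_ci_high

    def test_no_difference_is_null(self):
        res = typicality_contrast(
            _paired_hits([10, 20, 30], [10, 20, 30])
        )
        assert res.mean_diff_ms == 0.0
        assert res.degenerate  # zero-variance differences
        assert res.p == 1.0

    def test_constant_offset_degenerate_flagged(self):
        res = typicality_contrast(
            _paired_hits([10, 20, 30], [20, 30, 40])
        )
        assert res.mean_diff_ms == pytest.approx(10.0)
        assert res.degenerate and np.isinf(res.t)

    def test_recovers_generator_offset(self):
        cfg = SimulationConfig(
            n_participants=30,
            n_occurrences=10,
            n_inverted=12,
            n_chairs=12,
            typicality_offset=10.0,
            trial_noise_sd=50.0,
            seed=21,
        )
        t = simulate_dataset(cfg).trials
        hits = t[
            (t["stimulus_category"] == "upright_face")
            & (t["responded"] == "go")
        ]
        res = typicality_contrast(hits)
        se = res.sd_diff_ms / np.sqrt(res.n_pairs)
        assert abs(res.mean_diff_ms - 10.0) < 3 * se


class TestBayesFactor:
    def test_equal_bic_unity(self):
        assert bic_bayes_factor(10.0, 10.0).bf10 == 1.0

    def test_direct_values(self):
        assert bic_bayes_factor(10.0, 8.0).bf10 == pytest.approx(np.e)
        assert bic_bayes_factor(8.0, 10.0).bf10 == pytest.approx(1 / np.e)

    @given(
        a=st.floats(-500, 500, allow_nan=False),
        b=st.floats(-500, 500, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_reciprocal_symmetry(self, a, b):
        assert bic_bayes_factor(a, b).bf10 * bic_bayes_factor(
            b, a
        ).bf10 == pytest.approx(1.0, rel=1e-12)

    def test_requires_finite(self):
        with pytest.raises(ValueError):
            bic_bayes_factor(np.inf, 1.0)


class TestRankSum:
    def test_extreme_separation_exact(self):
        res = group_compare_rank([1, 2], [3, 4])
        assert res.w == 0.0
        assert res.method == "exact"
        assert res.p == pytest.approx(1 / 3)

    def test_identical_groups(self):
        res = group_compare_rank([1, 2], [1, 2])
        assert res.p == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        a, b = [3.1, 4.5, 2.2, 6.0], [5.5, 1.0, 7.7]
        r1 = group_compare_rank(a, b)
        r2 = group_compare_rank(b, a)
        assert r1.p == pytest.approx(r2.p)
        assert r1.w + r2.w == len(a) * len(b)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare_rank([], [1.0])


class TestBatteryCorrelations:
    def test_linear_pair_is_unity(self):
        b = pd.DataFrame(
            {
                "participant_id": ["a", "b", "c"],
                "cfmt_plus": [1, 2, 3],
                "ybt": [2, 4, 6],
            }
        )
        res = battery_correlations(b)
        assert res.r.loc["cfmt_plus", "ybt"] == pytest.approx(1.0)
        assert res.r.loc["cfmt_plus", "cfmt_plus"] == 1.0

    def test_hand_computed_r(self):
        b = pd.DataFrame(
            {
                "participant_id": list("abcd"),
                "cfmt_plus": [1, 2, 3, 4],
                "ybt": [2, 1, 4, 3],
            }
        )
        res = battery_correlations(b)
        assert res.r.loc["cfmt_plus", "ybt"] == pytest.approx(0.6)

    def test_too_few_pairs_rejected(self):
        b = pd.DataFrame(
            {
                "participant_id": list("abc"),
                "cfmt_plus": [1, 2, 3],
                "ybt": [2, np.nan, 6],
            }
        )
        with pytest.raises(ValueError, match="complete pairs"):
            battery_correlations(b)

    def test_simulated_battery_correlations_positive(self, small_data):
        cfg = SimulationConfig(n_participants=400, seed=31)
        from facespace import simulate_battery

        res = battery_correlations(simulate_battery(cfg))
        off = res.r.to_numpy()[~np.eye(4, dtype=bool)]
        assert (off > 0).all()


class TestRTModel:
    def test_interaction_coupling_recovered(self):
        """The typicality x score coefficient estimates the generator's
        ability-coupling slope (ms per composite-rank unit)."""
        cfg = SimulationConfig(
            n_participants=40,
            n_occurrences=10,
            n_inverted=12,
            n_chairs=12,
            ability_rt_coupling=0.8,
            trial_noise_sd=40.0,
            seed=23,
        )
        data = simulate_dataset(cfg)
        cleaned = filter_rts(data.trials)
        comp = aggregate_score(data.battery).table.merge(
            data.battery[["participant_id", "gender"]], on="participant_id"
        )
        rep = fit_rt_model(cleaned, comp, random_slope=False)
        row = rep.fit.coef("distinctive:score")
        assert abs(row["estimate"] - 0.8) < 3 * row["se"]

    def test_gender_effect_recovered(self, small_cleaned, small_composites):
        rep = fit_rt_model(
            small_cleaned, small_composites, random_slope=False
        )
        male = rep.fit.coef("male")
        # generator default: males 15 ms slower
        assert abs(male["estimate"] - 15.0) < 4 * male["se"]

    def test_report_serialises(self, small_cleaned, small_composites):
        rep = fit_rt_model(small_cleaned, small_composites, random_slope=False)
        d = rep.to_dict()
        assert "coefficients" in d and "bf10_interaction" in d


@pytest.fixture(scope="module")
def alpha_inputs(small_cleaned, small_composites):
    lr = learning_rate_table(small_cleaned.hits())
    return lr.table, small_composites


class TestAlphaModels:
    def test_both_scales_fitted_and_best_selected(self, alpha_inputs):
        lr_table, comp = alpha_inputs
        res = fit_alpha_model(lr_table, comp, random_slope=False)
        assert res.best_scale in {"original", "log"}
        assert np.isfinite(res.linear.fit.bic)
        assert res.n_dropped_log == (lr_table["alpha"] <= 0).sum()

    def test_outcome_scaling_equivariance(self, alpha_inputs):
        """Scaling the outcome by k scales estimates by k, leaves t alone."""
        lr_table, comp = alpha_inputs
        base = fit_alpha_model(lr_table, comp, random_slope=False)
        scaled_tab = lr_table.assign(alpha=lr_table["alpha"] * 1000.0)
        scaled = fit_alpha_model(scaled_tab, comp, random_slope=False)
        np.testing.assert_allclose(
            scaled.linear.fit.params["estimate"],
            base.linear.fit.params["estimate"] * 1000.0,
            rtol=1e-5,
        )
        np.testing.assert_allclose(
            scaled.linear.fit.params["t"],
            base.linear.fit.params["t"],
            rtol=1e-4,
        )

    def test_two_participants_required(self, alpha_inputs):
        lr_table, comp = alpha_inputs
        one = lr_table[lr_table["participant_id"] == "p001"]
        with pytest.raises(ValueError, match="participants"):
            fit_alpha_model(one, comp)
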