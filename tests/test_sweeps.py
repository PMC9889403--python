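"""Parameter-space sweeps, trend classification, gate and cascade comparisons."""

import numpy as np
import pytest

from gtpase_dora import (
    FeedbackLogic,
    HillSpec,
    Kinetics,
    KineticParameters,
    ModelSpec,
    Regime,
    RegimePreset,
    SweepConfig,
    TrendLabel,
    activation_levels,
    binned_mean_metric,
    classify_trend,
    compare_cascade,
    compare_logic_gates,
    default_feedback_grid,
    dora_result,
    match_or_feedback_strength,
    preset_for_regime,
    sample_parameter_space,
    sweep_single_parameter,
)
from gtpase_dora.steady_state import _mG_fixed_point, _tG_star_of_y, _tGEF_of_y


class TestClassifyTrend:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([3, 2, 1], TrendLabel.DECREASING),
            ([1, 2, 3], TrendLabel.INCREASING),
            ([1, 0.5, 0.8], TrendLabel.DEC_THEN_INC),
            ([0.5, 1.0, 0.7], TrendLabel.INC_THEN_DEC),
            ([1.0], TrendLabel.FLAT),
            ([1.0, 1.0, 1.0], TrendLabel.FLAT),
        ],
    )
    def test_basic_patterns(self, values, expected):
        assert classify_trend(values, 0.01).label is expected

    def test_sub_tolerance_wiggle_is_flat(self):
        eps = 5e-3
        t = classify_trend([1.0, 1.0 + eps, 1.0 - eps], tolerance=0.01)
        assert t.label is TrendLabel.FLAT

    def test_appending_sub_tolerance_values_is_invariant(self):
        base = [1.0, 0.6, 0.9]
        lab = classify_trend(base, 0.01).label
        assert classify_trend(base + [0.9 * (1 + 5e-3)], 0.01).label is lab

    def test_cumulative_drift_beyond_tolerance_counts(self):
        # each step is below tolerance but the drift is monotone and large
        vals = np.linspace(1.0, 0.5, 200)
        assert classify_trend(vals, 0.01).label is TrendLabel.DECREASING

    def test_two_sign_changes_flagged_ambiguous(self):
        t = classify_trend([1.0, 0.5, 0.9, 0.4], 0.01)
        assert t.ambiguous and t.label is None


class TestSampling:
    def test_empty_and_deterministic(self, params, ma_spec):
        cfg = SweepConfig(base=params, spec=ma_spec,
                          ranges={"k_on_mG": (0.1, 10)}, n_samples=0, seed=5)
        assert sample_parameter_space(cfg) == []
        cfg2 = SweepConfig(base=params, spec=ma_spec,
                           ranges={"k_on_mG": (0.1, 10)}, n_samples=10, seed=5)
        assert sample_parameter_space(cfg2) == sample_parameter_space(cfg2)

    def test_samples_within_ranges_log_uniform(self, params, ma_spec):
        cfg = SweepConfig(base=params, spec=ma_spec,
                          ranges={"k_on_mGAP": (1e-2, 1.0)}, n_samples=200, seed=9)
        vals = np.array([p.k_on_mGAP for p in sample_parameter_space(cfg)])
        assert vals.min() >= 1e-2 and vals.max() <= 1.0
        # log-uniform: roughly half the draws below the geometric midpoint
        assert 0.3 < np.mean(vals < 0.1) < 0.7

    def test_activation_coverage_non_degenerate(self, params, ma_spec):
        cfg = SweepConfig(
            base=params, spec=ma_spec,
            ranges={"k_on_mG": (1e-2, 1e1), "k_on_tG": (1e-2, 1e1), "k_on_mGAP": (1e-2, 1.0)},
            n_samples=50, seed=2,
        )
        acts = np.array([activation_levels(p, ma_spec)[1] for p in sample_parameter_space(cfg)])
        assert acts.min() < 0.3 and acts.max() > 0.7

    def test_invalid_range_rejected(self, params, ma_spec):
        with pytest.raises(ValueError):
            SweepConfig(base=params, spec=ma_spec, ranges={"k_on_mG": (0.0, 1.0)})


class TestSingleParameterSweep:
    def test_mass_action_mGAP_sweep_improves_alignment(self, params, ma_spec):
        cfg = SweepConfig(base=params, spec=ma_spec,
                          ranges={"k_on_mGAP": (1e-2, 1.0)}, n_sweep_points=9)
        sw = sweep_single_parameter(cfg)
        assert not sw.failures
        assert np.all(np.diff(sw.mG_activation) < 0)
        assert np.all(np.diff(sw.metric_mG) < 0)
        assert np.all(np.diff(sw.metric_tG) < 0)

    def test_single_point_sweep_is_flat(self, params, ma_spec):
        cfg = SweepConfig(base=params, spec=ma_spec,
                          ranges={"k_on_mGAP": (0.5, 0.5)}, n_sweep_points=1)
        sw = sweep_single_parameter(cfg)
        assert len(sw.results) == 1
        assert classify_trend(sw.metric_mG, 0.01).label is TrendLabel.FLAT

    def test_requires_exactly_one_parameter(self, params, ma_spec):
        with pytest.raises(ValueError):
            sweep_single_parameter(
                SweepConfig(base=params, spec=ma_spec,
                            ranges={"k_on_mG": (0.1, 1), "k_on_tG": (0.1, 1)})
            )

    def test_hill_regimes_give_three_trend_shapes(self):
        """Raising mGAP production monotonically lowers activation, but the
        metric trend flips with the starting activation level: falling when
        high, rising when low, with the non-monotone shapes in between."""
        hill = ModelSpec(kinetics=Kinetics.HILL)
        r = (1e-2, 1e1)
        ranges = {"k_on_R": r, "k_on_mG": r, "k_on_tG": r}
        base = KineticParameters(k_on_mGAP=0.01)
        labels = {}
        for regime in (Regime.HIGH_ACTIVATION, Regime.LOW_ACTIVATION):
            p = preset_for_regime(RegimePreset(name=regime, base=base), hill, seed=5, ranges=ranges)
            sw = sweep_single_parameter(
                SweepConfig(base=p, spec=hill, ranges={"k_on_mGAP": (0.01, 1.0)},
                            n_sweep_points=12)
            )
            labels[regime] = classify_trend(sw.metric_mG, 0.01).label
        assert labels[Regime.HIGH_ACTIVATION] is TrendLabel.DECREASING
        assert labels[Regime.LOW_ACTIVATION] is TrendLabel.INCREASING

    def test_hill_scan_orders_trends_by_activation(self):
        """Seeded scan: pure-decreasing sweeps sit at higher starting
        activation than every pure-increasing sweep, with the dec-then-inc
        shapes in between."""
        hill = ModelSpec(kinetics=Kinetics.HILL)
        r = (1e-2, 1e1)
        base = KineticParameters(k_on_mGAP=0.01)
        cfg = SweepConfig(base=base, spec=hill,
                          ranges={"k_on_R": r, "k_on_mG": r, "k_on_tG": r},
                          n_samples=30, seed=2)
        rows = []
        for p in sample_parameter_space(cfg):
            act0 = activation_levels(p, hill)[1]
            sw = sweep_single_parameter(
                SweepConfig(base=p, spec=hill, ranges={"k_on_mGAP": (0.01, 1.0)},
                            n_sweep_points=12)
            )
            rows.append((act0, classify_trend(sw.metric_mG, 0.01).label))
        by = lambda lab: [a for a, l in rows if l is lab]  # noqa: E731
        dec, inc, dti = by(TrendLabel.DECREASING), by(TrendLabel.INCREASING), by(TrendLabel.DEC_THEN_INC)
        assert dec and inc and dti
        assert min(dec) > max(inc)
        assert min(dti) > np.median(inc)


class TestBinnedMeans:
    def test_identical_results_collapse(self):
        from gtpase_dora import DoRAResult

        res = [DoRAResult(0.2, 0.3, 0.55)] * 5
        rows, empty = binned_mean_metric(res, n_bins=10)
        assert len(rows) == 1
        center, mean, sd, count = rows[0]
        assert mean == 0.2 and sd == 0.0 and count == 5
        assert len(empty) == 9

    def test_feedback_space_mean_metric_worse_at_matched_activation(self, params, ma_spec):
        """At equal mGTPase activation levels, randomly parameterized circuits
        with negative feedback align worse on average than circuits without
        (mass action, activation-binned means)."""
        fb = ModelSpec(feedback_logic=FeedbackLogic.AND)
        r = (1e-2, 1e1)
        cfg0 = SweepConfig(base=params, spec=ma_spec,
                           ranges={"k_on_mG": r, "k_on_tG": r, "k_on_mGAP": (1e-2, 1.0)},
                           n_samples=120, seed=21)
        res0 = [dora_result(p, ma_spec) for p in sample_parameter_space(cfg0)]
        cfg1 = SweepConfig(base=params, spec=fb,
                           ranges={"k_on_mG": r, "k_on_tG": r, "k_feedback": (1e-1, 10**2.6)},
                           n_samples=120, seed=22)
        res1 = [dora_result(p, fb) for p in sample_parameter_space(cfg1)]
        means0, _ = binned_mean_metric(res0, n_bins=8)
        means1, _ = binned_mean_metric(res1, n_bins=8)
        d0 = {c: m for c, m, _, n in means0 if n >= 3}
        d1 = {c: m for c, m, _, n in means1 if n >= 3}
        shared = set(d0) & set(d1)
        assert len(shared) >= 4
        for c in shared:
            assert d1[c] >= d0[c]

    def test_mass_action_binned_means_increase_with_activation(self, params, ma_spec):
        cfg = SweepConfig(
            base=params, spec=ma_spec,
            ranges={"k_on_mG": (1e-2, 1e1), "k_on_tG": (1e-2, 1e1), "k_on_mGAP": (1e-2, 1.0)},
            n_samples=80, seed=3,
        )
        res = [dora_result(p, ma_spec) for p in sample_parameter_space(cfg)]
        rows, _ = binned_mean_metric(res, n_bins=8)
        means = [m for _, m, _, _ in rows]
        assert all(a < b for a, b in zip(means, means[1:]))


class TestLogicGateMatching:
    def test_zero_feedback_maps_to_zero(self, params, ma_spec):
        assert match_or_feedback_strength(params, ma_spec, 0.0) == 0.0

    @pytest.mark.parametrize("kinetics", list(Kinetics))
    def test_matched_activation_equality(self, params, kinetics):
        spec = ModelSpec(kinetics=kinetics)
        k_and = 5.0
        k_or = match_or_feedback_strength(params, spec, k_and)
        and_spec = ModelSpec(kinetics=kinetics, feedback_logic=FeedbackLogic.AND)
        or_spec = ModelSpec(kinetics=kinetics, feedback_logic=FeedbackLogic.OR)
        _, y_and, _ = activation_levels(params.replace(k_feedback=k_and), and_spec)
        _, y_or, _ = activation_levels(params.replace(k_feedback=k_or), or_spec)
        assert abs(y_and - y_or) < 1e-8

    def test_root_agrees_with_closed_form_ratio(self, params, ma_spec):
        k_and = 3.0
        k_or = match_or_feedback_strength(params, ma_spec, k_and)
        and_spec = ModelSpec(feedback_logic=FeedbackLogic.AND)
        y_max = _mG_fixed_point(1.0, params.replace(k_feedback=k_and), and_spec)
        h1 = _tGEF_of_y(y_max, params, ma_spec)
        h2 = _tG_star_of_y(y_max, params, ma_spec)
        assert k_or == pytest.approx(k_and * h1 * h2 / (h1 + h2), abs=1e-8)

    def test_eq22_matched_feedback_inequality_pointwise(self, params, ma_spec):
        """(k_OR/k_AND)·(1/h1(y) + 1/h2(y)) >= 1 at every dose, with equality
        at saturation — the OR gate never deactivates less than AND."""
        k_and = 8.0
        k_or = match_or_feedback_strength(params, ma_spec, k_and)
        and_spec = ModelSpec(feedback_logic=FeedbackLogic.AND)
        p = params.replace(k_feedback=k_and)
        for S in np.logspace(-3, 3, 13):
            x = S / (S + 1.0)
            y = _mG_fixed_point(x, p, and_spec)
            if y == 0:
                continue
            h1 = _tGEF_of_y(y, params, ma_spec)
            h2 = _tG_star_of_y(y, params, ma_spec)
            assert (k_or / k_and) * (1.0 / h1 + 1.0 / h2) >= 1.0 - 1e-12

    def test_mass_action_or_never_worse_and_near_diagonal(self, params, ma_spec):
        rng = np.random.default_rng(31)
        cfg = SweepConfig(
            base=params, spec=ma_spec,
            ranges={"k_on_mG": (1e-1, 1e1), "k_on_tG": (1e-1, 1e1)},
            n_samples=12, seed=4,
        )
        sets = sample_parameter_space(cfg)
        k_and = 10 ** rng.uniform(-1, 2.6, size=len(sets))
        pairs, mean_dist, failures = compare_logic_gates(sets, k_and, ma_spec)
        assert not failures
        for q in pairs:
            assert q["metric_OR"] <= q["metric_AND"] + 1e-10
        # coarse proximity check at this small sample; the 10%-of-scale bound
        # is asserted at the full 500-pair design in the acceptance suite
        scale = np.mean([[q["metric_AND"], q["metric_OR"]] for q in pairs])
        assert mean_dist <= 0.2 * scale

    def test_zero_feedback_pairs_sit_on_diagonal(self, params, ma_spec):
        pairs, mean_dist, _ = compare_logic_gates([params], [0.0], ma_spec)
        assert pairs[0]["metric_AND"] == pairs[0]["metric_OR"]
        assert mean_dist == 0.0


class TestCascadeComparison:
    def test_mass_action_tG_never_better(self, params, ma_spec):
        cfg = SweepConfig(
            base=params, spec=ma_spec,
            ranges={"k_on_mG": (1e-2, 1e1), "k_on_tG": (1e-2, 1e1), "k_on_mGAP": (1e-2, 1.0)},
            n_samples=40, seed=6,
        )
        res = [dora_result(p, ma_spec) for p in sample_parameter_space(cfg)]
        cc = compare_cascade(res)
        assert cc["n_below"] == 0

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            compare_cascade([])


def test_default_feedback_grid_contract():
    g = default_feedback_grid()
    assert g[0] == 0.0
    assert np.all(np.diff(g) > 0)
    assert g[-1] == pytest.approx(10**2.6)
    assert len(g) == 9


class TestRegimePresets:
    def test_high_and_low_presets_hit_their_windows(self, ma_spec):
        hi = preset_for_regime(Regime.HIGH_ACTIVATION, ma_spec, seed=1)
        lo = preset_for_regime(Regime.LOW_ACTIVATION, ma_spec, seed=1)
        assert activation_levels(hi, ma_spec)[1] >= 0.8
        assert activation_levels(lo, ma_spec)[1] <= 0.2

    def test_deterministic_under_seed(self, ma_spec):
        a = preset_for_regime(Regime.INTERMEDIATE_ACTIVATION, ma_spec, seed=8)
        b = preset_for_regime(Regime.INTERMEDIATE_ACTIVATION, ma_spec, seed=8)
        assert a == b
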