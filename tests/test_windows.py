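"""Tests for window detection, curve completion, smoothing and profiles."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import dense_grid_window_oracle
from resistwin import synth, windows
from resistwin.windows import (
    CompletionRule,
    MortalityCurve,
    WindowReport,
    complete_curve,
    detect_dominance_window,
    detect_selection_window,
    dominance_profile,
    resistance_time_profile,
    selection_profile,
    smooth_mortality,
    window_metrics,
)


def _curve(axis, axis_kind="concentration", **arms):
    return MortalityCurve(axis_kind=axis_kind, axis=np.asarray(axis, float),
                          arms={k: np.asarray(v, float) for k, v in arms.items()})


class TestSmoothing:
    def test_constant_series_preserved(self):
        axis = np.logspace(-2, 1, 8)
        curve = _curve(axis, R=np.full(8, 0.4), S=np.full(8, 0.4))
        out = smooth_mortality(curve)
        assert np.allclose(out.arms["R"], 0.4)

    def test_linear_on_log_axis_reproduced(self):
        axis = np.logspace(-2, 2, 9)
        lin = np.linspace(0.05, 0.95, 9)
        out = smooth_mortality(_curve(axis, R=lin))
        assert np.allclose(out.arms["R"], lin, atol=1e-9)

    def test_noise_reduced_against_generating_curve(self):
        rng = np.random.default_rng(11)
        axis = np.logspace(-3, 1, 20)
        arm = synth.ArmDoseResponse(lc50=0.1, slope=2.0)
        truth = synth.loglogistic_mortality(axis, arm)
        noisy = np.clip(truth + rng.normal(0, 0.08, len(axis)), 0, 1)
        out = smooth_mortality(_curve(axis, S=noisy), span=0.5)
        rmse_raw = np.sqrt(np.mean((noisy - truth) ** 2))
        rmse_smooth = np.sqrt(np.mean((out.arms["S"] - truth) ** 2))
        assert rmse_smooth < rmse_raw

    def test_too_few_points_passes_through_with_warning(self):
        axis = np.array([0.1, 1.0, 10.0])
        series = np.array([0.1, 0.8, 0.9])
        out = smooth_mortality(_curve(axis, R=series))
        assert np.allclose(out.arms["R"], series)
        assert "R" in out.metadata["smoothing_warnings"]

    def test_bad_span_rejected(self):
        curve = _curve(np.logspace(-1, 1, 5), R=np.linspace(0, 1, 5))
        with pytest.raises(ValueError):
            smooth_mortality(curve, span=0.0)


class TestCompleteCurve:
    def test_missing_low_concentration_rr_filled_with_zero(self):
        axis = np.array([0.5, 1.0, 5.0, 10.0])
        rr = np.array([np.nan, np.nan, 0.4, 0.9])
        out = complete_curve(_curve(axis, RR=rr), [CompletionRule("RR", 0.0, hi=1.0)])
        assert np.allclose(out.arms["RR"], [0.0, 0.0, 0.4, 0.9])

    def test_missing_high_concentration_ss_filled_with_one(self):
        axis = np.array([0.001, 0.01, 0.1, 1.0])
        ss = np.array([0.1, 0.6, np.nan, np.nan])
        out = complete_curve(_curve(axis, SS=ss), [CompletionRule("SS", 1.0, lo=0.05)])
        assert np.allclose(out.arms["SS"], [0.1, 0.6, 1.0, 1.0])

    def test_gapless_curve_unchanged(self):
        axis = np.logspace(-1, 1, 5)
        series = np.linspace(0.1, 0.9, 5)
        out = complete_curve(_curve(axis, SS=series), [])
        assert np.allclose(out.arms["SS"], series)

    def test_rule_overlapping_observation_rejected(self):
        axis = np.array([0.5, 1.0, 5.0])
        rr = np.array([0.2, np.nan, 0.9])
        with pytest.raises(ValueError, match="overlaps observed"):
            complete_curve(_curve(axis, RR=rr), [CompletionRule("RR", 0.0, hi=1.0)])


class TestSelectionWindowDetection:
    def test_identical_strains_yield_no_window(self):
        axis = np.logspace(-2, 1, 10)
        series = np.linspace(0.05, 0.95, 10)
        report = detect_selection_window(_curve(axis, R=series, S=series), smoothed=False)
        assert report.is_empty
        assert window_metrics(report).kind == "no_window"

    def test_single_arm_rejected(self):
        axis = np.logspace(-2, 1, 10)
        with pytest.raises(ValueError):
            detect_selection_window(_curve(axis, S=np.linspace(0, 1, 10)), smoothed=False)

    def test_boundaries_match_dense_grid_oracle(self):
        lc50_s, lc50_r, slope, delta = 0.05, 0.5, 2.5, 0.05
        axis = np.logspace(-4, 2, 30)
        params = {
            "S": synth.ArmDoseResponse(lc50=lc50_s, slope=slope),
            "R": synth.ArmDoseResponse(lc50=lc50_r, slope=slope),
        }
        curve = synth.generate_strain_curves(params, axis)
        report = detect_selection_window(curve, delta=delta, smoothed=False)

        def diff(c):
            return synth.loglogistic_mortality(c, params["S"]) - synth.loglogistic_mortality(
                c, params["R"]
            )

        lo, hi = dense_grid_window_oracle(diff, axis[0], axis[-1], delta)
        step = np.log10(axis[1]) - np.log10(axis[0])
        assert abs(np.log10(report.close_at) - np.log10(lo)) <= step
        assert abs(np.log10(report.open_at) - np.log10(hi)) <= step

    def test_descending_input_gives_same_window(self):
        axis = np.logspace(-4, 2, 30)
        params = {
            "S": synth.ArmDoseResponse(lc50=0.05, slope=2.5),
            "R": synth.ArmDoseResponse(lc50=0.5, slope=2.5),
        }
        curve = synth.generate_strain_curves(params, axis)
        reversed_curve = MortalityCurve(
            axis_kind="concentration",
            axis=curve.axis[::-1],
            arms={k: v[::-1] for k, v in curve.arms.items()},
        )
        a = detect_selection_window(curve, delta=0.05, smoothed=False)
        b = detect_selection_window(reversed_curve, delta=0.05, smoothed=False)
        assert a.open_at == pytest.approx(b.open_at)
        assert np.array_equal(a.open_flags, b.open_flags)


class TestDominance:
    def test_heterozygote_at_ss_gives_zero_everywhere(self):
        axis = np.logspace(-2, 1, 8)
        ss = np.linspace(0.2, 1.0, 8)
        rr = np.linspace(0.0, 0.5, 8)
        h = dominance_profile(_curve(axis, SS=ss, SR=ss.copy(), RR=rr))
        assert np.allclose(h, 0.0)

    def test_published_culex_triple(self):
        axis = np.array([0.1, 1.0])
        curve = _curve(axis, SS=[1.0, 1.0], SR=[0.88, 0.88], RR=[0.0, 0.0])
        assert dominance_profile(curve) == pytest.approx([0.12, 0.12])

    def test_missing_genotype_arm_named(self):
        axis = np.logspace(-2, 1, 5)
        curve = _curve(axis, SS=np.linspace(0, 1, 5), SR=np.linspace(0, 1, 5))
        with pytest.raises(ValueError, match="RR"):
            dominance_profile(curve)

    def test_dominance_rises_as_concentration_declines(self, idealized_curve):
        h = dominance_profile(idealized_curve)
        defined = ~np.isnan(h)
        # ascending axis: h must be non-increasing in concentration
        assert np.all(np.diff(h[defined]) <= 1e-9)

    def test_dominance_window_empty_when_sr_tracks_ss(self):
        axis = np.logspace(-2, 1, 10)
        ss = np.linspace(0.3, 1.0, 10)
        report = detect_dominance_window(
            _curve(axis, SS=ss, SR=ss.copy(), RR=np.zeros(10)), smoothed=False
        )
        assert report.is_empty

    def test_dominance_window_strictly_inside_selection_window(self):
        axis = np.logspace(-4, 2, 30)
        curve = synth.generate_genotype_curves(synth.IDEALIZED_PARAMS, axis)
        sel = detect_selection_window(curve, delta=0.05, smoothed=False)
        dom = detect_dominance_window(curve, delta=0.05, smoothed=False)
        assert not dom.is_empty
        assert np.all(~dom.open_flags | sel.open_flags)
        assert dom.open_flags.sum() < sel.open_flags.sum()

    def test_best_case_scenario_has_no_dominance_window(self, idealized_axis):
        curve = synth.scenario_curves("best", idealized_axis)
        report = detect_dominance_window(curve, smoothed=False)
        assert report.is_empty

    def test_dominance_subset_of_selection_on_random_curves(self):
        rng = np.random.default_rng(7)
        axis = np.logspace(-3, 2, 20)
        for _ in range(50):
            lc_ss = 10 ** rng.uniform(-2.5, -0.5)
            lc_rr = lc_ss * 10 ** rng.uniform(0.5, 2.5)
            lc_sr = lc_ss * (lc_rr / lc_ss) ** rng.uniform(0.1, 0.9)
            params = {
                "SS": synth.ArmDoseResponse(lc50=lc_ss, slope=rng.uniform(1, 4)),
                "SR": synth.ArmDoseResponse(lc50=lc_sr, slope=rng.uniform(1, 4)),
                "RR": synth.ArmDoseResponse(lc50=lc_rr, slope=rng.uniform(1, 4)),
            }
            curve = synth.generate_genotype_curves(params, axis)
            noisy_arms = {
                k: np.clip(v + rng.normal(0, 0.05, len(v)), 0, 1)
                for k, v in curve.arms.items()
            }
            noisy = MortalityCurve("concentration", axis, noisy_arms)
            delta = rng.uniform(0.0, 0.1)
            sel = detect_selection_window(noisy, delta=delta, smoothed=False)
            dom = detect_dominance_window(noisy, delta=delta, smoothed=False)
            assert np.all(~dom.open_flags | sel.open_flags)


class TestProfiles:
    def test_equal_mortalities_give_zero_advantage(self):
        axis = np.logspace(-2, 1, 6)
        flat = np.full(6, 0.5)
        prof = selection_profile(_curve(axis, SS=flat, SR=flat.copy(), RR=flat.copy()))
        for series in prof.z.values():
            assert np.allclose(series, 0.0, atol=1e-12)

    def test_low_kill_beats_high_kill_along_profile(self):
        axis = np.array([0.1, 1.0])
        curve = _curve(axis, SS=[0.24, 1.0], SR=[0.0, 0.88], RR=[0.0, 0.0])
        prof = selection_profile(curve, x=0.3)
        for p0 in (0.01, 1e-4):
            assert prof.z[p0][0] > prof.z[p0][1]

    def test_advantage_peaks_inside_dominance_window(self, idealized_curve):
        prof = selection_profile(idealized_curve)
        for p0, series in prof.z.items():
            peak = np.nanargmax(series)
            assert prof.dominance[peak] > 0

    def test_zero_effectiveness_censors_everywhere(self):
        axis = np.logspace(-2, 1, 5)
        zero = np.zeros(5)
        prof = resistance_time_profile(_curve(axis, SS=zero, SR=zero.copy(), RR=zero.copy()))
        for p0 in prof.censored:
            assert prof.censored[p0].all()

    def test_fastest_resistance_inside_dominance_window(self, idealized_curve):
        prof = resistance_time_profile(idealized_curve, p0_list=(1e-4,))
        gens = np.where(prof.censored[1e-4], np.inf, prof.generations[1e-4])
        best = np.argmin(gens)
        assert np.isfinite(gens[best])
        assert prof.dominance[best] > 0

    def test_censored_outside_selection_window_at_rare_frequency(self, idealized_curve):
        sel = detect_selection_window(idealized_curve, smoothed=False)
        prof = resistance_time_profile(idealized_curve, p0_list=(1e-4,))
        outside = ~sel.open_flags
        assert outside.any()
        assert prof.censored[1e-4][outside].all()

    def test_profile_point_matches_direct_iteration(self, idealized_curve):
        from conftest import six_mass_oracle
        from resistwin.popgen import FitnessSet

        prof = resistance_time_profile(idealized_curve, p0_list=(0.01,))
        i = int(np.nanargmin(np.where(prof.censored[0.01], np.nan, prof.generations[0.01])))
        w = FitnessSet(
            w_ss=1 - idealized_curve.arms["SS"][i],
            w_sr=1 - idealized_curve.arms["SR"][i],
            w_rr=1 - idealized_curve.arms["RR"][i],
        )
        p, gens = 0.01, 0
        while p < 0.5 and gens <= 500:
            p = six_mass_oracle(p, 0.3, w)
            gens += 1
        assert prof.generations[0.01][i] == gens

    def test_reversed_axis_input_yields_identical_profiles(self, idealized_curve):
        reversed_curve = MortalityCurve(
            axis_kind="concentration",
            axis=idealized_curve.axis[::-1],
            arms={k: v[::-1] for k, v in idealized_curve.arms.items()},
        )
        a = selection_profile(idealized_curve, p0_list=(0.01,))
        b = selection_profile(reversed_curve, p0_list=(0.01,))
        assert np.array_equal(a.axis, b.axis)
        assert np.allclose(a.z[0.01], b.z[0.01])


class TestWindowMetrics:
    def _report(self, open_at, close_at, axis_kind="concentration", **kw):
        return WindowReport(
            window_kind="selection",
            axis_kind=axis_kind,
            axis=np.array([close_at, open_at]) if axis_kind == "concentration" else np.array([open_at, close_at]),
            open_flags=np.array([True, True]),
            open_at=open_at,
            close_at=close_at,
            **kw,
        )

    def test_printed_deltamethrin_boundaries_give_320_fold(self):
        measure = window_metrics(self._report(open_at=0.8, close_at=0.0025))
        assert measure.kind == "fold_range"
        assert measure.value == pytest.approx(320.0)

    def test_equal_boundaries_give_unit_fold_range(self):
        measure = window_metrics(self._report(open_at=0.5, close_at=0.5))
        assert measure.value == pytest.approx(1.0)

    def test_fold_range_invariant_to_boundary_labels(self):
        a = window_metrics(self._report(open_at=0.8, close_at=0.0025))
        b = window_metrics(self._report(open_at=0.0025, close_at=0.8))
        assert a.value == pytest.approx(b.value)
        assert a.value >= 1.0

    def test_open_ended_time_window_reports_observed_span(self):
        measure = window_metrics(
            self._report(
                open_at=0.0,
                close_at=18.0,
                axis_kind="time",
                open_unbounded=True,
                close_unbounded=True,
            )
        )
        assert measure.kind == "duration"
        assert measure.value == pytest.approx(18.0)
        assert measure.open_ended
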