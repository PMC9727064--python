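"""LL.4 fitting, IC50 derivation, and LOAEL calls.

The fit is cross-checked against a brute-force grid-search oracle that
profiles the asymptotes by ordinary linear least squares at every grid node —
written independently of the fitting path.
"""

import numpy as np
import pytest

from chipdili.dose_response import (
    DEFAULT_ALT_RULE,
    EndpointCall,
    InsufficientDesignError,
    albumin_ic50,
    bootstrap_ic50,
    fit_ll4,
    ll4,
    loael,
    min_across_days,
)
from chipdili.panel_io import DoseResponseSeries
from chipdili.synthetic_data import DesignStrategy, ll4_truth_series


def make_series(doses, values, endpoint="albumin", day=7):
    return DoseResponseSeries(
        drug="x", donor="d1", endpoint=endpoint, day=day,
        doses=tuple(doses), values=tuple(tuple(v) for v in values),
    )


def noiseless_series(truth, doses, reps=2):
    b, c, d, e = truth
    all_doses = [0.0] + list(doses)
    values = [tuple([float(ll4(x, b, c, d, e))] * reps) for x in all_doses]
    return make_series(all_doses, values)


def grid_oracle(series, n_grid=120):
    """Brute force: dense (b, ln e) grid, asymptotes by lstsq per node."""
    x, y = [], []
    for dose, reps in zip(series.doses, series.values):
        if dose > 0:
            x.extend([dose] * len(reps))
            y.extend(reps)
    x, y = np.asarray(x), np.asarray(y, dtype=float)
    lo, hi = min(series.nonzero_doses), max(series.nonzero_doses)
    best = (np.inf, None)
    for b in np.concatenate([-np.geomspace(0.25, 8, n_grid // 2)[::-1],
                             np.geomspace(0.25, 8, n_grid // 2)]):
        for loge in np.linspace(np.log(lo / 3), np.log(hi * 3), n_grid):
            s = 1.0 / (1.0 + np.exp(np.clip(b * (np.log(x) - loge), -700, 700)))
            A = np.column_stack([1 - s, s])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            rss = float(np.sum((A @ coef - y) ** 2))
            if rss < best[0]:
                best = (rss, (b, coef[0], coef[1], float(np.exp(loge))))
    return best


class TestFitLL4:
    def test_noiseless_exact_recovery(self):
        truth = (1.0, 0.0, 100.0, 10.0)
        s = noiseless_series(truth, np.geomspace(0.1, 300, 8))
        fit = fit_ll4(s)
        assert fit.converged
        for got, want in zip((fit.b, fit.c, fit.d, fit.e), truth):
            assert got == pytest.approx(want, rel=1e-6, abs=1e-6)

    def test_flat_series_flagged_no_effect(self):
        s = make_series([0, 1, 3, 10, 30], [(50.0, 50.0)] * 5)
        fit = fit_ll4(s)
        assert not fit.converged
        assert "no-effect" in fit.message

    def test_too_few_doses_raises(self):
        s = make_series([0, 1, 10], [(1.0,), (1.0,), (1.0,)])
        with pytest.raises(InsufficientDesignError):
            fit_ll4(s)

    def test_matches_grid_oracle_on_random_small_instances(self):
        rng = np.random.default_rng(2024)
        design = DesignStrategy(8, 2)
        for _ in range(20):
            truth = (
                float(rng.uniform(0.5, 3.0)), 0.0,
                float(rng.uniform(50, 150)),
                float(np.exp(rng.uniform(np.log(1), np.log(50)))),
            )
            s = ll4_truth_series(design, truth, sigma=0.10, rng=rng)
            fit = fit_ll4(s)
            rss_oracle, params = grid_oracle(s)
            # the continuous optimum can only improve on the grid optimum
            x, y = [], []
            for dose, reps in zip(s.doses, s.values):
                if dose > 0:
                    x.extend([dose] * len(reps))
                    y.extend(reps)
            rss_fit = float(np.sum((ll4(np.array(x), fit.b, fit.c, fit.d, fit.e) - np.array(y)) ** 2))
            assert rss_fit <= rss_oracle * (1 + 1e-9) + 1e-9
            # and agree with the oracle's location to grid resolution
            assert np.log(fit.e) == pytest.approx(np.log(params[3]), abs=0.15)

    def test_monotone_in_dose_for_single_signed_slope(self):
        x = np.geomspace(0.01, 1000, 50)
        y = ll4(x, 1.3, 5.0, 95.0, 7.0)
        assert np.all(np.diff(y) < 0)
        y_inc = ll4(x, -1.3, 5.0, 95.0, 7.0)
        assert np.all(np.diff(y_inc) > 0)


class TestAlbuminIC50:
    def test_symmetric_curve_ic50_equals_inflection(self):
        s = noiseless_series((1.2, 0.0, 80.0, 12.0), np.geomspace(0.1, 300, 8))
        fit = fit_ll4(s)
        call = albumin_ic50(fit, vehicle_mean=80.0, max_tested=300.0)
        assert not call.is_bound
        assert call.min_toxic_multiple == pytest.approx(12.0, rel=1e-6)

    def test_floor_above_half_effect_is_censored(self):
        s = noiseless_series((1.0, 64.0, 80.0, 12.0), np.geomspace(0.1, 300, 8))
        fit = fit_ll4(s)
        call = albumin_ic50(fit, vehicle_mean=80.0, max_tested=300.0)
        assert call.is_bound and call.min_toxic_multiple == 300.0

    def test_crossing_beyond_max_tested_is_censored(self):
        s = noiseless_series((1.0, 0.0, 100.0, 500.0), np.geomspace(0.1, 300, 8))
        fit = fit_ll4(s)
        call = albumin_ic50(fit, vehicle_mean=100.0, max_tested=300.0)
        assert call.is_bound

    def test_nonconverged_fit_censors_with_warning(self):
        s = make_series([0, 1, 3, 10, 30], [(50.0, 50.0)] * 5)
        fit = fit_ll4(s)
        with pytest.warns(UserWarning, match="censored"):
            call = albumin_ic50(fit, vehicle_mean=50.0, max_tested=30.0)
        assert call.is_bound

    def test_invariant_to_common_response_rescaling(self):
        rng = np.random.default_rng(7)
        s = ll4_truth_series(DesignStrategy(8, 2), (1.5, 0, 100, 20), 0.05, rng)
        call = albumin_ic50(fit_ll4(s), float(np.mean(s.vehicle_values)), s.max_tested)
        k = 37.5
        scaled = make_series(s.doses, [[k * v for v in reps] for reps in s.values])
        call_k = albumin_ic50(
            fit_ll4(scaled), k * float(np.mean(s.vehicle_values)), s.max_tested
        )
        assert call_k.min_toxic_multiple == pytest.approx(
            call.min_toxic_multiple, rel=1e-6
        )

    def test_truth_inside_bootstrap_interval(self):
        # bootstrap needs replicate-rich groups: use the 4x4 allocation
        rng = np.random.default_rng(42)
        s = ll4_truth_series(DesignStrategy(4, 4), (1.5, 0.0, 100.0, 25.0), 0.05, rng)
        boots = bootstrap_ic50(s, n_boot=200, seed=1)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        assert lo <= 25.0 <= hi


class TestLoael:
    def test_all_doses_at_vehicle_level_censored(self):
        s = make_series(
            [0, 1, 10, 100], [(30.0, 31.0), (30.5, 29.5), (30.2, 30.1), (29.9, 30.3)],
            endpoint="ALT",
        )
        call = loael(s)
        assert call.is_bound and call.min_toxic_multiple == 100.0

    def test_alt_doubling_trips_default_rule(self):
        s = make_series(
            [0, 10, 100], [(30.0, 31.0), (30.5, 29.5), (62.0, 60.0)], endpoint="ALT"
        )
        call = loael(s, DEFAULT_ALT_RULE)
        assert not call.is_bound and call.min_toxic_multiple == 100.0

    def test_morphology_score_step_detected(self):
        s = make_series(
            [0, 10, 100], [(0.0, 0.0), (2.0, 2.0), (3.0, 3.0)],
            endpoint="morphology_score",
        )
        call = loael(s)
        assert not call.is_bound and call.min_toxic_multiple == 10.0


class TestMinAcrossDays:
    def test_observed_day_dominates_bound_day(self):
        c3 = EndpointCall("x", "d1", "albumin", 300.0, True, day=3)
        c7 = EndpointCall("x", "d1", "albumin", 33.0, False, day=7)
        best = min_across_days([c3, c7])
        assert best.day == 7 and best.min_toxic_multiple == 33.0

    def test_all_bounds_keep_widest(self):
        c3 = EndpointCall("x", "d1", "ALT", 100.0, True, day=3)
        c7 = EndpointCall("x", "d1", "ALT", 300.0, True, day=7)
        best = min_across_days([c3, c7])
        assert best.is_bound and best.min_toxic_multiple == 300.0
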