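"""Portfolio economics: calibration, screening scenario, NPV, extrapolation.

Golden comparisons against the published interactive workbook require its
parameter sheet, which is not distributable here; those run as skips. The
identity, monotonicity and conservation properties of the model run
unconditionally on the packaged base case.
"""

from pathlib import Path

import numpy as np
import pytest

from chipdili.econ_model import (
    CalibrationError,
    EconConfig,
    EconScenario,
    PhaseParams,
    apply_screen,
    build_base_case,
    dili_fnr_reduction,
    implied_fnr,
    industry_value,
    load_econ_config,
    npv,
    run_scenario,
    sensitivity_analysis,
    uplift,
    uplift_ci,
)
from chipdili.panel_io import ValidationError

WORKBOOK = Path(__file__).with_name("workbook_base_case.yaml")  # not distributed


@pytest.fixture(scope="module")
def config():
    return load_econ_config()


@pytest.fixture(scope="module")
def base(config):
    return build_base_case(config)


def toy_config(p_advance=(1.0, 1.0), shares=None, **kw):
    """Two-phase toy pipeline (preclinical + phase1 ... submission collapsed)."""
    shares = shares or [{"safety": 0, "efficacy": 0, "other": 1.0}] * 5
    names = ("preclinical", "phase1", "phase2", "phase3", "submission")
    pa = list(p_advance) + [1.0] * (5 - len(p_advance))
    phases = [
        PhaseParams(n, cost_per_candidate=1.0, duration=1.0, p_advance=p, failure_shares=s)
        for n, p, s in zip(names, pa, shares)
    ]
    defaults = dict(
        p_unsafe=0.4, p_ineffective=0.5, discount_rate=0.0, launch_value=100.0,
        chip_cost_per_candidate=0.0, dili_share=0.13, chip_sensitivity=0.87,
        global_rd=196.0, small_molecule_share=0.56,
    )
    defaults.update(kw)
    return EconConfig(phases=phases, **defaults)


class TestBaseCase:
    def test_expected_approvals_is_one(self, base):
        assert base.expected_approvals == pytest.approx(1.0, abs=1e-9)

    def test_conservation_at_every_phase(self, base, config):
        n = base.states[0].total
        for state, ph in zip(base.states, config.phases):
            assert state.total == pytest.approx(n, rel=1e-9)
            assert min(state.counts) >= 0
            n *= ph.p_advance

    def test_safety_failures_never_exceed_unsafe_entrants(self, base):
        for state, (f_saf, _, _) in zip(base.states, base.failures):
            assert f_saf <= state.unsafe + 1e-9

    def test_no_attrition_preserves_everything(self):
        cfg = toy_config(p_advance=(1.0,))
        model = build_base_case(cfg)
        assert model.states[0].total == pytest.approx(1.0)
        assert model.expected_approvals == pytest.approx(1.0)
        assert model.states[0].counts == pytest.approx(model.approvals)

    def test_all_other_attrition_keeps_proportions(self):
        cfg = toy_config(p_advance=(0.5,))
        model = build_base_case(cfg)
        q0 = np.array(model.states[0].counts)
        q1 = np.array(model.states[1].counts)
        assert q1.sum() == pytest.approx(q0.sum() * 0.5)
        assert q1 / q1.sum() == pytest.approx(q0 / q0.sum())

    def test_infeasible_cause_shares_name_the_phase(self):
        shares = [{"safety": 1.0, "efficacy": 0.0, "other": 0.0}] + [
            {"safety": 0, "efficacy": 0, "other": 1.0}
        ] * 4
        cfg = toy_config(p_advance=(0.2,), shares=shares, p_unsafe=0.1)
        with pytest.raises(CalibrationError, match="preclinical"):
            build_base_case(cfg)


class TestImpliedFNR:
    def test_perfect_gate(self):
        # all preclinical attrition is safety-related and removes every
        # unsafe candidate: nothing unsafe enters Phase I
        shares = [{"safety": 1.0, "efficacy": 0.0, "other": 0.0}] + [
            {"safety": 0, "efficacy": 0, "other": 1.0}
        ] * 4
        cfg = toy_config(p_advance=(0.6,), shares=shares, p_unsafe=0.4)
        assert implied_fnr(build_base_case(cfg)) == pytest.approx(0.0)

    def test_gate_that_passes_everything(self):
        cfg = toy_config(p_advance=(1.0,))
        assert implied_fnr(build_base_case(cfg)) == pytest.approx(1.0)

    def test_no_unsafe_candidates_is_undefined(self):
        cfg = toy_config(p_unsafe=0.0)
        with pytest.raises(ValidationError):
            implied_fnr(build_base_case(cfg))


class TestApplyScreen:
    def test_identity_scenario_reproduces_base_bit_exactly(self, base, config):
        scen = apply_screen(base, EconScenario(fnr_reduction=0.0, chip_cost_per_candidate=0.0))
        for s_base, s_scen in zip(base.states, scen.states):
            assert s_scen.counts == s_base.counts
        assert npv(scen, config) == npv(base, config)

    def test_full_reduction_removes_all_unsafe_downstream(self, base):
        scen = apply_screen(base, EconScenario(fnr_reduction=1.0))
        for state in scen.states[1:]:
            assert state.unsafe == pytest.approx(0.0, abs=1e-12)

    def test_phase1_intake_held_at_base(self, base):
        scen = apply_screen(base, EconScenario(fnr_reduction=0.3))
        assert scen.states[1].total == pytest.approx(base.states[1].total)

    def test_approvals_monotone_in_fnr_reduction(self, base):
        approvals = [
            apply_screen(base, EconScenario(fnr_reduction=r)).expected_approvals
            for r in (0.0, 0.1, 0.3, 0.6, 1.0)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(approvals, approvals[1:]))
        assert approvals[-1] > approvals[0]

    def test_screened_panel_approvals_beat_base(self, base):
        scen = apply_screen(base, EconScenario(fnr_reduction=0.113))
        assert scen.expected_approvals > base.expected_approvals


class TestNPV:
    def test_undiscounted_is_plain_sum(self):
        cfg = toy_config(p_advance=(0.5,), discount_rate=0.0, launch_value=100.0)
        model = build_base_case(cfg)
        costs = sum(
            ph.cost_per_candidate * st.total for ph, st in zip(cfg.phases, model.states)
        )
        assert npv(model, cfg) == pytest.approx(100.0 * 1.0 - costs)

    def test_zero_costs_is_discounted_launch_value(self):
        cfg = toy_config(p_advance=(0.5,), discount_rate=0.10)
        phases = [
            PhaseParams(p.name, 0.0, p.duration, p.p_advance, p.failure_shares)
            for p in cfg.phases
        ]
        cfg0 = EconConfig(
            phases=phases, p_unsafe=0.4, p_ineffective=0.5, discount_rate=0.10,
            launch_value=100.0, chip_cost_per_candidate=0.0, dili_share=0.13,
            chip_sensitivity=0.87, global_rd=196.0, small_molecule_share=0.56,
        )
        model = build_base_case(cfg0)
        t_total = sum(p.duration for p in phases)
        assert npv(model, cfg0) == pytest.approx(100.0 / 1.10**t_total)

    def test_uplift_identity_and_zero_base_error(self):
        assert uplift(100.0, 100.0) == 0.0
        with pytest.raises(ValidationError):
            uplift(0.0, 1.0)


class TestEconChain:
    def test_dili_fnr_reduction_exact_product(self):
        assert dili_fnr_reduction(0.13, 0.87) == pytest.approx(0.1131, abs=1e-12)
        assert dili_fnr_reduction(0.13, 0.0) == 0.0
        assert dili_fnr_reduction(0.80, 0.87) == pytest.approx(0.696, abs=1e-12)

    def test_industry_value_linear_product(self):
        assert industry_value(0.0, 196.0, 0.56) == 0.0
        assert industry_value(0.028, 196.0, 0.56) == pytest.approx(3.073, abs=1e-3)
        assert industry_value(0.056, 196.0, 0.56) == pytest.approx(2 * 3.0731, abs=1e-3)

    def test_uplift_positive_and_near_linear_in_reduction(self, config):
        # secant deviation over [0, 0.2] below 10% of the range
        grid = np.linspace(0.0, 0.2, 9)
        ups = np.array([run_scenario(config, fnr_reduction=r).uplift for r in grid])
        assert ups[0] == pytest.approx(
            run_scenario(config, fnr_reduction=0.0).uplift
        )
        assert np.all(np.diff(ups) > 0)
        secant = ups[0] + (ups[-1] - ups[0]) * grid / 0.2
        assert np.max(np.abs(ups - secant)) < 0.10 * (ups[-1] - ups[0])

    def test_uplift_ci_ordering(self, config):
        lo, hi = uplift_ci(config, 0.615, 0.960)
        mid = run_scenario(config).uplift
        assert lo < mid < hi

    def test_five_organ_scenario_exceeds_single_organ(self, config):
        single = run_scenario(config).industry_value
        five = run_scenario(
            config, fnr_reduction=dili_fnr_reduction(0.80, 0.87)
        )
        assert five.industry_value > single


class TestSensitivityAnalysis:
    def test_zero_perturbation_changes_nothing(self, config):
        table = sensitivity_analysis(config, perturbation=0.0)
        assert (table["uplift_low"] == table["uplift_base"]).all()
        assert (table["uplift_high"] == table["uplift_base"]).all()

    def test_ten_percent_on_costs_preserves_positive_uplift(self, config):
        cost_params = [p for p in sensitivity_analysis(config, 0.10)["parameter"] if "cost" in p]
        table = sensitivity_analysis(config, 0.10, parameters=cost_params)
        vals = table[["uplift_low", "uplift_high"]].to_numpy().ravel()
        assert np.isfinite(vals).all() and (vals > 0).all()

    def test_invalid_perturbation_skipped_with_warning(self, config):
        with pytest.warns(UserWarning, match="skipped"):
            table = sensitivity_analysis(config, 0.10, parameters=["submission.p_advance"])
        assert np.isnan(table["uplift_high"]).all()


@pytest.mark.skipif(not WORKBOOK.exists(), reason="published workbook parameters not distributed")
class TestWorkbookGolden:
    """Cell-level comparisons against the interactive published model."""

    def test_uplift_matches_published_value(self, config):
        res = run_scenario(config)
        assert res.uplift == pytest.approx(0.028, abs=0.002)

    def test_industry_value_matches_published_value(self, config):
        res = run_scenario(config)
        assert res.industry_value == pytest.approx(3.0, abs=0.3)

    def test_ci_band_matches_published_interval(self, config):
        lo, hi = uplift_ci(config, 0.615, 0.960)
        assert (lo, hi) == (pytest.approx(0.019, abs=0.003), pytest.approx(0.031, abs=0.003))
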