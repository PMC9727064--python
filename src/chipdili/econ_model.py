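"""Drug-development portfolio economics with cause-decomposed attrition.

The model tracks a representative portfolio of candidate drugs through
preclinical development, Phase I-III trials and regulatory submission,
calibrated so the expected number of approvals is exactly one (the "base
case"). Unlike plain attrition models it decomposes each phase's failures
into safety-related, efficacy-related and other causes, and partitions the
portfolio into safe x effective quadrants: safety failures remove unsafe
candidates, efficacy failures remove ineffective candidates, other failures
remove proportionally. That structure exposes the decision quality of the
preclinical toxicology gate as an implied false-negative rate (FNR, the
share of unsafe candidates that slip into Phase I) and lets one price an
improved safety screen: lowering the FNR shifts the Phase I intake toward
safe candidates, more of which survive to approval.

A discounted-cashflow NPV (costs booked at phase start, launch value at
approval, annual discrete discounting) converts the intervention into a
percentage NPV uplift over the base case, which scales to an industry-wide
annual value when applied to global small-molecule R&D spending.

The scenario is conservative: the number of candidates entering Phase I is
held at its base-case value (improved screening redirects rather than
shrinks clinical investment), and per-quadrant phase hazards are frozen at
their base-case values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .panel_io import ValidationError

__all__ = [
    "PhaseParams",
    "PortfolioState",
    "PortfolioModel",
    "EconScenario",
    "EconResult",
    "EconConfig",
    "CalibrationError",
    "load_econ_config",
    "default_config_path",
    "build_base_case",
    "implied_fnr",
    "apply_screen",
    "npv",
    "uplift",
    "run_scenario",
    "dili_fnr_reduction",
    "industry_value",
    "uplift_ci",
    "sensitivity_analysis",
    "QUADRANTS",
]

PHASE_NAMES = ("preclinical", "phase1", "phase2", "phase3", "submission")
QUADRANTS = ("safe_effective", "safe_ineffective", "unsafe_effective", "unsafe_ineffective")
_UNSAFE = np.array([False, False, True, True])
_INEFFECTIVE = np.array([False, True, False, True])


class CalibrationError(ValueError):
    """Cause shares are infeasible for the quadrant composition at some phase."""


@dataclass(frozen=True)
class PhaseParams:
    """One development phase: cost ($M/candidate), duration (years), advance
    probability, and the split of failures into safety/efficacy/other."""

    name: str
    cost_per_candidate: float
    duration: float
    p_advance: float
    failure_shares: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.name not in PHASE_NAMES:
            raise ValidationError(f"unknown phase {self.name!r}")
        if not 0 < self.p_advance <= 1:
            raise ValidationError(f"{self.name}: p_advance must be in (0, 1]")
        if self.duration < 0:
            raise ValidationError(f"{self.name}: duration must be >= 0")
        if self.cost_per_candidate < 0:
            raise ValidationError(f"{self.name}: cost must be >= 0")
        shares = [self.failure_shares.get(k, 0.0) for k in ("safety", "efficacy", "other")]
        if any(s < 0 for s in shares) or abs(sum(shares) - 1.0) > 1e-9:
            raise ValidationError(
                f"{self.name}: failure shares must be >= 0 and sum to 1, got {shares}"
            )

    @property
    def shares(self) -> np.ndarray:
        return np.array(
            [self.failure_shares.get(k, 0.0) for k in ("safety", "efficacy", "other")]
        )


@dataclass(frozen=True)
class PortfolioState:
    """Expected candidate counts entering one phase, by quadrant."""

    phase: str
    counts: tuple[float, float, float, float]  # ordered as QUADRANTS

    @property
    def total(self) -> float:
        return float(sum(self.counts))

    @property
    def unsafe(self) -> float:
        return self.counts[2] + self.counts[3]

    @property
    def ineffective(self) -> float:
        return self.counts[1] + self.counts[3]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(QUADRANTS, self.counts))


@dataclass(frozen=True)
class PortfolioModel:
    """A propagated portfolio: per-phase entrant states, cause-specific
    survival factors, failures by cause, and the approval composition."""

    phases: tuple[PhaseParams, ...]
    states: tuple[PortfolioState, ...]
    approvals: tuple[float, float, float, float]
    survival_factors: tuple[tuple[float, float, float], ...]  # (safety, efficacy, other)
    failures: tuple[tuple[float, float, float], ...]
    chip_cost_total: float = 0.0

    @property
    def expected_approvals(self) -> float:
        return float(sum(self.approvals))


@dataclass(frozen=True)
class EconScenario:
    """An improved preclinical toxicology screen applied at the Phase I gate."""

    fnr_reduction: float
    chip_cost_per_candidate: float = 0.0
    hold_phase1_entrants: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.fnr_reduction <= 1:
            raise ValidationError("fnr_reduction must be in [0, 1]")
        if self.chip_cost_per_candidate < 0:
            raise ValidationError("chip cost must be >= 0")


@dataclass(frozen=True)
class EconResult:
    npv_base: float
    npv_scenario: float
    uplift: float
    industry_value: float | None = None
    ci: tuple[float, float] | None = None


@dataclass(frozen=True)
class EconConfig:
    """Full parameterization: phases, portfolio composition at preclinical
    entry (independent unsafe/ineffective probabilities), financials, chip
    screening economics, and industry extrapolation inputs. All money in $M
    of a single reference year except ``global_rd`` ($B/yr)."""

    phases: Sequence[PhaseParams]
    p_unsafe: float
    p_ineffective: float
    discount_rate: float
    launch_value: float
    chip_cost_per_candidate: float
    dili_share: float
    chip_sensitivity: float
    global_rd: float
    small_molecule_share: float
    hold_phase1_entrants: bool = True

    def __post_init__(self) -> None:
        names = [p.name for p in self.phases]
        if names != list(PHASE_NAMES):
            raise ValidationError(f"phases must be {PHASE_NAMES} in order, got {names}")
        for attr in ("p_unsafe", "p_ineffective", "dili_share", "chip_sensitivity",
                     "small_molecule_share"):
            v = getattr(self, attr)
            if not 0 <= v <= 1:
                raise ValidationError(f"{attr} must be in [0, 1], got {v}")
        if self.discount_rate < 0 or self.launch_value < 0 or self.global_rd < 0:
            raise ValidationError("financial parameters must be >= 0")


def default_config_path() -> Path:
    """Path of the packaged base-case parameter file."""
    return Path(str(resources.files("chipdili").joinpath("data/econ_base_case.yaml")))


def load_econ_config(path: str | Path | None = None) -> EconConfig:
    """Load and validate an economic parameter file (packaged default if None)."""
    path = default_config_path() if path is None else path
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        phases = [
            PhaseParams(
                name=p["name"],
                cost_per_candidate=float(p["cost_per_candidate"]),
                duration=float(p["duration"]),
                p_advance=float(p["p_advance"]),
                failure_shares={k: float(v) for k, v in p["failure_shares"].items()},
            )
            for p in raw["phases"]
        ]
        return EconConfig(
            phases=phases,
            p_unsafe=float(raw["composition"]["p_unsafe"]),
            p_ineffective=float(raw["composition"]["p_ineffective"]),
            discount_rate=float(raw["financials"]["discount_rate"]),
            launch_value=float(raw["financials"]["launch_value"]),
            chip_cost_per_candidate=float(raw["screening"]["chip_cost_per_candidate"]),
            dili_share=float(raw["screening"]["dili_share"]),
            chip_sensitivity=float(raw["screening"]["chip_sensitivity"]),
            global_rd=float(raw["industry"]["global_rd"]),
            small_molecule_share=float(raw["industry"]["small_molecule_share"]),
            hold_phase1_entrants=bool(raw["screening"].get("hold_phase1_entrants", True)),
        )
    except KeyError as exc:
        raise ValidationError(f"{path}: missing economic parameter {exc}") from exc


# ---------------------------------------------------------------------------
# base-case calibration and propagation
# ---------------------------------------------------------------------------

_TOL = 1e-9


def _propagate(
    entrants: np.ndarray, phases: Sequence[PhaseParams]
) -> tuple[list[PortfolioState], list[tuple[float, float, float]], list[tuple[float, float, float]], np.ndarray]:
    """March quadrant counts through the phases under cause-decomposed attrition.

    Per phase, safety failures scale down the unsafe quadrants, efficacy
    failures the ineffective quadrants (after safety removal), and other
    failures all quadrants proportionally; the three jointly reproduce the
    phase's total attrition. Raises :class:`CalibrationError` naming the phase
    when a cause's failures exceed its eligible pool.
    """
    q = entrants.astype(float).copy()
    states, factors, failures = [], [], []
    for ph in phases:
        states.append(PortfolioState(ph.name, tuple(float(v) for v in q)))
        n = q.sum()
        f_total = n * (1.0 - ph.p_advance)
        f_saf, f_eff, f_oth = ph.shares * f_total
        pool_u = q[_UNSAFE].sum()
        if f_saf > pool_u + _TOL:
            raise CalibrationError(
                f"{ph.name}: safety failures ({f_saf:.3f}) exceed unsafe candidates ({pool_u:.3f})"
            )
        s_saf = 1.0 - f_saf / pool_u if pool_u > 0 else 1.0
        q[_UNSAFE] *= s_saf
        pool_i = q[_INEFFECTIVE].sum()
        if f_eff > pool_i + _TOL:
            raise CalibrationError(
                f"{ph.name}: efficacy failures ({f_eff:.3f}) exceed ineffective candidates ({pool_i:.3f})"
            )
        s_eff = 1.0 - f_eff / pool_i if pool_i > 0 else 1.0
        q[_INEFFECTIVE] *= s_eff
        remaining = q.sum()
        if f_oth > remaining + _TOL:
            raise CalibrationError(f"{ph.name}: other failures exceed remaining candidates")
        s_oth = 1.0 - f_oth / remaining if remaining > 0 else 1.0
        q *= s_oth
        q = np.clip(q, 0.0, None)
        factors.append((float(s_saf), float(s_eff), float(s_oth)))
        failures.append((float(f_saf), float(f_eff), float(f_oth)))
    return states, factors, failures, q


def build_base_case(config: EconConfig) -> PortfolioModel:
    """Calibrate the archetypal single-approval portfolio.

    Preclinical entrants are scaled so the advance-probability chain yields an
    expected one approval; the entry composition is the independent product of
    ``p_unsafe`` and ``p_ineffective``.
    """
    p_chain = float(np.prod([p.p_advance for p in config.phases]))
    n0 = 1.0 / p_chain
    u, i = config.p_unsafe, config.p_ineffective
    entrants = n0 * np.array([(1 - u) * (1 - i), (1 - u) * i, u * (1 - i), u * i])
    states, factors, failures, final = _propagate(entrants, config.phases)
    return PortfolioModel(
        phases=tuple(config.phases),
        states=tuple(states),
        approvals=tuple(float(v) for v in final),
        survival_factors=tuple(factors),
        failures=tuple(failures),
    )


def implied_fnr(model: PortfolioModel) -> float:
    """FNR of the preclinical toxicology gate: unsafe candidates entering
    Phase I over unsafe candidates subjected to the gate."""
    u_gate = model.states[0].unsafe
    if u_gate <= 0:
        raise ValidationError("implied FNR undefined: no unsafe candidates at the gate")
    return model.states[1].unsafe / u_gate


def apply_screen(model: PortfolioModel, scenario: EconScenario) -> PortfolioModel:
    """Re-propagate the portfolio with an improved Phase I safety gate.

    Unsafe Phase I entrants are scaled by ``1 - fnr_reduction``. When
    ``hold_phase1_entrants`` the total Phase I intake is restored to its base
    value with candidates of the post-screen composition. Downstream phases
    reuse the base case's cause-specific survival factors, so the safety
    hazard applies only to the remaining unsafe candidates. Chip testing cost
    accrues per candidate screened at the gate (the base Phase I intake).
    """
    q1 = np.array(model.states[1].counts, dtype=float)
    n1_base = q1.sum()
    q1[_UNSAFE] *= 1.0 - scenario.fnr_reduction
    if scenario.hold_phase1_entrants and q1.sum() > 0:
        q1 *= n1_base / q1.sum()
    states = [model.states[0]]
    factors = [model.survival_factors[0]]
    failures = [model.failures[0]]
    q = q1.copy()
    for ph, (s_saf, s_eff, s_oth) in zip(model.phases[1:], model.survival_factors[1:]):
        states.append(PortfolioState(ph.name, tuple(float(v) for v in q)))
        f_saf = q[_UNSAFE].sum() * (1.0 - s_saf)
        q[_UNSAFE] *= s_saf
        f_eff = q[_INEFFECTIVE].sum() * (1.0 - s_eff)
        q[_INEFFECTIVE] *= s_eff
        f_oth = q.sum() * (1.0 - s_oth)
        q *= s_oth
        failures.append((float(f_saf), float(f_eff), float(f_oth)))
        factors.append((s_saf, s_eff, s_oth))
    n_screened = n1_base
    return PortfolioModel(
        phases=model.phases,
        states=tuple(states),
        approvals=tuple(float(v) for v in q),
        survival_factors=tuple(factors),
        failures=tuple(failures),
        chip_cost_total=scenario.chip_cost_per_candidate * n_screened,
    )


# ---------------------------------------------------------------------------
# discounted cashflow
# ---------------------------------------------------------------------------


def npv(model: PortfolioModel, config: EconConfig) -> float:
    """Portfolio NPV ($M): per-phase costs at phase start, launch value at
    approval, annual discrete discounting at the cost of capital."""
    r = config.discount_rate
    disc = lambda t: (1.0 + r) ** (-t)
    t = 0.0
    total = 0.0
    for ph, state in zip(model.phases, model.states):
        if ph.duration < 0:
            raise ValidationError(f"{ph.name}: negative duration")
        total -= ph.cost_per_candidate * state.total * disc(t)
        if ph.name == "phase1" and model.chip_cost_total:
            total -= model.chip_cost_total * disc(t)
        t += ph.duration
    total += config.launch_value * model.expected_approvals * disc(t)
    return float(total)


def uplift(npv_base: float, npv_scenario: float) -> float:
    """Relative NPV gain of the scenario over the base case."""
    if npv_base == 0:
        raise ValidationError("uplift undefined for zero base NPV")
    return (npv_scenario - npv_base) / abs(npv_base)


def dili_fnr_reduction(dili_share: float, chip_sensitivity: float) -> float:
    """Relative FNR reduction from screening one toxicity class: the class's
    share of safety-related trial failures times the assay's sensitivity."""
    for name, v in (("dili_share", dili_share), ("chip_sensitivity", chip_sensitivity)):
        if not 0 <= v <= 1:
            raise ValidationError(f"{name} must be in [0, 1], got {v}")
    return dili_share * chip_sensitivity


def industry_value(uplift_frac: float, global_rd: float, small_molecule_share: float) -> float:
    """Annual industry-wide value ($B/yr): uplift x global R&D spend ($B/yr)
    x small-molecule share."""
    if global_rd < 0 or not 0 <= small_molecule_share <= 1:
        raise ValidationError("invalid industry extrapolation inputs")
    return uplift_frac * global_rd * small_molecule_share


def run_scenario(
    config: EconConfig,
    fnr_reduction: float | None = None,
    chip_cost_per_candidate: float | None = None,
) -> EconResult:
    """Base case + screening scenario end to end.

    ``fnr_reduction`` defaults to ``dili_share * chip_sensitivity`` from the
    config; chip cost defaults to the config's CRO-style per-candidate price.
    """
    base = build_base_case(config)
    scen = apply_screen(
        base,
        EconScenario(
            fnr_reduction=(
                dili_fnr_reduction(config.dili_share, config.chip_sensitivity)
                if fnr_reduction is None
                else fnr_reduction
            ),
            chip_cost_per_candidate=(
                config.chip_cost_per_candidate
                if chip_cost_per_candidate is None
                else chip_cost_per_candidate
            ),
            hold_phase1_entrants=config.hold_phase1_entrants,
        ),
    )
    npv_b, npv_s = npv(base, config), npv(scen, config)
    up = uplift(npv_b, npv_s)
    return EconResult(
        npv_base=npv_b,
        npv_scenario=npv_s,
        uplift=up,
        industry_value=industry_value(up, config.global_rd, config.small_molecule_share),
    )


def uplift_ci(config: EconConfig, sens_low: float, sens_high: float) -> tuple[float, float]:
    """Propagate the chip-sensitivity confidence interval through the FNR
    reduction into an uplift interval."""
    ups = [
        run_scenario(config, fnr_reduction=dili_fnr_reduction(config.dili_share, s)).uplift
        for s in (sens_low, sens_high)
    ]
    return (min(ups), max(ups))


# ---------------------------------------------------------------------------
# sensitivity analysis
# ---------------------------------------------------------------------------


def _scalar_params(config: EconConfig) -> dict[str, float]:
    out: dict[str, float] = {
        "discount_rate": config.discount_rate,
        "launch_value": config.launch_value,
        "chip_cost_per_candidate": config.chip_cost_per_candidate,
        "p_unsafe": config.p_unsafe,
        "p_ineffective": config.p_ineffective,
    }
    for ph in config.phases:
        out[f"{ph.name}.cost_per_candidate"] = ph.cost_per_candidate
        out[f"{ph.name}.duration"] = ph.duration
        out[f"{ph.name}.p_advance"] = ph.p_advance
    return out


def _with_param(config: EconConfig, name: str, value: float) -> EconConfig:
    if "." in name:
        phase_name, attr = name.split(".", 1)
        phases = [
            replace(ph, **{attr: value}) if ph.name == phase_name else ph
            for ph in config.phases
        ]
        return replace(config, phases=phases)
    return replace(config, **{name: value})


def sensitivity_analysis(
    config: EconConfig,
    perturbation: float = 0.10,
    parameters: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Uplift under +/- relative perturbation of each scalar input.

    Reports per parameter the perturbed uplifts and an elasticity (relative
    uplift change per relative parameter change, central difference). Invalid
    perturbed configurations are skipped with a warning.
    """
    base_result = run_scenario(config)
    baseline = _scalar_params(config)
    names = list(parameters) if parameters is not None else list(baseline)
    rows = []
    for name in names:
        if name not in baseline:
            warnings.warn(f"unknown parameter {name!r} skipped")
            continue
        v0 = baseline[name]
        ups = {}
        for sign, label in ((-1, "low"), (+1, "high")):
            try:
                cfg = _with_param(config, name, v0 * (1 + sign * perturbation))
                ups[label] = run_scenario(cfg).uplift
            except (ValidationError, CalibrationError) as exc:
                warnings.warn(f"{name} {label}: {exc}; skipped")
                ups[label] = float("nan")
        if perturbation > 0 and np.isfinite([ups["low"], ups["high"]]).all() and base_result.uplift != 0:
            elasticity = (ups["high"] - ups["low"]) / (2 * perturbation * abs(base_result.uplift))
        else:
            elasticity = 0.0 if perturbation == 0 else float("nan")
        rows.append(
            {
                "parameter": name,
                "base_value": v0,
                "uplift_low": ups["low"],
                "uplift_base": base_result.uplift,
                "uplift_high": ups["high"],
                "elasticity": float(elasticity),
            }
        )
    return pd.DataFrame(rows)
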