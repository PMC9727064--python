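"""Synthetic inputs with known ground truth for the whole pipeline.

Generates labelled drug panels with binding parameters, LL.4 albumin
dose-response series (plus correlated ALT / morphology step responses) over
replicate designs matching the chip study (16x1, 8x2, 5x3, 4x4 on log-spaced
grids spanning 0.1-1000x unbound C_max), censored no-effect drugs, and
perturbed economic parameter sets for sensitivity testing.

Noise is additive Gaussian on the response scale by default (sigma expressed
as a fraction of the dynamic range d - c), with a lognormal option. Albumin is
generated as the most sensitive endpoint: ALT and morphology LOAELs sit at or
above the albumin IC50 by a configurable multiplicative shift. Randomness uses
one master seed with per-drug substreams keyed by drug index, so adding a drug
never reshuffles the data of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .panel_io import DoseResponseSeries, DrugRecord, ValidationError

__all__ = [
    "DesignStrategy",
    "NoiseModel",
    "SyntheticPanelSpec",
    "PAPER_STRATEGIES",
    "NOISE_LEVELS",
    "ll4_truth_series",
    "gen_panel",
    "gen_econ_params",
]


@dataclass(frozen=True)
class DesignStrategy:
    """Dose/replicate allocation on a log-spaced grid (n_doses x n_replicates)."""

    n_doses: int
    n_replicates: int
    dose_range: tuple[float, float] = (0.1, 1000.0)
    n_vehicle: int = 3

    def __post_init__(self) -> None:
        if self.n_doses * self.n_replicates > 16:
            raise ValidationError("design exceeds the 16-chip budget")
        if self.n_doses < 1 or self.n_replicates < 1:
            raise ValidationError("need >= 1 dose and >= 1 replicate")
        lo, hi = self.dose_range
        if not (0 < lo < hi):
            raise ValidationError("dose_range must be strictly positive and ascending")

    @property
    def doses(self) -> np.ndarray:
        return np.geomspace(self.dose_range[0], self.dose_range[1], self.n_doses)

    @property
    def label(self) -> str:
        return f"{self.n_doses}x{self.n_replicates}"


#: the four allocation strategies compared for the chip study's cycles 1-4
PAPER_STRATEGIES = (
    DesignStrategy(16, 1),
    DesignStrategy(8, 2),
    DesignStrategy(5, 3),
    DesignStrategy(4, 4),
)


@dataclass(frozen=True)
class NoiseModel:
    """Additive noise level; sigma is a fraction of the dynamic range d - c."""

    level: str
    sigma: float
    kind: str = "gaussian"

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValidationError("sigma must be > 0")
        if self.kind not in ("gaussian", "lognormal"):
            raise ValidationError(f"unknown noise kind {self.kind!r}")


NOISE_LEVELS = {
    "low": NoiseModel("low", 0.05),
    "medium": NoiseModel("medium", 0.15),
    "high": NoiseModel("high", 0.30),
}


def _apply_noise(clean: np.ndarray, z: np.ndarray, sigma_abs: float, kind: str) -> np.ndarray:
    if kind == "gaussian":
        return clean + sigma_abs * z
    # lognormal: multiplicative, matched coefficient of variation
    return clean * np.exp(sigma_abs / np.maximum(np.abs(clean), 1e-12) * z)


def ll4_truth_series(
    strategy: DesignStrategy,
    truth: tuple[float, float, float, float],
    sigma: float,
    rng: np.random.Generator,
    *,
    drug: str = "synthetic",
    donor: str = "d1",
    endpoint: str = "albumin",
    day: int = 7,
    noise_kind: str = "gaussian",
    z: np.ndarray | None = None,
) -> DoseResponseSeries:
    """One noisy LL.4 series under a design strategy.

    ``truth`` is (b, c, d, e); ``sigma`` is the noise fraction of d - c.
    Passing a pre-drawn standard-normal array ``z`` (shape: total observations
    incl. vehicle) couples noise across sigma values for paired comparisons.
    """
    from .dose_response import ll4  # local import avoids a cycle at import time

    b, c, d, e = truth
    doses = np.concatenate([[0.0], strategy.doses])
    reps = np.concatenate([[strategy.n_vehicle], np.full(strategy.n_doses, strategy.n_replicates)]).astype(int)
    total = int(reps.sum())
    if z is None:
        z = rng.standard_normal(total)
    elif len(z) != total:
        raise ValidationError(f"coupling array has {len(z)} draws, need {total}")
    sigma_abs = sigma * abs(d - c)
    values: list[tuple[float, ...]] = []
    pos = 0
    for dose, n in zip(doses, reps):
        clean = np.full(n, float(ll4(dose, b, c, d, e)))
        noisy = _apply_noise(clean, z[pos : pos + n], sigma_abs, noise_kind)
        values.append(tuple(float(v) for v in noisy))
        pos += n
    return DoseResponseSeries(
        drug=drug, donor=donor, endpoint=endpoint, day=day,
        doses=tuple(float(x) for x in doses), values=tuple(values),
    )


@dataclass(frozen=True)
class SyntheticPanelSpec:
    """Study conditions for a generated panel.

    Defaults mirror the chip study: an 8x2 allocation over 0.1-1000x unbound
    C_max, IC50s of toxic drugs spread over 1-100x, and censored no-effect
    drugs that stay flat within noise at every tested dose.
    """

    n_toxic: int
    n_nontoxic: int
    seed: int
    ic50_range: tuple[float, float] = (1.0, 100.0)
    fu_plasma_range: tuple[float, float] = (0.01, 1.0)
    fu_media_range: tuple[float, float] = (0.5, 1.0)
    design: DesignStrategy = field(default_factory=lambda: DesignStrategy(8, 2))
    noise: NoiseModel = field(default_factory=lambda: NOISE_LEVELS["medium"])
    days: tuple[int, ...] = (7,)
    donors: tuple[str, ...] = ("d1",)
    slope: float = 1.5
    upper: float = 100.0
    lower: float = 0.0
    alt_shift: float = 2.0  # ALT/morphology LOAEL >= albumin IC50 by this factor

    def __post_init__(self) -> None:
        if self.n_toxic < 0 or self.n_nontoxic < 0:
            raise ValidationError("drug counts must be >= 0")
        for name in ("ic50_range", "fu_plasma_range", "fu_media_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValidationError(f"invalid {name}")
        if not self.alt_shift >= 1:
            raise ValidationError("alt_shift must be >= 1 (albumin most sensitive)")


def _drug_rng(seed: int, index: int) -> np.random.Generator:
    # substream keyed by (master seed, drug index): stable under panel growth
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def gen_panel(
    spec: SyntheticPanelSpec,
) -> tuple[list[DrugRecord], list[DoseResponseSeries], pd.DataFrame]:
    """Generate a labelled panel, its endpoint series, and the truth table.

    Toxic drugs (Garside rank drawn from 1-3) carry decreasing LL.4 albumin
    curves with IC50 from ``ic50_range`` plus ALT/morphology step responses at
    correlated LOAELs; nontoxic drugs (rank 4-5) are flat within noise. The
    truth table records every generating parameter per drug.
    """
    records: list[DrugRecord] = []
    series: list[DoseResponseSeries] = []
    truth_rows: list[dict] = []
    doses_max = spec.design.dose_range[1]
    n_total = spec.n_toxic + spec.n_nontoxic
    for idx in range(n_total):
        rng = _drug_rng(spec.seed, idx)
        toxic = idx < spec.n_toxic
        name = f"synth-{'tox' if toxic else 'neg'}-{idx:03d}"
        fu_plasma = float(rng.uniform(*spec.fu_plasma_range))
        fu_media = float(rng.uniform(*spec.fu_media_range))
        rank = int(rng.integers(1, 4)) if toxic else int(rng.integers(4, 6))
        records.append(
            DrugRecord(
                name=name, garside_rank=rank, cmax_total=float(rng.uniform(10, 10_000)),
                fu_plasma=fu_plasma, fu_media=fu_media,
                donors_tested=frozenset(spec.donors),
            )
        )
        lo, hi = spec.ic50_range
        ic50 = float(np.exp(rng.uniform(np.log(lo), np.log(hi)))) if toxic else float("inf")
        alt_loael = min(ic50 * spec.alt_shift, np.inf)
        truth_rows.append(
            {
                "drug": name, "toxic": toxic, "garside_rank": rank,
                "fu_plasma": fu_plasma, "fu_media": fu_media,
                "ic50": ic50, "alt_loael": alt_loael,
                "slope": spec.slope, "upper": spec.upper, "lower": spec.lower,
                "sigma": spec.noise.sigma, "design": spec.design.label,
                "max_tested": doses_max,
            }
        )
        for donor in spec.donors:
            for day in spec.days:
                if toxic:
                    albumin_truth = (spec.slope, spec.lower, spec.upper, ic50)
                else:
                    # flat at the upper level: slope irrelevant, inflection far
                    # beyond the tested range
                    albumin_truth = (spec.slope, spec.upper, spec.upper, doses_max * 1e3)
                series.append(
                    ll4_truth_series(
                        spec.design, albumin_truth, spec.noise.sigma, rng,
                        drug=name, donor=donor, day=day,
                        noise_kind=spec.noise.kind,
                    )
                )
                series.append(
                    _step_series(
                        spec, rng, name, donor, day, "ALT",
                        loael=alt_loael if toxic else None,
                        base=30.0, elevated=150.0,
                    )
                )
                series.append(
                    _step_series(
                        spec, rng, name, donor, day, "morphology_score",
                        loael=alt_loael if toxic else None,
                        base=0.0, elevated=3.0,
                    )
                )
    truth = pd.DataFrame(truth_rows)
    return records, series, truth


def _step_series(
    spec: SyntheticPanelSpec,
    rng: np.random.Generator,
    drug: str,
    donor: str,
    day: int,
    endpoint: str,
    loael: float | None,
    base: float,
    elevated: float,
) -> DoseResponseSeries:
    """Step response: baseline below the LOAEL, elevated at and above it."""
    doses = np.concatenate([[0.0], spec.design.doses])
    reps = np.concatenate(
        [[spec.design.n_vehicle], np.full(spec.design.n_doses, spec.design.n_replicates)]
    ).astype(int)
    sigma_abs = spec.noise.sigma * (elevated - base) * 0.25
    values = []
    for dose, n in zip(doses, reps):
        level = elevated if (loael is not None and dose >= loael) else base
        noisy = level + sigma_abs * rng.standard_normal(n)
        if endpoint == "morphology_score":
            noisy = np.clip(np.round(noisy * 2) / 2, 0.0, 4.0)
        values.append(tuple(float(v) for v in noisy))
    return DoseResponseSeries(
        drug=drug, donor=donor, endpoint=endpoint, day=day,
        doses=tuple(float(x) for x in doses), values=tuple(values),
    )


def gen_econ_params(base_config, perturbation: float, seed: int, n_draws: int = 1):
    """Randomly perturbed economic parameter sets for sensitivity testing.

    Each scalar (costs, durations, discount rate, launch value, chip cost) is
    scaled by an independent uniform factor in ``[1 - perturbation,
    1 + perturbation]``; advance probabilities are additionally clipped to
    (0, 1] and failure-cause shares are renormalized to sum to one, so every
    draw satisfies the phase-parameter invariants. ``perturbation = 0``
    returns copies equal to the base configuration.
    """
    from .econ_model import EconConfig, PhaseParams  # late import avoids a cycle

    if not 0 <= perturbation < 1:
        raise ValidationError("perturbation must be in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(9,)))

    def jitter(x: float) -> float:
        return float(x * rng.uniform(1 - perturbation, 1 + perturbation))

    draws = []
    for _ in range(n_draws):
        phases = []
        for ph in base_config.phases:
            shares = np.array(
                [jitter(ph.failure_shares[k]) for k in ("safety", "efficacy", "other")]
            )
            shares = shares / shares.sum()
            phases.append(
                PhaseParams(
                    name=ph.name,
                    cost_per_candidate=jitter(ph.cost_per_candidate),
                    duration=jitter(ph.duration),
                    p_advance=float(np.clip(jitter(ph.p_advance), 1e-6, 1.0)),
                    failure_shares={
                        "safety": float(shares[0]),
                        "efficacy": float(shares[1]),
                        "other": float(shares[2]),
                    },
                )
            )
        draws.append(
            EconConfig(
                phases=phases,
                p_unsafe=float(np.clip(jitter(base_config.p_unsafe), 1e-6, 1 - 1e-6)),
                p_ineffective=float(np.clip(jitter(base_config.p_ineffective), 1e-6, 1 - 1e-6)),
                discount_rate=jitter(base_config.discount_rate),
                launch_value=jitter(base_config.launch_value),
                chip_cost_per_candidate=jitter(base_config.chip_cost_per_candidate),
                dili_share=base_config.dili_share,
                chip_sensitivity=base_config.chip_sensitivity,
                global_rd=base_config.global_rd,
                small_molecule_share=base_config.small_molecule_share,
            )
        )
    return draws
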