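"""Bound-aware threshold classification of MOS values and performance metrics.

A drug is called toxic when its MOS is an observed value strictly below the
threshold; censored bounds (">x", nothing observed up to x) are negative at
any threshold, and a value exactly equal to the threshold is negative ("a
value above the threshold indicates a drug negative for toxicity"). Ground
truth comes from the Garside DILI severity rank: ranks 1-3 are DILI-positive,
ranks 4-5 negative. Default decision thresholds: 50 on the uncorrected basis,
375 on the protein-binding-corrected basis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import spearmanr
from statsmodels.stats.proportion import proportion_confint

from .mos_scoring import MOSValue
from .panel_io import ValidationError

__all__ = [
    "DILICall",
    "ConfusionSummary",
    "truth_label",
    "classify",
    "confusion",
    "binomial_ci",
    "spearman_vs_severity",
    "choose_threshold",
    "DEFAULT_THRESHOLD_UNCORRECTED",
    "DEFAULT_THRESHOLD_CORRECTED",
    "GARSIDE_TOXIC_CUTOFF",
]

DEFAULT_THRESHOLD_UNCORRECTED = 50.0
DEFAULT_THRESHOLD_CORRECTED = 375.0

#: Garside rank at or below which a drug counts as DILI-positive ground truth
GARSIDE_TOXIC_CUTOFF = 3

_CI_METHODS = {
    "wilson": "wilson",
    "clopper_pearson": "beta",
    "agresti_coull": "agresti_coull",
    "logit": "normal",
}


@dataclass(frozen=True)
class DILICall:
    """One threshold decision; ``predicted`` is ``'toxic'`` iff the MOS is an
    observed (non-censored) value strictly below the threshold."""

    drug: str
    predicted: str
    mos: MOSValue
    threshold: float

    def __post_init__(self) -> None:
        expected = "toxic" if (not self.mos.is_bound and self.mos.value < self.threshold) else "nontoxic"
        if self.predicted != expected:
            raise ValidationError(f"{self.drug}: inconsistent prediction {self.predicted!r}")


@dataclass(frozen=True)
class ConfusionSummary:
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    ci_method: str

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def truth_label(rank: int) -> str:
    """DILI ground truth from the Garside severity rank (toxic iff rank <= 3)."""
    if rank not in (1, 2, 3, 4, 5):
        raise ValidationError(f"Garside rank must be in 1..5, got {rank!r}")
    return "toxic" if rank <= GARSIDE_TOXIC_CUTOFF else "nontoxic"


def classify(mos: MOSValue, threshold: float) -> DILICall:
    """Threshold decision on one MOS value (bounds always negative)."""
    if not threshold > 0:
        raise ValidationError("threshold must be > 0")
    predicted = "toxic" if (not mos.is_bound and mos.value < threshold) else "nontoxic"
    return DILICall(drug=mos.drug, predicted=predicted, mos=mos, threshold=threshold)


def binomial_ci(successes: int, n: int, method: str = "wilson") -> tuple[float, float]:
    """Two-sided 95% confidence interval for a binomial proportion."""
    if n <= 0:
        raise ValidationError("binomial CI needs n > 0")
    if not 0 <= successes <= n:
        raise ValidationError("successes must lie in [0, n]")
    if method not in _CI_METHODS:
        raise ValidationError(f"unknown CI method {method!r}; choose from {sorted(_CI_METHODS)}")
    low, high = proportion_confint(successes, n, alpha=0.05, method=_CI_METHODS[method])
    return float(low), float(high)


def summarize_counts(
    tp: int, tn: int, fp: int, fn: int, ci_method: str = "wilson"
) -> ConfusionSummary:
    """Sensitivity/specificity with binomial CIs from raw confusion counts."""
    if min(tp, tn, fp, fn) < 0:
        raise ValidationError("confusion counts must be >= 0")
    pos, neg = tp + fn, tn + fp
    sens = tp / pos if pos else float("nan")
    spec = tn / neg if neg else float("nan")
    sens_ci = binomial_ci(tp, pos, ci_method) if pos else (float("nan"),) * 2
    spec_ci = binomial_ci(tn, neg, ci_method) if neg else (float("nan"),) * 2
    return ConfusionSummary(
        tp=tp, tn=tn, fp=fp, fn=fn,
        sensitivity=sens, specificity=spec,
        sens_ci=sens_ci, spec_ci=spec_ci, ci_method=ci_method,
    )


def confusion(
    calls: Sequence[DILICall],
    labels: Mapping[str, str],
    ci_method: str = "wilson",
) -> ConfusionSummary:
    """Confusion counts and rates for a panel of threshold decisions.

    ``labels`` maps drug name to ``'toxic'``/``'nontoxic'``; a call without a
    label raises :class:`ValidationError`.
    """
    tp = tn = fp = fn = 0
    for call in calls:
        if call.drug not in labels:
            raise ValidationError(f"no truth label for drug {call.drug!r}")
        truth = labels[call.drug]
        if truth == "toxic":
            tp += call.predicted == "toxic"
            fn += call.predicted == "nontoxic"
        elif truth == "nontoxic":
            tn += call.predicted == "nontoxic"
            fp += call.predicted == "toxic"
        else:
            raise ValidationError(f"bad label {truth!r} for {call.drug!r}")
    return summarize_counts(tp, tn, fp, fn, ci_method)


def spearman_vs_severity(
    mos: Sequence[MOSValue],
    ranks: Sequence[int],
    drop_bounds: bool = False,
) -> float:
    """Spearman rho between MOS values and Garside severity ranks.

    Censored bounds are ranked at their numeric bound value (documented
    limitation); ``drop_bounds=True`` runs the sensitivity variant that
    excludes them. Low MOS should pair with low (severe) ranks, so a well
    rank-ordered assay yields positive rho.
    """
    if len(mos) != len(ranks):
        raise ValidationError("mos and ranks must be paired")
    vals = np.array([m.value for m in mos], dtype=float)
    rk = np.array(ranks, dtype=float)
    if drop_bounds:
        keep = np.array([not m.is_bound for m in mos])
        vals, rk = vals[keep], rk[keep]
    if len(vals) < 3:
        raise ValidationError("need >= 3 pairs for Spearman correlation")
    rho, _ = spearmanr(vals, rk)
    return float(rho)


def choose_threshold(
    mos: Sequence[MOSValue],
    labels: Mapping[str, str],
    candidates: Sequence[float],
) -> float:
    """Largest candidate threshold producing zero false positives.

    Sensitivity is non-decreasing in the threshold, so the largest FP-free
    candidate also maximizes sensitivity. A candidate is excluded when any
    negative-labelled drug has an observed MOS at or below it (boundary-safe:
    a threshold equal to an observed negative value is rejected). If every
    negative is censored the FP-free region is unbounded and the grid maximum
    is returned with a warning; if no candidate is FP-free the smallest is
    returned.
    """
    if not candidates:
        raise ValidationError("need at least one candidate threshold")
    negatives = [m for m in mos if labels.get(m.drug) == "nontoxic"]
    if not negatives:
        raise ValidationError("need at least one negative-labelled drug")
    observed_neg = [m.value for m in negatives if not m.is_bound]
    grid = sorted(candidates)
    if not observed_neg:
        warnings.warn("all negative drugs censored: FP-free region unbounded, returning grid maximum")
        return float(grid[-1])
    limit = min(observed_neg)
    feasible = [t for t in grid if t < limit]
    return float(feasible[-1]) if feasible else float(grid[0])


def threshold_sweep(
    mos: Sequence[MOSValue],
    labels: Mapping[str, str],
    candidates: Sequence[float],
    ci_method: str = "wilson",
) -> list[tuple[float, ConfusionSummary]]:
    """Confusion summaries across a grid of thresholds (choose_threshold's view)."""
    return [
        (float(t), confusion([classify(m, t) for m in mos], labels, ci_method))
        for t in sorted(candidates)
    ]
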