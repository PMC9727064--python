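"""Four-parameter log-logistic (LL.4) dose-response fitting and endpoint calls.

Albumin inhibition is modelled with the generalized log-logistic curve

    f(x) = c + (d - c) / (1 + exp(b * (ln x - ln e)))
         = c + (d - c) / (1 + (x / e)**b)

with slope ``b``, lower asymptote ``c``, upper asymptote ``d`` and inflection
dose ``e`` (in multiples of unbound C_max). The albumin IC50 is the dose at
which the fitted curve crosses half the vehicle mean (an absolute 50%
reduction in production, not 50% of the fitted span). ALT and morphology-score
endpoints are called as the lowest observed adverse effect level (LOAEL) under
configurable elevation rules. When no effect is observed up to the largest
multiple tested, the call is a censored bound at that multiple.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import f as f_dist

from .panel_io import DoseResponseSeries, ValidationError

__all__ = [
    "LL4Fit",
    "EndpointCall",
    "LoaelRule",
    "ll4",
    "fit_ll4",
    "albumin_ic50",
    "loael",
    "call_series",
    "min_across_days",
    "bootstrap_ic50",
    "DEFAULT_ALT_RULE",
    "DEFAULT_MORPHOLOGY_RULE",
]


def ll4(x, b: float, c: float, d: float, e: float):
    """Evaluate the LL.4 curve; at x = 0 the limit (d for b > 0, c for b < 0)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x > 0
    out[pos] = c + (d - c) / (1.0 + (x[pos] / e) ** b)
    out[~pos] = d if b > 0 else c
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class LL4Fit:
    """Least-squares LL.4 estimates, normalized so that d >= c.

    ``converged`` is False when the optimizer failed or the response is
    indistinguishable from flat (fitted span within twice the residual scale);
    ``message`` carries the diagnostic.
    """

    b: float
    c: float
    d: float
    e: float
    converged: bool
    residual_se: float
    message: str = ""

    def __post_init__(self) -> None:
        if not self.e > 0:
            raise ValidationError(f"inflection dose e must be > 0, got {self.e}")
        if self.converged and self.d < self.c:
            raise ValidationError("converged fit must satisfy d >= c")

    def __call__(self, x):
        return ll4(x, self.b, self.c, self.d, self.e)


@dataclass(frozen=True)
class EndpointCall:
    """Minimum toxic C_max multiple for one drug/donor/endpoint.

    ``is_bound`` means no adverse effect was observed at any tested dose and
    ``min_toxic_multiple`` equals the largest multiple tested (a ">x" bound).
    """

    drug: str
    donor: str
    endpoint: str
    min_toxic_multiple: float
    is_bound: bool
    day: int

    def __post_init__(self) -> None:
        if not self.min_toxic_multiple > 0:
            raise ValidationError("min_toxic_multiple must be > 0")


class InsufficientDesignError(ValidationError):
    """Too few distinct nonzero doses for a four-parameter fit."""


# ---------------------------------------------------------------------------
# LL.4 fitting: profiled nonlinear least squares
# ---------------------------------------------------------------------------


def _profile_cd(s: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Given s = 1/(1+(x/e)^b), solve the linear subproblem for (c, d)."""
    A = np.column_stack([1.0 - s, s])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(coef[0]), float(coef[1])


def _residuals(theta: np.ndarray, logx: np.ndarray, y: np.ndarray) -> np.ndarray:
    b, loge = theta
    s = 1.0 / (1.0 + np.exp(np.clip(b * (logx - loge), -700, 700)))
    c, d = _profile_cd(s, y)
    return c * (1.0 - s) + d * s - y


def _grid_profile(
    logx: np.ndarray, y: np.ndarray, b_grid: np.ndarray, loge_grid: np.ndarray
) -> tuple[float, float]:
    """Top (b, ln e) cells of a coarse grid with (c, d) profiled in closed form.

    Vectorized over all grid cells: for each (b, ln e) the model is linear in
    (c, d), solved from the 2x2 normal equations. Cells are ranked by RSS,
    ties to the smallest |b|; the leading cells seed the local refinement.
    """
    bb, ll = np.meshgrid(b_grid, loge_grid, indexing="ij")
    theta = np.column_stack([bb.ravel(), ll.ravel()])  # (m, 2)
    s = 1.0 / (1.0 + np.exp(np.clip(theta[:, :1] * (logx - theta[:, 1:2]), -700, 700)))
    t = 1.0 - s
    # 2x2 normal equations per cell
    a11 = (t * t).sum(axis=1)
    a12 = (t * s).sum(axis=1)
    a22 = (s * s).sum(axis=1)
    r1 = (t * y).sum(axis=1)
    r2 = (s * y).sum(axis=1)
    det = a11 * a22 - a12 * a12
    det = np.where(np.abs(det) < 1e-300, np.nan, det)
    c = (a22 * r1 - a12 * r2) / det
    d = (a11 * r2 - a12 * r1) / det
    fitted = c[:, None] * t + d[:, None] * s
    rss = ((fitted - y) ** 2).sum(axis=1)
    rss = np.where(np.isfinite(rss), rss, np.inf)
    order = np.lexsort((np.abs(theta[:, 0]), np.round(rss, 12)))
    picks = list(order[:3])
    # shallow-slope ridge catcher: the flattest-slope rows trade b against e
    # almost freely, so always seed one start from the best cell at each of
    # the two smallest |b| values
    min_abs_b = np.min(np.abs(theta[:, 0]))
    for sign in (1.0, -1.0):
        row = np.where(np.isclose(theta[:, 0], sign * min_abs_b))[0]
        if row.size:
            picks.append(row[np.argmin(rss[row])])
    seen: set[tuple[float, float]] = set()
    out = []
    for i in picks:
        key = (float(theta[i, 0]), float(theta[i, 1]))
        if key not in seen:
            seen.add(key)
            out.append(key)
    return out


def fit_ll4(
    series: DoseResponseSeries,
    *,
    n_b: int = 11,
    n_e: int = 13,
) -> LL4Fit:
    """Fit the LL.4 model to the nonzero-dose observations of a series.

    Profiled least squares: a vectorized coarse grid over (b, ln e) — slopes
    of both signs, inflection log-spaced across the tested range — with the
    asymptotes (c, d) solved linearly, followed by a local refinement of the
    best grid cell. Ties are broken by lowest residual sum of squares, then
    smallest |b|. Vehicle (dose 0) observations are excluded from the
    log-dose fit; they inform the IC50 target only (see
    :func:`albumin_ic50`).
    """
    doses = np.array(series.nonzero_doses, dtype=float)
    if len(doses) < 4:
        raise InsufficientDesignError(
            f"{series.drug}/{series.donor}: need >= 4 distinct nonzero doses, have {len(doses)}"
        )
    x = np.concatenate(
        [np.full(len(series.values[series.doses.index(d)]), d) for d in doses]
    )
    y = np.concatenate(
        [np.asarray(series.values[series.doses.index(d)], dtype=float) for d in doses]
    )
    logx = np.log(x)

    half = np.geomspace(0.25, 8.0, n_b // 2)
    b_grid = np.concatenate([-half[::-1], half])
    loge_grid = np.linspace(np.log(doses.min() / 3), np.log(doses.max() * 3), n_e)
    starts = _grid_profile(logx, y, b_grid, loge_grid)

    # zoom: one level of local grid refinement around each start (the RSS
    # surface can form curved shallow-slope ridges that defeat a Levenberg-
    # Marquardt polish from a coarse cell)
    db = np.log(b_grid[-1] / b_grid[-2])
    dl = loge_grid[1] - loge_grid[0]
    zoomed = []
    for b0, loge0 in starts:
        local_b = np.sign(b0) * np.exp(np.linspace(np.log(abs(b0)) - db, np.log(abs(b0)) + db, 9))
        local_l = np.linspace(loge0 - dl, loge0 + dl, 9)
        zoomed.append(_grid_profile(logx, y, local_b, local_l)[0])
    starts = zoomed

    candidates = list(starts)
    success, message = False, "local refinement failed on all starts"
    for b0, loge0 in starts:
        try:
            sol = least_squares(
                _residuals,
                x0=np.array([b0, loge0]),
                args=(logx, y),
                method="lm",
                xtol=1e-14,
                ftol=1e-14,
                max_nfev=400,
            )
        except Exception:  # singular steps on degenerate data
            continue
        candidates.append((float(sol.x[0]), float(sol.x[1])))
        if sol.success and not success:
            success, message = True, str(sol.message)

    def _evaluate(b: float, loge: float):
        # clamp pathological inflection estimates back toward the tested
        # range and derive the asymptotes from the clamped curve, so the
        # returned parameter set is self-consistent
        loge = float(np.clip(loge, np.log(doses.min()) - 14, np.log(doses.max()) + 14))
        s = 1.0 / (1.0 + np.exp(np.clip(b * (logx - loge), -700, 700)))
        c, d = _profile_cd(s, y)
        rss = float(np.sum((c * (1.0 - s) + d * s - y) ** 2))
        return rss, b, c, d, loge

    # best candidate over polished solutions and raw grid optima (ties to the
    # shallower slope)
    rss, b, c, d, loge = min(
        (_evaluate(bc, lc) for bc, lc in candidates),
        key=lambda t: (round(t[0], 12), abs(t[1])),
    )
    if c > d:  # (b,c,d,e) -> (-b,d,c,e) leaves the curve unchanged
        b, c, d = -b, d, c
    dof = max(len(y) - 4, 1)
    residual_se = float(np.sqrt(rss / dof))
    e = float(np.exp(loge))

    converged = success
    # lack-of-fit F-test against the constant model: a response that the
    # LL.4 curve does not explain significantly better than a flat line is
    # flagged no-effect (same null false-flag rate for every allocation of
    # the 16-chip budget)
    rss_const = float(np.sum((y - y.mean()) ** 2))
    if rss_const <= 1e-12 * max(np.abs(y).max() ** 2, 1.0):
        converged = False
        message = "no-effect: constant response"
    elif len(y) > 4:
        fstat = ((rss_const - rss) / 3.0) / max(rss / (len(y) - 4), 1e-300)
        if f_dist.sf(fstat, 3, len(y) - 4) > 0.05:
            converged = False
            message = "no-effect: lack-of-fit test does not reject a flat response"
    return LL4Fit(
        b=float(b), c=float(c), d=float(d), e=e,
        converged=converged, residual_se=residual_se,
        message="" if converged else message,
    )


def albumin_ic50(
    fit: LL4Fit,
    vehicle_mean: float,
    max_tested: float,
    *,
    drug: str = "",
    donor: str = "",
    day: int = 7,
) -> EndpointCall:
    """Dose at which the fitted curve reaches half the vehicle mean.

    Returns a censored bound at ``max_tested`` when the fit did not converge,
    the curve is not decreasing, the half-vehicle level lies outside the fitted
    span, or the crossing falls beyond the largest tested multiple.
    """
    if not vehicle_mean > 0:
        raise ValidationError("vehicle_mean must be > 0")
    target = 0.5 * vehicle_mean

    def bound(reason: str) -> EndpointCall:
        if reason:
            warnings.warn(f"{drug}/{donor} albumin IC50 censored: {reason}", stacklevel=2)
        return EndpointCall(
            drug=drug, donor=donor, endpoint="albumin",
            min_toxic_multiple=max_tested, is_bound=True, day=day,
        )

    if not fit.converged:
        return bound("fit did not converge")
    if fit.b <= 0:
        return bound("")  # non-decreasing curve: no 50% reduction
    if not (fit.c < target < fit.d):
        return bound("")  # floor above or ceiling below half-vehicle
    # solve in log space: a shallow fitted slope can push the crossing far
    # beyond any float range, which is simply a censored call
    log_x = np.log(fit.e) + np.log((fit.d - target) / (target - fit.c)) / fit.b
    if log_x > np.log(max_tested):
        return bound("")
    # a crossing that underflows to 0 is toxicity at any tested dose
    x = float(np.exp(max(log_x, np.log(1e-12))))
    return EndpointCall(
        drug=drug, donor=donor, endpoint="albumin",
        min_toxic_multiple=float(x), is_bound=False, day=day,
    )


# ---------------------------------------------------------------------------
# LOAEL rules for ALT and morphology
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LoaelRule:
    """Elevation criterion: dose mean must exceed vehicle_mean + z * vehicle_sd,
    AND exceed fold * vehicle_mean, AND exceed vehicle_mean + shift."""

    z: float = 0.0
    fold: float = 1.0
    shift: float = 0.0

    def exceeds(self, dose_mean: float, vehicle_mean: float, vehicle_sd: float) -> bool:
        return (
            dose_mean > vehicle_mean + self.z * vehicle_sd
            and dose_mean > self.fold * vehicle_mean
            and dose_mean >= vehicle_mean + self.shift
        )


DEFAULT_ALT_RULE = LoaelRule(z=2.0, fold=1.5)
DEFAULT_MORPHOLOGY_RULE = LoaelRule(shift=1.0)


def loael(series: DoseResponseSeries, rule: LoaelRule | None = None) -> EndpointCall:
    """Lowest dose whose replicate mean trips the elevation rule.

    A censored bound at the maximum tested multiple is returned when no dose
    does.
    """
    if rule is None:
        rule = DEFAULT_MORPHOLOGY_RULE if series.endpoint == "morphology_score" else DEFAULT_ALT_RULE
    veh = np.asarray(series.vehicle_values, dtype=float)
    veh_mean = float(veh.mean())
    veh_sd = float(veh.std(ddof=1)) if len(veh) > 1 else 0.0
    for dose in series.nonzero_doses:
        vals = np.asarray(series.values[series.doses.index(dose)], dtype=float)
        if rule.exceeds(float(vals.mean()), veh_mean, veh_sd):
            return EndpointCall(
                drug=series.drug, donor=series.donor, endpoint=series.endpoint,
                min_toxic_multiple=float(dose), is_bound=False, day=series.day,
            )
    return EndpointCall(
        drug=series.drug, donor=series.donor, endpoint=series.endpoint,
        min_toxic_multiple=series.max_tested, is_bound=True, day=series.day,
    )


def call_series(series: DoseResponseSeries, rule: LoaelRule | None = None) -> EndpointCall:
    """Dispatch one series to its endpoint call (albumin fit or LOAEL)."""
    if series.endpoint == "albumin":
        fit = fit_ll4(series)
        veh_mean = float(np.mean(series.vehicle_values))
        return albumin_ic50(
            fit, veh_mean, series.max_tested,
            drug=series.drug, donor=series.donor, day=series.day,
        )
    return loael(series, rule)


def min_across_days(calls: Sequence[EndpointCall]) -> EndpointCall:
    """Per drug/donor/endpoint call: the minimum across the tested days.

    Observed (non-bound) calls dominate bounds; among bounds the largest
    multiple tested is kept (widest censoring interval).
    """
    if not calls:
        raise ValidationError("need at least one per-day call")
    observed = [c for c in calls if not c.is_bound]
    if observed:
        return min(observed, key=lambda c: c.min_toxic_multiple)
    return max(calls, key=lambda c: c.min_toxic_multiple)


def bootstrap_ic50(
    series: DoseResponseSeries,
    n_boot: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Nonparametric bootstrap of the albumin IC50 (utility; resamples
    replicates within each dose group). Censored resamples contribute the
    maximum tested multiple."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_boot)
    for i in range(n_boot):
        values = tuple(
            tuple(rng.choice(v, size=len(v), replace=True)) for v in series.values
        )
        boot = DoseResponseSeries(
            drug=series.drug, donor=series.donor, endpoint=series.endpoint,
            day=series.day, doses=series.doses, values=values,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[i] = call_series(boot).min_toxic_multiple
    return out
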