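# Methods

This note documents the models, the defaults and their rationale, the
synthetic-data generator's scope, and the numerical choices, in the order the
pipeline runs.

## Exposure arithmetic and panel data

Doses are kept as dimensionless multiples of the unbound plasma C_max
throughout; conversion to mass units (`cmax_total_ng_ml × fu_plasma`) happens
only at I/O boundaries. When the unbound fraction in the 2% FBS chip medium is
not supplied per drug, it is extrapolated from plasma binding by
protein-dilution scaling, `fu_media = 1 / (1 + R·(1−fu)/fu)` with `R` the
medium-to-plasma protein-content ratio (default 0.02). This is a standard
scaling assumption, not a measurement; explicit per-drug values always win.
The bundled benchmark panel carries only rank-level information (Garside
severity, matched pairs, donors tested) because per-drug exposure and binding
values were not published; every operation that needs them validates their
presence and fails loudly.

Chip QC converts effluent concentrations to production rates as
`conc (µg/mL) × flow (µL/h) × 24 / 1000 / (cells/10⁶)` µg per 10⁶ hepatocytes
per day; the hepatocyte count per chip is a configuration parameter, never a
silent constant. The coefficient of variation uses the sample (n−1) standard
deviation.

## Dose–response model

Albumin series are fit with the four-parameter log-logistic (LL.4) curve.
Vehicle (dose-0) observations are excluded from the log-dose fit; they set the
IC50 target (half the vehicle mean) only. The optimizer is profiled least
squares: for fixed (b, ln e) the asymptotes (c, d) solve a 2×2 linear system,
so the search runs over a vectorized coarse grid (slopes ±0.25…±8, inflection
log-spaced across three decades beyond the tested range), zooms one level
around the leading cells — the RSS surface forms curved shallow-slope ridges
where b and e trade off almost freely — and polishes each candidate with
Levenberg–Marquardt. Ties break by lowest residual sum of squares, then
smallest |b|. The parameterization `(b,c,d,e) ↔ (−b,d,c,e)` is degenerate;
fits are normalized to d ≥ c.

A fit is flagged *no-effect* by a lack-of-fit F-test (LL.4 vs constant,
α = 0.05). An explicit statistical test is used rather than a span threshold
because its null behaviour is identical for every allocation of the same chip
budget (equal n and residual degrees of freedom), which matters for the
design comparison below.

The albumin IC50 is defined against the vehicle mean (an absolute 50%
reduction in production), not the fitted span: a curve whose floor stays above
half of vehicle never reaches IC50 and yields a censored bound at the largest
multiple tested, as do non-converged fits, increasing fits, and crossings
beyond the tested range. The crossing is solved in log space so shallow fitted
slopes cannot overflow.

ALT and morphology-score rules are not standardized anywhere; the defaults are
config-exposed: ALT elevation requires the dose-group mean to exceed both
`vehicle + 2·SD(vehicle)` and `1.5 × vehicle`; the morphology rule requires a
mean score at least 1 point above vehicle on the 0–4 rubric. Per-drug calls
take the minimum across days (day-7 values usually dominate but day-3 values
are occasionally lower) and then the minimum across endpoints, with observed
values always dominating censored bounds.

## MOS scoring and classification

Censoring semantics: `">x"` means nothing was observed up to x. Bounds never
compete with observed values in minima — combining donors takes the smallest
observed value, or the largest bound when every donor is censored. The
corrected/uncorrected bases satisfy `corrected = uncorrected / fu_plasma`
identically, bound flags included; because per-drug corrected values were
never published, the corrected pipeline is validated by this identity and by
its confusion counts rather than cell-by-cell.

Classification is strict: toxic ⇔ observed MOS < threshold; a value exactly at
the threshold is negative. Ground truth is Garside rank ≤ 3 = DILI-positive —
the cutoff is validated by exact reconstruction of the published single-donor
confusion row (16, 5, 0, 6), which only that cutoff reproduces. Reconstructing
the donor-2 row from the published per-donor values under the stated rule
gives (10, 3, 0, 5) where the original prints (9, 3, 0, 6); the discrepant
drug cannot be identified from published information, so that row is reported
but not enforced.

Binomial intervals default to Wilson; Clopper–Pearson, Agresti–Coull and logit
are selectable because the original CI method is unidentified (Wilson comes
close: 51.8–86.8% vs the printed 51.4–86.8% for 16/22). Spearman correlation
against severity ranks censored bounds at their numeric bound value — a
documented limitation, with a drop-bounds sensitivity mode — so the reported
coefficients (0.30 combined, uncorrected basis) are convention-dependent and
are not comparable digit-for-digit with other bound-handling choices.
Threshold selection returns the largest candidate with zero false positives,
excluding candidates at or above any observed negative-class MOS (a threshold
sitting exactly on a negative observation is fragile and is rejected).

## Design simulation

The simulation compares 16×1, 8×2, 5×3 and 4×4 dose/replicate allocations of
a 16-chip budget on log-spaced grids spanning 0.1–1000× unbound C_max, plus 3
vehicle chips. Generating truth defaults to `(b, c, d, e) = (2, 0, 100, 10)`:
a steep slope typical of overt cytotoxicity. The steepness matters — by the
Cramér–Rao bound, spreading chips over 16 distinct doses beats duplicating 8
doses only when the transition is sharp (roughly b ≳ 2); for shallow slopes
the ordering reverses. Noise is additive Gaussian with σ at 5%, 15%, 30% of
the dynamic range for low/medium/high.

The scored estimate is the fitted IC50 parameter. Fits that do not identify
it — non-converged, non-decreasing, or inflection outside the tested range —
are excluded and counted rather than substituted with the grid maximum:
substitution would make the RMSE a censoring-frequency contest dominated by
`(grid max − truth)²` ≈ 10⁶ per event. Noise draws are keyed by (master seed,
dataset index) only, so strategies are compared on common random numbers and
noise levels on the same draws scaled by σ; both comparisons are paired, and
every table cell is bit-reproducible from its seed. Headline comparisons use
500 datasets per cell repeated over five master seeds to bound sampling error;
orderings, not magnitudes, are the reproducible conclusions.

## Portfolio economics

The base case follows the familiar published R&D pipeline benchmark:
preclinical → Phase I → II → III → submission with advance probabilities
0.69 / 0.54 / 0.34 / 0.70 / 0.91, per-candidate costs 5 / 15 / 40 / 150 / 40
$M, cycle times 1 / 1.5 / 2.5 / 2.5 / 1.5 years, 11% cost of capital, and
entrants scaled so expected approvals equal exactly one (≈ 12.4 preclinical
candidates). Failure-cause shares per phase (safety / efficacy / other) are
literature-informed choices — safety-heavy early, efficacy-dominated in
Phases II–III, mostly "other" at submission — and the entry composition
(P(unsafe) = 0.55, P(ineffective) = 0.75, independent) was chosen once so
that the cause decomposition stays feasible at every phase with headroom
under ±10% parameter perturbation. These two groups of numbers are the least
constrained inputs: the original interactive workbook that pins them down is
not redistributable, so absolute outputs (base NPV $145.9M, implied
preclinical-tox FNR 0.61, uplift 8.5%, ≈ $9.3B/yr industry value) should be
read as internally consistent illustrations, while the model's structure —
identity at zero reduction, monotonicity in the FNR reduction, quadrant
conservation, near-linearity of uplift — is what the tests pin down.

Mechanics: per phase, safety failures scale down the unsafe quadrants,
efficacy failures the ineffective quadrants, other failures all quadrants
proportionally, jointly matching total attrition; infeasible shares raise a
calibration error naming the phase. The improved screen scales unsafe Phase-I
entrants by (1 − FNR reduction); the Phase-I intake is conservatively held at
its base value with candidates of the post-screen composition, downstream
phases reuse the base case's cause-specific survival factors (so the safety
hazard applies only to remaining unsafe candidates), and chip testing is
priced per screened candidate (default $0.1M, a CRO-style figure) at the
Phase-I gate. Discounting is annual and discrete, costs booked at phase
start, launch value ($1.6B default, an order-of-magnitude literature figure
for the NPV of one launch) at approval; all money is $M of a single reference
year with no inflation adjustment. The uplift confidence band propagates only
the chip-sensitivity binomial interval through the FNR reduction; full
parameter-uncertainty propagation is out of scope. Sensitivity analysis
perturbs each scalar input ±10% and reports elasticities, skipping perturbed
values that leave the valid range (e.g. an advance probability above 1).

## Synthetic data

The generator emulates the study's inputs: labelled panels with binding
fractions, LL.4 albumin curves for toxic drugs (IC50 log-uniform over the
configured range) with ALT/morphology step responses at LOAELs placed at or
above the albumin IC50 (albumin is modelled as the most sensitive endpoint),
and flat-within-noise censored series for non-toxic drugs. Noise is additive
Gaussian on the response scale (lognormal available). One master seed feeds
per-drug substreams keyed by drug index, so extending a panel never
reshuffles existing drugs. What it does **not** emulate: donor-to-donor
biological variability, correlated replicate errors within a chip, imaging
endpoints, PDMS drug adsorption, or any pharmacokinetics — so green tests on
synthetic panels demonstrate the pipeline's statistical correctness, not the
chip's biological predictivity.

## Problem sizes and determinism

Defaults keep the full suite in single-digit minutes: 500 datasets per
design-simulation cell × 5 seeds, 100 seeded series for recovery statistics,
200 bootstrap resamples, 120×120 oracle grids on 20 instances. Every
stochastic component takes an explicit integer seed and is bit-reproducible;
reports are JSON with stable key order and carry a run manifest (command,
input digests, seeds, package version) so equal manifests imply equal
outputs.

## Known limitations

- Bound ranking in the Spearman statistic is a convention; published
  correlation values computed under an unknown convention are not exact
  comparators.
- The economic model is expected-value and deterministic (no stochastic
  portfolio simulation, no revenue curves, no tax), and its absolute outputs
  inherit the uncertainty of the transcribed base case.
- The corrected-basis pipeline cannot be validated per drug against published
  cells (none exist), only through identities and aggregate counts.
- LOAEL elevation rules are package defaults, not community standards; calls
  on real data should report the rule used.
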