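# chipdili

Tools for deciding, from microfluidic Liver-Chip experiments, whether a
small-molecule drug is likely to cause drug-induced liver injury (DILI) — and
for pricing what better preclinical toxicology is worth to a drug-development
portfolio. The package is aimed at preclinical safety scientists working with
organ-on-chip (microphysiological) models and at analysts quantifying the R&D
productivity impact of improved predictive validity.

## What it computes

**DILI decision pipeline.** Chip endpoints (albumin production, ALT release,
morphology injury score) measured over a dose grid in multiples of the unbound
plasma C_max are turned into a per-drug *minimum toxic concentration*:

- albumin follows the four-parameter log-logistic curve
  `f(x) = c + (d − c) / (1 + (x/e)^b)`; its IC50 is the dose at which the
  fitted curve crosses half the vehicle mean;
- ALT and morphology are called at the lowest observed adverse effect level
  (LOAEL) under configurable elevation rules;
- the drug/donor call is the minimum across endpoints and study days, and
  donors combine as the minimum observed value (or, when nothing was observed
  anywhere, the widest censored bound `">x"`).

That minimum converts to a margin-of-safety (MOS)-like value on two bases:
*uncorrected* (free assay concentration / total plasma C_max, the hepatic-
spheroid convention) and *protein-binding corrected* (free assay concentration
/ unbound plasma C_max); the two differ exactly by `1/fu_plasma`. Drugs are
classified toxic when an observed MOS falls strictly below a threshold
(default 50 uncorrected, 375 corrected); censored bounds are negative at any
threshold. Performance against the Garside DILI severity scale (rank ≤ 3 =
DILI-positive) is reported as confusion counts, sensitivity/specificity with
Wilson binomial intervals, and a Spearman correlation to severity.

**Design simulation.** A Monte-Carlo re-run of the dose/replicate allocation
question — within a 16-chip budget, is 16×1 better than 8×2, 5×3, 4×4? —
scored by RMSE of the fitted IC50 parameter under three noise levels with
paired noise draws.

**Portfolio economics.** A phase-by-phase pipeline model calibrated to one
expected approval, with failures decomposed into safety/efficacy/other causes
and the portfolio tracked as safe×effective quadrants. The preclinical
toxicology gate's implied false-negative rate (FNR) can be reduced — e.g. by
`13% × 87% = 11.3%` when a Liver-Chip with 87% sensitivity screens the DILI
share of safety failures — and the model prices the change as a discounted-
cashflow NPV uplift and an industry-wide annual value.

## Worked example

The package bundles the published 27-drug benchmark panel (Garside ranks,
matched structural pairs) and its published MOS table. Classify at the
uncorrected threshold of 50:

```bash
chipdili classify --threshold 50 --out report.json
```

The report's two-donor confusion block reads:

```json
"combined": {
  "tp": 12, "tn": 3, "fp": 0, "fn": 3,
  "sensitivity": 0.8, "specificity": 1.0,
  "sens_ci": [0.5481455128483064, 0.9295245065301845],
  "ci_method": "wilson", "n": 18,
  "false_negatives": ["Levofloxacin", "Stavudine", "Tacrine"]
}
```

Of the 15 clinically hepatotoxic drugs tested in two donors, 12 fall below
the threshold (80% sensitivity), none of the 3 non-toxic drugs is flagged
(100% specificity), and the three misses are exactly the drugs whose observed
or censored MOS sits above 50 — e.g. stavudine's combined MOS of 107 is a
false negative at this threshold. The single-donor block gives (16, 5, 0, 6),
sensitivity 73% with Wilson CI (51.8%, 86.8%).

The economic chain, with the packaged base case:

```bash
chipdili econ scenario
```

```json
{
  "npv_base": 145.85624475931314,
  "npv_scenario": 158.23167515427343,
  "uplift": 0.084846764123002,
  "industry_value_bn_per_year": 9.3127808301407
}
```

A portfolio worth $145.9M per expected approval gains 8.5% in NPV when the
Phase-I intake's unsafe share is cut by 11.3% (the DILI share of safety
failures times the chip's two-donor corrected sensitivity); applied to global
small-molecule R&D spending that is ≈ $9.3B/yr under this parameterization.
The uplift magnitude is sensitive to the base case's launch value and
failure-cause shares — see `docs/methods.md` for what is and is not pinned
down by published information.

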