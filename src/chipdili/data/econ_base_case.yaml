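# Base-case parameters for the portfolio economics model.
#
# Phase advance probabilities, per-candidate costs ($M), cycle times (years)
# and the 11% cost of capital follow the widely used Paul et al.-style R&D
# pipeline benchmark (preclinical through submission; entrants are scaled so
# the chain yields exactly one expected approval, ~12.4 preclinical
# candidates). Failure-cause shares (safety / efficacy / other) per phase are
# literature-informed choices in the spirit of published attrition-cause
# surveys: safety-dominated early, efficacy-dominated in Phase II/III,
# regulatory/commercial at submission. The portfolio composition at
# preclinical entry (independent probabilities of being unsafe and of being
# ineffective) is chosen so the cause decomposition stays feasible at every
# phase, with headroom under +/-10% parameter perturbation; see
# docs/methods.md for the rationale and limitations of each value.
phases:
  - name: preclinical
    cost_per_candidate: 5
    duration: 1.0
    p_advance: 0.69
    failure_shares: {safety: 0.40, efficacy: 0.30, other: 0.30}
  - name: phase1
    cost_per_candidate: 15
    duration: 1.5
    p_advance: 0.54
    failure_shares: {safety: 0.35, efficacy: 0.25, other: 0.40}
  - name: phase2
    cost_per_candidate: 40
    duration: 2.5
    p_advance: 0.34
    failure_shares: {safety: 0.25, efficacy: 0.48, other: 0.27}
  - name: phase3
    cost_per_candidate: 150
    duration: 2.5
    p_advance: 0.70
    failure_shares: {safety: 0.14, efficacy: 0.55, other: 0.31}
  - name: submission
    cost_per_candidate: 40
    duration: 1.5
    p_advance: 0.91
    failure_shares: {safety: 0.05, efficacy: 0.15, other: 0.80}

composition:
  p_unsafe: 0.55        # probability a preclinical entrant is unsafe
  p_ineffective: 0.75   # probability a preclinical entrant is ineffective

financials:
  discount_rate: 0.11   # annual cost of capital
  launch_value: 1600    # $M, NPV of one launch at approval

screening:
  chip_cost_per_candidate: 0.1   # $M, CRO-style organ-chip testing price
  dili_share: 0.13               # DILI share of safety-related trial failures
  chip_sensitivity: 0.87         # two-donor, protein-binding-corrected chip
  hold_phase1_entrants: true     # conservative: keep Phase I intake at base

industry:
  global_rd: 196                 # $B/yr world-wide pharma R&D investment
  small_molecule_share: 0.56
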