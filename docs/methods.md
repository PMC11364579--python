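# Methods

## Decision problem

A cohort of patients with an incidentally detected renal lesion (age 63,
pre-test probability of malignancy 0.19) is classified once, at entry, as
benign or malignant by one of two strategies: contrast-enhanced MRI read
by experts (sensitivity 0.80, specificity 0.35) or the same MRI with
deep-learning decision support (0.92, 0.41). Classification is a one-shot
event; the model then follows each diagnostic outcome through a 10-year
annual-cycle Markov cohort model and accumulates discounted costs (USD,
payer perspective) and quality-adjusted life years.

## Decision tree and entry costs

`classify` splits the cohort into TP/FP/TN/FN via
TP = prev·sens, FN = prev·(1−sens), TN = (1−prev)·spec,
FP = (1−prev)·(1−spec). Entry charges at t = 0 (undiscounted):

| outcome | charge | entry state |
|---|---|---|
| all | MRI $453 (+ AI surcharge in the AI arm) | — |
| TP | + timely surgery $7,652 | Resected, year 1 |
| FP | + biopsy $1,535 + unnecessary surgery $4,884 | Benign post-surgery, year 1 |
| TN | — | Benign |
| FN | — | Malignant, undetected |

The AI surcharge (`cost_ai_per_use`, default $0) is charged once per
patient in the AI arm only; this makes the arm's total cost exactly
linear in the surcharge, which the threshold analysis exploits.

Two structural readings of the false-positive workup are supported. The
default (`fp_includes_biopsy = true`) prices a biopsy before the
unnecessary surgery — consistent with the FP first-year utility being a
post-biopsy weight — while `false` charges surgery only. Both keep the FP
first-year utility at 0.995.

## Markov model

Ten computational states expand seven narrative ones: tunnel pairs
(year 1 / later) carry the first-year vs later-year cost and utility
distinctions for post-unnecessary-surgery benign, resected, and
metastatic disease. Annual transitions:

- **Benign states**: die at `benign_mortality` (default 0 — background
  mortality is attributed only to patients carrying a malignancy, whose
  life-table risk already approximates the background); year-1 tunnel
  advances deterministically.
- **Malignant, undetected** (false negatives): life-table death q(age);
  survivors metastasize with 1.0%/year; the remainder is detected with
  probability 1 after the first undetected year and moves to Resected
  year 1, charging the $7,652 surgery as a transition cost on arrival
  (discounted at the arrival cycle).
- **Resected, year 1**: life-table death; then non-R0 residual (5.7%) and
  local recurrence (1.8%) both enter Recurrence; metastasis 0.18%;
  residual mass to Resected, later. **Resected, later**: same minus the
  non-R0 term.
- **Recurrence**: life-table death; repeat surgery succeeds with 41.2%
  (back to Resected year 1), otherwise metastatic.
- **Metastatic**: dies at 33.5%/year (assumed to dominate background
  mortality, which is not added on top); year-1 tunnel advances.
- **Dead**: absorbing.

Competing risks are resolved death-first within a cycle: the annual death
probability is taken off the top and the stated annual event
probabilities are applied to the survivors, the residual going to the
row's default destination. Probabilities are used as given, not converted
to rates, matching annual-cycle cohort semantics. Rows are validated to
sum to 1 within 1e-9.

Rewards per cycle in state: Benign and later-year states without disease
cost $0 at utility 1; Resected year 1 and Recurrence cost $492 at utility
0.97 (Recurrence has no separately published rewards; a repeat treatment
year is the natural analogue); Resected later $246 at 1; Metastatic
$70,703 / $34,716 at 0.66; Dead (0, 0).

First-year utilities are composed by default
(`compose_monthly_qol = true`) as 11/12 of the annual weight plus 1/12 of
the one-month post-surgery weight (0.7), since the one-month QoL weights
are inputs of the model; e.g. Resected year 1 becomes
(11·0.97 + 0.7)/12 ≈ 0.9475. Setting the switch to `false` treats the
annual first-year weights as already inclusive of the procedure.

Discounting uses d(t) = 1.03^(−t) with t = 0 for the first cycle; rewards
accrue at cycle start; no half-cycle correction by default (the
trapezoidal correction is available as `half_cycle: true`). The final
transition leads beyond the accrual window, so arrivals it produces are
not charged. A cohort held in the benign state therefore earns exactly
Σₜ₌₀⁹ 1.03^(−t) ≈ 8.7861 QALYs, which the tests assert.

The cohort recursion is linear in the initial occupancy, so per-state
discounted totals (computed once per parameter set from an identity
start) give both strategies' totals as dot products — the probabilistic
analysis relies on this.

## Life table

Background mortality for carriers of a localized tumor comes from a
period life table (integer age → annual death probability qx). The
bundled `us_life_table_2017.csv` is a rounded transcription of 2017 US
total-population values for ages 63–73 (q(63) ≈ 0.0117 rising to
q(73) ≈ 0.0266). Totals are insensitive to small transcription error: a
10% perturbation of qx moves cohort QALYs by < 0.01. Synthetic Gompertz
tables (qx = 1 − exp(−a·e^{b·(age−start)})) are used everywhere a test
does not depend on the bundled values.

## Cost-effectiveness analysis

ΔC and ΔE are comparator (MRI+AI) minus reference (MRI). Dominance
(ΔC < 0 < ΔE), dominated, equivalence and cost-minimization (ΔE = 0) are
labeled rather than dividing; otherwise ICER = ΔC/ΔE.
NMB = λ·ΔE − ΔC. The maximum AI price at willingness-to-pay λ is computed
in closed form, price(λ) = −ΔC₀ + λ·ΔE₀, valid because the surcharge is a
one-time undiscounted per-patient cost; the tests cross-check it against
bisection on the full pipeline. The threshold curve is evaluated on a
λ-grid of $0–$200,000 in $10,000 steps.

## Sensitivity analyses

**One-way (tornado).** Default parameter set: the four accuracies,
prevalence, and the seven costs the model actually charges; default
ranges ±20% of base, clipped to [0, 1] for probabilities (exact ranges
configurable). The outcome is the signed ΔC/ΔE (or NMB), each parameter
varied alone; bars sort by width. `find_crossing` bisects any predicate
on the comparison to |bracket| < 1e-6.

**Probabilistic.** Every non-structural parameter with a non-degenerate
base value is drawn independently — beta for probabilities and utilities,
gamma for costs — calibrated by method of moments to the base value as
mean and a coefficient of variation of 0.2 (a conventional default where
dispersions are not published; overridable per parameter). Means pinned
at 0 or 1 stay fixed; beta targets whose variance is infeasible
(sd² ≥ μ(1−μ), e.g. μ = 0.995 at cv 0.2) are clipped just inside the
feasibility bound with a warning. Both strategies are evaluated on the
same joint draw. 30,000 iterations run in ~15 s; the CEAC is the fraction
of draws with positive incremental NMB at each λ on the grid, verified in
tests against direct counting. One seeded `numpy` generator per run;
reruns are bitwise identical.

## Numerical and degenerate-input choices

- Row-stochasticity enforced at 1e-9; occupancy conservation asserted at
  1e-12 in tests, including under random PSA draws.
- The engine is validated against an exhaustive path-enumeration oracle
  (all state paths, probability-weighted discounted rewards) on ≤4-state,
  ≤3-cycle toy models and on the full model truncated to 3 cycles, at
  1e-10.
- `p_death_surgery` (0 by default) and `cost_cect` are configuration-only:
  surgery mortality is not wired into the matrices at its zero default,
  and the contrast-CT fee documents the source of the follow-up costs
  rather than being charged separately. `u_month_biopsy` only enters the
  composition mode. Nonzero `p_death_surgery` values are accepted but
  inert; this is a documented limitation.
- FN ordering within the undetected year: metastasis is applied before
  detection; with detection probability 1 the undetected state empties
  after one cycle either way.
- `load_config` falls back to the built-in base case for missing keys and
  rejects unknown keys, non-numeric values, and out-of-range values with
  the offending key named.

## What the synthetic generators do and do not show

The Gompertz tables emulate plausible, monotone old-age mortality; toy
models exercise the accumulator on arbitrary stochastic matrices. Tests
passing on these show the engine's arithmetic is right, not that the
bundled parameter values describe any real cohort: all clinical content
enters through the base-case parameter table, which is itself a
literature synthesis, not patient-level data.

## Limitations

- Under the base-case inputs a false negative is both cheaper and more
  effective than a true positive (the undetected year carries utility 1
  and only a 1% metastasis risk, while treatment and its risk cascade are
  delayed and discounted). The QALY advantage of the AI arm therefore
  rests on its lower false-positive burden and is small (≈ +0.0006);
  conclusions about the effectiveness delta are structurally fragile and
  sensitive to the first-year utility composition.
- No correlation between sampled parameters; no value-of-information
  analysis; two strategies only (no efficiency frontier).
- The cohort recursion is exact for this model class; there is no
  individual-level simulation and no state memory beyond the defined
  tunnel states.
- Costs are undiscounted 2017-era USD fees without inflation adjustment;
  no currency conversion or fee-schedule lookups.
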