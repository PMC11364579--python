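# renalcea

Early health-technology assessment of AI-assisted MRI characterization of
incidental renal lesions, as a tested, reusable Python pipeline.

Incidental renal masses are common on abdominal imaging, and deciding
whether a lesion is benign or malignant drives very different downstream
care: timely partial/radical nephrectomy for a detected malignancy,
unnecessary surgery for a false positive, and delayed treatment with a
window for metastatic spread for a false negative. `renalcea` models two
diagnostic strategies for a 63-year-old cohort with a 19% pre-test
probability of malignancy — expert MRI reading alone (sensitivity 0.80,
specificity 0.35) and MRI with deep-learning support (0.92, 0.41) — from a
US healthcare-payer perspective, and asks what the AI support may cost per
application while remaining cost-effective.

It is written for health-economics researchers and methods-minded
radiologists who want the full model, not a spreadsheet: every parameter,
structural switch, and analysis is library code with a thin CLI on top.

## Model

A decision tree splits the cohort by diagnostic outcome
(TP/FP/TN/FN = prevalence × sensitivity/specificity), attaches one-time
entry costs (imaging, AI surcharge, biopsy/surgery), and hands the cohort
to a Markov state-transition model run for 10 annual cycles:
benign; benign after unnecessary surgery (year 1 / later); undetected
malignancy; resected malignancy (year 1 / later); recurrence; metastatic
(year 1 / later); dead. First-year/later-year distinctions are tunnel
states so that first-year costs and utilities ($492 vs $246 localized;
$70,703 vs $34,716 metastatic; utility 0.97 vs 1) can differ. Mortality of
patients carrying a localized tumor is age-dependent via a bundled period
life table; metastatic patients die at 33.5% per year; death is resolved
first within each cycle and the remaining probability is split among
disease events.

Costs *C* and QALYs *E* are discounted at 3% per year. Strategies are
compared by incremental cost-effectiveness ratio ICER = ΔC/ΔE (with
dominance reported instead when ΔC < 0 and ΔE > 0) and net monetary
benefit NMB = λ·ΔE − ΔC at willingness to pay λ = $100,000/QALY. Because
the AI surcharge is a one-time per-patient cost, the maximum justifiable
AI price at willingness-to-pay λ has the closed form

    price(λ) = −ΔC₀ + λ·ΔE₀

with ΔC₀, ΔE₀ the increments at zero surcharge. One-way (tornado)
sensitivity analysis, bisection for parameter sign-crossings, and a
30,000-iteration probabilistic sensitivity analysis (beta-distributed
probabilities/utilities, gamma-distributed costs, method-of-moments
calibration at a default coefficient of variation of 0.2) complete the
toolkit. See `docs/methods.md` for assumptions and numerical choices.

## Worked example

```sh
$ renalcea base --out out/
MRI:    $8,080  8.5892 QALYs
MRI+AI: $7,793  8.5898 QALYs
status: MRI+AI is dominant
max AI price: $287.17 (dominance), $349.92 (WTP $100,000/QALY)
```

Reading: over 10 years the MRI strategy costs $8,080 per patient and
yields 8.5892 discounted QALYs; adding AI support (at $0 per application)
saves $287 and gains 0.0006 QALYs, so it is the dominant strategy. A
priced AI application stays dominant up to $287.17 and remains
cost-effective at $100,000/QALY up to $349.92. The same run writes
`summary.json`/`summary.csv`, per-cycle cohort traces for both arms, and
the fully resolved configuration.

```sh
$ renalcea threshold --out out/
max AI price $287.17 at WTP $0 rising to $412.66 at WTP $200,000/QALY

$ renalcea dsa --out out/
tornado: 12 parameters, widest bar: ai_sens
incremental cost crosses zero at MRI specificity 0.4052 and MRI+AI specificity 0.3548

$ renalcea psa --n-iterations 30000 --seed 1 --out out/
```

`dsa` reports that the AI arm stops saving money if MRI-alone specificity
rises above ≈0.41 or AI specificity falls below ≈0.35; `psa` writes the
cost-effectiveness scatter and the acceptability curve (the AI arm is
cost-effective in >60% of draws at every WTP from $0 to $200,000).

The same functionality is available as a library
(`renalcea.evaluate_all`, `renalcea.compare`, `renalcea.run_psa`, ...),
and every default can be overridden from a flat YAML file:

```yaml
parameters:
  ai_sens: 0.95
  cost_ai_per_use: 100
options:
  half_cycle: true
life_table: my_life_table.csv
```

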