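# mesacea

A Markov cohort cost-effectiveness model comparing two oral mesalazine
(5-ASA) formulations — MMX mesalazine, 1,200 mg tablets taken once daily
("Mezavant"), and delayed-release mesalazine, 400 mg tablets taken in
divided doses ("Asacol") — for the induction and maintenance of remission
in mild-to-moderate ulcerative colitis (UC), evaluated from the
perspective of the German Statutory Health Insurance (SHI, price year
2009). It is written for health economists and HTA analysts who want a
tested, scriptable re-implementation of the model rather than a
spreadsheet.

## The model

A cohort of UC patients (starting age 43.2 years, all in active disease)
moves through eight health states in 8-week cycles:

* active UC on first-line mesalazine (2,400 mg/day),
* active UC on an increased dose (4,800 mg/day),
* active UC on second-line treatment (4,800 mg/day + tapered oral
  prednisolone),
* mesalazine failure → hospitalisation without surgery,
* surgery (with 2.1% surgical mortality),
* post-surgery (absorbing until death),
* remission (maintenance mesalazine 2,400 mg/day), and
* death.

Remission is expanded into tunnel sub-states so the per-cycle relapse
probability can fall by 1% (relative) per additional year spent in
remission. Costs per state-cycle combine drug acquisition at net SHI
prices, an 8-week share of the quarterly EBM gastroenterologist lump sum
plus outpatient procedures (47.21 € per active cycle), and DRG lump sums
for inpatient stays (1,584.27 € without, 3,812.55 € with surgery). Costs
and QALYs (state utilities 0.589 active / 0.317 severe / 0.845 remission)
are discounted at 5%/year. Outputs per arm are discounted cost `C`,
discounted QALYs `Q`, undiscounted days in remission and event counts;
the comparison reports ΔC, ΔQ and either the ICER ΔC/ΔQ or a dominance
verdict. A probabilistic sensitivity analysis (beta distributions for
probabilities and utilities, gamma for costs, method of moments) and
one-way sensitivity analyses propagate parameter uncertainty.

## Worked example

```python
from mesacea import MarkovCEModel

results = MarkovCEModel.base_case().fit()
print(results.summary())
```

prints

```
Markov cohort cost-effectiveness analysis (five_years, 32 cycles of 56 days, discount 5.0%/yr)

arm         cost (EUR)    QALYs  rem. days  episodes  surgeries
MEZAVANT         3,990    3.603       1642     0.093     0.0100
ASACOL           4,701    3.587       1616     0.119     0.0128

incremental (MEZAVANT - ASACOL): cost -711 EUR, QALYs +0.016
conclusion: dominant (cost per QALY: NA)
```

Over five years the once-daily MMX arm costs 711 € less per patient,
gains 0.016 QALYs and 26 remission days, and avoids 0.026 inpatient
episodes and 0.003 surgeries — it *dominates* the comparator (cheaper
and more effective), so no ICER is reported. Probabilistic and one-way
analyses hang off the same objects:

```python
psa = MarkovCEModel.base_case().run_psa(n_iter=10_000, seed=1)
print(psa.summary())                      # P(cost-saving and QALY-gaining)
owsa = MarkovCEModel.base_case().run_owsa("p_surgery_hosp", (0.05, 0.30), steps=6)
print(owsa.max_abs_cost_deviation)        # ~5 EUR: share of surgery barely matters
```

The same analyses are available from the shell via the `mesacea` CLI
(`run`, `psa`, `owsa`, `fixtures`, `validate`), which exports traces,
CE-plane scatter and CEAC files plus a JSON run manifest.

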