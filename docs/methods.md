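# Methods

## Model structure

The model is a discrete-time Markov cohort simulation of the treatment
pathway of mild-to-moderate ulcerative colitis under two oral mesalazine
formulations, evaluated from the German SHI perspective. Cycles are 8
weeks (56 days; a cycle is 56/365.25 of a year, with 56/364 = 8/52
available via `ModelConfig.days_per_year`). The base-case horizon is five
years — `floor(5 * 365.25 / 56) = 32` cycles — and a lifelong horizon
truncates at age 105, by which the cohort is essentially extinct under
any plausible life table.

The eight logical states and their transitions: first-line active
disease either remits (40.5% / 32.6% per cycle for the MMX and
delayed-release arms) or escalates to the increased dose; the increased
dose remits (61.5% / 60.0%) or escalates to second line; second line
(mesalazine + prednisolone) remits (68%) or fails into hospitalisation;
hospitalisation leads to remission (89.1%) or surgery (10.9%); surgery
leads to post-surgery (97.9%) or death (2.1%). Post-surgery and death
are absorbing (up to background mortality). Active treatment stages and
inpatient states have no self-loops: each lasts exactly one cycle, as
implied by complementary outgoing probabilities.

### Remission tunnel and time-dependent relapse

The relapse probability falls by 1% *relative* per additional year spent
in remission, up to 5 tracked years (both the decrement interpretation
and the cap are open in the source material; both are configurable).
Remission is therefore expanded into cycle-granular tunnel sub-states —
7 per tunnel year (`ceil(365.25/56)`), plus one terminal sub-state — so
each cohort slice advances exactly one tunnel year every 7 cycles while
the process remains Markovian. Aggregating tunnel sub-states recovers
the single logical remission state; with a zero decrement the aggregate
trace is invariant to the tunnel depth (property-tested).

### Relapse time basis

The published transition table prints remission→relapse values of 6.5%
and 9.2% with a footnote marker. Treated verbatim as per-cycle
probabilities they imply annual relapse risks near the one-year
maintenance data they were derived from (62.2% / 51.5% still in
remission at 12 months), but they then produce arm differences several
times larger than every reported incremental result. Interpreting them
as *annual* probabilities converted to the cycle length,
`1 - (1 - p)^(56/365.25)` (≈1.03% and 1.47% per cycle), reproduces the
reported incremental cost, QALY, remission-day and event differences to
within tens of percent, and is adopted as the base case
(`relapse_basis="annual"`); the verbatim reading remains available as
`relapse_basis="per_cycle"`. This is the single most consequential
reconstruction choice in the package.

### Surgery share among hospitalised patients

Two candidate values appear in the source material: 25.8% (the UK-audit
admission share, printed in the transition table) and 10.9% (German
Federal Statistical Office, stated in the discussion as the model input
and as the centre of the 5–30% one-way sensitivity range). The base case
uses 10.9%, which also reproduces the reported surgery-difference
magnitude; 25.8% is a one-line scenario
(`apply_parameter(bundle, "p_surgery_hosp", 0.258)`). The one-way
analysis shows the choice moves the incremental cost by only a few euro.

### Background mortality

The printed transition table carries 0.0% death from all non-surgical
states, so the 5-year base case applies *no* background mortality
(surgical mortality only). The lifelong horizon layers age-specific
all-cause mortality from a life table onto every alive state: the annual
probability at the cohort's current integer age (age advances
continuously from 43.2 and is floored for lookup) is converted to the
cycle length, added to the death column, and the remaining row rescaled
by `1 - q`.

## Economic accrual

Costs and QALYs accrue on the state occupancy at the *start* of each
cycle, discounted by `(1.05)^(-t * 56/365.25)`; an optional half-cycle
correction averages start- and end-of-cycle occupancy. Days in remission
and event counts (entries into hospitalisation and surgery, counted from
inflows so self-loop configurations stay correct) are reported
undiscounted in natural units. Monetary arithmetic is kept at full
floating precision and rounded to cents (breakdowns) or whole euro
(summaries) only at report time.

Maintenance dosing in remission is 2,400 mg/day for both products (their
labelled standard maintenance regimen; the source is silent, and this is
the only choice consistent with the reported cost advantage). Second
line keeps mesalazine at 4,800 mg/day with the prednisolone taper
(40→5 mg/day in weekly 5 mg steps, 0.25 € per 40 mg ⇒ 7.875 €/cycle).
Each arm is costed at its own product's net price throughout.
Post-surgery patients are assumed to incur no drug or follow-up cost.

## Sensitivity analyses

**PSA.** Each of 10,000 seeded draws samples, in a fixed documented
order: the three utilities (beta; SE = printed SD/√151; states sharing a
printed utility share one draw, and utilities are shared between arms),
remission probabilities (beta with binomial SEs from pseudo-trial sizes
— 170/arm first line, 85/arm increased dose, 170 for the shared second
line, hospitalisation and maintenance parameters; arm-specific rates are
drawn independently per arm), and all cost parameters (gamma, 20%
relative SE) including the per-product tablet prices, since drug
acquisition is a component of the drawn health-state costs
(`sample_drug_prices=False` holds the statutory reference prices fixed).
All distributions are method-of-moments, so every distribution mean
equals its deterministic value; zero dispersion degenerates the PSA to
the deterministic result exactly (tested). Both arms are evaluated on
the same draw. Draws violating parameter support are rejected, logged
and counted; by construction of the families the rejection rate is zero.
The dominance probability is the fraction of draws in the south-east CE
quadrant (cost-saving with a QALY gain); under these declared
assumptions it is ≈65–70%, and ≈90% if drug prices are held fixed — the
quantity is strongly assumption-dependent because almost all draws are
cost-saving and the verdict hinges on the sign of ΔQALY and Δcost noise.

**OWSA.** Deterministic re-runs over an evenly spaced grid of one named
parameter, all others at base values, reporting incremental results per
grid point and the maximum absolute deviation of the incremental cost
from base — tornado-ready.

## Synthetic data

`mesacea.synthetic` generates every input: the fully transcribed
base-case bundle (lossless YAML round-trip), binomial pseudo-trials
matching the PSA's dispersion structure, seeded perturbed scenario sets,
and a Gompertz life table `q(a) = 1 - exp(-b e^{c a})` with `b = 4.2e-5`,
`c = 0.09`, calibrated so `q(43) ≈ 2e-3` — a synthetic stand-in for
official age-specific mortality, adequate for structural and qualitative
checks (dominance on the lifelong horizon) but not for reproducing any
official lifelong point estimate. Generated artifacts pass the same
validators as user-supplied files. What passing tests therefore show is
internal correctness and faithfulness to the printed inputs — not
external validity of the trial efficacy data, the cross-sectional
resource-use snapshot, or full adherence (assumed perfect).

## Numerical choices

Transition rows must sum to 1 within 1e-9 (assembly error otherwise);
occupancy conservation is enforced at 1e-12 per cycle (1e-9 under
age-varying matrices). The cohort iteration is validated against an
independent per-individual microsimulation (10⁵ patients, same matrices)
within 3 Monte-Carlo standard errors per state and cycle. Degenerate
inputs are defined: a zero-cycle run returns the initial distribution;
single-point OWSA grids at the base value return the base result; ties
in dominance classification (|Δ| ≤ 1e-12) are labelled "equivalent".

## Known limitations

* The reported absolute cost and QALY levels of the source analysis
  cannot be reconciled with its own incremental results under any
  convention of this structure (they imply mutually exclusive
  active-state occupancies); this package prioritises the incremental
  results, so its absolute levels differ from the printed ones.
* Adherence, colorectal-cancer risk modulation, TNF-α/immunosuppressant
  pathways and post-surgical complications are out of scope by design.
* PSA dispersion for parameters without printed uncertainty rests on
  declared assumptions (pseudo-trial sizes, 20% relative cost SE).
* The April-2010 price scenario keeps the cost saving but — contrary to
  a qualitative claim in the source discussion — slightly *narrows* it,
  since both net prices fell by the same ~11.5%.
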