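# Methods

## Model

`laaocea` implements a deterministic Markov cohort model comparing
transcatheter left atrial appendage occlusion (LAAO) with seven
antithrombotic drug strategies — aspirin, clopidogrel+aspirin, warfarin,
dabigatran 110 mg and 150 mg, apixaban, rivaroxaban — for stroke
prophylaxis in non-valvular atrial fibrillation.  A cohort of 65-year-olds
starts in the well state and moves between eight health states over
one-year cycles to age 85 (20 cycles):

well · post-mild-stroke · post-moderate/severe-stroke · post-ICH ·
post-MI · post-TIA · dead (vascular/event) · dead (other).

All living states face the same annual event probabilities (recurrent
events are allowed, with no post-event rate escalation).  Ischemic-stroke
incidence is split by a strategy-class severity mix (fatal /
moderate-severe / mild / no residual); TIA incidence is derived from the
share of neurological ischemic events that are TIAs (28 %):
`stroke_rate × 0.28/0.72`.  Minor and major hemorrhages are transient —
they cost money and a 90-day utility decrement but do not move the
cohort.  ICH survivors enter the post-ICH state, carrying the
moderate-severe stroke utility (0.39) and the ICH long-term cost, since
no ICH-specific utility is published.  Sequela states persist for life
and accrue long-term annual costs; post-event utilities are
`min(baseline, sequela weight)`.

Annual percentage rates convert to cycle probabilities directly
(`rate/100`; a constant-hazard option exists — at these magnitudes the two
differ by <2 % relative).  Costs and QALYs discount at 3 %/yr, cycle 0
undiscounted.  Outcomes are total discounted cost (US$), total discounted
QALYs, and undiscounted life-years, with a full per-cycle trace.

### The device arm

The LAAO strategy is an implant-success mixture: with probability 0.868
the cohort follows the occlusion branch — first year on the phased
regimen (45 days warfarin, 180 days clopidogrel+aspirin, then aspirin)
with the published pro-rata first-year bleeding/MI rates, lifelong
aspirin-class rates thereafter — and with probability 0.132 it continues
on warfarin.  Cycle 0 charges the $22,500 procedure+device cost
(successful branch), two $334 transesophageal echocardiograms, and the
expected pericardial-effusion hospitalization (2.07 % × $73,770) to both
branches.  First-year drug cost is the duration-weighted blend of the
three regimens plus pro-rata INR monitoring.

Three published first-year rows (minor hemorrhage 4.28, fatal hemorrhage
0.45, MI 0.76 %/yr) disagree with the naive 45/180/140-day pro-rata
computation (4.56, 0.34, 0.79); the published values are used verbatim
and the discrepancy is asserted in a documented test.
`pro_rata_first_year_rate` is provided for user-defined regimens.

### Mortality

Total annual death probability is the all-cause rate plus the tabulated
vascular-death rate (rivaroxaban and LAAO have no vascular row; only
all-cause applies).  Fatal stroke and fatal hemorrhage route to the
vascular/event death state but are debited from the all-cause flow — they
are treated as already counted in it.  The additive alternative is a
config switch; docs/calibration.md explains why it was rejected.

## Parameters

Every input lives in a YAML "parameter book" of `(base, low, high)`
triples — event rates (%/yr), severity mixes, utilities, US$ costs — with
a canonical book shipped in-package.  Validation hard-fails on missing
strategies/rates, utilities outside [0,1], negative costs or rates
outside [0,100], and soft-reports range anomalies.  The published
antiplatelet severity mix sums to 99.9 % and is renormalized to the
simplex on use.

Key settings (ModelConfig): start age 65; 20 one-year cycles; 3 %/yr
discount; $50,000/QALY decision threshold; the structural switches and
their calibrated defaults are documented in docs/calibration.md.

## Uncertainty analysis

**One-way / tornado** — each parameter with a range is set to its low and
high bound in turn and the LAAO-vs-warfarin ICER recomputed; bars sort by
swing width.  **Scenarios** — stroke risk scales all arms' stroke rates
by `chads_rate(score)/2.8` (the per-score rates are untreated-population
rates; 2.8 %/yr places the base case between scores 1 and 2); bleeding
risk scales major/ICH/fatal hemorrhage of the anticoagulant-containing
arms (and the device arm's first year) by the ratio of the per-score rate
to warfarin's base major-hemorrhage rate, leaving antiplatelet arms and
minor hemorrhage untouched; horizon truncates the cycle count; device
cost replaces the procedure+device total only.

**PSA** — ranges are read as 95 % intervals (`sd = (high−low)/3.92`).
Parameters with native support [0,1] (rates on the fraction scale,
severity fractions, utilities, implant success) get method-of-moments
beta fits; costs get gamma fits; degenerate ranges are point masses; a
fit whose implied variance reaches the Bernoulli bound falls back to a
variance-capped beta with a warning.  Draw *i* of a run with master seed
*s* uses a generator seeded by `(s, i)`, samples every parameter
independently in a fixed order, and evaluates all eight strategies on the
same book (common parameters within a draw).  The optimal strategy per
draw maximizes net monetary benefit `wtp × QALY − cost`; exact ties split
credit equally.  The acceptability curve spans $0–150k in $5k steps.  The
engine broadcasts over the draw dimension, so 10,000 draws × 8 strategies
× 20 cycles runs in a few seconds.

## Synthetic data

The generator produces three kinds of books.  *Canonical*: the in-repo
transcription of the published inputs, byte-stable across calls.
*Random*: one PSA draw, reproducible from its seed; always passes
validation by construction (beta draws cannot leave [0,1], gamma draws
cannot go negative).  *Degenerate*: no-event, no-death, zero-cost and
unit-utility overrides, composable, engineered so the engine has exact
closed-form answers — a no-event cohort's discounted QALYs equal the
annuity `u·Σ (1−m)^t (1+d)^−t`, and the composed well cohort accrues
exactly one QALY per undiscounted cycle.

What the generator does *not* emulate: patient-level heterogeneity,
parameter correlations (none are published; independence is assumed),
age-dependent background mortality, treatment switching beyond the
post-implant regimen, or secular drug-price trends.  Passing tests
therefore demonstrate fidelity to the published table-driven cohort
model, not predictive validity for any real population.

## Numerical choices

Cohort mass is asserted conserved to 1e-10 every cycle.  Competing
per-cycle exit probabilities above 1 raise an error naming the state and
cycle (unreachable for the published inputs, reachable for extreme
user-supplied rates).  ICERs are computed at full precision and rounded
to whole dollars only for display; dominance returns a code, not a
number.  The frontier algorithm sorts by cost, removes absolute
dominance, then iteratively removes extended-dominated members until
ICERs strictly increase; equal-cost ties keep the higher-QALY arm and
exact cost-and-QALY ties are co-listed.  A tie at the NMB argmax splits
probability mass equally (measure-zero under continuous draws but must be
deterministic).

## Known limitations

* The transition topology of the original model is not published; the
  structural calibration (docs/calibration.md) brackets it but cannot
  recover it exactly.  Per-strategy totals reproduce within ±7 % / ±0.35
  QALYs, not exactly.
* The published probabilistic headline (86.24 %) is not reproducible from
  the printed inputs under the stated distribution recipe; this package
  computes 95–96 % and reports it as such (see calibration report).
* TIA carries the baseline utility (no TIA weight is published) and a
  lifelong post-TIA cost state; ICH borrows the severe-stroke utility.
* The published hospitalization *rates* (≈20 %/yr for drug arms) carry no
  cost in this model; only their footprint through stroke/pericardial
  events is priced.  The device-arm hospitalization row (1.08 %/yr) is
  stored but inert.
* Single-country payer prices, no inflation adjustment, no budget-impact
  or societal perspective.
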