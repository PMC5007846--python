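# Calibration report

The published model this package re-implements was built in a commercial
decision-tree package, and its write-up names the health states and every
input value but not the permitted transitions, the accrual convention, or
how several one-off costs were charged.  Those structural choices change
lifetime totals by more than the parameter uncertainty does, so the engine
exposes them as explicit switches and fixes their defaults by calibration
against the published per-strategy totals.  This note records the
procedure and the frozen result; `analysis/01_calibration_grid.py`
reproduces it.

## Calibration surface

| switch | options | frozen default |
|---|---|---|
| `mortality_mode` | `background_plus_vascular`, `additive_fatal` | `background_plus_vascular` |
| `accrual` | `start`, `end`, `half_cycle` | `start` |
| `death_cost_mode` | `none`, `background`, `all` | `background` |
| `charge_stroke_hospitalization` | on/off | off |
| `inr_visits_per_year` | any | 26 |
| `event_disutility_days` | any | 90 |
| `device_cost_branches` | `success_only`, `both` | `success_only` |
| `rate_conversion` | `direct`, `exponential` | `direct` |

## Scoring

Each of the 480 combinations in the grid was scored against:

* per-strategy discounted lifetime cost, relative to the published value,
  normalized by a ±10 % band;
* per-strategy discounted QALYs, normalized by a ±0.5 QALY band;
* the 5-year-horizon device-vs-warfarin ICER, normalized by a ±15 % band.

The score is the worst-case margin over all 17 checks (1 = exact, 0 = on a
band edge).  The two top configurations tie at margin 0.29; the runner-up
(full-cycle transient disutility, device cost charged to both implant
branches) fails a qualitative requirement — the device arm must dominate
all four NOACs at every stroke-risk score, and it loses cost dominance to
dabigatran 150 mg at scores 5–6 — so the winner was frozen.

## Frozen configuration, rationale

* **Mortality composition.**  Total annual death probability is the
  all-cause rate plus the vascular-death rate where one is tabulated;
  fatal stroke and fatal hemorrhage route to the vascular/event death
  state but are debited from the all-cause flow rather than added on top.
  Adding them on top over-kills the dabigatran arms (dabigatran 150 mg
  lands ≈ 8.3 QALYs against a published 9.00).
* **Accrual.**  State membership accrues utility and continuous costs at
  the start of each cycle, discounted by (1+d)^-t with cycle 0
  undiscounted; no half-cycle correction.  Half-cycle accrual pushes the
  clopidogrel+aspirin arm ~14 % below its published cost.
* **Death cost.**  The $10,000 terminal-care cost is charged per
  background (non-vascular) death only.  Charging it on vascular deaths
  too overshoots the antiplatelet arms, whose vascular mortality is
  4.7 %/yr.
* **Stroke hospitalization.**  The $80,964 stroke-hospitalization charge
  is *not* added per moderate-to-severe stroke: the $14,680 short-term
  event cost is taken as covering the acute admission.  Charging it
  overshoots the aspirin arm (2.8 %/yr strokes) by ~30 %.  The
  pericardial-effusion hospitalization ($73,770 × 2.07 %) *is* charged at
  implantation, since procedure complications have no other cost row.
* **INR monitoring.**  26 visits/yr (fortnightly), within the 2–4-week
  interval typical of anticoagulation clinics; the source prices a visit
  but never states a frequency.  12/yr leaves the warfarin arm outside
  its cost band under every otherwise-feasible combination.
* **Transient-event disutility.**  Hemorrhage and MI utilities (0.8,
  0.84) apply for 90 days of the event cycle.  A full-year application
  costs the warfarin arm ≈ 0.33 QALYs through its 18.6 %/yr
  minor-hemorrhage rate alone, which is clinically implausible for
  self-limited bleeds and drags the 5-year ICER low.
* **Device cost branch.**  The $22,500 procedure+device cost is charged
  only to the 86.8 % successful-implant branch; the 13.2 % who continue
  warfarin carry the TEE and pericardial-effusion costs but not the
  device.  Charging the device to both branches inflates the short-horizon
  ICER ~20 % past its band and breaks the NOAC-dominance pattern above.

## Frozen-default scorecard (base case, 20-year horizon)

| strategy | cost (model) | cost (published) | Δ | QALYs (model) | QALYs (published) | Δ |
|---|---|---|---|---|---|---|
| aspirin | $13,048 | $12,877 | +1.3 % | 6.47 | 6.12 | +0.35 |
| clopidogrel+aspirin | $24,886 | $26,287 | −5.3 % | 6.58 | 6.29 | +0.29 |
| warfarin | $26,106 | $28,090 | −7.1 % | 9.47 | 9.45 | +0.02 |
| LAA occlusion | $37,470 | $37,789 | −0.8 % | 11.07 | 10.99 | +0.08 |
| dabigatran 110 mg | $43,275 | $42,712 | +1.3 % | 8.94 | 8.76 | +0.18 |
| dabigatran 150 mg | $42,788 | $43,946 | −2.6 % | 9.15 | 9.00 | +0.15 |
| rivaroxaban | $47,681 | $51,064 | −6.6 % | 9.96 | 9.86 | +0.10 |
| apixaban | $52,130 | $53,315 | −2.2 % | 9.53 | 9.40 | +0.13 |

5-year device-vs-warfarin ICER: $80,807/QALY (published $74,422, +8.6 %).
The frontier, dominance labels, tornado top-two and every scenario pattern
reproduce the published qualitative structure exactly.

## Known residual

The probabilistic headline does not calibrate: with the stated beta/gamma
fits (sd = range/3.92) the device arm maximizes net monetary benefit in
95–96 % of 10,000 draws at $50,000/QALY, versus a published 86.24 %, and
this holds across every structural configuration that satisfies the bands
above.  The package's base-case net-benefit gap matches the published
point estimates almost exactly, so the difference must come from larger
draw-level variance in the original model — consistent with its very wide
warfarin-mortality tornado bar (−$32,048…$12,994), which is likewise not
reproducible from the printed inputs (this model: $25,076…$5,505).
Spreads are not inflated to force agreement; the statistic is reported as
computed.
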