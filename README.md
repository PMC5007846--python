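# laaocea

A Markov cohort cost-effectiveness model of transcatheter **left atrial
appendage occlusion (LAAO)** versus seven antithrombotic drug strategies
— aspirin, clopidogrel+aspirin, warfarin, dabigatran 110/150 mg,
apixaban, rivaroxaban — for stroke prophylaxis in non-valvular atrial
fibrillation, from a US payer perspective.  It is written for health
economists and methodologists who want a transparent, scriptable,
fully-tested re-implementation of a published table-driven decision
model: every input is a `(base, low, high)` triple in a YAML parameter
book, and every analysis layer (cohort engine, incremental analysis,
scenario sweeps, tornado, probabilistic sensitivity analysis) is an
importable function.

## Model in brief

A cohort of 65-year-olds moves between eight health states (well,
post-stroke by severity, post-ICH, post-MI, post-TIA, two absorbing death
states) in one-year cycles to age 85.  Strategy *k* accrues discounted
cost and quality-adjusted life years

```
C_k = Σ_t (1+d)^-t · c_k(t)        E_k = Σ_t (1+d)^-t · Σ_s π_k(s,t) u(s)
```

with d = 3 %/yr.  Strategies are compared by the incremental
cost-effectiveness ratio ICER = ΔC/ΔE against a willingness-to-pay
threshold λ = $50,000/QALY, the efficiency frontier (absolute and
extended dominance), and net monetary benefit NMB = λ·E − C.  Parameter
uncertainty propagates through beta fits (probabilities, utilities) and
gamma fits (costs) with sd = range/3.92, summarized as
cost-effectiveness acceptability curves over 10,000 Monte-Carlo draws.
The LAAO arm is an implant-success mixture (86.8 % occlusion branch with
a phased 45/180-day drug regimen, 13.2 % continuing warfarin) with
procedure, device, echocardiography and pericardial-effusion costs at
cycle 0.  Structural conventions the source publication leaves open are
explicit config switches, frozen by a documented calibration
(`docs/calibration.md`).

## Worked example

```python
import laaocea as L

book = L.canonical_book()                  # the published inputs
outs = L.run_all_strategies(book)          # eight cohort runs
table = L.efficiency_frontier(outs)
print(table.frame().to_string(index=False, float_format=lambda v: f"{v:,.2f}"))
```

```
           strategy          display_name  discounted_cost  discounted_qaly  cost_per_qaly                label  icer_vs_next_best
            aspirin               Aspirin        13,047.80             6.47       2,016.85          on_frontier                NaN
clopidogrel_aspirin Clopidogrel + aspirin        24,885.67             6.58       3,783.32   extended_dominated                NaN
           warfarin              Warfarin        26,106.26             9.47       2,756.08          on_frontier           4,348.71
               laao         LAA occlusion        37,470.36            11.07       3,385.86          on_frontier           7,127.10
     dabigatran_150     Dabigatran 150 mg        42,788.49             9.15       4,678.89 absolutely_dominated                NaN
     dabigatran_110     Dabigatran 110 mg        43,274.76             8.94       4,840.93 absolutely_dominated                NaN
        rivaroxaban           Rivaroxaban        47,680.81             9.96       4,788.94 absolutely_dominated                NaN
           apixaban              Apixaban        52,130.22             9.53       5,470.48 absolutely_dominated                NaN
```

Read: LAA occlusion yields the most QALYs (11.07) at $37,470 lifetime
cost; the efficiency frontier runs aspirin → warfarin → LAAO at
increasing ICERs ($4,349 then $7,127 per QALY, both far below $50,000);
clopidogrel+aspirin is excluded by extended dominance and all four NOACs
are absolutely dominated (costlier and less effective than the device).

The same pipeline is scriptable from a shell:

```
laao-cea base-case  --out-dir results/
laao-cea sensitivity --which chads2
laao-cea psa --n-draws 10000 --seed 1
```

and the numbered drivers under `analysis/` narrate the full study:
calibration grid, base case, the four scenario axes (stroke-risk score,
bleeding-risk score, horizon, device cost), tornado, and the PSA.

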