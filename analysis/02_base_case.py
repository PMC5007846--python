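"""Base-case analysis: lifetime costs, QALYs, dominance and the frontier.

Runs all eight stroke-prevention strategies over the 20-year horizon,
prints the ranked cost-effectiveness table, and writes
results/base_case_table.{csv,json} plus the frontier plot.

Finding: LAA occlusion accrues the most QALYs (~11.1) at a lifetime cost
of ~$37.5k; the efficiency frontier runs aspirin -> warfarin -> LAAO,
clopidogrel+aspirin is extended-dominated, and all four NOACs are
absolutely dominated by the device arm.
"""

from pathlib import Path

from laaocea import canonical_book, compute_icer, efficiency_frontier, run_all_strategies
from laaocea.cea import IcerCode
from laaocea.cli import write_base_case

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    book = canonical_book()
    outcomes = run_all_strategies(book)
    table = efficiency_frontier(outcomes)

    print(table.frame().to_string(index=False,
                                  float_format=lambda v: f"{v:,.2f}"))
    print("\nefficiency frontier:", " -> ".join(table.frontier))
    laao = outcomes["laao"]
    for comparator in ("aspirin", "clopidogrel_aspirin", "warfarin"):
        icer = compute_icer(laao, outcomes[comparator])
        label = icer.value if isinstance(icer, IcerCode) else f"${icer:,.0f}/QALY"
        print(f"LAAO vs {comparator}: {label}")

    write_base_case(book, OUT)
    print(f"\ntable and frontier plot written to {OUT}")


if __name__ == "__main__":
    main()
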