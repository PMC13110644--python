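"""One-way deterministic sensitivity analysis.

Reruns the pipeline for every scenario in the built-in grid (adherence and
test accuracy from 20% below base to near-perfect, each unit cost halved
and doubled, screened-fraction bounds, a 10-year horizon, lifetime-linear
fracture risk) and reports which scenarios change a strategy's
cost-effectiveness at the 20,000/QALY threshold relative to the base case.
"""
from pathlib import Path

from fracture_cea.parameters import reference_bundle
from fracture_cea.sensitivity import evaluate_bundle, run_dsa

OUT = Path(__file__).resolve().parent.parent / "results"
LAM = 20000


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for scenario in ("mof", "hf"):
        bundle = reference_bundle(scenario)
        _, base = evaluate_bundle(bundle)
        base_ce = {(c.intervention, c.comparator): c.cost_effective_at(LAM)
                   for c in base}
        table = run_dsa(bundle)
        table.to_csv(OUT / f"dsa_{scenario}.csv", index=False)

        flips = []
        for _, row in table.iterrows():
            ce = row[f"nmb_at_{LAM}"] > 0
            if ce != base_ce[(row.intervention, row.comparator)]:
                flips.append((row.scenario, row.intervention, row.comparator, ce))
        print(f"\n=== {scenario.upper()}: {table.scenario.nunique()} scenarios, "
              f"{len(table)} comparison rows ===")
        if flips:
            print(f"  scenarios flipping cost-effectiveness at {LAM:,}/QALY:")
            for label, i, c, ce in flips:
                verdict = "becomes" if ce else "loses"
                print(f"    {label}: {i} vs {c} {verdict} cost-effectiveness")
        else:
            print(f"  every scenario agrees with the base case at {LAM:,}/QALY")


if __name__ == "__main__":
    main()
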