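"""Write the synthetic parameter bundles the analysis runs on.

The packaged reference bundles (one per fracture type) hold the central
synthetic values; this script materialises them as JSON next to the other
outputs so every later step can be traced to an explicit parameter file.
"""
from pathlib import Path

from fracture_cea.parameters import reference_bundle, save_bundle

OUT = Path(__file__).resolve().parent.parent / "results" / "parameters"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for scenario in ("mof", "hf"):
        bundle = reference_bundle(scenario)
        path = OUT / f"bundle_{scenario}.json"
        save_bundle(bundle, path)
        epi = bundle.epidemiology
        print(f"{scenario.upper()}: cohort {bundle.config.cohort_size:.0f}, "
              f"ages {bundle.config.start_age}-{bundle.config.end_age}, "
              f"discount {bundle.config.discount_rate:.1%}; "
              f"p10 fracture (op/pe/nm) = "
              f"{epi.p10_fracture_by_state['osteoporosis']:.2f}/"
              f"{epi.p10_fracture_by_state['osteopenia']:.2f}/"
              f"{epi.p10_fracture_by_state['normal']:.2f} -> {path.name}")


if __name__ == "__main__":
    main()
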