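"""Age- and sex-stratified analyses.

The current-practice screened fraction follows the NICE-derived eligibility
gradient: about 1%–5% of 40–49-year-olds qualify for risk assessment,
35%–50% of women aged 50–64 and men aged 50–74, and everyone from age 65
(women) or 75 (men). Each subgroup run starts the cohort at the band's
lower age, applies the band's screened fraction to the current-practice
strategy, and scales fracture and mortality parameters by the bundle's
sex-specific multipliers.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .parameters import ParameterBundle, ParameterError
from .sensitivity import evaluate_bundle

__all__ = ["SubgroupSpec", "subgroup_screen_fraction", "default_subgroup_specs",
           "run_subgroups"]


@dataclass(frozen=True)
class SubgroupSpec:
    sex: str
    age_low: int
    age_high: int
    screened_fraction_base: float
    screened_fraction_low: float
    screened_fraction_high: float

    def validate(self) -> None:
        if self.sex not in ("men", "women", "all"):
            raise ParameterError(f"sex must be men/women/all, got {self.sex!r}")
        if not self.age_low < self.age_high:
            raise ParameterError(
                f"age_low {self.age_low} must precede age_high {self.age_high}")
        for name in ("screened_fraction_low", "screened_fraction_base",
                     "screened_fraction_high"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v!r}")
        if not (self.screened_fraction_low <= self.screened_fraction_base
                <= self.screened_fraction_high):
            raise ParameterError("screened fractions must satisfy low <= base <= high")

    @property
    def label(self) -> str:
        return f"{self.sex}_{self.age_low}_{self.age_high}"


def subgroup_screen_fraction(sex: str, age_band: tuple[int, int]) -> SubgroupSpec:
    """NICE-derived screened fraction for a sex/age band.

    40–49 (either sex): 1%–5% (base 3%); women 50–64 and men 50–74:
    35%–50% (base at the midpoint, 42.5%); women from 65 and men from 75:
    everyone qualifies.
    """
    if sex not in ("men", "women"):
        raise ParameterError(f"sex must be 'men' or 'women', got {sex!r}")
    low, high = age_band
    if low >= high:
        raise ParameterError(f"invalid age band {age_band!r}")
    if low < 40 or high > 79:
        raise ParameterError(f"age band {age_band!r} outside the modelled 40-79 range")
    universal_from = 65 if sex == "women" else 75
    middle_to = 64 if sex == "women" else 74
    if high <= 49:
        fractions = (0.01, 0.03, 0.05)
    elif low >= universal_from:
        fractions = (1.0, 1.0, 1.0)
    elif low >= 50 and high <= middle_to:
        fractions = (0.35, 0.425, 0.50)
    else:
        raise ParameterError(
            f"age band {age_band!r} straddles eligibility boundaries for {sex}")
    spec = SubgroupSpec(sex=sex, age_low=low, age_high=high,
                        screened_fraction_low=fractions[0],
                        screened_fraction_base=fractions[1],
                        screened_fraction_high=fractions[2])
    spec.validate()
    return spec


def default_subgroup_specs() -> list[SubgroupSpec]:
    """The six canonical sex × age-band subgroups."""
    return [
        subgroup_screen_fraction("women", (40, 49)),
        subgroup_screen_fraction("women", (50, 64)),
        subgroup_screen_fraction("women", (65, 79)),
        subgroup_screen_fraction("men", (40, 49)),
        subgroup_screen_fraction("men", (50, 74)),
        subgroup_screen_fraction("men", (75, 79)),
    ]


def _subgroup_bundle(bundle: ParameterBundle, spec: SubgroupSpec) -> ParameterBundle:
    d = bundle.to_dict()
    d["config"]["start_age"] = spec.age_low  # cohort still runs to end_age
    d["screening"]["S1"]["screened_fraction"] = spec.screened_fraction_base
    return ParameterBundle.from_dict(d)


def run_subgroups(bundle: ParameterBundle,
                  specs: list[SubgroupSpec] | None = None,
                  comparator: str = "S1") -> pd.DataFrame:
    """Pipeline per subgroup; same comparison schema as the base case with
    sex and age-band key columns prepended."""
    if specs is None:
        specs = default_subgroup_specs()
    rows = []
    for spec in specs:
        spec.validate()
        sub_bundle = _subgroup_bundle(bundle, spec)
        outcomes, comparisons = evaluate_bundle(sub_bundle, comparator, sex=spec.sex)
        for comp in comparisons:
            row = {
                "sex": spec.sex,
                "age_low": spec.age_low,
                "age_high": spec.age_high,
                "screened_fraction_s1": spec.screened_fraction_base,
                "intervention": comp.intervention,
                "comparator": comp.comparator,
                "mean_cost_intervention": outcomes[comp.intervention].mean_cost,
                "mean_qaly_intervention": outcomes[comp.intervention].mean_qaly,
                "delta_cost": comp.delta_cost,
                "delta_qaly": comp.delta_qaly,
                "icer": comp.icer.value,
                "dominance": comp.dominance.value,
            }
            for lam, value in comp.nmb_by_threshold.items():
                row[f"nmb_at_{int(lam)}"] = value
            rows.append(row)
    return pd.DataFrame(rows)
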