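"""Shared fixtures: the packaged reference bundles and helpers for
building degenerate model worlds (zero risk, zero mortality, flat
utilities) used by closed-form checks."""
from __future__ import annotations

import pytest
from hypothesis import settings

from fracture_cea import ParameterBundle, reference_bundle

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def mof_bundle() -> ParameterBundle:
    return reference_bundle("mof")


@pytest.fixture(scope="session")
def hf_bundle() -> ParameterBundle:
    return reference_bundle("hf")


def edit_bundle(bundle: ParameterBundle, **dotted) -> ParameterBundle:
    """Copy a bundle with dotted-path overrides, e.g.
    ``edit_bundle(b, **{"config.discount_rate": 0.0})``."""
    d = bundle.to_dict()
    for path, value in dotted.items():
        node = d
        tokens = path.split(".")
        for tok in tokens[:-1]:
            node = node[tok]
        node[tokens[-1]] = value
    return ParameterBundle.from_dict(d)


def full_health_bundle(bundle: ParameterBundle, discount_rate: float = 0.0
                       ) -> ParameterBundle:
    """No fracture risk, no mortality, utility 1 everywhere: the cohort
    accrues exactly one (discounted) QALY per person per cycle."""
    ages = range(bundle.config.start_age, bundle.config.end_age + 1)
    return edit_bundle(
        bundle,
        **{
            "config.discount_rate": discount_rate,
            "epidemiology.p10_fracture_by_state":
                {"osteoporosis": 0.0, "osteopenia": 0.0, "normal": 0.0},
            "epidemiology.refracture_annual": 0.0,
            "epidemiology.background_mortality": {str(a): 0.0 for a in ages},
            "utilities.baseline_utility_by_age": {str(a): 1.0 for a in ages},
            "utilities.fracture_year_multiplier": 1.0,
            "utilities.postfracture_multiplier": 1.0,
        },
    )
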