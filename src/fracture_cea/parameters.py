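"""Model inputs: domain types, risk-scale conversions, moment matching,
synthetic parameter generation and bundle (de)serialisation.

All model inputs travel together in a :class:`ParameterBundle` — cohort and
run configuration, per-strategy screening-test characteristics,
epidemiology (BMD prevalences, fracture and mortality probabilities,
treatment effects), unit costs and age-specific utilities — validated
against the invariants each component must satisfy.

Because the underlying study's parameter tables are not publicly deposited,
:func:`generate_parameter_set` produces a synthetic but field-realistic
parameter set: every value is plausible for a UK adult population with
intellectual disabilities, but none is taken from the study's supplement.
"""
from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ParameterError",
    "ModelConfig",
    "ScreeningProfile",
    "EpidemiologyParams",
    "CostParams",
    "UtilityParams",
    "ParameterBundle",
    "annualize_risk",
    "deannualize_risk",
    "extrapolate_lifetime_risk",
    "beta_from_mean_cv",
    "gamma_from_mean_cv",
    "generate_parameter_set",
    "central_parameter_set",
    "reference_bundle",
    "save_bundle",
    "load_bundle",
    "load_age_table_csv",
    "STRATEGY_IDS",
]

STRATEGY_IDS = ("S1", "S2", "S3")
FRACTURE_TYPES = ("MOF", "HF")
HORIZON_MODES = ("lifetime", "ten_year")
RISK_MODELS = ("constant_hazard", "lifetime_linear")
TOOLS = ("QFracture", "IDFracture", "DXA_direct")
BMD_CATEGORIES = ("osteoporosis", "osteopenia", "normal")
SEXES = ("men", "women", "all")


class ParameterError(ValueError):
    """Raised when a model input violates its invariants."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


def _prob(x: float, name: str) -> None:
    _require(0.0 <= x <= 1.0, f"{name} must be in [0, 1], got {x!r}")


# ---------------------------------------------------------------------------
# risk-scale conversions
# ---------------------------------------------------------------------------

def annualize_risk(p10: float) -> float:
    """Convert a 10-year probability to an annual probability under a
    constant hazard: 1 − (1 − p10)^(1/10)."""
    _require(0.0 <= p10 <= 1.0, f"10-year probability must be in [0, 1], got {p10!r}")
    return 1.0 - (1.0 - p10) ** 0.1


def deannualize_risk(p_annual: float, years: float = 10.0) -> float:
    """Inverse of :func:`annualize_risk`: compound an annual probability over
    ``years`` cycles."""
    _require(0.0 <= p_annual <= 1.0, f"annual probability must be in [0, 1], got {p_annual!r}")
    return 1.0 - (1.0 - p_annual) ** years


def extrapolate_lifetime_risk(p10: float, horizon_years: float) -> float:
    """Linearly scale a 10-year probability to ``horizon_years``, capped at 1."""
    _require(0.0 <= p10 <= 1.0, f"10-year probability must be in [0, 1], got {p10!r}")
    _require(horizon_years > 0, f"horizon must be positive, got {horizon_years!r}")
    return min(1.0, p10 * horizon_years / 10.0)


# ---------------------------------------------------------------------------
# moment-matched distribution parameterisation (for PSA)
# ---------------------------------------------------------------------------

def beta_from_mean_cv(mean: float, cv: float) -> tuple[float, float]:
    """Beta shape pair (α, β) with the requested mean and coefficient of
    variation.

    Matches first and second moments: with var = (cv·mean)² and
    k = mean(1−mean)/var − 1, α = mean·k and β = (1−mean)·k. The implied
    variance must be attainable by a beta (k > 0).
    """
    _require(0.0 < mean < 1.0, f"beta mean must be strictly inside (0, 1), got {mean!r}")
    _require(cv > 0.0, f"coefficient of variation must be positive, got {cv!r}")
    var = (cv * mean) ** 2
    k = mean * (1.0 - mean) / var - 1.0
    _require(
        k > 0.0,
        f"variance {var!r} too large for a beta with mean {mean!r} "
        f"(needs var < mean(1-mean))",
    )
    return mean * k, (1.0 - mean) * k


def gamma_from_mean_cv(mean: float, cv: float) -> tuple[float, float]:
    """Gamma (shape, scale) with the requested mean and coefficient of
    variation: shape = 1/cv², scale = mean·cv²."""
    _require(mean > 0.0, f"gamma mean must be positive, got {mean!r}")
    _require(cv > 0.0, f"coefficient of variation must be positive, got {cv!r}")
    shape = 1.0 / cv**2
    return shape, mean / shape


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Structural run configuration (never sampled in PSA)."""

    discount_rate: float = 0.035
    start_age: int = 40
    end_age: int = 100
    cycle_length: float = 1.0
    cohort_size: float = 1000.0
    fracture_type: str = "MOF"
    thresholds: list[float] = field(default_factory=lambda: [15000.0, 20000.0, 30000.0])
    horizon_mode: str = "lifetime"
    risk_model: str = "constant_hazard"

    def validate(self) -> None:
        _require(0.0 <= self.discount_rate < 1.0,
                 f"discount_rate must be in [0, 1), got {self.discount_rate!r}")
        _require(self.start_age < self.end_age,
                 f"start_age {self.start_age!r} must precede end_age {self.end_age!r}")
        _require(self.cycle_length == 1.0,
                 f"cycle_length is fixed at 1 year, got {self.cycle_length!r}")
        _require(self.cohort_size > 0, f"cohort_size must be positive, got {self.cohort_size!r}")
        _require(self.fracture_type in FRACTURE_TYPES,
                 f"fracture_type must be one of {FRACTURE_TYPES}, got {self.fracture_type!r}")
        _require(self.horizon_mode in HORIZON_MODES,
                 f"horizon_mode must be one of {HORIZON_MODES}, got {self.horizon_mode!r}")
        _require(self.risk_model in RISK_MODELS,
                 f"risk_model must be one of {RISK_MODELS}, got {self.risk_model!r}")
        _require(len(self.thresholds) > 0, "thresholds must be non-empty")
        _require(all(t > 0 for t in self.thresholds),
                 f"thresholds must be strictly positive, got {self.thresholds!r}")
        _require(all(a < b for a, b in zip(self.thresholds, self.thresholds[1:])),
                 f"thresholds must be strictly increasing, got {self.thresholds!r}")

    @property
    def horizon_cycles(self) -> int:
        """Number of annual cycles actually run."""
        if self.horizon_mode == "ten_year":
            return 10
        return self.end_age - self.start_age


@dataclass
class ScreeningProfile:
    """Risk-score characteristics for one assessment strategy.

    ``screened_fraction`` is the share of the cohort that receives the risk
    score at baseline (1.0 for universal strategies); ``sensitivity`` and
    ``specificity`` are measured against the true low-BMD condition
    (osteoporosis or osteopenia on a subsequent DXA).
    """

    screened_fraction: float
    sensitivity: float
    specificity: float
    tool: str

    def validate(self) -> None:
        _prob(self.screened_fraction, "screened_fraction")
        _prob(self.sensitivity, "sensitivity")
        _prob(self.specificity, "specificity")
        _require(self.tool in TOOLS, f"tool must be one of {TOOLS}, got {self.tool!r}")


@dataclass
class EpidemiologyParams:
    """Baseline BMD mix, fracture and mortality probabilities, and
    treatment effects."""

    prev_osteoporosis: float
    prev_osteopenia: float
    prev_normal: float
    frac_no_fracture: float
    p10_fracture_by_state: dict[str, float]
    refracture_annual: float
    rr_bisphosphonate: float
    rr_vitd_calcium: float
    adherence_annual: float
    background_mortality: dict[int, float]
    fracture_mortality_multiplier: float
    postfracture_mortality_multiplier: float
    sex_fracture_multiplier: dict[str, float] = field(
        default_factory=lambda: {"men": 1.0, "women": 1.0, "all": 1.0})
    sex_mortality_multiplier: dict[str, float] = field(
        default_factory=lambda: {"men": 1.0, "women": 1.0, "all": 1.0})

    def validate(self, start_age: int = 40, end_age: int = 100) -> None:
        for name in ("prev_osteoporosis", "prev_osteopenia", "prev_normal",
                     "frac_no_fracture", "refracture_annual", "adherence_annual"):
            _prob(getattr(self, name), name)
        total = self.prev_osteoporosis + self.prev_osteopenia + self.prev_normal
        _require(abs(total - 1.0) <= 1e-9,
                 f"BMD prevalences must sum to 1, got {total!r}")
        _require(set(self.p10_fracture_by_state) == set(BMD_CATEGORIES),
                 f"p10_fracture_by_state must have keys {BMD_CATEGORIES}, "
                 f"got {sorted(self.p10_fracture_by_state)!r}")
        for cat, p in self.p10_fracture_by_state.items():
            _prob(p, f"p10_fracture_by_state[{cat}]")
        for name in ("rr_bisphosphonate", "rr_vitd_calcium"):
            rr = getattr(self, name)
            _require(0.0 < rr <= 1.0, f"{name} must be in (0, 1], got {rr!r}")
        for age in range(start_age, end_age + 1):
            if age not in self.background_mortality:
                raise ParameterError(
                    f"background_mortality is missing age {age}")
            _prob(self.background_mortality[age], f"background_mortality[{age}]")
        _require(self.fracture_mortality_multiplier >= 1.0,
                 "fracture_mortality_multiplier must be >= 1")
        _require(self.postfracture_mortality_multiplier >= 1.0,
                 "postfracture_mortality_multiplier must be >= 1")
        for table_name in ("sex_fracture_multiplier", "sex_mortality_multiplier"):
            table = getattr(self, table_name)
            for sex in ("men", "women"):
                _require(sex in table, f"{table_name} missing entry for {sex!r}")
                _require(table[sex] > 0, f"{table_name}[{sex}] must be positive")

    def mortality_at(self, age: int) -> float:
        try:
            return self.background_mortality[age]
        except KeyError:
            raise ParameterError(f"background_mortality is missing age {age}") from None


@dataclass
class CostParams:
    """Unit costs (GBP, 2021/22 prices)."""

    cost_risk_score: float
    cost_dxa: float
    cost_treat_osteoporosis_annual: float
    cost_treat_osteopenia_annual: float
    cost_fracture_year1: float
    cost_postfracture_annual: float

    def validate(self) -> None:
        for name, value in asdict(self).items():
            _require(value >= 0.0, f"{name} must be non-negative, got {value!r}")


@dataclass
class UtilityParams:
    """EQ-5D-style utilities: an age-specific fracture-free baseline with
    multiplicative decrements during the fracture year and thereafter."""

    baseline_utility_by_age: dict[int, float]
    fracture_year_multiplier: float
    postfracture_multiplier: float

    def validate(self, start_age: int = 40, end_age: int = 100) -> None:
        for age in range(start_age, end_age + 1):
            if age not in self.baseline_utility_by_age:
                raise ParameterError(f"baseline_utility_by_age is missing age {age}")
            _prob(self.baseline_utility_by_age[age], f"baseline_utility_by_age[{age}]")
        _prob(self.fracture_year_multiplier, "fracture_year_multiplier")
        _prob(self.postfracture_multiplier, "postfracture_multiplier")

    def utility_at(self, age: int) -> float:
        try:
            return self.baseline_utility_by_age[age]
        except KeyError:
            raise ParameterError(f"baseline_utility_by_age is missing age {age}") from None


@dataclass
class ParameterBundle:
    """Every input the pipeline needs, as one validated object."""

    config: ModelConfig
    screening: dict[str, ScreeningProfile]
    epidemiology: EpidemiologyParams
    costs: CostParams
    utilities: UtilityParams
    uncertainty: dict[str, float] = field(
        default_factory=lambda: {"probabilities": 0.2, "utilities": 0.2, "costs": 0.2})

    def validate(self) -> "ParameterBundle":
        self.config.validate()
        _require(set(self.screening) == set(STRATEGY_IDS),
                 f"screening must define exactly strategies {STRATEGY_IDS}, "
                 f"got {sorted(self.screening)!r}")
        for profile in self.screening.values():
            profile.validate()
        self.epidemiology.validate(self.config.start_age, self.config.end_age)
        self.costs.validate()
        self.utilities.validate(self.config.start_age, self.config.end_age)
        for group in ("probabilities", "utilities", "costs"):
            _require(group in self.uncertainty, f"uncertainty missing group {group!r}")
            _require(self.uncertainty[group] > 0,
                     f"uncertainty[{group}] must be positive")
        return self

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "config": asdict(self.config),
            "screening": {k: asdict(v) for k, v in self.screening.items()},
            "epidemiology": asdict(self.epidemiology),
            "costs": asdict(self.costs),
            "utilities": asdict(self.utilities),
            "uncertainty": dict(self.uncertainty),
        }
        # JSON object keys are strings; age tables converted on load
        d["epidemiology"]["background_mortality"] = {
            str(a): v for a, v in self.epidemiology.background_mortality.items()}
        d["utilities"]["baseline_utility_by_age"] = {
            str(a): v for a, v in self.utilities.baseline_utility_by_age.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterBundle":
        try:
            config = ModelConfig(**d["config"])
            screening = {k: ScreeningProfile(**v) for k, v in d["screening"].items()}
            epi_raw = dict(d["epidemiology"])
            epi_raw["background_mortality"] = {
                int(a): float(v) for a, v in epi_raw["background_mortality"].items()}
            epidemiology = EpidemiologyParams(**epi_raw)
            costs = CostParams(**d["costs"])
            util_raw = dict(d["utilities"])
            util_raw["baseline_utility_by_age"] = {
                int(a): float(v) for a, v in util_raw["baseline_utility_by_age"].items()}
            utilities = UtilityParams(**util_raw)
            uncertainty = dict(d.get("uncertainty", {}))
        except KeyError as e:
            raise ParameterError(f"bundle is missing field {e.args[0]!r}") from None
        except TypeError as e:
            raise ParameterError(f"malformed bundle: {e}") from None
        bundle = cls(config=config, screening=screening, epidemiology=epidemiology,
                     costs=costs, utilities=utilities, uncertainty=uncertainty)
        return bundle.validate()

    def copy(self) -> "ParameterBundle":
        return copy.deepcopy(self)


def save_bundle(bundle: ParameterBundle, path: str | Path) -> None:
    """Write a bundle to JSON (floats round-trip exactly)."""
    bundle.validate()
    Path(path).write_text(json.dumps(bundle.to_dict(), indent=1) + "\n")


def load_bundle(path: str | Path) -> ParameterBundle:
    """Read and validate a bundle from JSON."""
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ParameterError(f"cannot parse bundle file {path}: {e}") from None
    return ParameterBundle.from_dict(raw)


def load_age_table_csv(path: str | Path) -> dict[int, float]:
    """Import a 2-column (age, value) CSV as an age table."""
    frame = pd.read_csv(path, float_precision="round_trip")
    if frame.shape[1] != 2:
        raise ParameterError(f"age table {path} must have exactly 2 columns (age, value)")
    ages, values = frame.iloc[:, 0], frame.iloc[:, 1]
    return {int(a): float(v) for a, v in zip(ages, values)}


# ---------------------------------------------------------------------------
# synthetic parameter generation
# ---------------------------------------------------------------------------

# Central values: field-realistic for a UK NHS analysis of adults with
# intellectual disabilities, anchored where the study design fixes them
# (cohort 1000, ages 40-100, 3.5% discounting, S1 screened fraction 3%).
# The fracture-specific blocks differ between major osteoporotic fracture
# (MOF: common, moderate unit cost) and hip fracture (HF: rarer, costlier,
# deadlier).
_CENTRAL_COMMON = {
    "prev_osteoporosis": 0.20,
    "prev_osteopenia": 0.40,
    "prev_normal": 0.40,
    "frac_no_fracture": 0.50,
    "rr_bisphosphonate": 0.60,   # alendronate vs no treatment
    "rr_vitd_calcium": 0.90,     # vitamin D + calcium vs no treatment
    "adherence_annual": 0.80,
    "mortality_anchor_40": 0.005,
    "mortality_anchor_100": 0.45,
    "utility_at_40": 0.88,
    "utility_slope_per_year": 0.002,
    "cost_risk_score": 5.0,
    "cost_dxa": 80.0,
    "cost_treat_osteoporosis_annual": 65.0,
    "cost_treat_osteopenia_annual": 45.0,
    "sex_fracture_multiplier": {"men": 0.75, "women": 1.25, "all": 1.0},
    "sex_mortality_multiplier": {"men": 1.15, "women": 0.90, "all": 1.0},
}

_CENTRAL_BY_FRACTURE = {
    "MOF": {
        "p10_fracture_by_state": {"osteoporosis": 0.25, "osteopenia": 0.15, "normal": 0.08},
        "refracture_annual": 0.06,
        "fracture_mortality_multiplier": 1.8,
        "postfracture_mortality_multiplier": 1.3,
        "cost_fracture_year1": 4500.0,
        "cost_postfracture_annual": 1200.0,
        "fracture_year_multiplier": 0.82,
        "postfracture_multiplier": 0.92,
    },
    "HF": {
        "p10_fracture_by_state": {"osteoporosis": 0.10, "osteopenia": 0.05, "normal": 0.02},
        "refracture_annual": 0.04,
        "fracture_mortality_multiplier": 3.0,
        "postfracture_mortality_multiplier": 1.8,
        "cost_fracture_year1": 14000.0,
        "cost_postfracture_annual": 3500.0,
        "fracture_year_multiplier": 0.70,
        "postfracture_multiplier": 0.80,
    },
}

_CENTRAL_SCREENING = {
    "S1": {"screened_fraction": 0.03, "sensitivity": 0.65, "specificity": 0.82,
           "tool": "QFracture"},
    "S2": {"screened_fraction": 1.00, "sensitivity": 0.78, "specificity": 0.85,
           "tool": "IDFracture"},
    "S3": {"screened_fraction": 1.00, "sensitivity": 1.00, "specificity": 1.00,
           "tool": "DXA_direct"},
}

_SCENARIOS = {None: "MOF", "base": "MOF", "mof": "MOF", "hf": "HF"}


def _gompertz_mortality(m40: float, m100: float,
                        start: int = 40, end: int = 100) -> dict[int, float]:
    """Log-linear (Gompertz-like) annual death probability through the two
    anchors; strictly increasing in age."""
    b = math.log(m100 / m40) / (end - start)
    a = math.log(m40) - b * start
    return {age: math.exp(a + b * age) for age in range(start, end + 1)}


def _assemble_bundle(vals: dict, screening: dict, fracture_type: str) -> ParameterBundle:
    mortality = _gompertz_mortality(vals["mortality_anchor_40"], vals["mortality_anchor_100"])
    utilities = {age: min(1.0, max(0.0, vals["utility_at_40"]
                                   - vals["utility_slope_per_year"] * (age - 40)))
                 for age in range(40, 101)}
    return ParameterBundle(
        config=ModelConfig(fracture_type=fracture_type),
        screening={k: ScreeningProfile(**v) for k, v in screening.items()},
        epidemiology=EpidemiologyParams(
            prev_osteoporosis=vals["prev_osteoporosis"],
            prev_osteopenia=vals["prev_osteopenia"],
            prev_normal=vals["prev_normal"],
            frac_no_fracture=vals["frac_no_fracture"],
            p10_fracture_by_state=dict(vals["p10_fracture_by_state"]),
            refracture_annual=vals["refracture_annual"],
            rr_bisphosphonate=vals["rr_bisphosphonate"],
            rr_vitd_calcium=vals["rr_vitd_calcium"],
            adherence_annual=vals["adherence_annual"],
            background_mortality=mortality,
            fracture_mortality_multiplier=vals["fracture_mortality_multiplier"],
            postfracture_mortality_multiplier=vals["postfracture_mortality_multiplier"],
            sex_fracture_multiplier=dict(vals["sex_fracture_multiplier"]),
            sex_mortality_multiplier=dict(vals["sex_mortality_multiplier"]),
        ),
        costs=CostParams(
            cost_risk_score=vals["cost_risk_score"],
            cost_dxa=vals["cost_dxa"],
            cost_treat_osteoporosis_annual=vals["cost_treat_osteoporosis_annual"],
            cost_treat_osteopenia_annual=vals["cost_treat_osteopenia_annual"],
            cost_fracture_year1=vals["cost_fracture_year1"],
            cost_postfracture_annual=vals["cost_postfracture_annual"],
        ),
        utilities=UtilityParams(
            baseline_utility_by_age=utilities,
            fracture_year_multiplier=vals["fracture_year_multiplier"],
            postfracture_multiplier=vals["postfracture_multiplier"],
        ),
    ).validate()


def _resolve_scenario(scenario: str | None) -> str:
    key = scenario.lower() if isinstance(scenario, str) else scenario
    if key not in _SCENARIOS:
        raise ParameterError(
            f"unknown scenario {scenario!r}; expected one of "
            f"{sorted(k for k in _SCENARIOS if k)!r} or None")
    return _SCENARIOS[key]


def central_parameter_set(scenario: str | None = None) -> ParameterBundle:
    """The unjittered synthetic parameter set (the package's base case)."""
    fracture_type = _resolve_scenario(scenario)
    vals = {**_CENTRAL_COMMON, **_CENTRAL_BY_FRACTURE[fracture_type]}
    return _assemble_bundle(vals, _CENTRAL_SCREENING, fracture_type)


def generate_parameter_set(seed: int, scenario: str | None = None) -> ParameterBundle:
    """A complete, invariant-satisfying bundle with seed-determined jitter.

    Epidemiological, cost and utility parameters are perturbed by up to
    ±10% around the central values (structural configuration — discounting,
    ages, cohort size — stays fixed), giving a family of plausible model
    worlds for property testing and robustness checks. The same seed always
    yields the same bundle.
    """
    fracture_type = _resolve_scenario(scenario)
    rng = np.random.default_rng(seed)
    central = {**_CENTRAL_COMMON, **_CENTRAL_BY_FRACTURE[fracture_type]}
    vals = dict(central)

    def jit(x: float, lo: float = 0.0, hi: float = 1.0) -> float:
        return float(np.clip(x * rng.uniform(0.9, 1.1), lo, hi))

    prevs = np.array([central["prev_osteoporosis"], central["prev_osteopenia"],
                      central["prev_normal"]])
    prevs = prevs * rng.uniform(0.9, 1.1, size=3)
    prevs = prevs / prevs.sum()
    vals["prev_osteoporosis"], vals["prev_osteopenia"], vals["prev_normal"] = map(float, prevs)

    vals["frac_no_fracture"] = jit(central["frac_no_fracture"])
    vals["p10_fracture_by_state"] = {
        cat: jit(p) for cat, p in central["p10_fracture_by_state"].items()}
    vals["refracture_annual"] = jit(central["refracture_annual"])
    vals["rr_bisphosphonate"] = jit(central["rr_bisphosphonate"], lo=1e-6)
    vals["rr_vitd_calcium"] = jit(central["rr_vitd_calcium"], lo=1e-6)
    vals["adherence_annual"] = jit(central["adherence_annual"])
    vals["mortality_anchor_40"] = jit(central["mortality_anchor_40"], lo=1e-6, hi=0.5)
    vals["mortality_anchor_100"] = jit(central["mortality_anchor_100"], lo=0.1, hi=0.99)
    vals["utility_at_40"] = jit(central["utility_at_40"], lo=0.5, hi=0.99)
    vals["utility_slope_per_year"] = jit(central["utility_slope_per_year"], hi=0.01)
    vals["fracture_mortality_multiplier"] = max(
        1.0, central["fracture_mortality_multiplier"] * rng.uniform(0.9, 1.1))
    vals["postfracture_mortality_multiplier"] = max(
        1.0, central["postfracture_mortality_multiplier"] * rng.uniform(0.9, 1.1))
    for name in ("cost_risk_score", "cost_dxa", "cost_treat_osteoporosis_annual",
                 "cost_treat_osteopenia_annual", "cost_fracture_year1",
                 "cost_postfracture_annual"):
        vals[name] = float(central[name] * rng.uniform(0.9, 1.1))
    vals["fracture_year_multiplier"] = jit(central["fracture_year_multiplier"])
    vals["postfracture_multiplier"] = jit(central["postfracture_multiplier"])

    screening = copy.deepcopy(_CENTRAL_SCREENING)
    screening["S1"]["screened_fraction"] = float(
        np.clip(0.03 * rng.uniform(0.9, 1.1), 0.01, 0.05))
    for sid in ("S1", "S2"):
        screening[sid]["sensitivity"] = float(
            np.clip(screening[sid]["sensitivity"] * rng.uniform(0.9, 1.1), 0.0, 0.999))
        screening[sid]["specificity"] = float(
            np.clip(screening[sid]["specificity"] * rng.uniform(0.9, 1.1), 0.0, 0.999))

    return _assemble_bundle(vals, screening, fracture_type)


def reference_bundle(scenario: str | None = None) -> ParameterBundle:
    """The version-pinned reference bundle shipped with the package
    (synthetic; used by golden tests and the analysis scripts)."""
    from importlib.resources import files

    fracture_type = _resolve_scenario(scenario)
    name = f"reference_bundle_{fracture_type.lower()}.json"
    raw = json.loads(files("fracture_cea.data").joinpath(name).read_text())
    return ParameterBundle.from_dict(raw)
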