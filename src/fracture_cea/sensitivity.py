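"""Deterministic scenario analysis, probabilistic sensitivity analysis and
cost-effectiveness acceptability curves.

Deterministic scenarios change exactly one parameter path of the bundle
(set or multiply) and rerun the whole pipeline. The PSA resamples every
probability and utility from a moment-matched beta, every cost from a
moment-matched gamma (prevalences jointly from a Dirichlet so they keep
summing to one), leaves structural settings untouched, and summarises the
resulting cloud of incremental cost/QALY points as CEAC curves: the share
of draws with positive incremental net monetary benefit at each
willingness-to-pay value. Ties (NMB exactly zero) count as not
cost-effective.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import PairwiseComparison, compare_strategies, nmb
from .markov import StrategyOutcome, run_strategy
from .parameters import (
    ParameterBundle,
    ParameterError,
    beta_from_mean_cv,
)

__all__ = [
    "ScenarioSpec",
    "PSAResult",
    "evaluate_bundle",
    "apply_scenario",
    "builtin_scenario_grid",
    "run_dsa",
    "draw_psa_bundle",
    "run_psa",
    "compute_ceac",
    "plot_ce_plane",
    "plot_ceac",
]

DEFAULT_LAMBDA_GRID = np.arange(0.0, 50001.0, 2500.0)


def evaluate_bundle(bundle: ParameterBundle, comparator: str = "S1",
                    sex: str = "all") -> tuple[dict[str, StrategyOutcome],
                                               list[PairwiseComparison]]:
    """Full pipeline on one bundle: decision tree → Markov → economics."""
    outcomes = {sid: run_strategy(sid, bundle, sex=sex)[1]
                for sid in sorted(bundle.screening)}
    comparisons = compare_strategies(outcomes, comparator, bundle.config.thresholds)
    return outcomes, comparisons


# ---------------------------------------------------------------------------
# deterministic scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioSpec:
    """One single-parameter modification: ``path`` is a dotted route into
    the bundle's serialised form (e.g. ``costs.cost_dxa``,
    ``screening.S2.sensitivity``, ``config.horizon_mode``)."""

    label: str
    path: str
    modifier: str  # "set_value" | "multiply"
    operand: object


def apply_scenario(bundle: ParameterBundle, scenario: ScenarioSpec) -> ParameterBundle:
    """Return a copy of the bundle with exactly one parameter changed; the
    modified bundle is revalidated, so out-of-range modifications fail."""
    if scenario.modifier not in ("set_value", "multiply"):
        raise ParameterError(f"unknown modifier {scenario.modifier!r}")
    d = bundle.to_dict()
    tokens = scenario.path.split(".")
    node = d
    for tok in tokens[:-1]:
        if not isinstance(node, dict) or tok not in node:
            raise ParameterError(f"unknown parameter path {scenario.path!r}")
        node = node[tok]
    leaf = tokens[-1]
    if not isinstance(node, dict) or leaf not in node:
        raise ParameterError(f"unknown parameter path {scenario.path!r}")
    if scenario.modifier == "set_value":
        node[leaf] = scenario.operand
    else:
        if not isinstance(node[leaf], (int, float)):
            raise ParameterError(
                f"cannot multiply non-numeric parameter {scenario.path!r}")
        node[leaf] = node[leaf] * scenario.operand
    return ParameterBundle.from_dict(d)


def builtin_scenario_grid(bundle: ParameterBundle) -> list[ScenarioSpec]:
    """The standard one-way scenario set: treatment adherence and risk-tool
    accuracy varied from 20% below base up to (near-)perfect, every unit
    cost halved and doubled, the current-practice screened fraction at its
    1%/5% bounds, a 10-year horizon, and lifetime-linear fracture risk."""
    grid: list[ScenarioSpec] = [
        ScenarioSpec("adherence_minus20pct", "epidemiology.adherence_annual",
                     "multiply", 0.8),
        ScenarioSpec("adherence_100pct", "epidemiology.adherence_annual",
                     "set_value", 1.0),
        ScenarioSpec("qfracture_sensitivity_minus20pct", "screening.S1.sensitivity",
                     "multiply", 0.8),
        ScenarioSpec("qfracture_sensitivity_100pct", "screening.S1.sensitivity",
                     "set_value", 1.0),
        ScenarioSpec("qfracture_specificity_minus20pct", "screening.S1.specificity",
                     "multiply", 0.8),
        ScenarioSpec("qfracture_specificity_100pct", "screening.S1.specificity",
                     "set_value", 1.0),
        ScenarioSpec("idfracture_sensitivity_minus20pct", "screening.S2.sensitivity",
                     "multiply", 0.8),
        ScenarioSpec("idfracture_sensitivity_99_9pct", "screening.S2.sensitivity",
                     "set_value", 0.999),
        ScenarioSpec("idfracture_specificity_minus20pct", "screening.S2.specificity",
                     "multiply", 0.8),
        ScenarioSpec("idfracture_specificity_100pct", "screening.S2.specificity",
                     "set_value", 1.0),
        ScenarioSpec("s1_screened_fraction_1pct", "screening.S1.screened_fraction",
                     "set_value", 0.01),
        ScenarioSpec("s1_screened_fraction_5pct", "screening.S1.screened_fraction",
                     "set_value", 0.05),
        ScenarioSpec("ten_year_horizon", "config.horizon_mode", "set_value", "ten_year"),
        ScenarioSpec("lifetime_linear_risk", "config.risk_model", "set_value",
                     "lifetime_linear"),
    ]
    cost_fields = ("cost_risk_score", "cost_dxa", "cost_treat_osteoporosis_annual",
                   "cost_treat_osteopenia_annual", "cost_fracture_year1",
                   "cost_postfracture_annual")
    for name in cost_fields:
        grid.append(ScenarioSpec(f"{name}_halved", f"costs.{name}", "multiply", 0.5))
        grid.append(ScenarioSpec(f"{name}_doubled", f"costs.{name}", "multiply", 2.0))
    return grid


def run_dsa(bundle: ParameterBundle, scenarios: list[ScenarioSpec] | None = None,
            comparator: str = "S1") -> pd.DataFrame:
    """One row per scenario per pairwise comparison."""
    if scenarios is None:
        scenarios = builtin_scenario_grid(bundle)
    if not scenarios:
        raise ParameterError("scenario list must be non-empty")
    rows = []
    for spec in scenarios:
        modified = apply_scenario(bundle, spec)
        _, comparisons = evaluate_bundle(modified, comparator)
        for comp in comparisons:
            row = {
                "scenario": spec.label,
                "intervention": comp.intervention,
                "comparator": comp.comparator,
                "delta_cost": comp.delta_cost,
                "delta_qaly": comp.delta_qaly,
                "icer": comp.icer.value,
                "dominance": comp.dominance.value,
            }
            for lam, value in comp.nmb_by_threshold.items():
                row[f"nmb_at_{int(lam)}"] = value
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _beta_draw(rng: np.random.Generator, mean: float, cv: float, name: str) -> float:
    """Moment-matched beta draw; boundary means (0 or 1) carry no sampling
    uncertainty and are returned unchanged."""
    if mean <= 0.0 or mean >= 1.0:
        return mean
    try:
        a, b = beta_from_mean_cv(mean, cv)
    except ParameterError as e:
        raise ParameterError(f"cannot moment-match beta for {name}: {e}") from None
    return float(rng.beta(a, b))


def _gamma_draw(rng: np.random.Generator, mean: float, cv: float, name: str) -> float:
    if mean <= 0.0:
        return mean
    shape = 1.0 / cv**2
    return float(rng.gamma(shape, mean / shape))


def _dirichlet_prevalences(rng: np.random.Generator, prevs: np.ndarray,
                           cv: float) -> np.ndarray:
    """Joint prevalence draw preserving the sum-to-one invariant; the
    concentration is moment-matched so the first component's coefficient of
    variation equals the requested one."""
    p = prevs[0]
    var = (cv * p) ** 2
    k = p * (1.0 - p) / var - 1.0
    if k <= 0:
        raise ParameterError("prevalence uncertainty too large for a Dirichlet")
    return rng.dirichlet(prevs * k)


def draw_psa_bundle(bundle: ParameterBundle, seed) -> ParameterBundle:
    """One PSA draw: probabilities and utilities from moment-matched betas,
    costs from moment-matched gammas, prevalences from a Dirichlet;
    structural configuration (discounting, ages, cohort size, horizon) is
    never sampled. ``seed`` may be an integer or a shared Generator."""
    rng = _as_rng(seed)
    cv_p = bundle.uncertainty["probabilities"]
    cv_u = bundle.uncertainty["utilities"]
    cv_c = bundle.uncertainty["costs"]
    d = bundle.to_dict()

    epi = d["epidemiology"]
    prevs = np.array([epi["prev_osteoporosis"], epi["prev_osteopenia"],
                      epi["prev_normal"]])
    prevs = _dirichlet_prevalences(rng, prevs, cv_p)
    epi["prev_osteoporosis"], epi["prev_osteopenia"], epi["prev_normal"] = map(float, prevs)
    for name in ("frac_no_fracture", "refracture_annual", "rr_bisphosphonate",
                 "rr_vitd_calcium", "adherence_annual"):
        epi[name] = _beta_draw(rng, epi[name], cv_p, f"epidemiology.{name}")
    for cat in sorted(epi["p10_fracture_by_state"]):
        epi["p10_fracture_by_state"][cat] = _beta_draw(
            rng, epi["p10_fracture_by_state"][cat], cv_p,
            f"epidemiology.p10_fracture_by_state.{cat}")
    for age in sorted(epi["background_mortality"], key=int):
        epi["background_mortality"][age] = _beta_draw(
            rng, epi["background_mortality"][age], cv_p,
            f"epidemiology.background_mortality.{age}")

    for sid in sorted(d["screening"]):
        prof = d["screening"][sid]
        for name in ("screened_fraction", "sensitivity", "specificity"):
            prof[name] = _beta_draw(rng, prof[name], cv_p, f"screening.{sid}.{name}")

    for name in sorted(d["costs"]):
        d["costs"][name] = _gamma_draw(rng, d["costs"][name], cv_c, f"costs.{name}")

    util = d["utilities"]
    for age in sorted(util["baseline_utility_by_age"], key=int):
        util["baseline_utility_by_age"][age] = _beta_draw(
            rng, util["baseline_utility_by_age"][age], cv_u,
            f"utilities.baseline_utility_by_age.{age}")
    for name in ("fracture_year_multiplier", "postfracture_multiplier"):
        util[name] = _beta_draw(rng, util[name], cv_u, f"utilities.{name}")

    return ParameterBundle.from_dict(d)


@dataclass
class PSAResult:
    """Per-draw cost-effectiveness-plane points and derived CEAC curves.

    ``points[comp]`` is an (n_draws, 2) array of (ΔC, ΔE) for the
    comparison labelled ``"S2_vs_S1"`` etc.
    """

    points: dict[str, np.ndarray]
    n_draws: int
    seed: int
    lambdas: np.ndarray
    ceac: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for comp, pts in self.points.items():
            for i, (dc, de) in enumerate(pts):
                rows.append({"comparison": comp, "draw": i,
                             "delta_cost": dc, "delta_qaly": de})
        return pd.DataFrame(rows)

    def ceac_frame(self) -> pd.DataFrame:
        rows = []
        for comp, probs in self.ceac.items():
            for lam, p in zip(self.lambdas, probs):
                rows.append({"comparison": comp, "threshold": lam,
                             "prob_cost_effective": p})
        return pd.DataFrame(rows)


def compute_ceac(points: dict[str, np.ndarray], lambdas) -> dict[str, np.ndarray]:
    """CEAC(λ) = fraction of draws with λ·ΔE − ΔC strictly positive."""
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 0:
        raise ParameterError("lambda grid must be non-empty")
    if not points or any(len(p) == 0 for p in points.values()):
        raise ParameterError("point set must be non-empty")
    out = {}
    for comp, pts in points.items():
        pts = np.asarray(pts, dtype=float)
        dc, de = pts[:, 0], pts[:, 1]
        nmb_matrix = lambdas[:, None] * de[None, :] - dc[None, :]
        out[comp] = (nmb_matrix > 0).mean(axis=1)
    return out


def run_psa(bundle: ParameterBundle, n_draws: int = 1000, seed: int = 0,
            comparator: str = "S1", lambdas=None) -> PSAResult:
    """Full-pipeline PSA: each draw resamples the bundle (screening
    parameters included, so the decision tree reruns) and records the
    incremental (ΔC, ΔE) point for every comparison."""
    if n_draws < 1:
        raise ParameterError("n_draws must be at least 1")
    lambdas = DEFAULT_LAMBDA_GRID if lambdas is None else np.asarray(lambdas, float)
    rng = np.random.default_rng(seed)
    collected: dict[str, list[tuple[float, float]]] = {}
    for _ in range(n_draws):
        sampled = draw_psa_bundle(bundle, rng)
        _, comparisons = evaluate_bundle(sampled, comparator)
        for comp in comparisons:
            key = f"{comp.intervention}_vs_{comp.comparator}"
            collected.setdefault(key, []).append((comp.delta_cost, comp.delta_qaly))
    points = {k: np.array(v) for k, v in collected.items()}
    return PSAResult(points=points, n_draws=n_draws, seed=seed, lambdas=lambdas,
                     ceac=compute_ceac(points, lambdas))


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

def plot_ce_plane(result: PSAResult, thresholds: list[float], path) -> None:
    """Scatter of PSA draws on the cost-effectiveness plane with
    willingness-to-pay rays through the origin."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for comp, pts in result.points.items():
        ax.scatter(pts[:, 1], pts[:, 0], s=6, alpha=0.4, label=comp)
    de_span = max(abs(pts[:, 1]).max() for pts in result.points.values())
    xs = np.linspace(-de_span, de_span, 50)
    for lam in thresholds:
        ax.plot(xs, lam * xs, lw=0.8, ls="--", color="grey")
        ax.annotate(f"£{lam:,.0f}/QALY", (xs[-1], lam * xs[-1]), fontsize=7)
    ax.axhline(0, color="black", lw=0.6)
    ax.axvline(0, color="black", lw=0.6)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (GBP, 2021/22)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(result: PSAResult, path) -> None:
    """Cost-effectiveness acceptability curve per comparison."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for comp, probs in result.ceac.items():
        ax.plot(result.lambdas, probs, marker="o", ms=3, label=comp)
    ax.axhline(0.5, color="grey", lw=0.6, ls="--")
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("Willingness-to-pay threshold (GBP/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# re-export for convenience in scenario sanity checks
__all__.append("nmb")
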