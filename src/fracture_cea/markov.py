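"""Nine-state annual-cycle Markov cohort engine.

Propagates the post-screening state distribution one year at a time from
the starting age to age 100 (or over a 10-year horizon), accruing costs
and quality-adjusted life years from start-of-cycle occupancy with no
half-cycle correction, and discounting both streams at the configured
annual rate. Competing risks within a cycle are resolved death-first:
death claims its probability m(age) first and fracture applies to the
survivors, so each row is stochastic without renormalisation.

Also provides an individual-level microsimulation that replays the same
transition rows person by person — the Monte-Carlo oracle the cohort
expectation is validated against.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decision_tree import initial_state_distribution
from .parameters import (
    ParameterBundle,
    ParameterError,
    annualize_risk,
    extrapolate_lifetime_risk,
)
from .states import (
    DEAD,
    FRACTURE,
    NORMAL,
    NO_FRACTURE,
    N_STATES,
    POST_FRACTURE,
    STATES,
    TREATED_OP,
    TREATED_PE,
    UNTREATED_OP,
    UNTREATED_PE,
    StateDistribution,
)

__all__ = [
    "TransitionMatrix",
    "MarkovTrace",
    "StrategyOutcome",
    "MicrosimEstimate",
    "annual_fracture_probs",
    "build_transition_matrix",
    "discount_factor",
    "run_cohort",
    "trace_totals",
    "run_strategy",
    "microsim_oracle",
    "cycle1_report",
]

TransitionMatrix = np.ndarray  # 9x9, row-stochastic


@dataclass
class StrategyOutcome:
    """Per-person discounted totals for one strategy run."""

    mean_cost: float
    mean_qaly: float


@dataclass
class MicrosimEstimate:
    """Microsimulation means with Monte-Carlo standard errors."""

    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float


@dataclass
class MarkovTrace:
    """Per-cycle occupancy and cost/QALY streams for one strategy.

    ``occupancy[k]`` is the start-of-cycle distribution from which cycle
    ``k`` accrues; ``occupancy[-1]`` is the final distribution after the
    last transition.
    """

    ages: np.ndarray                 # length H
    occupancy: np.ndarray            # (H+1, 9) persons
    cycle_cost: np.ndarray           # length H, undiscounted, whole cohort
    cycle_qaly: np.ndarray
    disc_cost: np.ndarray
    disc_qaly: np.ndarray
    cohort_size: float
    upfront_cost: float

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cycle, per-state export."""
        rows = []
        for k, age in enumerate(self.ages):
            for s, name in enumerate(STATES):
                rows.append({
                    "cycle": k, "age": int(age), "state": name,
                    "occupancy": self.occupancy[k, s],
                    "cycle_cost": self.cycle_cost[k],
                    "cycle_qaly": self.cycle_qaly[k],
                    "disc_cost": self.disc_cost[k],
                    "disc_qaly": self.disc_qaly[k],
                })
        return pd.DataFrame(rows)


def discount_factor(rate: float, cycle_index: int) -> float:
    """(1 + rate)^(−k); cycle 0 is undiscounted."""
    if rate < 0:
        raise ParameterError(f"discount rate must be non-negative, got {rate!r}")
    if cycle_index < 0:
        raise ParameterError(f"cycle index must be non-negative, got {cycle_index!r}")
    return (1.0 + rate) ** (-cycle_index)


def annual_fracture_probs(bundle: ParameterBundle, sex: str = "all") -> dict[str, float]:
    """Annual fracture probability per BMD category, before treatment effect.

    Under the constant-hazard model the 10-year probability is annualised
    as 1 − (1 − p10)^(1/10); under the lifetime-linear model the 10-year
    probability is first extrapolated linearly to the full modelled horizon
    H (capped at 1) and spread evenly, annual p = min(1, p10·H/10)/H.
    """
    cfg, epi = bundle.config, bundle.epidemiology
    mult = epi.sex_fracture_multiplier.get(sex, 1.0)
    out = {}
    for cat, p10 in epi.p10_fracture_by_state.items():
        p10_adj = min(1.0, p10 * mult)
        if cfg.risk_model == "lifetime_linear":
            horizon = cfg.end_age - cfg.start_age
            out[cat] = extrapolate_lifetime_risk(p10_adj, horizon) / horizon
        else:
            out[cat] = annualize_risk(p10_adj)
    return out


def _capped(p: float, what: str) -> float:
    if p > 1.0:
        warnings.warn(f"{what} exceeded 1 after multipliers; capped", RuntimeWarning,
                      stacklevel=3)
        return 1.0
    return p


def build_transition_matrix(age: int, bundle: ParameterBundle,
                            sex: str = "all") -> TransitionMatrix:
    """One-cycle transition matrix at a given age.

    Death is resolved first (probability m, state-specific multipliers for
    the fracture year and thereafter); fracture applies to survivors with
    the annualised category risk, scaled by the treatment relative risk in
    treated states; non-adherent treated survivors without a fracture move
    permanently to the matching untreated state. The fracture state is a
    one-cycle tunnel exiting to post fracture; the no-fracture pool faces
    background mortality only; death absorbs.
    """
    cfg, epi = bundle.config, bundle.epidemiology
    if not cfg.start_age <= age <= cfg.end_age:
        raise ParameterError(
            f"age {age} outside model range [{cfg.start_age}, {cfg.end_age}]")
    m = _capped(epi.mortality_at(age) * epi.sex_mortality_multiplier.get(sex, 1.0),
                f"background mortality at age {age}")
    p_fx = annual_fracture_probs(bundle, sex)
    a = epi.adherence_annual

    P = np.zeros((N_STATES, N_STATES))

    def untreated_row(idx: int, p: float) -> None:
        P[idx, DEAD] = m
        P[idx, FRACTURE] = (1.0 - m) * p
        P[idx, idx] = 1.0 - m - P[idx, FRACTURE]

    def treated_row(idx: int, untreated_idx: int, p: float, rr: float) -> None:
        p_t = p * rr
        P[idx, DEAD] = m
        P[idx, FRACTURE] = (1.0 - m) * p_t
        survive_nofx = (1.0 - m) * (1.0 - p_t)
        P[idx, untreated_idx] = survive_nofx * (1.0 - a)
        P[idx, idx] = survive_nofx * a

    untreated_row(UNTREATED_OP, p_fx["osteoporosis"])
    untreated_row(UNTREATED_PE, p_fx["osteopenia"])
    untreated_row(NORMAL, p_fx["normal"])
    treated_row(TREATED_OP, UNTREATED_OP, p_fx["osteoporosis"], epi.rr_bisphosphonate)
    treated_row(TREATED_PE, UNTREATED_PE, p_fx["osteopenia"], epi.rr_vitd_calcium)

    P[NO_FRACTURE, DEAD] = m
    P[NO_FRACTURE, NO_FRACTURE] = 1.0 - m

    m_fx = _capped(m * epi.fracture_mortality_multiplier,
                   f"fracture-year mortality at age {age}")
    P[FRACTURE, DEAD] = m_fx
    P[FRACTURE, POST_FRACTURE] = 1.0 - m_fx  # one-cycle tunnel

    m_post = _capped(m * epi.postfracture_mortality_multiplier,
                     f"post-fracture mortality at age {age}")
    P[POST_FRACTURE, DEAD] = m_post
    P[POST_FRACTURE, FRACTURE] = (1.0 - m_post) * epi.refracture_annual
    P[POST_FRACTURE, POST_FRACTURE] = 1.0 - m_post - P[POST_FRACTURE, FRACTURE]

    P[DEAD, DEAD] = 1.0
    return P


def _state_cost_vector(bundle: ParameterBundle) -> np.ndarray:
    c = bundle.costs
    vec = np.zeros(N_STATES)
    vec[TREATED_OP] = c.cost_treat_osteoporosis_annual
    vec[TREATED_PE] = c.cost_treat_osteopenia_annual
    vec[FRACTURE] = c.cost_fracture_year1
    vec[POST_FRACTURE] = c.cost_postfracture_annual
    return vec


def _state_utility_vector(bundle: ParameterBundle, age: int) -> np.ndarray:
    u = bundle.utilities
    base = u.utility_at(age)
    vec = np.full(N_STATES, base)
    vec[FRACTURE] = base * u.fracture_year_multiplier
    vec[POST_FRACTURE] = base * u.postfracture_multiplier
    vec[DEAD] = 0.0
    return vec


def run_cohort(initial: StateDistribution, bundle: ParameterBundle,
               upfront_cost: float = 0.0, sex: str = "all") -> MarkovTrace:
    """Propagate the cohort over the configured horizon.

    Costs and QALYs accrue from start-of-cycle occupancy (no half-cycle
    correction); the upfront assessment cost enters undiscounted at cycle 0.
    """
    cfg = bundle.config
    n_cycles = cfg.horizon_cycles
    if n_cycles < 1:
        raise ParameterError("horizon must cover at least one cycle")
    initial.validate(cfg.cohort_size)

    ages = np.arange(cfg.start_age, cfg.start_age + n_cycles)
    occupancy = np.zeros((n_cycles + 1, N_STATES))
    occupancy[0] = initial.as_array()
    cycle_cost = np.zeros(n_cycles)
    cycle_qaly = np.zeros(n_cycles)
    disc_cost = np.zeros(n_cycles)
    disc_qaly = np.zeros(n_cycles)
    cost_vec = _state_cost_vector(bundle)

    for k, age in enumerate(ages):
        occ = occupancy[k]
        cycle_cost[k] = occ @ cost_vec
        if k == 0:
            cycle_cost[k] += upfront_cost
        cycle_qaly[k] = occ @ _state_utility_vector(bundle, int(age))
        v = discount_factor(cfg.discount_rate, k)
        disc_cost[k] = cycle_cost[k] * v
        disc_qaly[k] = cycle_qaly[k] * v
        occupancy[k + 1] = occ @ build_transition_matrix(int(age), bundle, sex)

    return MarkovTrace(ages=ages, occupancy=occupancy, cycle_cost=cycle_cost,
                       cycle_qaly=cycle_qaly, disc_cost=disc_cost, disc_qaly=disc_qaly,
                       cohort_size=cfg.cohort_size, upfront_cost=upfront_cost)


def trace_totals(trace: MarkovTrace) -> StrategyOutcome:
    """Discounted totals per person."""
    if len(trace.ages) == 0:
        raise ParameterError("cannot total an empty trace")
    return StrategyOutcome(
        mean_cost=float(trace.disc_cost.sum() / trace.cohort_size),
        mean_qaly=float(trace.disc_qaly.sum() / trace.cohort_size),
    )


def run_strategy(strategy_id: str, bundle: ParameterBundle,
                 sex: str = "all") -> tuple[MarkovTrace, StrategyOutcome]:
    """Decision tree → Markov cohort → per-person totals, in one call."""
    outcome = initial_state_distribution(strategy_id, bundle)
    trace = run_cohort(outcome.initial_distribution, bundle,
                       upfront_cost=outcome.upfront_cost, sex=sex)
    return trace, trace_totals(trace)


def cycle1_report(bundle: ParameterBundle) -> pd.DataFrame:
    """Predicted population size in each health state at cycle 1 (the
    post-screening starting distribution), per strategy — the structural
    sanity check that occupancy matches the cohort size."""
    rows = {}
    for sid in sorted(bundle.screening):
        dist = initial_state_distribution(sid, bundle).initial_distribution
        rows[sid] = dist.to_dict()
    frame = pd.DataFrame(rows).T
    frame.index.name = "strategy"
    frame["total"] = frame.sum(axis=1)
    return frame


def microsim_oracle(initial: StateDistribution, bundle: ParameterBundle,
                    upfront_cost: float, n_individuals: int, seed: int,
                    sex: str = "all") -> MicrosimEstimate:
    """Individual-level Monte-Carlo replay of the cohort model.

    Each simulated person starts in a state drawn from the initial
    distribution, walks the same per-age transition rows, and accrues the
    same discounted cost and QALY streams; the per-person upfront cost is
    the cohort upfront cost split equally. The cohort model's means should
    agree with these estimates to within Monte-Carlo error.
    """
    if n_individuals <= 0:
        raise ParameterError("n_individuals must be positive")
    cfg = bundle.config
    initial.validate(cfg.cohort_size)
    rng = np.random.default_rng(seed)
    n_cycles = cfg.horizon_cycles
    ages = np.arange(cfg.start_age, cfg.start_age + n_cycles)

    p0 = initial.as_array() / cfg.cohort_size
    states = rng.choice(N_STATES, size=n_individuals, p=p0)
    cost = np.full(n_individuals, upfront_cost / cfg.cohort_size)
    qaly = np.zeros(n_individuals)
    cost_vec = _state_cost_vector(bundle)

    for k, age in enumerate(ages):
        v = discount_factor(cfg.discount_rate, k)
        cost += v * cost_vec[states]
        qaly += v * _state_utility_vector(bundle, int(age))[states]
        cum = build_transition_matrix(int(age), bundle, sex).cumsum(axis=1)
        cum[:, -1] = 1.0  # guard against round-off at the top edge
        u = rng.random(n_individuals)
        states = (cum[states] < u[:, None]).sum(axis=1)

    return MicrosimEstimate(
        mean_cost=float(cost.mean()),
        mean_qaly=float(qaly.mean()),
        se_cost=float(cost.std(ddof=1) / np.sqrt(n_individuals)),
        se_qaly=float(qaly.std(ddof=1) / np.sqrt(n_individuals)),
    )
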