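"""Screening cascade: strategy definition → initial Markov state
distribution, DXA count and upfront assessment cost.

The cascade is evaluated on expected (fractional) person counts. A fraction
of the cohort receives the risk score; those testing positive — true
positives among the low-BMD (osteoporotic or osteopenic) and false
positives among the normal-BMD — proceed to a perfectly accurate DXA and
are treated according to the confirmed category. The direct-DXA strategy
skips the risk score and scans everyone. A fixed share of every baseline
bone-status state (treated and untreated alike) is then set aside in the
lifetime 'no fracture' state, so the never-fracturing share of the cohort
is identical across strategies.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import CostParams, ParameterBundle, ParameterError, STRATEGY_IDS
from .states import (
    NORMAL,
    NO_FRACTURE,
    N_STATES,
    TREATED_OP,
    TREATED_PE,
    UNTREATED_OP,
    UNTREATED_PE,
    StateDistribution,
)

__all__ = ["ScreeningOutcome", "screen_positive_rate",
           "initial_state_distribution", "upfront_assessment_cost"]


@dataclass
class ScreeningOutcome:
    """Result of running the decision tree for one strategy."""

    initial_distribution: StateDistribution
    n_risk_scored: float
    n_dxa: float
    upfront_cost: float


def screen_positive_rate(prev_low_bmd: float, sens: float, spec: float) -> float:
    """Marginal probability of a positive risk score:
    prev·sens + (1−prev)·(1−spec)."""
    for name, v in (("prev_low_bmd", prev_low_bmd), ("sens", sens), ("spec", spec)):
        if not 0.0 <= v <= 1.0:
            raise ParameterError(f"{name} must be in [0, 1], got {v!r}")
    return prev_low_bmd * sens + (1.0 - prev_low_bmd) * (1.0 - spec)


def upfront_assessment_cost(n_risk_scored: float, n_dxa: float,
                            costs: CostParams, strategy_id: str) -> float:
    """Baseline assessment spend: risk scores plus diagnostic DXA scans.

    The direct-DXA strategy (S3) has no risk-score component by
    construction (``n_risk_scored`` is zero there)."""
    if n_risk_scored < 0 or n_dxa < 0:
        raise ParameterError("assessment counts must be non-negative")
    if strategy_id not in STRATEGY_IDS:
        raise ParameterError(f"unknown strategy {strategy_id!r}")
    return n_risk_scored * costs.cost_risk_score + n_dxa * costs.cost_dxa


def initial_state_distribution(strategy_id: str, bundle: ParameterBundle) -> ScreeningOutcome:
    """Run the screening cascade for one strategy.

    Expected counts flow through four steps: (1) a fraction of the cohort
    is risk-scored (direct DXA skips this); (2) scored persons test
    positive with the tool's sensitivity if their true BMD is low, or with
    1−specificity if normal; (3) positives receive a DXA and are classified
    perfectly into treated osteoporosis / treated osteopenia / normal BMD;
    (4) a fraction of every bone-status state is moved to the lifetime
    no-fracture state. Occupancy is conserved at the cohort size.
    """
    if strategy_id not in STRATEGY_IDS:
        raise ParameterError(f"unknown strategy {strategy_id!r}")
    bundle.validate()
    cfg, epi = bundle.config, bundle.epidemiology
    profile = bundle.screening[strategy_id]
    n = cfg.cohort_size

    n_op = n * epi.prev_osteoporosis
    n_pe = n * epi.prev_osteopenia
    n_nm = n * epi.prev_normal

    counts = np.zeros(N_STATES)
    if profile.tool == "DXA_direct":
        # everyone proceeds straight to DXA, classified perfectly
        n_scored = 0.0
        n_dxa = n
        counts[TREATED_OP] = n_op
        counts[TREATED_PE] = n_pe
        counts[NORMAL] = n_nm
    else:
        s = profile.screened_fraction
        n_scored = s * n
        # positives by true category among the scored
        pos_op = s * n_op * profile.sensitivity
        pos_pe = s * n_pe * profile.sensitivity
        pos_nm = s * n_nm * (1.0 - profile.specificity)
        n_dxa = pos_op + pos_pe + pos_nm
        counts[TREATED_OP] = pos_op
        counts[TREATED_PE] = pos_pe
        counts[UNTREATED_OP] = n_op - pos_op
        counts[UNTREATED_PE] = n_pe - pos_pe
        counts[NORMAL] = n_nm  # false positives return to normal untreated

    # lifetime no-fracture pool, drawn proportionally from every baseline
    # bone-status state (treated included): the pool represents the share of
    # the at-risk population that will never fracture, independent of the
    # screening strategy, so it must not differ between arms
    f = epi.frac_no_fracture
    for idx in (UNTREATED_OP, TREATED_OP, UNTREATED_PE, TREATED_PE, NORMAL):
        moved = counts[idx] * f
        counts[idx] -= moved
        counts[NO_FRACTURE] += moved

    dist = StateDistribution(counts)
    dist.validate(n, baseline=True)
    cost = upfront_assessment_cost(n_scored, n_dxa, bundle.costs, strategy_id)
    return ScreeningOutcome(initial_distribution=dist, n_risk_scored=n_scored,
                            n_dxa=n_dxa, upfront_cost=cost)
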