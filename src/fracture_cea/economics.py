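"""Incremental cost-effectiveness: ICER, dominance quadrants and net
monetary benefit.

Conventions: ΔC and ΔE are intervention minus comparator; the ICER is
ΔC/ΔE and only interpretable together with its cost-effectiveness-plane
quadrant (a negative ICER is 'dominant' when the intervention is cheaper
and more effective, 'dominated' in the opposite corner); the incremental
net monetary benefit at willingness-to-pay λ is NMB(λ) = λ·ΔE − ΔC, and
NMB(λ) ≥ 0 ⇔ ICER ≤ λ whenever ΔE > 0.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .markov import StrategyOutcome
from .parameters import ParameterError

__all__ = ["Dominance", "ICERResult", "PairwiseComparison",
           "icer", "nmb", "classify_dominance", "compare_strategies",
           "comparison_table"]


class Dominance(str, Enum):
    DOMINANT = "dominant"            # cheaper, more effective (SE quadrant)
    DOMINATED = "dominated"          # costlier, less effective (NW quadrant)
    TRADE_OFF_NE = "trade_off_NE"    # costlier, more effective
    TRADE_OFF_SW = "trade_off_SW"    # cheaper, less effective


@dataclass(frozen=True)
class ICERResult:
    """ICER value plus the quadrant that disambiguates its sign; ``value``
    is None when ΔE = 0 (ratio undefined)."""

    value: float | None
    quadrant: Dominance
    label: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.value is None:
            return self.label
        return f"{self.value:.1f} ({self.quadrant.value})"


def classify_dominance(delta_cost: float, delta_qaly: float) -> Dominance:
    """Cost-effectiveness-plane quadrant. Exact zeros are deterministic
    ties: ΔE ≥ 0 maps to the NE trade-off, ΔE < 0 with ΔC ≤ 0 to the SW."""
    if delta_cost < 0 and delta_qaly > 0:
        return Dominance.DOMINANT
    if delta_cost > 0 and delta_qaly < 0:
        return Dominance.DOMINATED
    if delta_qaly >= 0:
        return Dominance.TRADE_OFF_NE
    return Dominance.TRADE_OFF_SW


def icer(delta_cost: float, delta_qaly: float) -> ICERResult:
    """Incremental cost-effectiveness ratio ΔC/ΔE, tagged with its quadrant.

    ΔE = 0 yields a labelled non-numeric result rather than an exception.
    """
    quadrant = classify_dominance(delta_cost, delta_qaly)
    if delta_qaly == 0:
        return ICERResult(value=None, quadrant=quadrant, label="undefined (ΔE = 0)")
    value = delta_cost / delta_qaly
    return ICERResult(value=value, quadrant=quadrant, label=quadrant.value)


def nmb(delta_cost: float, delta_qaly: float, threshold: float) -> float:
    """Incremental net monetary benefit λ·ΔE − ΔC."""
    if threshold < 0:
        raise ParameterError(f"threshold must be non-negative, got {threshold!r}")
    return threshold * delta_qaly - delta_cost


@dataclass
class PairwiseComparison:
    """One intervention-vs-comparator comparison with its full economics."""

    intervention: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    icer: ICERResult
    dominance: Dominance
    nmb_by_threshold: dict[float, float] = field(default_factory=dict)

    def cost_effective_at(self, threshold: float) -> bool:
        """Positive incremental NMB at λ (strict; an exact zero counts as
        not cost-effective)."""
        return self.nmb_by_threshold.get(threshold, nmb(
            self.delta_cost, self.delta_qaly, threshold)) > 0


def _pairwise(intervention: str, comparator: str,
              oi: StrategyOutcome, oc: StrategyOutcome,
              thresholds: list[float]) -> PairwiseComparison:
    dc = oi.mean_cost - oc.mean_cost
    de = oi.mean_qaly - oc.mean_qaly
    return PairwiseComparison(
        intervention=intervention, comparator=comparator,
        delta_cost=dc, delta_qaly=de,
        icer=icer(dc, de), dominance=classify_dominance(dc, de),
        nmb_by_threshold={lam: nmb(dc, de, lam) for lam in thresholds},
    )


def compare_strategies(outcomes: dict[str, StrategyOutcome], comparator_id: str,
                       thresholds: list[float]) -> list[PairwiseComparison]:
    """All pairwise comparisons against the comparator, plus S3 vs S2 when
    both are present (the secondary head-to-head the analysis reports)."""
    if comparator_id not in outcomes:
        raise ParameterError(f"comparator {comparator_id!r} missing from outcomes")
    if len(outcomes) < 2:
        raise ParameterError("need at least one non-comparator strategy")
    comparisons = [
        _pairwise(sid, comparator_id, outcomes[sid], outcomes[comparator_id], thresholds)
        for sid in sorted(outcomes) if sid != comparator_id
    ]
    if {"S2", "S3"} <= set(outcomes) and comparator_id not in ("S2", "S3"):
        comparisons.append(_pairwise("S3", "S2", outcomes["S3"], outcomes["S2"],
                                     thresholds))
    return comparisons


def comparison_table(outcomes: dict[str, StrategyOutcome],
                     comparisons: list[PairwiseComparison],
                     comparator_id: str) -> pd.DataFrame:
    """Base-case table: one row per strategy with mean cost/QALY and the
    incremental columns against the comparator (cost, QALY, ICER, NMB per
    threshold). Monetary columns are GBP at 2021/22 prices."""
    thresholds = sorted({lam for c in comparisons for lam in c.nmb_by_threshold})
    by_intervention = {c.intervention: c for c in comparisons
                       if c.comparator == comparator_id}
    rows = []
    for sid in sorted(outcomes):
        out = outcomes[sid]
        row: dict[str, object] = {
            "strategy": sid,
            "mean_cost_gbp_2021_22": out.mean_cost,
            "mean_qaly": out.mean_qaly,
        }
        comp = by_intervention.get(sid)
        if comp is None:
            row.update({"incremental_cost": math.nan, "incremental_qaly": math.nan,
                        "icer": math.nan, "dominance": ""})
            for lam in thresholds:
                row[f"nmb_at_{int(lam)}"] = math.nan
        else:
            row.update({
                "incremental_cost": comp.delta_cost,
                "incremental_qaly": comp.delta_qaly,
                "icer": comp.icer.value if comp.icer.value is not None else math.nan,
                "dominance": comp.dominance.value,
            })
            for lam in thresholds:
                row[f"nmb_at_{int(lam)}"] = comp.nmb_by_threshold[lam]
        rows.append(row)
    return pd.DataFrame(rows)
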