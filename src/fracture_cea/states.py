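"""The nine health states of the fracture Markov model and cohort occupancy.

State ordering is fixed and shared by every module that builds or consumes
transition matrices: the five post-screening bone-status states, the
lifetime 'no fracture' pool, the one-year fracture state, the chronic
post-fracture state, and absorbing death.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STATES: tuple[str, ...] = (
    "untreated_osteoporosis",
    "treated_osteoporosis",
    "untreated_osteopenia",
    "treated_osteopenia",
    "normal_bmd",
    "no_fracture",
    "fracture",
    "post_fracture",
    "dead",
)

N_STATES = len(STATES)
STATE_INDEX: dict[str, int] = {name: i for i, name in enumerate(STATES)}

# short aliases used when building transition rows
UNTREATED_OP = STATE_INDEX["untreated_osteoporosis"]
TREATED_OP = STATE_INDEX["treated_osteoporosis"]
UNTREATED_PE = STATE_INDEX["untreated_osteopenia"]
TREATED_PE = STATE_INDEX["treated_osteopenia"]
NORMAL = STATE_INDEX["normal_bmd"]
NO_FRACTURE = STATE_INDEX["no_fracture"]
FRACTURE = STATE_INDEX["fracture"]
POST_FRACTURE = STATE_INDEX["post_fracture"]
DEAD = STATE_INDEX["dead"]


@dataclass
class StateDistribution:
    """Occupancy (persons) of the nine health states at one point in time."""

    counts: np.ndarray = field(default_factory=lambda: np.zeros(N_STATES))

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=float)
        if arr.shape != (N_STATES,):
            raise ValueError(f"expected {N_STATES} state occupancies, got shape {arr.shape}")
        self.counts = arr

    def as_array(self) -> np.ndarray:
        return self.counts

    def total(self) -> float:
        return float(self.counts.sum())

    def __getitem__(self, state: str) -> float:
        return float(self.counts[STATE_INDEX[state]])

    def to_dict(self) -> dict[str, float]:
        return {name: float(v) for name, v in zip(STATES, self.counts)}

    @classmethod
    def from_dict(cls, occupancy: dict[str, float]) -> "StateDistribution":
        counts = np.zeros(N_STATES)
        for name, v in occupancy.items():
            if name not in STATE_INDEX:
                raise ValueError(f"unknown health state {name!r}")
            counts[STATE_INDEX[name]] = float(v)
        return cls(counts)

    def validate(self, cohort_size: float, *, baseline: bool = False, atol: float = 1e-9) -> None:
        """Check non-negativity and conservation; at baseline the fracture,
        post-fracture and dead states must be empty."""
        if np.any(self.counts < -atol):
            bad = STATES[int(np.argmin(self.counts))]
            raise ValueError(f"negative occupancy in state {bad!r}")
        if abs(self.total() - cohort_size) > max(atol, atol * cohort_size):
            raise ValueError(
                f"occupancy sums to {self.total()!r}, expected cohort size {cohort_size!r}"
            )
        if baseline:
            for idx in (FRACTURE, POST_FRACTURE, DEAD):
                if abs(self.counts[idx]) > atol:
                    raise ValueError(f"state {STATES[idx]!r} must be empty at baseline")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StateDistribution):
            return NotImplemented
        return bool(np.array_equal(self.counts, other.counts))
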