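"""Goal-programming relocation model for a single incoming animal.

Given the predicted LOS class of the animal at every shelter in a network
(phase-1 output), relocation costs r_{l',l} from the current shelter l',
and remaining capacity t_{l,y,s} per shelter x animal type x size, the
model picks the one destination shelter that best trades off adoption
speed against relocation cost.

Each objective becomes a goal with a target value: the encoded LOS score
e_l against the preferred score p^s, and the relocation cost against the
preferred cost p^r.  Deviation variables measure shortfall/excess
(e_l + d1m − d1p = p^s, analogously for cost) and the solver minimizes
the weighted, scaled sum of the *positive* deviations only:

    Z = w1 d1p / f1  +  w2 d2p / f2

subject to: exactly one shelter chosen; the destination has a free
housing unit for this type/size; its LOS score respects the bound u^LS;
the relocation cost respects the bound u^RC.  Because one animal is
assigned to exactly one shelter, the program is solved exactly by
enumerating the feasible set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocessing import LOS_CLASSES, SIZE_CATEGORIES

# Ordinal LOS-score encodings.  The model needs a numeric e_l for a
# categorical prediction; the default is the rank 1..4, the alternative
# uses representative stay days per class (bin midpoints, cap for the top).
ORDINAL_ENCODING = {"low": 1.0, "medium": 2.0, "high": 3.0, "very_high": 4.0}
DAYS_ENCODING = {"low": 4.0, "medium": 25.0, "high": 204.0, "very_high": 365.0}
LOS_ENCODINGS = {"ordinal": ORDINAL_ENCODING, "days": DAYS_ENCODING}


def encode_los(los_class: str, mapping: Mapping[str, float] | str = "ordinal") -> float:
    """Numeric LOS score e_l for a predicted class.

    The mapping must be strictly increasing over (low, medium, high,
    very_high) so that the LOS goal keeps its ordering.
    """
    if isinstance(mapping, str):
        mapping = LOS_ENCODINGS[mapping]
    vals = [mapping[c] for c in LOS_CLASSES]
    if not all(a < b for a, b in zip(vals, vals[1:])):
        raise ValueError(f"LOS encoding not strictly increasing: {vals}")
    return float(mapping[los_class])


@dataclass
class ShelterNetwork:
    """Shelters, pairwise relocation costs, and remaining capacity.

    ``capacity[(shelter, animal_type, size)]`` is the number of free
    housing units for that type/size at that shelter.
    """

    shelters: list[str]
    relocation_cost: np.ndarray  # square, >= 0, zero diagonal
    capacity: dict[tuple[str, str, str], int]

    def __post_init__(self):
        self.relocation_cost = np.asarray(self.relocation_cost, dtype=float)
        n = len(self.shelters)
        if self.relocation_cost.shape != (n, n):
            raise ValueError("cost matrix shape does not match shelter list")
        if (self.relocation_cost < 0).any():
            raise ValueError("negative relocation cost")
        if not np.allclose(np.diag(self.relocation_cost), 0.0):
            raise ValueError("cost matrix diagonal must be zero")
        if any(v < 0 for v in self.capacity.values()):
            raise ValueError("negative capacity")

    def index(self, shelter: str) -> int:
        return self.shelters.index(shelter)

    def cost(self, origin: str, dest: str) -> float:
        return float(self.relocation_cost[self.index(origin), self.index(dest)])

    def units(self, shelter: str, animal_type: str, size: str) -> int:
        return int(self.capacity.get((shelter, animal_type, size), 0))

    def decrement(self, shelter: str, animal_type: str, size: str) -> None:
        """Consume one housing unit (sequential batch assignment)."""
        key = (shelter, animal_type, size)
        if self.capacity.get(key, 0) < 1:
            raise ValueError(f"no remaining capacity at {key}")
        self.capacity[key] -= 1


@dataclass
class RelocationProblem:
    """One relocation decision: the animal, its per-shelter LOS scores,
    goals, weights, scaling factors, and bounds."""

    current_shelter: str
    animal_type: str
    size: str
    predicted_los: dict[str, str]  # shelter -> LOS class
    goal_los: float = ORDINAL_ENCODING["low"]  # p^s: most-ambitious target
    goal_cost: float = 0.0                     # p^r
    w1: float = 1.0
    w2: float = 1.0
    f1: float | None = None  # default: max encoded LOS score
    f2: float | None = None  # default: the cost bound u^RC
    u_ls: float = ORDINAL_ENCODING["very_high"]  # LOS-score upper bound
    u_rc: float = float("inf")                   # relocation-cost upper bound
    los_encoding: Mapping[str, float] | str = "ordinal"

    def validate(self, network: ShelterNetwork) -> None:
        if self.current_shelter not in network.shelters:
            raise ValueError(f"current shelter {self.current_shelter!r} "
                             "not in network")
        missing = [l for l in network.shelters if l not in self.predicted_los]
        if missing:
            raise ValueError(f"predicted LOS missing for shelter(s): {missing}")
        if self.w1 < 0 or self.w2 < 0 or self.w1 + self.w2 <= 0:
            raise ValueError("weights must be non-negative and not both zero")
        if self.size not in SIZE_CATEGORIES:
            raise ValueError(f"unknown size {self.size!r}")

    def score(self, shelter: str) -> float:
        return encode_los(self.predicted_los[shelter], self.los_encoding)

    def scaling(self) -> tuple[float, float]:
        enc = (LOS_ENCODINGS[self.los_encoding]
               if isinstance(self.los_encoding, str) else self.los_encoding)
        f1 = self.f1 if self.f1 is not None else max(enc.values())
        f2 = self.f2 if self.f2 is not None else (
            self.u_rc if np.isfinite(self.u_rc) and self.u_rc > 0 else 1.0)
        if f1 <= 0 or f2 <= 0:
            raise ValueError("scaling factors must be positive")
        return float(f1), float(f2)


@dataclass
class Assignment:
    shelter: str
    ls_objective: float    # LS^O = e_l
    rc_objective: float    # RC^O = r_{l',l}
    d1_minus: float
    d1_plus: float
    d2_minus: float
    d2_plus: float
    z: float


@dataclass
class RelocationSolution:
    status: str  # optimal | infeasible
    chosen: Assignment | None
    trace: list[Assignment] = field(default_factory=list)
    exclusions: dict[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def asg(a: Assignment) -> dict:
            return {"shelter": a.shelter, "ls_objective": a.ls_objective,
                    "rc_objective": a.rc_objective,
                    "d1_minus": a.d1_minus, "d1_plus": a.d1_plus,
                    "d2_minus": a.d2_minus, "d2_plus": a.d2_plus, "z": a.z}
        return {
            "status": self.status,
            "chosen": None if self.chosen is None else asg(self.chosen),
            "trace": [asg(a) for a in self.trace],
            "exclusions": self.exclusions,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def feasible_set(problem: RelocationProblem, network: ShelterNetwork,
                 ) -> tuple[list[str], dict[str, list[str]]]:
    """Shelters satisfying the hard constraints, plus per-shelter
    diagnostics naming the violated constraint(s) for the excluded ones.

    A shelter stays feasible iff it has a free unit for this animal's
    type/size, its LOS score is within u^LS, and the relocation cost from
    the current shelter is within u^RC (trivially true for staying put,
    since the self-cost is zero).
    """
    problem.validate(network)
    feasible, excluded = [], {}
    for l in network.shelters:
        reasons = []
        if network.units(l, problem.animal_type, problem.size) < 1:
            reasons.append("capacity")
        if problem.score(l) > problem.u_ls:
            reasons.append("los_bound")
        if network.cost(problem.current_shelter, l) > problem.u_rc:
            reasons.append("cost_bound")
        if reasons:
            excluded[l] = reasons
        else:
            feasible.append(l)
    return feasible, excluded


def evaluate_assignment(problem: RelocationProblem, network: ShelterNetwork,
                        shelter: str) -> Assignment:
    """Objectives, deviations, and scaled objective Z for assigning the
    animal to one shelter.

    The goal identities e_l + d1m − d1p = p^s and r + d2m − d2p = p^r hold
    exactly, with min(dm, dp) = 0 per goal; only positive deviations enter
    Z (falling short of an ambitious goal is not penalized).
    """
    if shelter not in network.shelters:
        raise ValueError(f"unknown shelter {shelter!r}")
    e = problem.score(shelter)
    r = network.cost(problem.current_shelter, shelter)
    d1_plus = max(0.0, e - problem.goal_los)
    d1_minus = max(0.0, problem.goal_los - e)
    d2_plus = max(0.0, r - problem.goal_cost)
    d2_minus = max(0.0, problem.goal_cost - r)
    f1, f2 = problem.scaling()
    z = problem.w1 * d1_plus / f1 + problem.w2 * d2_plus / f2
    return Assignment(shelter, e, r, d1_minus, d1_plus, d2_minus, d2_plus, z)


def solve(problem: RelocationProblem, network: ShelterNetwork) -> RelocationSolution:
    """Exact solve by enumerating the feasible set.

    The single-assignment constraint makes the decision space the feasible
    shelters themselves, so enumeration is exact.  Ties on Z break to the
    lower relocation cost, then to the lexicographically smaller shelter
    id (reproducibility).  An empty feasible set yields status
    ``infeasible`` with per-shelter diagnostics, not an exception.
    """
    feasible, excluded = feasible_set(problem, network)
    trace = [evaluate_assignment(problem, network, l) for l in feasible]
    if not trace:
        return RelocationSolution(status="infeasible", chosen=None,
                                  trace=[], exclusions=excluded)
    best = min(trace, key=lambda a: (a.z, a.rc_objective, a.shelter))
    return RelocationSolution(status="optimal", chosen=best,
                              trace=trace, exclusions=excluded)


def weight_sweep(problem: RelocationProblem, network: ShelterNetwork,
                 weights: Sequence[tuple[float, float]],
                 ) -> list[dict]:
    """Solve once per (w1, w2) pair for a trade-off table."""
    rows = []
    for w1, w2 in weights:
        p = RelocationProblem(**{**problem.__dict__, "w1": w1, "w2": w2})
        sol = solve(p, network)
        rows.append({
            "w1": w1, "w2": w2, "status": sol.status,
            "chosen": None if sol.chosen is None else sol.chosen.shelter,
            "z": None if sol.chosen is None else sol.chosen.z,
        })
    return rows


# ---------------------------------------------------------------------------
# Network file I/O
# ---------------------------------------------------------------------------

def load_network(costs_path: str | Path, capacity_path: str | Path,
                 ) -> ShelterNetwork:
    """Read a network from a square cost CSV (shelter ids as header row and
    first column) and a long capacity CSV (shelter,type,size,units)."""
    costs = pd.read_csv(costs_path, index_col=0)
    shelters = [str(s) for s in costs.index]
    if [str(c) for c in costs.columns] != shelters:
        raise ValueError("cost matrix header row and column disagree")
    cap = pd.read_csv(capacity_path, dtype={"shelter": str, "type": str,
                                            "size": str})
    for col in ("shelter", "type", "size", "units"):
        if col not in cap.columns:
            raise ValueError(f"capacity file missing column {col!r}")
    capacity = {(str(r.shelter), str(r.type), str(r.size)): int(r.units)
                for r in cap.itertuples(index=False)}
    return ShelterNetwork(shelters=shelters,
                          relocation_cost=costs.to_numpy(dtype=float),
                          capacity=capacity)


def save_network(network: ShelterNetwork, costs_path: str | Path,
                 capacity_path: str | Path) -> None:
    pd.DataFrame(network.relocation_cost, index=network.shelters,
                 columns=network.shelters).to_csv(costs_path)
    rows = [{"shelter": k[0], "type": k[1], "size": k[2], "units": v}
            for k, v in sorted(network.capacity.items())]
    pd.DataFrame(rows, columns=["shelter", "type", "size", "units"]).to_csv(
        capacity_path, index=False)
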