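"""Monte Carlo selection of a conformer ensemble against experimental shifts.

The objective is the RMSD between experimental shifts and the ensemble-average
predicted shifts, pooled over all restraints, with carbon values divided by a
scale factor so they do not dominate the proton residuals.  Moves are add /
swap / remove under hard size bounds; acceptance is greedy by default, with
an optional fixed-temperature Metropolis rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .conformers import ConformerModel, ModelPool
from .shift_data import RestraintSet

__all__ = [
    "SelectionConfig",
    "Ensemble",
    "ensemble_average_shifts",
    "cs_rmsd",
    "select_ensemble",
]


@dataclass
class SelectionConfig:
    min_size: int = 10
    max_size: int = 30
    cycles: int = 5_000_000
    carbon_scale: float = 4.0
    seed: int = 0
    acceptance_rule: str = "greedy"  # "greedy" | "metropolis"
    temperature: float = 0.05  # ppm, metropolis only
    trace_every: int = 1000

    def __post_init__(self) -> None:
        if not (1 <= self.min_size <= self.max_size):
            raise ValueError("require 1 <= min_size <= max_size")
        if self.carbon_scale <= 0:
            raise ValueError("carbon_scale must be > 0")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.acceptance_rule not in ("greedy", "metropolis"):
            raise ValueError(f"unknown acceptance_rule {self.acceptance_rule!r}")


@dataclass
class Ensemble:
    member_ids: frozenset
    rmsd: float
    trace: list[tuple[int, float]] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


def _restraint_keys(restraints: RestraintSet) -> list[tuple[int, str]]:
    if len(restraints) == 0:
        raise ValueError("restraint set is empty")
    return restraints.keys()


def ensemble_average_shifts(
    models: Sequence[ConformerModel], restraints: RestraintSet
) -> dict[tuple[int, str], float]:
    """Arithmetic mean of predicted shifts per restraint over the members."""
    if not models:
        raise ValueError("no models to average")
    keys = _restraint_keys(restraints)
    out: dict[tuple[int, str], float] = {}
    for key in keys:
        total = 0.0
        for m in models:
            if key not in m.predicted_shifts:
                raise KeyError(
                    f"model {m.model_id} has no prediction for residue {key[0]} atom {key[1]}"
                )
            total += m.predicted_shifts[key]
        out[key] = total / len(models)
    return out


def cs_rmsd(
    averaged: dict[tuple[int, str], float],
    experimental: RestraintSet,
    carbon_scale: float = 4.0,
) -> float:
    """Pooled RMSD (ppm) with carbon restraints scaled down on both sides."""
    if len(experimental) == 0:
        raise ValueError("restraint set is empty")
    sq = 0.0
    for r in experimental:
        key = (r.residue_number, r.atom)
        if key not in averaged:
            raise KeyError(f"averaged shifts missing residue {key[0]} atom {key[1]}")
        scale = carbon_scale if r.atom_class == "carbon" else 1.0
        diff = averaged[key] / scale - r.shift / scale
        sq += diff * diff
    return math.sqrt(sq / len(experimental))


def _prediction_matrix(
    pool: ModelPool, restraints: RestraintSet
) -> tuple[np.ndarray, np.ndarray]:
    """(P, y): per-model predictions and experimental values, restraint order."""
    keys = _restraint_keys(restraints)
    y = np.array([r.shift for r in restraints], dtype=float)
    P = np.empty((len(pool), len(keys)), dtype=float)
    for i, m in enumerate(pool.models):
        for j, key in enumerate(keys):
            if key not in m.predicted_shifts:
                raise KeyError(
                    f"model {m.model_id} has no prediction for residue {key[0]} atom {key[1]}"
                )
            P[i, j] = m.predicted_shifts[key]
    return P, y


def select_ensemble(
    pool: ModelPool, restraints: RestraintSet, cfg: SelectionConfig
) -> Ensemble:
    """Run the add/swap/remove Monte Carlo search and return the best-seen ensemble.

    Starts from a uniformly random ensemble of min_size members.  Each cycle
    proposes one move chosen uniformly among the currently legal ones (add
    below max_size, swap, remove above min_size); under the greedy rule a move
    is accepted iff it does not worsen the objective.  Fully reproducible for
    a given seed; returns the best ensemble visited plus a periodic RMSD trace.
    """
    n = len(pool)
    if n < cfg.min_size:
        raise ValueError(f"pool of {n} models is smaller than min_size={cfg.min_size}")
    P, y = _prediction_matrix(pool, restraints)
    scale = np.array(
        [cfg.carbon_scale if c == "carbon" else 1.0 for c in restraints.atom_classes]
    )
    Pw = P / scale  # scaled predictions
    yw = y / scale  # scaled experiment
    rng = np.random.default_rng(cfg.seed)
    ids = np.array([m.model_id for m in pool.models])

    members = list(rng.choice(n, size=cfg.min_size, replace=False))
    in_ensemble = np.zeros(n, dtype=bool)
    in_ensemble[members] = True
    ssum = Pw[members].sum(axis=0)
    nr = len(restraints)

    def rmsd_of(total: np.ndarray, k: int) -> float:
        diff = total / k - yw
        return math.sqrt(float(diff @ diff) / nr)

    current = rmsd_of(ssum, len(members))
    best_rmsd = current
    best_members = frozenset(int(i) for i in ids[members])
    trace: list[tuple[int, float]] = [(0, current)]
    metropolis = cfg.acceptance_rule == "metropolis"
    max_size = min(cfg.max_size, n)

    for cycle in range(1, cfg.cycles + 1):
        k = len(members)
        moves = []
        if k < max_size:
            moves.append("add")
        if 0 < k < n:
            moves.append("swap")
        if k > cfg.min_size:
            moves.append("remove")
        move = moves[rng.integers(len(moves))]

        if move == "add":
            candidates = np.flatnonzero(~in_ensemble)
            pick = candidates[rng.integers(len(candidates))]
            new_sum = ssum + Pw[pick]
            new_k = k + 1
            action = ("add", pick, None)
        elif move == "remove":
            pos = rng.integers(k)
            out = members[pos]
            new_sum = ssum - Pw[out]
            new_k = k - 1
            action = ("remove", out, pos)
        else:  # swap
            pos = rng.integers(k)
            out = members[pos]
            candidates = np.flatnonzero(~in_ensemble)
            pick = candidates[rng.integers(len(candidates))]
            new_sum = ssum - Pw[out] + Pw[pick]
            new_k = k
            action = ("swap", (out, pos, pick), None)

        proposed = rmsd_of(new_sum, new_k)
        if metropolis:
            accept = proposed <= current or rng.random() < math.exp(
                -(proposed - current) / cfg.temperature
            )
        else:
            accept = proposed <= current
        if accept:
            kind = action[0]
            if kind == "add":
                members.append(action[1])
                in_ensemble[action[1]] = True
            elif kind == "remove":
                members.pop(action[2])
                in_ensemble[action[1]] = False
            else:
                out, pos, pick = action[1]
                members[pos] = pick
                in_ensemble[out] = False
                in_ensemble[pick] = True
            ssum = new_sum
            current = proposed
            if current < best_rmsd:
                best_rmsd = current
                best_members = frozenset(int(i) for i in ids[members])
        if cycle % cfg.trace_every == 0:
            trace.append((cycle, current))

    # Recompute the objective from scratch for the returned set so the
    # reported RMSD is free of incremental-update rounding drift.
    id_to_row = {mid: i for i, mid in enumerate(ids)}
    rows = [id_to_row[mid] for mid in best_members]
    best_rmsd = rmsd_of(Pw[rows].sum(axis=0), len(rows))
    return Ensemble(member_ids=best_members, rmsd=best_rmsd, trace=trace)
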