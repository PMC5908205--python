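"""The gating network: learned arbitration between behavioral modules.

Each registered module has one gating unit whose value ``g^k = z_k . r`` is a
weighted sum of the gating input (all cue-cell activities concatenated with
the planning-graph node activities).  Selection is a hierarchical
winner-take-all: first among the Direction modules, then between that winner,
the spatial module(s) and Exploration.  Learning is TD Q-learning on the
gating level, with the distinctive generalized credit assignment: every
module with a valid proposal is reinforced in proportion to the cosine of the
angle between its proposed and the executed orientation, so a module that
proposed the executed movement gets the full update and one that proposed the
opposite movement gets the opposite update.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .strategies import Proposal, ExplorationState

#: module kinds and their fixed tie-break priority (lower wins)
KIND_DIRECTION = "direction"
KIND_PLANNING = "planning"
KIND_LOCALE = "locale"
KIND_EXPLORATION = "exploration"

_TIE_PRIORITY = {KIND_PLANNING: 0, KIND_LOCALE: 1,
                 KIND_DIRECTION: 2, KIND_EXPLORATION: 3}


@dataclass(frozen=True)
class SelectionOutcome:
    winner: int                      # module index
    executed_orientation: float
    gating_values: np.ndarray
    persistence: bool = False        # winner imposed by exploration persistence


class GatingNetwork:
    """Gating units over the CC (+) PG input vector."""

    def __init__(self, kinds: list[str], n_inputs: int, *,
                 eta: float = 0.05, gamma: float = 0.9,
                 bootstrap: str = "max",
                 rng: np.random.Generator | None = None, init_scale: float = 0.01):
        for k in kinds:
            if k not in _TIE_PRIORITY:
                raise ValueError(f"unknown module kind {k!r}")
        if bootstrap not in ("max", "selected"):
            raise ValueError("bootstrap must be 'max' or 'selected'")
        self.kinds = list(kinds)
        self.eta = eta
        self.gamma = gamma
        self.bootstrap = bootstrap
        #: selection-time lower bound on the Exploration unit's value: random
        #: exploration is the fallback whenever every learned strategy's
        #: prediction has been extinguished to (or below) this baseline
        self.exploration_floor = 0.05
        rng = rng or np.random.default_rng(0)
        # zero-mean random initialization: per-agent idiosyncratic priors
        # over strategies without a systematic optimism offset
        self.z = (rng.random((n_inputs, len(kinds))) - 0.5) * init_scale

    @property
    def n_modules(self) -> int:
        return len(self.kinds)


def gating_values(net: GatingNetwork, r: np.ndarray) -> np.ndarray:
    if r.shape[0] != net.z.shape[0]:
        raise ValueError(f"dimension mismatch: z {net.z.shape} vs input {r.shape}")
    return r @ net.z


def _better(net: GatingNetwork, g: np.ndarray, a: int, b: int) -> int:
    """Winner of a pairwise comparison with the fixed tie order."""
    if g[a] > g[b]:
        return a
    if g[b] > g[a]:
        return b
    ka = (_TIE_PRIORITY[net.kinds[a]], a)
    kb = (_TIE_PRIORITY[net.kinds[b]], b)
    return a if ka < kb else b


def select_module(net: GatingNetwork, proposals: list[Proposal],
                  g: np.ndarray, persistence: ExplorationState) -> SelectionOutcome:
    """Hierarchical winner-take-all over valid proposals.

    While exploration persistence is active the Exploration module wins
    outright, bypassing the comparison (its pending orientation is executed);
    otherwise a first winner-take-all runs among the valid Direction modules
    and a second among {that winner, spatial module(s), Exploration}.
    """
    valid = [p.valid for p in proposals]
    by_index = {p.module_id: p for p in proposals}
    floor = getattr(net, "exploration_floor", 0.0)
    if floor:
        g = g.copy()
        for k, kind in enumerate(net.kinds):
            if kind == KIND_EXPLORATION and g[k] < floor:
                g[k] = floor
    if persistence.steps_remaining > 0:
        for k, kind in enumerate(net.kinds):
            if kind == KIND_EXPLORATION:
                return SelectionOutcome(k, by_index[k].orientation, g.copy(),
                                        persistence=True)
    stage1: int | None = None
    for k, kind in enumerate(net.kinds):
        if kind == KIND_DIRECTION and valid[k]:
            stage1 = k if stage1 is None else _better(net, g, stage1, k)
    winner: int | None = stage1
    for k, kind in enumerate(net.kinds):
        if kind != KIND_DIRECTION and valid[k]:
            winner = k if winner is None else _better(net, g, winner, k)
    if winner is None:
        raise ValueError("no valid proposal to select from")
    return SelectionOutcome(winner, by_index[winner].orientation, g.copy())


def gating_update(net: GatingNetwork, r_t: np.ndarray, r_next: np.ndarray | None,
                  proposals: list[Proposal], executed_orientation: float,
                  selected: int, reward: float, terminal: bool,
                  *, g_t: np.ndarray | None = None,
                  g_next: np.ndarray | None = None) -> float:
    """Generalized TD update of the gating weights.  Returns delta.

    delta is computed from the selected module's gating value and bootstraps
    on the best gating value at the next input; every module with a valid
    proposal has its column updated, scaled by the cosine of the angular
    distance between its proposal and the executed orientation.
    """
    if g_t is None:
        g_t = gating_values(net, r_t)
    if terminal:
        bootstrap = 0.0
    else:
        if g_next is None:
            g_next = gating_values(net, r_next)
        if getattr(net, "bootstrap", "max") == "selected":
            bootstrap = net.gamma * float(g_next[selected])
        else:
            bootstrap = net.gamma * float(np.max(g_next))
    delta = reward + bootstrap - float(g_t[selected])
    idx = [p.module_id for p in proposals if p.valid]
    kappa = np.array([math.cos(p.orientation - executed_orientation)
                      for p in proposals if p.valid])
    net.z[:, idx] += (net.eta * delta) * r_t[:, None] * kappa[None, :]
    return delta
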