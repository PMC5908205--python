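"""The behavioral experts: model-free Direction/Locale modules (TD Q-learning
over action cells), model-based Planning over the topological graph, and
random Exploration with persistence.

Every module speaks the same common currency: a proposed allocentric movement
orientation.  Model-free modules are greedy over their action cells (a ring of
``N_AC`` cells with preferred orientations ``phi_i = 2 pi i / N_AC``);
exploration is an explicit separate module, so no softmax is used anywhere.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .arena import TWO_PI, wrap_angle
from .cognitive_map import PlanningGraph

N_AC_DEFAULT = 36


@dataclass(frozen=True)
class Proposal:
    module_id: int
    orientation: float = 0.0
    valid: bool = True


class MFModule:
    """A model-free expert: Q-learning from an input population to action cells.

    Direction modules read one cue's cue-cell ring; a Locale module reads the
    place-cell population.  The activation of action cell i is the linear sum
    ``a_i = sum_j W_ij r_j`` and is interpreted as the value of moving along
    ``phi_i``.
    """

    def __init__(self, module_id: int, n_inputs: int, *, n_ac: int = N_AC_DEFAULT,
                 eta: float = 0.05, gamma: float = 0.9,
                 rng: np.random.Generator | None = None, init_scale: float = 0.01):
        self.id = module_id
        self.n_ac = n_ac
        self.eta = eta
        self.gamma = gamma
        rng = rng or np.random.default_rng(0)
        self.W = rng.random((n_ac, n_inputs)) * init_scale
        self.phi = TWO_PI * np.arange(n_ac) / n_ac

    def nearest_ac(self, orientation: float) -> int:
        """Index of the action cell angularly nearest an orientation.

        Ties (orientation exactly between two cells) break to the lowest index.
        """
        d = np.abs((self.phi - orientation + math.pi) % TWO_PI - math.pi)
        return int(np.argmin(d))


def ac_activations(module: MFModule, inputs: np.ndarray) -> np.ndarray:
    if inputs.shape[0] != module.W.shape[1]:
        raise ValueError(
            f"dimension mismatch: W {module.W.shape} vs input {inputs.shape}")
    return module.W @ inputs


def mf_propose(module: MFModule, inputs: np.ndarray,
               activations: np.ndarray | None = None) -> Proposal:
    """Greedy proposal: the preferred orientation of the argmax action cell."""
    a = activations if activations is not None else ac_activations(module, inputs)
    return Proposal(module_id=module.id, orientation=float(module.phi[int(np.argmax(a))]))


def mf_update(module: MFModule, input_t: np.ndarray, executed_orientation: float,
              reward: float, input_next: np.ndarray | None, terminal: bool,
              *, a_t: np.ndarray | None = None,
              a_next: np.ndarray | None = None) -> float:
    """One TD Q-learning step on the row of the executed action cell.

    delta = R + gamma * max_i a_i(next) * [not terminal] - a_{i*}(t); only the
    row of the action cell nearest the executed orientation changes.  Returns
    delta.  Precomputed activations may be passed to avoid recomputation.
    """
    i = module.nearest_ac(executed_orientation)
    if a_t is None:
        a_t = ac_activations(module, input_t)
    if terminal:
        bootstrap = 0.0
    else:
        if a_next is None:
            a_next = ac_activations(module, input_next)
        bootstrap = module.gamma * float(np.max(a_next))
    delta = reward + bootstrap - float(a_t[i])
    module.W[i] += module.eta * delta * input_t
    return delta


# ---------------------------------------------------------------------------
# Planning
# ---------------------------------------------------------------------------

def planning_propagate(graph: PlanningGraph) -> PlanningGraph:
    """Activation diffusion of the goal value over the graph (in place).

    The goal node gets value 1; iterating ``G_i <- alpha * max_neighbor G``
    to its fixpoint leaves every node with ``alpha`` raised to its unweighted
    graph distance from the goal, and 0 on unreachable nodes.
    """
    if graph.goal_node is None:
        raise ValueError("no goal set on the planning graph")
    n = graph.n_nodes
    G = np.zeros(n)
    G[graph.goal_node] = 1.0
    A = graph.adjacency
    alpha = graph.alpha
    while True:
        neigh = np.where(A, G[None, :], 0.0).max(axis=1)
        cand = np.maximum(G, alpha * neigh)
        cand[graph.goal_node] = 1.0
        if np.array_equal(cand, G):
            break
        G = cand
    graph.G = G
    _cache_proposals(graph)
    return graph


def _cache_proposals(graph: PlanningGraph) -> None:
    """Precompute each node's proposal (orientation, validity) for the
    current goal-value field, so the per-timestep lookup is O(1)."""
    n = graph.n_nodes
    ori = np.zeros(n)
    valid = np.zeros(n, dtype=bool)
    target = np.zeros((n, 2))
    gx, gy = graph.goal_position if graph.goal_position else (0.0, 0.0)
    for node in range(n):
        cx, cy = graph.centroids[node]
        if node == graph.goal_node:
            ori[node] = wrap_angle(math.atan2(gy - cy, gx - cx))
            valid[node] = not (math.isnan(cx) or math.isnan(cy))
            target[node] = (gx, gy)
            continue
        neighbors = np.nonzero(graph.adjacency[node])[0]
        if neighbors.size == 0:
            continue
        best = neighbors[int(np.argmax(graph.G[neighbors]))]
        bx, by = graph.centroids[best]
        if math.isnan(cx) or math.isnan(bx):
            continue
        ori[node] = wrap_angle(math.atan2(by - cy, bx - cx))
        valid[node] = True
        target[node] = (bx, by)
    graph.prop_orientation = ori
    graph.prop_valid = valid
    graph.prop_target = target


def planning_set_goal(graph: PlanningGraph, node: int,
                      position: tuple[float, float]) -> PlanningGraph:
    """Declare the goal at a node and repropagate; any prior goal is replaced."""
    if not (0 <= node < graph.n_nodes):
        raise KeyError(f"unknown node {node}")
    graph.goal_node = int(node)
    graph.goal_position = (float(position[0]), float(position[1]))
    return planning_propagate(graph)


def planning_propose(graph: PlanningGraph, node: int, module_id: int = -1,
                     position: tuple[float, float] | None = None) -> Proposal:
    """Direction of the first step of the best plan from ``node``.

    Invalid before any goal is known, and at a neighborless non-goal node.
    At the goal node the proposal points at the memorized goal position; else
    toward the centroid of the neighbor with the largest goal value (ties to
    the lowest node id).  The direction is taken from ``position`` when the
    caller supplies the agent's actual location (the trial loop does: aiming
    from where the agent really is avoids oscillation at field boundaries),
    and from the node centroid otherwise.
    """
    if graph.goal_node is None:
        return Proposal(module_id=module_id, valid=False)
    cached = getattr(graph, "prop_valid", None)
    if cached is None:
        _cache_proposals(graph)
    if not graph.prop_valid[node]:
        return Proposal(module_id=module_id, valid=False)
    if position is not None:
        tx, ty = graph.prop_target[node]
        return Proposal(module_id=module_id,
                        orientation=wrap_angle(math.atan2(ty - position[1],
                                                          tx - position[0])))
    return Proposal(module_id=module_id,
                    orientation=float(graph.prop_orientation[node]))


# ---------------------------------------------------------------------------
# Exploration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExplorationState:
    """Persistence bookkeeping: a drawn orientation is reused for three
    consecutive executed steps before a new draw."""

    orientation: float | None = None
    steps_remaining: int = 0


def exploration_propose(state: ExplorationState,
                        rng: np.random.Generator,
                        module_id: int = -1) -> tuple[Proposal, ExplorationState]:
    """Propose a random (or persisted) orientation.

    A fresh draw is uniform on [0, 2pi) and arms two further persistence
    steps; the returned state must only be committed by the caller when the
    Exploration module is actually the executed one.
    """
    if state.steps_remaining > 0:
        new_state = ExplorationState(state.orientation, state.steps_remaining - 1)
        return Proposal(module_id=module_id, orientation=state.orientation), new_state
    phi = float(rng.uniform(0.0, TWO_PI))
    return (Proposal(module_id=module_id, orientation=phi),
            ExplorationState(phi, 2))
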