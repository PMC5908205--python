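"""Hebbian place-cell learning and the topological planning graph.

The map is learned off-line, before any rewarded trial, from a random walk:

1. a pool of place cells (default 1000) learns by competitive Hebbian updates
   on the entorhinal input (grid + cue cells) while the agent wanders;
2. a sparser pool of graph cells (default 100) learns, by the same rule, from
   the place-cell activities;
3. the walk is replayed and an edge is added between every pair of
   consecutive distinct winning graph cells -- two nodes are linked exactly
   when the agent moved between the locations they represent without a third
   winner in between.

Nothing in this module reads reward: the map is reward-independent, which is
what makes one-trial goal relocation possible downstream (only the goal value
field on the graph changes when the platform moves).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arena import Maze, Pose
from .perception import PerceptionState


@dataclass
class MapParams:
    n_place_cells: int = 1000
    n_graph_cells: int = 100
    k_winners_pc: int = 10       # competitive Hebbian winners per update
    k_winners_gc: int = 1        # single winner: online k-means-like node tuning
    rate_pc: float = 0.2
    rate_gc: float = 0.2
    #: exponent sharpening the divisively normalized activities; >1 makes
    #: place fields sparser/more localized
    sharpness: float = 12.0
    #: population sparseness: only the k most active place cells stay active
    n_active_pc: int = 50


def hebbian_update(W: np.ndarray, pre: np.ndarray, post: np.ndarray,
                   rate: float, k: int = 10) -> np.ndarray:
    """Competitive Hebbian update, in place.

    The ``k`` most active post cells get ``dW_ij = rate * post_i * pre_j`` and
    their rows are renormalized to unit norm; other rows are untouched.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if W.shape != (post.shape[0], pre.shape[0]):
        raise ValueError(
            f"dimension mismatch: W {W.shape} vs post {post.shape}, pre {pre.shape}")
    if rate == 0.0:
        return W
    k = min(k, W.shape[0])
    idx = np.argpartition(post, -k)[-k:]
    W[idx] += rate * post[idx, None] * pre[None, :]
    norms = np.linalg.norm(W[idx], axis=1)
    norms[norms == 0.0] = 1.0
    W[idx] /= norms[:, None]
    return W


def _normalized_activity(raw: np.ndarray, sharpness: float,
                         topk: int | None = None) -> np.ndarray:
    """Rectify, divide by the maximum, sharpen, and (optionally) silence all
    but the ``topk`` most active cells; output in [0, 1]."""
    a = np.maximum(raw, 0.0)
    m = a.max()
    if m <= 0.0:
        return a
    a = a / m
    if sharpness != 1.0:
        a **= sharpness
    if topk is not None and topk < a.shape[0]:
        thr = np.partition(a, -topk)[-topk]
        a[a < thr] = 0.0
    return a


class PlaceCellPopulation:
    """Place cells: unit-norm weight rows over the EC input.

    The activation rule is a rectified weighted sum, divisively normalized by
    the population maximum, with a sharpening exponent and k-winner
    population sparseness that make the fields localized (the dentate code
    the rest of the model assumes is sparse).
    """

    def __init__(self, W: np.ndarray, sharpness: float = 12.0,
                 n_active: int | None = 50):
        self.W = W
        self.sharpness = sharpness
        self.n_active = n_active
        self.field_centers: np.ndarray | None = None  # (n_pc, 2)

    @property
    def n_cells(self) -> int:
        return self.W.shape[0]

    def activity(self, ec: np.ndarray) -> np.ndarray:
        return _normalized_activity(self.W @ ec, self.sharpness, self.n_active)


def _random_unit_rows(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    W = rng.random(shape)
    W /= np.linalg.norm(W, axis=1, keepdims=True)
    return W


def _imprint_rows(rng: np.random.Generator, patterns: np.ndarray,
                  n_rows: int) -> np.ndarray:
    """Initial weights imprinted from randomly chosen input patterns.

    Each row is a (seeded) random sample of the observed presynaptic activity,
    normalized to unit norm -- the data-driven analogue of random
    initialization that guarantees the competitive layer covers the explored
    space instead of collapsing onto a handful of globally tuned cells.
    """
    idx = rng.choice(patterns.shape[0], size=n_rows, replace=True)
    W = patterns[idx].astype(float).copy()
    norms = np.linalg.norm(W, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    return W / norms


def learn_place_cells(walk: list[Pose], maze: Maze, params: MapParams,
                      seed: int | np.random.Generator,
                      perception: PerceptionState | None = None) -> PlaceCellPopulation:
    """Train the place-cell pool along a walk.

    Weights are randomly initialized from ``seed``; a competitive Hebbian
    update is applied at every walk step with the EC input as presynaptic and
    the place-cell activity as postsynaptic term.  Field centres are estimated
    as activity-weighted means of the visited positions.
    """
    if len(walk) == 0:
        raise ValueError("walk must be nonempty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    P = perception or PerceptionState(maze)
    # proximal cues are masked out of the map pathway: the corresponding
    # weight columns stay zero, so the learned fields are anchored on the
    # idiothetic and distal-cue frame only
    ec_all = np.stack([P.ec_input(p).copy() for p in walk]) * P.map_mask
    W = _imprint_rows(rng, ec_all, params.n_place_cells)
    pop = PlaceCellPopulation(W, sharpness=params.sharpness,
                              n_active=params.n_active_pc)
    wsum = np.zeros(params.n_place_cells)
    wpos = np.zeros((params.n_place_cells, 2))
    for ec, pose in zip(ec_all, walk):
        act = pop.activity(ec)
        hebbian_update(W, ec, act, params.rate_pc, k=params.k_winners_pc)
        wsum += act
        wpos += act[:, None] * np.array([pose.x, pose.y])
    with np.errstate(invalid="ignore", divide="ignore"):
        pop.field_centers = np.where(wsum[:, None] > 0, wpos / wsum[:, None], np.nan)
    return pop


@dataclass
class PlanningGraph:
    """Sparse topological graph over graph cells.

    ``G`` holds the goal-value field produced by activation diffusion: the
    goal node has value 1 and every other node ``alpha`` raised to its graph
    distance from the goal (0 if unreachable).
    """

    W: np.ndarray                   # (n_gc, n_pc) unit-norm rows
    centroids: np.ndarray           # (n_gc, 2); NaN for never-winning nodes
    adjacency: np.ndarray           # (n_gc, n_gc) bool, symmetric, irreflexive
    alpha: float = 0.9
    goal_node: int | None = None
    goal_position: tuple[float, float] | None = None
    G: np.ndarray = field(default=None)  # type: ignore[assignment]
    sharpness: float = 1.0

    def __post_init__(self) -> None:
        if self.G is None:
            self.G = np.zeros(self.W.shape[0])

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    def node_activity(self, pc_activity: np.ndarray) -> np.ndarray:
        return _normalized_activity(self.W @ pc_activity, self.sharpness)

    def edges(self) -> list[tuple[int, int]]:
        ii, jj = np.nonzero(np.triu(self.adjacency))
        return list(zip(ii.tolist(), jj.tolist()))


def learn_graph(pc_pop: PlaceCellPopulation, walk: list[Pose],
                params: MapParams | None = None,
                seed: int | np.random.Generator = 0,
                perception: PerceptionState | None = None,
                maze: Maze | None = None,
                pc_acts: np.ndarray | None = None) -> PlanningGraph:
    """Learn graph-cell weights along the walk, then extract nodes and edges.

    ``pc_acts`` may supply precomputed place-cell activities (one row per walk
    step); otherwise they are computed from ``perception``.
    """
    params = params or MapParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if pc_acts is None:
        if perception is None:
            perception = PerceptionState(maze)
        pc_acts = np.stack([pc_pop.activity(perception.ec_input(p)) for p in walk])
    W = _imprint_rows(rng, pc_acts, params.n_graph_cells)
    graph = PlanningGraph(W=W, centroids=np.full((params.n_graph_cells, 2), np.nan),
                          adjacency=np.zeros((params.n_graph_cells,) * 2, dtype=bool))
    for act in pc_acts:
        g = graph.node_activity(act)
        hebbian_update(W, act, g, params.rate_gc, k=params.k_winners_gc)
    # replay: winner per step, consecutive-distinct-winner edges, centroids
    raw = pc_acts @ W.T                                    # (n_steps, n_gc)
    winners = np.argmax(raw, axis=1)
    xy = np.array([[p.x, p.y] for p in walk])
    wact = raw[np.arange(len(walk)), winners]
    wsum = np.zeros(params.n_graph_cells)
    wpos = np.zeros((params.n_graph_cells, 2))
    np.add.at(wsum, winners, wact)
    np.add.at(wpos, winners, wact[:, None] * xy)
    seen = wsum > 0
    graph.centroids[seen] = wpos[seen] / wsum[seen, None]
    for a, b in zip(winners[:-1], winners[1:]):
        if a != b:
            graph.adjacency[a, b] = True
            graph.adjacency[b, a] = True
    return graph


def dump_graph(graph: PlanningGraph, path) -> None:
    """Write the learned graph as a plain-text file for inspection:
    one ``node x y G`` line per node (NaN centroids for nodes that never won)
    followed by one ``edge i j`` line per undirected edge."""
    with open(path, "w") as fh:
        fh.write("# node id x y G\n")
        for i in range(graph.n_nodes):
            x, y = graph.centroids[i]
            fh.write(f"node {i} {x:.3f} {y:.3f} {graph.G[i]:.6f}\n")
        fh.write("# edge i j\n")
        for a, b in graph.edges():
            fh.write(f"edge {a} {b}\n")


def current_node(graph: PlanningGraph, pc_activity: np.ndarray) -> int:
    """Most active graph cell; ties broken by lowest node id."""
    if not np.any(pc_activity):
        raise ValueError("all-zero place-cell activity: agent is unlocalized")
    return int(np.argmax(graph.W @ pc_activity))
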