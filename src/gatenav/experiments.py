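"""The six water-maze protocols, group composition, and the simulation loop.

Six classic protocols are generated procedurally (no external data):

I   reference memory: hidden stable platform, distal cues only;
II  delayed matching to place: hidden platform moved every 4-trial session;
III cue/place competition: cued stable platform, cue hidden on trials 3, 6, 9,
    platform and cue moved to the opposite position on competition trial 10;
IV  gradual competition: platform moved every session, a proximal cue held at
    a constant offset from it;
V   generalization gradient: two training stages with proximal cue B on the
    platform near distal cue F, then probe trials with B rotated by
    0/45/90/135 degrees (gradient) or absent (extinction);
VI  blocking: platform cued by proximal cue A and moved per session or per
    trial (Stage 1), fixed and cued by A ("Same") or a novel cue B ("Diff")
    (Stage 2), then a cue-less, platform-less test trial (Stage 3).

Agents move 6 cm per timestep, trials are capped at 350 timesteps, and a
failed trial ends with a guided return to the platform (learning updates keep
running en route, which is what plants the planning goal the first time).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .arena import (Maze, Pose, CueSpec, PlatformSpec, Region, move_agent,
                    on_platform, in_region, STEP_CM, TWO_PI, wrap_angle)
from .perception import PerceptionState, PerceptionParams
from .cognitive_map import (MapParams, PlaceCellPopulation, PlanningGraph,
                            learn_place_cells, learn_graph, current_node)
from .strategies import (MFModule, Proposal, ExplorationState, ac_activations,
                         mf_propose, mf_update, planning_propose,
                         planning_set_goal, exploration_propose, N_AC_DEFAULT)
from .gating import (GatingNetwork, gating_values, select_module, gating_update,
                     KIND_DIRECTION, KIND_PLANNING, KIND_LOCALE, KIND_EXPLORATION)

MAX_STEPS = 350
PRETRAIN_STEPS = 1000

EXPERIMENTS = ("I", "II", "III", "IV", "V", "VI")
GROUPS = ("D", "P", "L", "DP", "DL", "chance")

#: the two per-experiment free parameters: (Direction learning rate,
#: gating learning rate); every other parameter is shared across experiments
DEFAULT_RATES: dict[str, tuple[float, float]] = {
    "I": (0.10, 0.30),
    "II": (0.10, 0.30),
    "III": (1.20, 0.20),
    "IV": (0.35, 0.20),
    "V": (0.30, 0.10),
    "VI": (0.03, 0.30),
}

#: per-experiment gating discount (environment-dependent, like the paper's
#: per-experiment parameter table): the blocking protocol needs the longer
#: value horizon for goal-directed pool crossing in its probe trial
DEFAULT_GATING_GAMMA: dict[str, float] = {"VI": 0.95}


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

@dataclass
class TrialSpec:
    session: int                 # 1-based
    trial: int                   # 1-based within session
    index: int                   # 0-based global
    tag: str                     # escape|hidden-cue|competition|gradient|extinction|test
    start: tuple[float, float]
    platform_center: tuple[float, float] | None
    platform_present: bool
    cue_visibility: dict[str, bool] = field(default_factory=dict)
    cue_positions: dict[str, tuple[float, float]] = field(default_factory=dict)
    gradient_angle: float | None = None   # degrees, gradient trials only


@dataclass
class ExperimentProtocol:
    id: str
    condition: str
    maze: Maze
    trials: list[TrialSpec]
    #: stage-2 platform angle (Exp VI) / octant references (Exp V), for analyses
    meta: dict = field(default_factory=dict)


@dataclass
class ProtocolParams:
    """Config-overridable protocol lengths."""

    exp1_n_trials: int = 20
    exp2_n_sessions: int = 9
    exp4_n_sessions: int = 11
    start_radius: float = 85.0
    slot_radius: float = 50.0


def _wall_starts(radius: float) -> list[tuple[float, float]]:
    return [(radius * math.cos(a), radius * math.sin(a))
            for a in (0.0, math.pi / 2, math.pi, 3 * math.pi / 2)]


def _start_sequence(rng: np.random.Generator, n: int,
                    radius: float) -> list[tuple[float, float]]:
    """Pseudo-randomized starts: balanced shuffled blocks of the 4 wall points."""
    pts = _wall_starts(radius)
    seq: list[tuple[float, float]] = []
    while len(seq) < n:
        order = rng.permutation(4)
        seq.extend(pts[i] for i in order)
    return seq[:n]


def _distal_ring(angles_deg: tuple[float, ...], radius: float = 120.0) -> list[CueSpec]:
    return [CueSpec(id=f"d{i+1}", kind="distal",
                    position=(radius * math.cos(math.radians(a)),
                              radius * math.sin(math.radians(a))))
            for i, a in enumerate(angles_deg)]


def _slots(n: int, radius: float) -> list[tuple[float, float]]:
    return [(radius * math.cos(math.radians(22.5 + i * 45.0)),
             radius * math.sin(math.radians(22.5 + i * 45.0))) for i in range(n)]


def _slot_walk(rng: np.random.Generator, n: int, slots: list) -> list:
    """Seeded slot sequence with no immediate repeats."""
    out = [slots[rng.integers(len(slots))]]
    while len(out) < n:
        c = slots[rng.integers(len(slots))]
        if c != out[-1]:
            out.append(c)
    return out


def build_protocol(exp_id: str, condition: str = "",
                   seed: int | np.random.Generator = 0,
                   params: ProtocolParams | None = None) -> ExperimentProtocol:
    """Build the deterministic trial list of one experiment.

    ``condition`` is required for Experiment VI (one of Session-Same,
    Session-Diff, Trial-Same, Trial-Diff) and ignored elsewhere.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pp = params or ProtocolParams()
    if exp_id == "I":
        return _protocol_I(rng, pp)
    if exp_id == "II":
        return _protocol_II(rng, pp)
    if exp_id == "III":
        return _protocol_III(rng, pp)
    if exp_id == "IV":
        return _protocol_IV(rng, pp)
    if exp_id == "V":
        return _protocol_V(rng, pp)
    if exp_id == "VI":
        return _protocol_VI(rng, pp, condition)
    raise ValueError(f"unknown experiment id {exp_id!r}")


def _protocol_I(rng, pp) -> ExperimentProtocol:
    maze = Maze(cues=_distal_ring((45, 135, 225, 315)),
                platform=PlatformSpec(center=(50 * math.cos(math.radians(45)),
                                              50 * math.sin(math.radians(45)))))
    center = maze.platform.center
    n = pp.exp1_n_trials
    starts = _start_sequence(rng, n, pp.start_radius)
    trials = [TrialSpec(session=i // 4 + 1, trial=i % 4 + 1, index=i, tag="escape",
                        start=starts[i], platform_center=center, platform_present=True)
              for i in range(n)]
    return ExperimentProtocol("I", "", maze, trials)


def _protocol_II(rng, pp) -> ExperimentProtocol:
    maze = Maze(cues=_distal_ring((45, 135, 225, 315)))
    slots = _slots(8, pp.slot_radius)
    centers = _slot_walk(rng, pp.exp2_n_sessions, slots)
    n = pp.exp2_n_sessions * 4
    starts = _start_sequence(rng, n, pp.start_radius)
    trials = [TrialSpec(session=i // 4 + 1, trial=i % 4 + 1, index=i, tag="escape",
                        start=starts[i], platform_center=centers[i // 4],
                        platform_present=True)
              for i in range(n)]
    return ExperimentProtocol("II", "", maze, trials)


def _protocol_III(rng, pp) -> ExperimentProtocol:
    cues = _distal_ring((45, 135, 225, 315))
    cues.append(CueSpec(id="c", kind="proximal", position=(0, 0),
                        platform_offset=(0.0, 0.0)))
    c0 = (pp.slot_radius * math.cos(math.radians(45)),
          pp.slot_radius * math.sin(math.radians(45)))
    c_opp = (-c0[0], -c0[1])
    maze = Maze(cues=cues, platform=PlatformSpec(center=c0, cued=True))
    starts = _start_sequence(rng, 10, pp.start_radius)
    hidden = {3, 6, 9}
    trials = []
    for i in range(10):
        t = i + 1
        tag = "competition" if t == 10 else ("hidden-cue" if t in hidden else "escape")
        trials.append(TrialSpec(
            session=1, trial=t, index=i, tag=tag, start=starts[i],
            platform_center=c_opp if t == 10 else c0, platform_present=True,
            cue_visibility={"c": t not in hidden}))
    return ExperimentProtocol("III", "", maze, trials,
                              meta={"old_platform": c0, "new_platform": c_opp})


def _protocol_IV(rng, pp) -> ExperimentProtocol:
    cues = _distal_ring((45, 135, 225, 315))
    cues.append(CueSpec(id="c", kind="proximal", position=(0, 0),
                        platform_offset=(0.0, 4.0)))
    maze = Maze(cues=cues)
    slots = _slots(8, pp.slot_radius)
    centers = _slot_walk(rng, pp.exp4_n_sessions, slots)
    n = pp.exp4_n_sessions * 4
    starts = _start_sequence(rng, n, pp.start_radius)
    trials = [TrialSpec(session=i // 4 + 1, trial=i % 4 + 1, index=i, tag="escape",
                        start=starts[i], platform_center=centers[i // 4],
                        platform_present=True)
              for i in range(n)]
    return ExperimentProtocol("IV", "", maze, trials)


def _protocol_V(rng, pp) -> ExperimentProtocol:
    f_angle = math.pi / 2
    cues = [CueSpec(id="F", kind="distal",
                    position=(120 * math.cos(f_angle), 120 * math.sin(f_angle))),
            CueSpec(id="B", kind="proximal", position=(0, 0),
                    platform_offset=(0.0, 0.0))]
    p_angle = f_angle - math.radians(15.0)     # platform offset from F's octant
    platform = (60 * math.cos(p_angle), 60 * math.sin(p_angle))
    maze = Maze(cues=cues, platform=PlatformSpec(center=platform, cued=True))
    rot_dir = 1.0 if rng.random() < 0.5 else -1.0
    angles = list(rng.permutation([0.0, 45.0, 90.0, 135.0]))
    angles.append(float(rng.choice([0.0, 45.0, 90.0, 135.0])))
    n_total = 4 * 8 + 10 * 9
    starts = iter(_start_sequence(rng, n_total, pp.start_radius))
    trials: list[TrialSpec] = []
    idx = 0
    grad_i = 0
    for sess in range(1, 5):            # Stage 1: 4 sessions x 8 escape trials
        for t in range(1, 9):
            trials.append(TrialSpec(session=sess, trial=t, index=idx, tag="escape",
                                    start=next(starts), platform_center=platform,
                                    platform_present=True,
                                    cue_visibility={"B": True, "F": True}))
            idx += 1
    for s2 in range(1, 11):             # Stage 2: 10 sessions x (8 escape + 1 probe)
        sess = 4 + s2
        for t in range(1, 9):
            trials.append(TrialSpec(session=sess, trial=t, index=idx, tag="escape",
                                    start=next(starts), platform_center=platform,
                                    platform_present=True,
                                    cue_visibility={"B": True, "F": True}))
            idx += 1
        # probe trials start at the wall opposite the platform so that no
        # rotated B octant contains the release point
        probe_start = (pp.start_radius * math.cos(p_angle + math.pi),
                       pp.start_radius * math.sin(p_angle + math.pi))
        if s2 % 2 == 0:                 # gradient trial: B rotated, no platform
            ang = angles[grad_i]
            grad_i += 1
            rot = math.radians(rot_dir * ang)
            bpos = (60 * math.cos(p_angle + rot), 60 * math.sin(p_angle + rot))
            trials.append(TrialSpec(session=sess, trial=9, index=idx, tag="gradient",
                                    start=probe_start, platform_center=None,
                                    platform_present=False,
                                    cue_visibility={"B": True, "F": True},
                                    cue_positions={"B": bpos}, gradient_angle=ang))
        else:                           # extinction trial: F only, no platform
            trials.append(TrialSpec(session=sess, trial=9, index=idx, tag="extinction",
                                    start=probe_start, platform_center=None,
                                    platform_present=False,
                                    cue_visibility={"B": False, "F": True}))
        idx += 1
    return ExperimentProtocol("V", "", maze, trials,
                              meta={"f_angle": f_angle, "b_angle": p_angle,
                                    "rot_dir": rot_dir})


def _protocol_VI(rng, pp, condition: str) -> ExperimentProtocol:
    valid = {"Session-Same", "Session-Diff", "Trial-Same", "Trial-Diff"}
    if condition not in valid:
        raise ValueError(f"Experiment VI condition must be one of {sorted(valid)}")
    per_trial = condition.startswith("Trial")
    same = condition.endswith("Same")
    cues = _distal_ring((0, 90, 180, 270))
    cues.append(CueSpec(id="A", kind="proximal", position=(0, 0),
                        platform_offset=(0.0, 0.0), visible=True))
    cues.append(CueSpec(id="B", kind="proximal", position=(0, 0),
                        platform_offset=(0.0, 0.0), visible=False))
    maze = Maze(cues=cues)
    slots = _slots(8, pp.slot_radius)
    stage2_center = slots[0]
    n_total = 12 * 4 + 3 * 4 + 1
    starts = iter(_start_sequence(rng, n_total, pp.start_radius))
    trials: list[TrialSpec] = []
    idx = 0
    if per_trial:
        stage1_centers = _slot_walk(rng, 12 * 4, slots)
    else:
        per_session = _slot_walk(rng, 12, slots)
        stage1_centers = [per_session[i // 4] for i in range(12 * 4)]
    for i in range(12 * 4):             # Stage 1
        trials.append(TrialSpec(session=i // 4 + 1, trial=i % 4 + 1, index=idx,
                                tag="escape", start=next(starts),
                                platform_center=stage1_centers[i],
                                platform_present=True,
                                cue_visibility={"A": True, "B": False}))
        idx += 1
    for i in range(3 * 4):              # Stage 2: sessions 13-15, fixed platform
        vis = {"A": True, "B": False} if same else {"A": False, "B": True}
        trials.append(TrialSpec(session=13 + i // 4, trial=i % 4 + 1, index=idx,
                                tag="escape", start=next(starts),
                                platform_center=stage2_center,
                                platform_present=True, cue_visibility=vis))
        idx += 1
    # the probe runs from the wall opposite the trained platform, outside
    # the goal quadrant, so occupancy is not confounded by the release point
    goal_angle = math.atan2(stage2_center[1], stage2_center[0])
    probe_start = (pp.start_radius * math.cos(goal_angle + math.pi),
                   pp.start_radius * math.sin(goal_angle + math.pi))
    trials.append(TrialSpec(session=16, trial=1, index=idx, tag="test",
                            start=probe_start, platform_center=None,
                            platform_present=False,
                            cue_visibility={"A": False, "B": False}))
    return ExperimentProtocol("VI", condition, maze, trials,
                              meta={"stage2_center": stage2_center,
                                    "goal_angle": math.atan2(stage2_center[1],
                                                             stage2_center[0])})


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------

@dataclass
class StrategyParams:
    n_ac: int = N_AC_DEFAULT
    eta_direction: float = 0.05
    eta_locale: float = 0.3
    gamma: float = 0.9
    alpha: float = 0.9          # planning devaluation factor
    init_scale: float = 0.01
    eta_gating: float = 0.05
    gamma_gating: float = 0.9
    gating_bootstrap: str = "max"      # "max" or "selected" TD target
    gating_init_scale: float = 0.5


class NavigationModel:
    """One simulated agent: perception, optional cognitive map, behavioral
    modules and the gating network, wired for one maze."""

    def __init__(self, maze: Maze, perception: PerceptionState, group: str,
                 sparams: StrategyParams, rng: np.random.Generator,
                 pc_pop: PlaceCellPopulation | None = None,
                 graph: PlanningGraph | None = None):
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        self.maze = maze
        self.perception = perception
        self.group = group
        self.params = sparams
        self.rng = rng
        self.pc_pop = pc_pop
        self.graph = graph
        if graph is not None:
            graph.alpha = sparams.alpha

        kinds: list[str] = []
        names: list[str] = []
        self.mf_modules: list[MFModule] = []
        self.mf_sources: list[tuple[str, str]] = []   # ("cue", id) or ("pc", "")

        def add_direction(cue_id: str) -> None:
            m = MFModule(len(kinds), perception.params.n_cc_per_cue,
                         n_ac=sparams.n_ac, eta=sparams.eta_direction,
                         gamma=sparams.gamma, rng=rng,
                         init_scale=sparams.init_scale)
            self.mf_modules.append(m)
            self.mf_sources.append(("cue", cue_id))
            kinds.append(KIND_DIRECTION)
            names.append(f"D:{cue_id}")

        if group == "D":
            for c in maze.cues:
                add_direction(c.id)
        elif group in ("DP", "DL"):
            # proximal cues only; with none (Exps I/II) the composition is
            # effectively spatial module + exploration
            for c in maze.cues:
                if c.kind == "proximal":
                    add_direction(c.id)
        if group in ("P", "DP"):
            if graph is None:
                raise ValueError("Planning groups need a trained planning graph")
            self.planning_index = len(kinds)
            kinds.append(KIND_PLANNING)
            names.append("P")
        else:
            self.planning_index = None
        if group in ("L", "DL"):
            if pc_pop is None:
                raise ValueError("Locale groups need a trained place-cell pool")
            m = MFModule(len(kinds), pc_pop.n_cells, n_ac=sparams.n_ac,
                         eta=sparams.eta_locale, gamma=sparams.gamma, rng=rng,
                         init_scale=sparams.init_scale)
            self.mf_modules.append(m)
            self.mf_sources.append(("pc", ""))
            kinds.append(KIND_LOCALE)
            names.append("L")
        self.exploration_index = len(kinds)
        kinds.append(KIND_EXPLORATION)
        names.append("E")

        self.kinds = kinds
        self.names = names
        # fixed input scales: peak cue-ring norm (all distance sub-rings at
        # full strength) and peak sparse place-code norm
        d = np.abs((perception._pref - perception._pref[0] + math.pi)
                   % TWO_PI - math.pi)
        ring = np.exp(-d * d / (2.0 * perception.params.sigma ** 2))
        self._cue_scale = 1.0 / math.sqrt(float(ring @ ring))
        n_act = (pc_pop.n_active if pc_pop is not None and pc_pop.n_active
                 else 1)
        self._pc_scale = 1.0 / math.sqrt(float(n_act))
        self.uses_map = pc_pop is not None
        n_gate = perception.n_cc + (graph.n_nodes if graph is not None else
                                    (pc_pop.n_cells if pc_pop is not None else 0))
        # gating input: cue cells (+) planning-graph node activities when a
        # graph exists ((+) place cells for map-without-graph variants)
        self.gating = GatingNetwork(kinds, n_gate, eta=sparams.eta_gating,
                                    gamma=sparams.gamma_gating,
                                    bootstrap=sparams.gating_bootstrap, rng=rng,
                                    init_scale=sparams.gating_init_scale)
        self.explo_state = ExplorationState()

    @property
    def n_modules(self) -> int:
        return len(self.kinds)

    def module_input(self, src: tuple[str, str], cc: np.ndarray,
                     pc: np.ndarray | None) -> np.ndarray:
        """A module's input population activity, scaled by a fixed constant.

        Each module's input is divided by the peak norm its population can
        reach, so the TD step size of the Q-updates stays bounded
        (eta * ||r||^2 <= eta) while the natural attenuation with distance is
        preserved -- a far cue produces a scaled-down copy of the near
        pattern, which is what lets an approach policy learned close to the
        cue generalize to first sightings from afar.
        """
        if src[0] == "cue":
            return cc[self.perception.cc_slices[src[1]]] * self._cue_scale
        return pc * self._pc_scale

    def percepts(self, pose: Pose):
        """(cc, pc, current graph node, gating input) at a pose.

        The graph-cell activation is computed once: its argmax is the current
        node and its normalized form the PG part of the gating input.
        """
        P = self.perception
        ec = P.ec_input(pose)
        cc = P.cc_segment(ec).copy()
        node = None
        if self.pc_pop is not None:
            pc = self.pc_pop.activity(ec)
            if self.graph is not None:
                raw = self.graph.W @ pc
                m = raw.max()
                node = int(np.argmax(raw)) if m > 0 else None
                tail = raw / m if m > 0 else raw
            else:
                tail = pc
            r = np.concatenate([cc, tail])
        else:
            pc = None
            r = cc.copy()
        # unit-norm gating input keeps the TD updates of the gating network
        # stable (effective step size eta * ||r||^2 = eta)
        nrm = math.sqrt(float(r @ r))
        if nrm > 0.0:
            r /= nrm
        return cc, pc, node, r


def apply_group(protocol: ExperimentProtocol, group: str,
                sparams: StrategyParams, rng: np.random.Generator,
                perception_params: PerceptionParams | None = None,
                map_params: MapParams | None = None) -> NavigationModel:
    """Instantiate a model of the given composition for a protocol's maze,
    pre-training the cognitive map (1000-step random walk) when the group
    includes a spatial module."""
    maze = protocol.maze
    _apply_trial_to_maze(maze, protocol.trials[0])
    maze.platform.present = False
    perception = PerceptionState(maze, perception_params)
    pc_pop = graph = None
    if group in ("P", "DP", "L", "DL"):
        mp = map_params or MapParams()
        walk = random_walk(maze, PRETRAIN_STEPS, rng)
        perc_cache = [perception.ec_input(p) * perception.map_mask for p in walk]
        pc_pop = _learn_pc_from_cache(perc_cache, walk, mp, rng)
        pc_acts = np.stack([pc_pop.activity(e) for e in perc_cache])
        graph = learn_graph(pc_pop, walk, mp, rng, pc_acts=pc_acts)
    return NavigationModel(maze, perception, group, sparams, rng,
                           pc_pop=pc_pop, graph=graph)


def _learn_pc_from_cache(ec_cache, walk, mp: MapParams,
                         rng: np.random.Generator) -> PlaceCellPopulation:
    from .cognitive_map import hebbian_update, PlaceCellPopulation, _imprint_rows
    W = _imprint_rows(rng, np.stack(ec_cache), mp.n_place_cells)
    pop = PlaceCellPopulation(W, sharpness=mp.sharpness, n_active=mp.n_active_pc)
    wsum = np.zeros(mp.n_place_cells)
    wpos = np.zeros((mp.n_place_cells, 2))
    for ec, pose in zip(ec_cache, walk):
        act = pop.activity(ec)
        hebbian_update(W, ec, act, mp.rate_pc, k=mp.k_winners_pc)
        wsum += act
        wpos += act[:, None] * np.array([pose.x, pose.y])
    with np.errstate(invalid="ignore", divide="ignore"):
        pop.field_centers = np.where(wsum[:, None] > 0, wpos / wsum[:, None], np.nan)
    return pop


def random_walk(maze: Maze, n_steps: int, rng: np.random.Generator,
                persistence: int = 8) -> list[Pose]:
    """Persistent random walk used for map pre-training."""
    r0 = maze.max_agent_dist * math.sqrt(rng.random())
    a0 = rng.uniform(0, TWO_PI)
    pose = Pose(r0 * math.cos(a0), r0 * math.sin(a0))
    walk = [pose]
    while len(walk) < n_steps:
        phi = rng.uniform(0, TWO_PI)
        for _ in range(persistence):
            pose = move_agent(pose, phi, STEP_CM, maze)
            walk.append(pose)
            if len(walk) >= n_steps:
                break
    return walk


# ---------------------------------------------------------------------------
# Trial loop
# ---------------------------------------------------------------------------

@dataclass
class TrialRecord:
    session: int
    trial: int
    index: int
    tag: str
    start: tuple[float, float]
    xy: np.ndarray                # (n_steps, 2) positions after each free step
    selected: np.ndarray          # (n_steps,) module index
    latency: int                  # timesteps to platform, capped at MAX_STEPS
    rewarded: bool                # platform reached without guidance
    guided: bool                  # guided return used
    gradient_angle: float | None = None
    proposals: np.ndarray | None = None   # (n_steps, n_mod) orientations, optional
    proposal_valid: np.ndarray | None = None


def _apply_trial_to_maze(maze: Maze, spec: TrialSpec) -> None:
    if spec.platform_center is not None:
        maze.move_platform(spec.platform_center, present=spec.platform_present)
    else:
        maze.platform.present = False
    for cid, vis in spec.cue_visibility.items():
        maze.cue(cid).visible = vis
    for cid, pos in spec.cue_positions.items():
        maze.cue(cid).position = pos


def run_trial(model: NavigationModel, maze: Maze, spec: TrialSpec,
              rng: np.random.Generator, log_proposals: bool = False) -> TrialRecord:
    """Simulate one trial: perceive, propose, gate, move, learn.

    On reaching the platform the trial ends with the terminal reward update
    and (for Planning groups) the goal is planted at the current graph node.
    A trial that times out with a platform present ends with a guided
    straight-line return during which learning updates keep running.
    """
    _apply_trial_to_maze(maze, spec)
    model.perception.sync()
    pose = Pose(spec.start[0], spec.start[1])
    nmod = model.n_modules
    explo_idx = model.exploration_index

    xy = np.empty((MAX_STEPS, 2), dtype=np.float32)
    sel = np.empty(MAX_STEPS, dtype=np.int16)
    props = np.empty((MAX_STEPS, nmod), dtype=np.float32) if log_proposals else None
    pvalid = np.empty((MAX_STEPS, nmod), dtype=bool) if log_proposals else None

    if on_platform(pose, maze.platform):     # started on the platform
        return TrialRecord(spec.session, spec.trial, spec.index, spec.tag,
                           spec.start, xy[:0], sel[:0], 0, True, False,
                           spec.gradient_angle,
                           props[:0] if log_proposals else None,
                           pvalid[:0] if log_proposals else None)

    chance_only = nmod == 1                   # exploration only: fast path
    cc, pc, node, r = (None,) * 4
    if not chance_only:
        cc, pc, node, r = model.percepts(pose)

    n = 0
    rewarded = False
    for t in range(MAX_STEPS):
        if chance_only:
            prop, new_state = exploration_propose(model.explo_state, rng,
                                                  module_id=explo_idx)
            model.explo_state = new_state
            phi = prop.orientation
            winner = explo_idx
        else:
            proposals, mf_acts = _collect_proposals(model, cc, pc, node, rng, pose)
            g = gating_values(model.gating, r)
            outcome = select_module(model.gating, proposals, g, model.explo_state)
            winner = outcome.winner
            phi = outcome.executed_orientation
            if winner == explo_idx:
                model.explo_state = model._pending_explo
            else:
                model.explo_state = ExplorationState()
        pose = move_agent(pose, phi, STEP_CM, maze)
        reward = 1.0 if on_platform(pose, maze.platform) else 0.0
        terminal = reward > 0
        xy[n, 0] = pose.x
        xy[n, 1] = pose.y
        sel[n] = winner
        if log_proposals and not chance_only:
            for p in proposals:
                props[n, p.module_id] = p.orientation
                pvalid[n, p.module_id] = p.valid
        n += 1
        if not chance_only:
            cc2, pc2, node2, r2 = model.percepts(pose)
            _learn_step(model, cc, pc, cc2, pc2, r, r2, proposals, mf_acts,
                        phi, winner, reward, terminal, g)
            cc, pc, node, r = cc2, pc2, node2, r2
        if terminal:
            rewarded = True
            _plant_goal(model, node)
            break

    guided = False
    if not rewarded and maze.platform.present:
        guided = True
        _guided_return(model, maze, pose, rng, chance_only, cc, pc, node, r)

    latency = n if rewarded else MAX_STEPS
    return TrialRecord(spec.session, spec.trial, spec.index, spec.tag, spec.start,
                       xy[:n].copy(), sel[:n].copy(), latency, rewarded, guided,
                       spec.gradient_angle,
                       props[:n].copy() if log_proposals else None,
                       pvalid[:n].copy() if log_proposals else None)


def _collect_proposals(model: NavigationModel, cc, pc, node, rng, pose):
    proposals: list[Proposal] = []
    mf_acts: dict[int, np.ndarray] = {}
    for m, src in zip(model.mf_modules, model.mf_sources):
        inp = model.module_input(src, cc, pc)
        if not inp.any():
            # a module whose cue is invisible is blind: its action values all
            # read zero, so its orientation readout is noise (uniform random);
            # it stays in the competition with its learned gating value
            mf_acts[m.id] = None
            proposals.append(Proposal(module_id=m.id,
                                      orientation=float(rng.uniform(0.0, TWO_PI))))
            continue
        a = m.W @ inp
        mf_acts[m.id] = a
        proposals.append(Proposal(module_id=m.id,
                                  orientation=float(m.phi[int(np.argmax(a))])))
    if model.planning_index is not None:
        if node is None:
            raise ValueError("all-zero graph activation: agent is unlocalized")
        proposals.append(planning_propose(model.graph, node,
                                          module_id=model.planning_index,
                                          position=(pose.x, pose.y)))
    prop, pending = exploration_propose(model.explo_state, rng,
                                        module_id=model.exploration_index)
    model._pending_explo = pending
    proposals.append(prop)
    return proposals, mf_acts


def _learn_step(model, cc_t, pc_t, cc_next, pc_next, r_t, r_next,
                proposals, mf_acts, phi, winner, reward, terminal, g_t):
    for m, src in zip(model.mf_modules, model.mf_sources):
        if mf_acts[m.id] is None:
            continue                      # blind module: no experience to learn from
        inp_t = model.module_input(src, cc_t, pc_t)
        inp_next = None if terminal else model.module_input(src, cc_next, pc_next)
        mf_update(m, inp_t, phi, reward, inp_next, terminal, a_t=mf_acts[m.id])
    gating_update(model.gating, r_t, None if terminal else r_next, proposals,
                  phi, winner, reward, terminal, g_t=g_t)


def _plant_goal(model: NavigationModel, node: int | None) -> None:
    if model.planning_index is None or node is None:
        return
    planning_set_goal(model.graph, node, model.maze.platform.center)


def _guided_return(model, maze, pose, rng, chance_only, cc, pc, node, r):
    """Straight-line guidance to the platform with learning updates running."""
    target = maze.platform.center
    for _ in range(200):
        if on_platform(pose, maze.platform):
            break
        phi = wrap_angle(math.atan2(target[1] - pose.y, target[0] - pose.x))
        pose = move_agent(pose, phi, STEP_CM, maze)
        reward = 1.0 if on_platform(pose, maze.platform) else 0.0
        if chance_only:
            continue
        proposals, mf_acts = _collect_proposals(model, cc, pc, node, rng, pose)
        g = gating_values(model.gating, r)
        # no behavioral selection here; delta is computed on the module the
        # gating would have picked, the executed orientation is the guided one
        outcome = select_module(model.gating, proposals, g, ExplorationState())
        terminal = reward > 0
        cc2, pc2, node2, r2 = model.percepts(pose)
        _learn_step(model, cc, pc, cc2, pc2, r, r2, proposals, mf_acts,
                    phi, outcome.winner, reward, terminal, g)
        cc, pc, node, r = cc2, pc2, node2, r2
        if terminal:
            _plant_goal(model, node)
            break


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    experiment: str
    condition: str
    group: str
    master_seed: int
    module_names: list[str]
    module_kinds: list[str]
    records: list[list[TrialRecord]]   # [repeat][trial]
    protocol_meta: dict = field(default_factory=dict)

    @property
    def n_repeats(self) -> int:
        return len(self.records)


def run_experiment(experiment: str, group: str, master_seed: int, *,
                   condition: str = "", n_repeats: int = 50,
                   sparams: StrategyParams | None = None,
                   perception_params: PerceptionParams | None = None,
                   map_params: MapParams | None = None,
                   protocol_params: ProtocolParams | None = None,
                   log_proposals: bool = False) -> ExperimentResult:
    """Run one experiment x group: per repeat, fresh weights, fresh map
    pre-training, then all protocol trials in order.  Deterministic given
    ``master_seed``."""
    if experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment!r}")
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    if sparams is None:
        eta_d, eta_g = DEFAULT_RATES[experiment]
        sparams = StrategyParams(eta_direction=eta_d, eta_gating=eta_g,
                                 gamma_gating=DEFAULT_GATING_GAMMA.get(
                                     experiment, 0.9))
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n_repeats)
    all_records: list[list[TrialRecord]] = []
    names = kinds = None
    meta: dict = {}
    for child in children:
        rng = np.random.default_rng(child)
        protocol = build_protocol(experiment, condition, rng, protocol_params)
        model = apply_group(protocol, group, sparams, rng,
                            perception_params, map_params)
        names, kinds = model.names, model.kinds
        meta = protocol.meta
        records = [run_trial(model, protocol.maze, spec, rng, log_proposals)
                   for spec in protocol.trials]
        all_records.append(records)
    return ExperimentResult(experiment, condition, group, master_seed,
                            names, kinds, all_records, meta)
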