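"""Sensory populations: cue cells (visual) and grid cells (idiothetic).

The entorhinal input vector fed to the place-cell layer is the concatenation
of a grid-cell population (a deterministic, lattice-periodic function of the
true position -- path integration is assumed perfect) and one ring of
bearing-tuned cue cells per landmark.

Cue cell m of a cue's ring prefers allocentric bearing ``theta_m`` and
responds with a circular Gaussian tuning in bearing multiplied by an
exponential decay in distance::

    r_m = exp(-d(theta_m, bearing)^2 / (2 sigma^2)) * exp(-distance / lam_m)

A ring holds ``n_distance_scales`` copies of each bearing, each copy with its
own distance constant (a fraction of the cue kind's base constant), so that a
linear readout of the ring can express distance-dependent as well as purely
directional policies.  Distal cues use a long base constant so that they act
mostly as directional references; an invisible cue silences its whole ring.

Grid cells follow the standard three-plane-wave interference pattern: the sum
of three cosines of wave vectors 60 degrees apart, rectified into [0, 1].
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .arena import Maze, Pose, CueSpec, bearing_distance, TWO_PI


@dataclass
class PerceptionParams:
    n_cc_per_cue: int = 24             # bearings x distance scales per cue
    n_distance_scales: int = 2
    distance_scale_factors: tuple[float, ...] = (1.0, 0.25)
    sigma: float = math.pi / 4.0       # cue-cell bearing tuning width (rad)
    lambda_proximal: float = 100.0     # base distance constant, proximal (cm)
    lambda_distal: float = 150.0       # base distance constant, distal (cm)
    grid_scales: tuple[float, ...] = (60.0, 90.0, 130.0)
    grid_phases_per_scale: int = 9     # 3 x 3 phase offsets per scale
    grid_orientations: tuple[float, ...] = (0.0, 0.35, 0.7)

    @property
    def n_grid(self) -> int:
        return len(self.grid_scales) * self.grid_phases_per_scale


@dataclass
class CueCellBlock:
    """Ring of bearing-tuned cells for one cue.

    ``lam`` is the per-cell distance constant; ``preferred`` the per-cell
    bearing.  With ``n_distance_scales > 1`` the ring is several bearing
    sub-rings, one per distance constant.
    """

    cue_id: str
    n_cells: int
    sigma: float
    lam: float | np.ndarray
    n_distance_scales: int = 1
    preferred: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n_bear, rem = divmod(self.n_cells, self.n_distance_scales)
        if rem:
            raise ValueError("n_cells must be a multiple of n_distance_scales")
        ring = TWO_PI * np.arange(n_bear) / n_bear
        self.preferred = np.tile(ring, self.n_distance_scales)
        lam = np.asarray(self.lam, dtype=float)
        if lam.ndim == 0:
            lam = np.full(self.n_cells, float(lam))
        if lam.shape != (self.n_cells,):
            raise ValueError("lam must be scalar or one value per cell")
        self.lam = lam


@dataclass
class GridCellBlock:
    """Plane-wave grid-cell population: wave vectors and phase offsets."""

    scales: np.ndarray        # (n,)
    orientations: np.ndarray  # (n,)
    phases: np.ndarray        # (n, 2) spatial offsets (cm)
    k: np.ndarray = field(init=False)  # (n, 3, 2) wave vectors

    def __post_init__(self) -> None:
        if np.any(self.scales <= 0):
            raise ValueError("grid scale must be positive")
        n = len(self.scales)
        mag = 4.0 * math.pi / (math.sqrt(3.0) * self.scales)  # (n,)
        ang = self.orientations[:, None] + np.arange(3) * (math.pi / 3.0)
        self.k = np.empty((n, 3, 2))
        self.k[:, :, 0] = mag[:, None] * np.cos(ang)
        self.k[:, :, 1] = mag[:, None] * np.sin(ang)

    @property
    def n_cells(self) -> int:
        return len(self.scales)


def make_grid_block(params: PerceptionParams) -> GridCellBlock:
    """Deterministic grid population: phases tile each scale's unit cell."""
    per = params.grid_phases_per_scale
    side = int(round(math.sqrt(per)))
    if side * side != per:
        raise ValueError("grid_phases_per_scale must be a perfect square")
    scales, oris, phases = [], [], []
    for s, o in zip(params.grid_scales, params.grid_orientations):
        for i in range(side):
            for j in range(side):
                scales.append(s)
                oris.append(o)
                phases.append((s * i / side, s * j / side))
    return GridCellBlock(np.array(scales), np.array(oris), np.array(phases))


def grid_cell_activity(position: tuple[float, float],
                       block: GridCellBlock) -> np.ndarray:
    """Activities in [0, 1]: the three-cosine sum rectified and scaled.

    The cosine sum lies in [-1.5, 3]; rectifying before scaling gives the
    zero-background bump pattern of real grid fields (1 at each lattice node,
    i.e. wherever position - phase is a lattice vector).
    """
    p = np.asarray(position, dtype=float)
    d = p[None, :] - block.phases                     # (n, 2)
    s = np.cos(np.einsum("nkd,nd->nk", block.k, d)).sum(axis=1)  # in [-1.5, 3]
    return np.maximum(s, 0.0) / 3.0


def cue_cell_activity(pose: Pose, cue: CueSpec, block: CueCellBlock) -> np.ndarray:
    """One cue ring's activities; all zero when the cue is invisible."""
    if block.cue_id != cue.id:
        raise ValueError("block does not belong to this cue")
    if not cue.visible:
        return np.zeros(block.n_cells)
    bearing, dist = bearing_distance(pose, cue)
    d = np.abs((block.preferred - bearing + math.pi) % TWO_PI - math.pi)
    return np.exp(-d * d / (2.0 * block.sigma ** 2)) * np.exp(-dist / block.lam)


class PerceptionState:
    """Bound perception for one maze: fixed EC layout and fast evaluation.

    The EC vector is ``[grid activities; cue rings in maze cue order]`` and has
    constant length for the lifetime of the maze.
    """

    def __init__(self, maze: Maze, params: PerceptionParams | None = None):
        self.maze = maze
        self.params = params or PerceptionParams()
        p = self.params
        self.grid = make_grid_block(p)
        n_bear = p.n_cc_per_cue // p.n_distance_scales
        factors = np.repeat(np.asarray(p.distance_scale_factors)
                            [: p.n_distance_scales], n_bear)

        def lam_for(c: CueSpec) -> np.ndarray:
            base = p.lambda_proximal if c.kind == "proximal" else p.lambda_distal
            return base * factors

        self.blocks = [
            CueCellBlock(cue_id=c.id, n_cells=p.n_cc_per_cue, sigma=p.sigma,
                         lam=lam_for(c), n_distance_scales=p.n_distance_scales)
            for c in maze.cues
        ]
        self.n_grid = self.grid.n_cells
        self.n_cc = p.n_cc_per_cue * len(maze.cues)
        self.n_ec = self.n_grid + self.n_cc
        # per-cue slices into the CC segment
        self.cc_slices = {
            c.id: slice(i * p.n_cc_per_cue, (i + 1) * p.n_cc_per_cue)
            for i, c in enumerate(maze.cues)
        }
        # precomputed cue constants for the vectorized path
        self._pref = (self.blocks[0].preferred if self.blocks
                      else np.zeros(p.n_cc_per_cue))
        self._inv2s2 = 1.0 / (2.0 * p.sigma ** 2)
        self._lams = (np.stack([b.lam for b in self.blocks]) if self.blocks
                      else np.zeros((0, p.n_cc_per_cue)))
        self._ec = np.zeros(self.n_ec)
        self._cue_xy = np.zeros((len(maze.cues), 2))
        self._vis = np.zeros(len(maze.cues), dtype=bool)
        # flattened grid wave vectors for the fused evaluation path
        self._Kg = self.grid.k.reshape(-1, 2)                       # (3n, 2)
        self._Kg_off = np.einsum("nkd,nd->nk", self.grid.k,
                                 self.grid.phases).ravel()          # (3n,)
        # the spatial map is anchored on idiothetic + distal-cue input only:
        # proximal cues (which may travel with the platform) are masked out of
        # the place-cell pathway, while Direction modules and the gating
        # network keep seeing every cue ring
        self.map_mask = np.ones(self.n_ec, dtype=bool)
        for c in maze.cues:
            if c.kind == "proximal":
                sl = self.cc_slices[c.id]
                self.map_mask[self.n_grid + sl.start:
                              self.n_grid + sl.stop] = False
        self.sync()

    def sync(self) -> None:
        """Refresh the cached cue positions/visibilities from the maze.

        Must be called after any change to cue placement or visibility
        (the trial driver does this when it applies a trial spec).
        """
        for i, c in enumerate(self.maze.cues):
            self._cue_xy[i, 0] = c.position[0]
            self._cue_xy[i, 1] = c.position[1]
            self._vis[i] = c.visible

    def ec_input(self, pose: Pose) -> np.ndarray:
        """EC vector at a pose (returns an internal buffer; copy to keep)."""
        ec = self._ec
        ph = self._Kg[:, 0] * pose.x + self._Kg[:, 1] * pose.y - self._Kg_off
        s = np.cos(ph).reshape(-1, 3).sum(axis=1)
        ec[: self.n_grid] = np.maximum(s, 0.0) / 3.0
        if len(self.blocks):
            xy = self._cue_xy
            dx = xy[:, 0] - pose.x
            dy = xy[:, 1] - pose.y
            dist = np.hypot(dx, dy)
            bearing = np.arctan2(dy, dx)
            dang = np.abs((self._pref[None, :] - bearing[:, None] + math.pi)
                          % TWO_PI - math.pi)
            act = np.exp(-dang * dang * self._inv2s2)
            act *= np.exp(-dist[:, None] / self._lams)
            act[~self._vis] = 0.0
            ec[self.n_grid:] = act.ravel()
        return ec

    def cc_segment(self, ec: np.ndarray) -> np.ndarray:
        """View of the cue-cell part of an EC vector."""
        return ec[self.n_grid:]


def ec_input(pose: Pose, maze: Maze, perception_state: PerceptionState) -> np.ndarray:
    """Functional wrapper; errors if the state was built for another maze."""
    if perception_state.maze is not maze:
        raise ValueError("perception state was built for a different maze")
    perception_state.sync()
    return perception_state.ec_input(pose).copy()
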