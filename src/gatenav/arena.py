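"""Circular water-maze geometry, cues, platform and agent kinematics.

All positions are in centimetres in an arena-centred frame; all angles are
allocentric radians in [0, 2pi), with 0 the fixed reference direction of the
environment (set once when the maze is built).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

TWO_PI = 2.0 * math.pi

#: Agent body radius (cm); the agent is simulated as a 15 cm diameter disk.
AGENT_RADIUS = 7.5
#: Distance moved per timestep (cm).
STEP_CM = 6.0


def wrap_angle(theta: float) -> float:
    """Map an angle to [0, 2pi)."""
    return theta % TWO_PI


def ang_diff(a: float, b: float) -> float:
    """Smallest absolute angular difference between two angles (<= pi)."""
    d = (a - b) % TWO_PI
    return min(d, TWO_PI - d)


@dataclass(frozen=True)
class Pose:
    """Agent pose: position (cm) and allocentric heading in [0, 2pi)."""

    x: float
    y: float
    heading: float = 0.0

    @property
    def position(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class CueSpec:
    """A landmark.

    Proximal cues lie inside the arena (typically attached to the platform via
    ``platform_offset``); distal cues sit at or beyond the wall and act mainly
    as directional references.
    """

    id: str
    kind: str  # {"proximal", "distal"}
    position: tuple[float, float]
    visible: bool = True
    platform_offset: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("proximal", "distal"):
            raise ValueError(f"unknown cue kind {self.kind!r}")


@dataclass
class PlatformSpec:
    """The escape platform: a disk, possibly absent, possibly cue-marked."""

    center: tuple[float, float]
    radius: float = 5.0
    present: bool = True
    cued: bool = False


@dataclass
class Maze:
    """Arena geometry plus its cue set and platform."""

    arena_radius: float = 100.0
    cues: list[CueSpec] = field(default_factory=list)
    platform: PlatformSpec = field(
        default_factory=lambda: PlatformSpec(center=(0.0, 0.0), present=False)
    )
    #: allocentric zero direction, fixed at construction
    reference_direction: float = 0.0

    def __post_init__(self) -> None:
        ids = [c.id for c in self.cues]
        if len(ids) != len(set(ids)):
            raise ValueError("cue ids must be unique")
        self._check_platform()

    def _check_platform(self) -> None:
        p = self.platform
        if p.present:
            if math.hypot(*p.center) + p.radius > self.arena_radius + 1e-9:
                raise ValueError("platform must lie fully inside the arena")

    def cue(self, cue_id: str) -> CueSpec:
        for c in self.cues:
            if c.id == cue_id:
                return c
        raise KeyError(cue_id)

    def move_platform(self, center: tuple[float, float], present: bool = True) -> None:
        """Move the platform; cues with a platform offset track it."""
        self.platform.center = center
        self.platform.present = present
        self._check_platform()
        for c in self.cues:
            if c.platform_offset is not None:
                c.position = (center[0] + c.platform_offset[0],
                              center[1] + c.platform_offset[1])

    @property
    def max_agent_dist(self) -> float:
        return self.arena_radius - AGENT_RADIUS


@dataclass(frozen=True)
class Region:
    """A sector (angular wedge from the arena centre) or a disk region.

    Sector membership is computed on the position angle only; the octants and
    quadrants of the occupancy analyses are sectors of width pi/4 and pi/2.
    """

    shape: str  # {"sector", "disk"}
    center_angle: float = 0.0
    angular_width: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)
    radius: float = 0.0

    def __post_init__(self) -> None:
        if self.shape == "sector":
            if not (0.0 < self.angular_width <= TWO_PI):
                raise ValueError("sector angular_width must be in (0, 2pi]")
        elif self.shape == "disk":
            if self.radius <= 0:
                raise ValueError("disk radius must be positive")
        else:
            raise ValueError(f"unknown region shape {self.shape!r}")

    @classmethod
    def sector(cls, center_angle: float, angular_width: float) -> "Region":
        return cls(shape="sector", center_angle=wrap_angle(center_angle),
                   angular_width=angular_width)

    @classmethod
    def octant(cls, center_angle: float) -> "Region":
        return cls.sector(center_angle, math.pi / 4.0)

    @classmethod
    def quadrant(cls, center_angle: float) -> "Region":
        return cls.sector(center_angle, math.pi / 2.0)

    @classmethod
    def disk(cls, center: tuple[float, float], radius: float) -> "Region":
        return cls(shape="disk", center=center, radius=radius)


def move_agent(pose: Pose, heading_cmd: float, step: float, maze: Maze) -> Pose:
    """Displace the agent ``step`` cm along ``heading_cmd``.

    If the displaced centre would cross the wall constraint the position is
    radially clamped to ``arena_radius - AGENT_RADIUS`` while keeping the
    displaced angular coordinate (the agent slides along the wall).
    """
    if step < 0:
        raise ValueError("step must be >= 0")
    heading_cmd = wrap_angle(heading_cmd)
    x = pose.x + step * math.cos(heading_cmd)
    y = pose.y + step * math.sin(heading_cmd)
    r = math.hypot(x, y)
    rmax = maze.max_agent_dist
    if r > rmax:
        scale = rmax / r
        x *= scale
        y *= scale
    return Pose(x, y, heading_cmd)


def on_platform(pose: Pose, platform: PlatformSpec) -> bool:
    """True iff the platform is present and the agent centre is on it."""
    if not platform.present:
        return False
    return math.hypot(pose.x - platform.center[0],
                      pose.y - platform.center[1]) <= platform.radius


def in_region(position: tuple[float, float], region: Region) -> bool:
    if region.shape == "sector":
        theta = math.atan2(position[1], position[0])
        return ang_diff(theta, region.center_angle) <= region.angular_width / 2.0
    return math.hypot(position[0] - region.center[0],
                      position[1] - region.center[1]) <= region.radius


def in_region_mask(xy: np.ndarray, region: Region) -> np.ndarray:
    """Vectorized membership for an (n, 2) array of positions."""
    xy = np.asarray(xy, dtype=float)
    if region.shape == "sector":
        theta = np.arctan2(xy[:, 1], xy[:, 0])
        d = (theta - region.center_angle) % TWO_PI
        d = np.minimum(d, TWO_PI - d)
        return d <= region.angular_width / 2.0
    return np.hypot(xy[:, 0] - region.center[0],
                    xy[:, 1] - region.center[1]) <= region.radius


def bearing_distance(pose: Pose, cue: CueSpec) -> tuple[float, float]:
    """Allocentric bearing (in [0, 2pi)) and distance from the agent to a cue.

    A cue coincident with the agent centre has bearing 0 and distance 0.
    """
    dx = cue.position[0] - pose.x
    dy = cue.position[1] - pose.y
    dist = math.hypot(dx, dy)
    if dist == 0.0:
        return 0.0, 0.0
    return wrap_angle(math.atan2(dy, dx)), dist
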