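import math

import numpy as np
import pytest

from gatenav.arena import Maze, CueSpec, PlatformSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_maze():
    """100 cm arena, one distal and one proximal cue, platform in the NE."""
    return Maze(
        arena_radius=100.0,
        cues=[
            CueSpec(id="far", kind="distal", position=(120.0, 0.0)),
            CueSpec(id="near", kind="proximal", position=(35.0, 35.0)),
        ],
        platform=PlatformSpec(center=(35.0, 35.0), radius=5.0),
    )


@pytest.fixture
def bare_maze():
    return Maze(platform=PlatformSpec(center=(0.0, 0.0), present=False))
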