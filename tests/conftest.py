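from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")

from dptitrate.mechanics import PVManeuver


def two_line_maneuver(
    knot_v: float = 5.0,
    knot_p: float = 16.0,
    s1: float = 1.0,
    s2: float = 3.0,
    v_max: float = 10.0,
    step: float = 1.0,
    limb: str = "inflation",
) -> PVManeuver:
    """A maneuver lying exactly on two line segments meeting at (knot_v, knot_p)."""
    v = np.arange(0.0, v_max + step / 2, step)
    p = np.where(v <= knot_v, knot_p + s1 * (v - knot_v), knot_p + s2 * (v - knot_v))
    return PVManeuver(subject_id="t", limb=limb, v=v, p=p, step=step)


@pytest.fixture
def clean_two_line() -> PVManeuver:
    return two_line_maneuver()
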