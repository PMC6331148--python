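import numpy as np
import pytest

from latacc.identity import (
    AcceptanceSegment,
    Agent,
    CulturalIdentity,
    Population,
    PositionGrid,
)
from latacc.synthesis import default_templates, sample_prototype


@pytest.fixture(scope="session")
def grid():
    return PositionGrid(400)


@pytest.fixture(scope="session")
def wide_margin_segment():
    """Worked-example segment [-0.85, -0.15] with m.a.position at the lower
    bound, hence a wide upper margin (0.70)."""
    return AcceptanceSegment(-0.85, -0.85, -0.15)


@pytest.fixture(scope="session")
def narrow_margin_segment():
    """Same segment with m.a.position -0.50, hence an upper margin of 0.35."""
    return AcceptanceSegment(-0.85, -0.50, -0.15)


@pytest.fixture(scope="session")
def six_agent_pop():
    """Template-sampled six-prototype population used as the oracle fixture."""
    rng = np.random.default_rng(42)
    fractions = {"M": 0.2, "C": 0.5, "A": 0.3}
    agents = []
    for t in default_templates():
        ident = sample_prototype(t, rng)
        agents.append(
            Agent(
                agent_id=f"{t.group}_{t.type_tag}",
                identity=ident,
                weight=fractions[t.group] * 0.5,
                type_tag=t.type_tag,
            )
        )
    return Population(agents=tuple(agents))


def random_segment(rng, a_lo=-0.8, a_hi=0.8, margin_lo=0.05, margin_hi=0.6):
    """Random valid acceptance segment with margins in the given range,
    clipped to the position axis."""
    a = rng.uniform(a_lo, a_hi)
    ml = rng.uniform(margin_lo, margin_hi)
    mh = rng.uniform(margin_lo, margin_hi)
    return AcceptanceSegment(max(-1.0, a - ml), a, min(1.0, a + mh))


def random_identity(rng, worldviews=("M", "C", "A")):
    """Random identity with at least one positive m.a.position."""
    segs = {k: random_segment(rng) for k in worldviews}
    # guarantee a positive preferred position somewhere
    segs[worldviews[-1]] = random_segment(rng, a_lo=0.05, a_hi=0.8)
    return CulturalIdentity(segments=segs, worldviews=tuple(worldviews))
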