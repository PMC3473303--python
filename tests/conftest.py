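import numpy as np
import pytest

import trustgame as tg


@pytest.fixture
def baseline() -> tg.Scenario:
    return tg.Scenario.table1_baseline()


def make_random_scenario(rng: np.random.Generator) -> tg.Scenario:
    """A random scenario satisfying every payoff-ordering invariant.

    Utilities are drawn on the 0-100 scale constrained so that
    u1 >= u3 >= u2, u4; v1 >= v2, v3 >= v4; v2 >= u2.
    """
    u2 = rng.uniform(0.0, 50.0)
    u4 = rng.uniform(0.0, 50.0)
    u3 = rng.uniform(max(u2, u4), 100.0)
    u1 = rng.uniform(u3, 100.0)
    v2 = rng.uniform(u2, 100.0)
    v4 = rng.uniform(0.0, 100.0)
    v3 = rng.uniform(v4, 100.0)
    v1 = rng.uniform(max(v2, v3), 100.0)
    return tg.Scenario(
        payoffs=tg.GamePayoffs(u1=u1, u2=u2, u3=u3, u4=u4,
                               v1=v1, v2=v2, v3=v3, v4=v4),
        probs=tg.GameProbabilities(*rng.uniform(0.0, 1.0, 4)),
        psych=tg.PsychParams(regret=rng.uniform(), guilt=rng.uniform()),
    ).validate()
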