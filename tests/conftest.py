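import numpy as np
import pytest

from fcmalloc import (
    EngineConfig,
    RelationshipAnswer,
    WeightMatrix,
    create_trial,
    default_scale,
)


@pytest.fixture(scope="session")
def scale():
    return default_scale()


@pytest.fixture()
def small_design():
    """3 factors + outcome, intervention on two factors."""
    return create_trial(["a", "b", "c"], "out", {"a": +1, "b": -1})


@pytest.fixture()
def chain_matrix():
    """intervention -> a -> out, both weights 1, everything else 0."""
    concepts = ("a", "b", "out", "intervention")
    W = np.zeros((4, 4))
    W[3, 0] = 1.0   # intervention -> a
    W[0, 2] = 1.0   # a -> out
    return WeightMatrix(weights=W, concepts=concepts, outcome="out",
                        intervention="intervention")


@pytest.fixture(scope="session")
def engine_config():
    return EngineConfig()


def answers_for(pair, spec):
    """Build RelationshipAnswer lists like [(count, term, direction), ...]."""
    src, tgt = pair
    out = []
    i = 0
    for count, term, direction in spec:
        for _ in range(count):
            out.append(RelationshipAnswer(
                participant_id=f"P{i:03d}", source=src, target=tgt,
                term=term, direction=direction,
            ))
            i += 1
    return out


@pytest.fixture()
def make_answers():
    return answers_for
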