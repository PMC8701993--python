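import numpy as np
import pytest

from quartetgc.quartets import quartet_from_aligned
from quartetgc.simulate import SimConfig, simulate_quartet


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


def make_quartet(cfg: SimConfig, rng, qid="q0", pattern="LCT"):
    """Simulate one quartet and wrap it as an aligned Quartet object."""
    seqs, truth = simulate_quartet(cfg, rng, quartet_id=qid)
    q = quartet_from_aligned(qid, pattern, truth.genes,
                             [seqs[k] for k in ("p1", "p2", "o1", "o2")])
    return q, truth


@pytest.fixture
def whole_conversion_cfg():
    return SimConfig(conversion_fraction=1.0, conversion_kind_mix={"whole": 1.0, "partial": 0.0})


@pytest.fixture
def partial_conversion_cfg():
    return SimConfig(conversion_fraction=1.0, conversion_kind_mix={"whole": 0.0, "partial": 1.0})


@pytest.fixture
def null_cfg():
    return SimConfig(conversion_fraction=0.0)
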