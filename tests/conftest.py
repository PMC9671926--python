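import numpy as np
import pytest

from lncmech.io_core import MotifModel


@pytest.fixture(scope="session")
def fixture_motifs() -> list[MotifModel]:
    """Small deterministic motif set (widths 3-6) used across scan tests."""
    rng = np.random.default_rng(20240917)
    motifs = []
    for w in (3, 4, 5, 6):
        probs = rng.dirichlet(np.full(4, 0.7), size=w).T
        motifs.append(MotifModel(motif_id=f"fix_w{w}", probs=probs))
    # one informative motif with a sharp consensus
    probs = np.full((4, 5), 0.02)
    cons = rng.integers(0, 4, size=5)
    probs[cons, np.arange(5)] = 0.94
    motifs.append(MotifModel(motif_id="fix_sharp", probs=probs))
    return motifs


@pytest.fixture(scope="session")
def skewed_background() -> np.ndarray:
    return np.array([0.3, 0.2, 0.2, 0.3])
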