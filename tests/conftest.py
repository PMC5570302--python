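import numpy as np
import pytest

from vecv import PairedData


@pytest.fixture
def x30():
    """The canonical observed vector of the simulation scenarios: integers 1..30."""
    return np.arange(1, 31, dtype=float)


@pytest.fixture
def random_pairs():
    """Factory for random validation sets with non-degenerate observed values."""

    def make(seed: int, n: int | None = None) -> PairedData:
        rng = np.random.default_rng(seed)
        if n is None:
            n = int(rng.integers(2, 101))
        obs = rng.normal(rng.uniform(-10, 10), rng.uniform(0.5, 20), size=n)
        # mix of scale bias, shift and noise so every accuracy regime appears
        pred = (
            rng.uniform(0.2, 1.8) * obs
            + rng.uniform(-5, 5)
            + rng.normal(0, rng.uniform(0, 10), size=n)
        )
        return PairedData(obs, pred)

    return make
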