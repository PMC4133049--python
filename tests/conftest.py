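import numpy as np
import pytest

from fatescape import EpigeneticLandscape, FatePanel, SyntheticSpec, synth_fate_panel


@pytest.fixture
def ortho_panel():
    """Two exactly orthogonal fates on 8 TFs (A = identity)."""
    xi = np.column_stack(
        [np.ones(8, dtype=int), np.array([1, 1, 1, 1, -1, -1, -1, -1])]
    )
    return FatePanel(tuple(f"T{i}" for i in range(8)), ("A", "B"), xi)


@pytest.fixture
def correlated_panel():
    """N=4 panel with fates (+,+,+,+) and (+,+,+,-): A = [[1, .5], [.5, 1]]."""
    xi = np.array([[1, 1], [1, 1], [1, 1], [1, -1]])
    return FatePanel(("T0", "T1", "T2", "T3"), ("A", "B"), xi)


@pytest.fixture
def hadamard3_panel():
    """Three mutually orthogonal ±1 patterns on 12 TFs."""
    block = np.array([[1, 1, 1], [1, 1, -1], [1, -1, 1], [1, -1, -1]])
    xi = np.vstack([block] * 3)
    return FatePanel(tuple(f"T{i}" for i in range(12)), ("A", "B", "C"), xi)


@pytest.fixture
def small_synth_panel():
    return synth_fate_panel(SyntheticSpec(n_tfs=120, n_fates=5, seed=21))


@pytest.fixture
def fitted(small_synth_panel):
    return EpigeneticLandscape().fit(small_synth_panel)


def random_pm1(rng, *shape):
    return rng.choice([-1.0, 1.0], size=shape)
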