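import numpy as np
import pytest

from mpbwt import panel_from_matrix

# 4x3 tri-allelic worked panel used throughout; its transform states and
# match sets were computed by hand and cross-checked with the brute-force
# oracles.
WORKED_ROWS = [[0, 1, 2], [1, 1, 0], [0, 1, 0], [2, 0, 1]]


@pytest.fixture
def worked_panel():
    return panel_from_matrix(np.array(WORKED_ROWS))


def random_panel(rng, max_m=30, max_n=60, alphabets=(2, 3, 5, 10), structured=False):
    """Small random panel for oracle comparisons.

    With ``structured=True`` haplotypes are noisy copies of a few
    templates, which produces long shared segments and therefore many
    matches — the regime the block-scan logic has to get right.
    """
    M = int(rng.integers(2, max_m + 1))
    N = int(rng.integers(1, max_n + 1))
    t = int(rng.choice(alphabets))
    if structured:
        templates = rng.integers(0, t, size=(3, N))
        X = templates[rng.integers(0, 3, size=M)]
        noise = rng.random((M, N)) < 0.08
        X[noise] = rng.integers(0, t, size=int(noise.sum()))
    else:
        X = rng.integers(0, t, size=(M, N))
    return panel_from_matrix(X, alphabet_size=t)
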