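import numpy as np
import pytest

from erpdtw import pairwise_cost


def enumerate_paths(n, m):
    """All monotone alignment paths from (0,0) to (n-1,m-1).

    Steps are down, right, or diagonal — the alignment set behind both the
    hard-DTW minimum and the Soft-DTW log-sum-exp.
    """
    if n == 1 and m == 1:
        return [[(0, 0)]]
    out = []
    for pn, pm in ((n - 1, m), (n, m - 1), (n - 1, m - 1)):
        if pn >= 1 and pm >= 1:
            for p in enumerate_paths(pn, pm):
                out.append(p + [(n - 1, m - 1)])
    return out


def brute_force_dtw(x, y, metric="sqeuclidean"):
    """Minimum path cost over the explicitly enumerated alignment set."""
    delta = pairwise_cost(x, y, metric)
    n, m = delta.shape
    return min(sum(delta[i, j] for i, j in p) for p in enumerate_paths(n, m))


def brute_force_soft_dtw(x, y, gamma, metric="sqeuclidean"):
    """-gamma * logsumexp(-cost/gamma) over all enumerated alignments."""
    from scipy.special import logsumexp

    delta = pairwise_cost(x, y, metric)
    n, m = delta.shape
    costs = np.array([sum(delta[i, j] for i, j in p)
                      for p in enumerate_paths(n, m)])
    if gamma == 0:
        return float(costs.min())
    return float(-gamma * logsumexp(-costs / gamma))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """2 subjects x 2 labels x 4 trials of tiny (16 samples, 3 ch) epochs."""
    from erpdtw import config_for_scale, generate_dataset

    return generate_dataset(config_for_scale(
        seq_len=16, n_channels=3, n_subjects=2, trials_per_label=4, seed=7))


def random_series_pairs(rng, n_pairs, max_len, dims=(1,)):
    """Random (x, y) series pairs covering the given dimensions."""
    pairs = []
    for k in range(n_pairs):
        p = dims[k % len(dims)]
        n = int(rng.integers(1, max_len + 1))
        m = int(rng.integers(1, max_len + 1))
        pairs.append((rng.standard_normal((p, n)) * 2,
                      rng.standard_normal((p, m)) * 2))
    return pairs
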