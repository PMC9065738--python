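import numpy as np
import pytest

from pyuntb import CommunityMatrix


@pytest.fixture
def small_cm():
    """2 OTUs x 2 samples with column sums (4, 2)."""
    return CommunityMatrix(["otuA", "otuB"], ["s1", "s2"],
                           np.array([[3, 0], [1, 2]]))


@pytest.fixture
def wide_cm():
    """A richer deterministic table for filters and transforms."""
    rng = np.random.default_rng(1234)
    counts = rng.integers(0, 40, size=(12, 6))
    counts[:, 3] = 0
    counts[0, 3] = 7  # sample with only 7 reads
    return CommunityMatrix([f"otu{i}" for i in range(12)],
                           [f"s{j}" for j in range(6)], counts)


def make_cm(counts, prefix="o"):
    counts = np.asarray(counts)
    return CommunityMatrix([f"{prefix}{i}" for i in range(counts.shape[0])],
                           [f"s{j}" for j in range(counts.shape[1])], counts)


def null_process_metacommunity(seed, pool=300, n_samples=20,
                               rich_range=(100, 200), reads=50_000):
    """Samples generated by the proportional-frequency null process itself:
    a shallow power-law (Zipf 0.5) regional pool with occupancy weights
    proportional to abundance**0.25, per-sample richness uniform in
    ``rich_range``.  Under this generator the observed data are one more
    draw of the null model, the fully stochastic regime."""
    rng = np.random.default_rng(seed)
    mean_rel = 1.0 / np.arange(1, pool + 1) ** 0.5
    mean_rel /= mean_rel.sum()
    occ = mean_rel ** 0.25
    occ /= occ.sum()
    rel = np.zeros((pool, n_samples))
    rich = rng.integers(rich_range[0], rich_range[1] + 1, size=n_samples)
    for j in range(n_samples):
        chosen = rng.choice(pool, size=int(rich[j]), replace=False, p=occ)
        w = mean_rel[chosen]
        rel[chosen, j] = w / w.sum()
    counts = np.rint(rel * reads).astype(np.int64)
    return make_cm(counts[counts.sum(axis=1) > 0])
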