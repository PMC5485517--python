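import itertools

import numpy as np
import pytest

from epistage import GenotypeDataset, MISSING


def naive_contingency(genotypes: np.ndarray, phenotype: np.ndarray,
                      snps: tuple[int, ...]) -> np.ndarray:
    """Brute-force nested-loop joint-genotype counting oracle."""
    k = len(snps)
    counts = np.zeros((3 ** k, 2), dtype=np.int64)
    for i in range(genotypes.shape[0]):
        gs = [int(genotypes[i, s]) for s in snps]
        if any(g == MISSING for g in gs):
            continue
        u = 0
        for g in gs:
            u = u * 3 + g
        counts[u, 0 if phenotype[i] == 1 else 1] += 1
    return counts


def naive_chi2(counts: np.ndarray) -> float:
    """Independent textbook chi-squared-of-independence computation."""
    counts = counts.astype(float)
    n = counts.sum()
    stat = 0.0
    for u in range(counts.shape[0]):
        row = counts[u].sum()
        if row == 0:
            continue
        for v in range(counts.shape[1]):
            col = counts[:, v].sum()
            e = row * col / n
            stat += (counts[u, v] - e) ** 2 / e
    return stat


@pytest.fixture
def random_dataset():
    def make(n=50, m=5, seed=0, missing_rate=0.0, balanced=True):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 3, size=(n, m)).astype(np.int8)
        if missing_rate > 0:
            g[rng.random((n, m)) < missing_rate] = MISSING
        if balanced:
            y = np.zeros(n, dtype=np.int8)
            y[: n // 2] = 1
        else:
            y = rng.integers(0, 2, size=n).astype(np.int8)
        return GenotypeDataset(g, y, [f"snp{j}" for j in range(m)])
    return make


def all_ksubsets(items, k):
    return list(itertools.combinations(items, k))
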