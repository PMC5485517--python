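"""Stage 2: K-locus interaction search over candidate SNP pairs.

Small candidate sets are handled exhaustively: the SNPs of all candidate
pairs are merged into one set S and every K-subset of S is chi-squared
tested.  Large sets are searched with ant-colony optimization: ants
repeatedly pick d candidate pairs by pheromone-weighted roulette, the union
of the picked pairs is scored by its chi-squared statistic (scaled by fs
for three-SNP unions so they compete fairly with four-SNP ones), and
pheromone evaporates globally while the picked pairs are reinforced in
proportion to the ant's fitness.  Finally every K-subset of the best stored
unions is tested against the Bonferroni level alpha0 / C(M,K).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .association_stats import (
    TestResult,
    bonferroni_level,
    chi_squared_stats_batch,
    chi_squared_test,
    critical_statistic,
)
from .genotype_data import (
    BitEncodedDataset,
    ContingencyTable,
    GenotypeDataset,
    class_onehot,
    contingency_table,
    joint_genotype_counts,
)

__all__ = [
    "AcoConfig",
    "PheromoneState",
    "MergedCombination",
    "Stage2Result",
    "EXHAUSTIVE_W_MAX",
    "exhaustive_search",
    "select_pair",
    "merge_and_score",
    "update_pheromones",
    "aco_search",
    "run_stage2",
]

#: candidate-set size below which the exhaustive strategy is used
EXHAUSTIVE_W_MAX = 2000

#: pheromone deposit is 0.01 x the ant's fitness
DEPOSIT_SCALE = 0.01


@dataclass
class AcoConfig:
    tau0: float = 100.0
    n_ants: int | None = None       # default 0.1*W clamped to [500, 5000]
    rho: float = 0.05
    d: int = 2
    max_iter: int | None = None     # default 0.1*W
    delta: float = 1.0
    beta: float = 1.0
    eta: float = 1.0
    fs: float = 2.0
    top_t: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (0,1)")
        if self.d < 2:
            raise ValueError("d must be >= 2")
        if self.fs < 1.0:
            raise ValueError("fs must be >= 1")
        if self.tau0 <= 0:
            raise ValueError("tau0 must be positive")

    def resolved(self, W: int) -> "AcoConfig":
        """Fill W-dependent defaults: n = 0.1 W in [500, 5000], MaxIter = 0.1 W."""
        n = self.n_ants if self.n_ants is not None else int(min(5000, max(500, 0.1 * W)))
        it = self.max_iter if self.max_iter is not None else max(1, int(0.1 * W))
        return replace(self, n_ants=n, max_iter=it)


@dataclass
class PheromoneState:
    tau: np.ndarray  # (W,) positive

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=np.float64)
        if (self.tau <= 0).any():
            raise ValueError("pheromone values must stay positive")


@dataclass
class MergedCombination:
    snps: tuple[int, ...]
    chi2: float
    fitness: float
    source_pairs: tuple[int, ...]


@dataclass
class Stage2Result:
    interactions: list[tuple[tuple[int, ...], TestResult]]
    strategy: str
    W: int
    bonferroni_level: float


def _as_pairs(candidates) -> list[tuple[int, int]]:
    out = []
    for c in candidates:
        pair = c.pair if hasattr(c, "pair") else tuple(c)
        out.append((int(pair[0]), int(pair[1])))
    return out


# ---------------------------------------------------------------------------
# Exhaustive strategy
# ---------------------------------------------------------------------------

def _exhaustive_dense(
    ds: GenotypeDataset, S: list[int], K: int, crit: float
) -> list[tuple[tuple[int, ...], float]]:
    """All K-subsets of S with statistic above ``crit``, via batched GEMM
    counting: for each (K-1)-subset prefix the joint-genotype one-hot of
    the prefix is contracted against the one-hot of every later SNP."""
    xc, xu = class_onehot(ds)
    L = len(S)
    hits: list[tuple[tuple[int, ...], float]] = []
    rows = 3 ** K
    for combo in itertools.combinations(range(L), K - 1):
        if combo[-1] >= L - 1:
            continue
        tail = S[combo[-1] + 1 :]
        t = len(tail)
        pc = xc[:, S[combo[0]], :]
        pu = xu[:, S[combo[0]], :]
        for pos in combo[1:]:
            pc = (pc[:, :, None] * xc[:, S[pos], None, :]).reshape(pc.shape[0], -1)
            pu = (pu[:, :, None] * xu[:, S[pos], None, :]).reshape(pu.shape[0], -1)
        gc = pc.T @ xc[:, tail, :].reshape(xc.shape[0], -1)
        gu = pu.T @ xu[:, tail, :].reshape(xu.shape[0], -1)
        pref = 3 ** (K - 1)
        cc = gc.reshape(pref, t, 3).transpose(0, 2, 1).reshape(rows, t)
        cu = gu.reshape(pref, t, 3).transpose(0, 2, 1).reshape(rows, t)
        stats = chi_squared_stats_batch(np.stack([cc, cu], axis=1))
        for h in np.flatnonzero(stats > crit):
            snps = tuple(S[p] for p in combo) + (tail[int(h)],)
            hits.append((snps, float(stats[h])))
    return hits


def exhaustive_search(
    candidates,
    data: GenotypeDataset | BitEncodedDataset,
    K: int,
    alpha0: float = 0.05,
    M: int | None = None,
) -> list[tuple[tuple[int, ...], TestResult]]:
    """Evaluate every K-subset of the merged candidate SNP set.

    Returns the subsets whose p-value beats the Bonferroni level
    alpha0 / C(M, K), sorted by ascending p-value.  An SNP set smaller
    than K yields an empty result.
    """
    if K < 3:
        raise ValueError("interaction order K must be >= 3")
    pairs = _as_pairs(candidates)
    S = sorted({s for p in pairs for s in p})
    if M is None:
        M = data.n_snps
    if len(S) < K:
        return []
    level = bonferroni_level(alpha0, M, K)
    df = 3 ** K - 1
    crit = critical_statistic(level, df)

    if isinstance(data, GenotypeDataset):
        raw = _exhaustive_dense(data, S, K, crit)
    else:
        raw = []
        for snps in itertools.combinations(S, K):
            res = chi_squared_test(contingency_table(data, snps))
            if res.statistic > crit:
                raw.append((snps, res.statistic))

    results = [
        (snps, TestResult(stat, df, float(chi2_dist.sf(stat, df))))
        for snps, stat in raw
    ]
    results.sort(key=lambda r: (r[1].p_value, -r[1].statistic, r[0]))
    return results


# ---------------------------------------------------------------------------
# Ant-colony strategy
# ---------------------------------------------------------------------------

def _chi2_stat(counts: np.ndarray) -> float:
    """Statistic of :func:`chi_squared_test` without the p-value lookup
    (the ant-colony inner loop only ranks by the statistic)."""
    c = counts.astype(np.float64)
    col = c.sum(axis=0)
    row = c.sum(axis=1)
    keep = row > 0
    n = col.sum()
    expected = row[keep, None] * col[None, :] / n
    return float(((c[keep] - expected) ** 2 / expected).sum())


def _selection_weights(state: PheromoneState, config: AcoConfig) -> np.ndarray:
    return state.tau ** config.delta * config.eta ** config.beta


def select_pair(state: PheromoneState, config: AcoConfig, rng: np.random.Generator) -> int:
    """Roulette-wheel selection: index i with probability
    tau_i^delta eta^beta / sum_j tau_j^delta eta^beta."""
    w = _selection_weights(state, config)
    cum = np.cumsum(w)
    u = rng.random() * cum[-1]
    return int(np.searchsorted(cum, u, side="right"))


def _select_pairs_batch(
    weights: np.ndarray, n_ants: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_ants, 2) distinct candidate indices per ant by exact successive
    roulette without replacement, vectorized across ants."""
    cum = np.cumsum(weights)
    total = cum[-1]
    first = np.searchsorted(cum, rng.random(n_ants) * total, side="right")
    first = np.minimum(first, weights.size - 1)
    w_first = weights[first]
    below = cum[first] - w_first          # cdf mass strictly before `first`
    u = rng.random(n_ants) * (total - w_first)
    u = np.where(u < below, u, u + w_first)
    second = np.searchsorted(cum, u, side="right")
    second = np.minimum(second, weights.size - 1)
    # guard against float-boundary collisions
    bad = np.flatnonzero(second == first)
    for b in bad:
        j = int(first[b])
        while True:
            cand = int(np.searchsorted(cum, rng.random() * total, side="right"))
            cand = min(cand, weights.size - 1)
            if cand != j:
                second[b] = cand
                break
    return np.stack([first, second], axis=1)


def _select_without_replacement(
    weights: np.ndarray, d: int, rng: np.random.Generator
) -> np.ndarray:
    w = weights.astype(np.float64).copy()
    out = np.empty(d, dtype=np.int64)
    for t in range(d):
        cum = np.cumsum(w)
        idx = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        idx = min(idx, w.size - 1)
        out[t] = idx
        w[idx] = 0.0
    return out


def merge_and_score(
    picked: tuple[int, ...],
    candidates,
    data: GenotypeDataset | BitEncodedDataset,
    config: AcoConfig,
) -> MergedCombination:
    """Union the SNPs of the picked candidate pairs and score the union.

    Fitness = fs * chi2 when the union has exactly 3 SNPs, else chi2.
    """
    pairs = _as_pairs(candidates)
    snps = tuple(sorted({s for idx in picked for s in pairs[idx]}))
    if isinstance(data, GenotypeDataset):
        counts = joint_genotype_counts(data.genotypes, data.phenotype, snps)
        res = chi_squared_test(ContingencyTable(counts, k=len(snps)))
    else:
        res = chi_squared_test(contingency_table(data, snps))
    fitness = res.statistic * config.fs if len(snps) == 3 else res.statistic
    return MergedCombination(snps=snps, chi2=res.statistic, fitness=fitness,
                             source_pairs=tuple(int(i) for i in picked))


def update_pheromones(
    state: PheromoneState,
    ant_results: list[tuple[tuple[int, ...], float]],
    config: AcoConfig,
) -> PheromoneState:
    """tau_i <- (1 - rho) tau_i for every candidate; each candidate picked
    by an ant additionally gains 0.01 x that ant's fitness (deposits from
    several ants accumulate)."""
    tau = state.tau * (1.0 - config.rho)
    for picked, fitness in ant_results:
        for idx in picked:
            tau[idx] += DEPOSIT_SCALE * fitness
    return PheromoneState(tau=tau)


def aco_search(
    candidates,
    data: GenotypeDataset | BitEncodedDataset,
    K: int,
    config: AcoConfig | None = None,
    alpha0: float = 0.05,
    M: int | None = None,
) -> list[tuple[tuple[int, ...], TestResult]]:
    """Ant-colony search over candidate pairs, then Bonferroni reporting.

    Runs MaxIter iterations of pick/merge/score/update, keeps the top_t
    distinct merged unions by fitness, and finally tests every K-subset of
    the stored unions at level alpha0 / C(M, K).  Fully reproducible given
    ``config.seed``.
    """
    if K < 3:
        raise ValueError("interaction order K must be >= 3")
    pairs = _as_pairs(candidates)
    W = len(pairs)
    if M is None:
        M = data.n_snps
    config = (config or AcoConfig()).resolved(W)
    if config.d > W:
        raise ValueError(f"d={config.d} exceeds the candidate count W={W}")
    rng = np.random.default_rng(config.seed)

    if isinstance(data, GenotypeDataset):
        geno, pheno = data.genotypes, data.phenotype
        def score_union(snps: tuple[int, ...]) -> float:
            return _chi2_stat(joint_genotype_counts(geno, pheno, snps))
    else:
        def score_union(snps: tuple[int, ...]) -> float:
            return _chi2_stat(contingency_table(data, snps).counts)

    pair_arr = [tuple(p) for p in pairs]
    union_cache: dict[tuple[int, ...], tuple[tuple[int, ...], float]] = {}
    best: dict[tuple[int, ...], float] = {}
    state = PheromoneState(tau=np.full(W, config.tau0))

    def evaluate(picked: tuple[int, ...]) -> tuple[tuple[int, ...], float]:
        key = tuple(sorted(picked))
        hit = union_cache.get(key)
        if hit is None:
            snps = tuple(sorted({s for idx in key for s in pair_arr[idx]}))
            chi2 = score_union(snps)
            fitness = chi2 * config.fs if len(snps) == 3 else chi2
            hit = (snps, fitness)
            union_cache[key] = hit
        return hit

    for _ in range(config.max_iter):
        weights = _selection_weights(state, config)
        if config.d == 2:
            picks = _select_pairs_batch(weights, config.n_ants, rng)
        else:
            picks = np.stack([
                _select_without_replacement(weights, config.d, rng)
                for _ in range(config.n_ants)
            ])
        ant_results: list[tuple[tuple[int, ...], float]] = []
        for row in picks:
            picked = tuple(int(x) for x in row)
            snps, fitness = evaluate(picked)
            ant_results.append((picked, fitness))
            prev = best.get(snps)
            if prev is None or fitness > prev:
                best[snps] = fitness
        state = update_pheromones(state, ant_results, config)
        if len(best) > 20 * config.top_t:
            keep = sorted(best.items(), key=lambda kv: -kv[1])[: config.top_t]
            best = dict(keep)

    stored = sorted(best.items(), key=lambda kv: -kv[1])[: config.top_t]
    level = bonferroni_level(alpha0, M, K)
    df = 3 ** K - 1
    seen: set[tuple[int, ...]] = set()
    results: list[tuple[tuple[int, ...], TestResult]] = []
    for snps, _fit in stored:
        if len(snps) < K:
            continue
        for sub in itertools.combinations(snps, K):
            if sub in seen:
                continue
            seen.add(sub)
            stat = score_union(sub)
            p = float(chi2_dist.sf(stat, df))
            if p < level:
                results.append((sub, TestResult(stat, df, p)))
    results.sort(key=lambda r: (r[1].p_value, -r[1].statistic, r[0]))
    return results


def run_stage2(
    candidates,
    data: GenotypeDataset | BitEncodedDataset,
    K: int = 3,
    config: AcoConfig | None = None,
    alpha0: float = 0.05,
    M: int | None = None,
    strategy: str = "auto",
) -> Stage2Result:
    """Dispatch to the exhaustive strategy when W < 2000, else to ACO.

    ``strategy`` in {"auto", "exhaustive", "aco"} allows a user override.
    """
    pairs = _as_pairs(candidates)
    if not pairs:
        raise ValueError("candidate set is empty")
    W = len(pairs)
    if M is None:
        M = data.n_snps
    if strategy == "auto":
        strategy = "exhaustive" if W < EXHAUSTIVE_W_MAX else "aco"
    if strategy == "exhaustive":
        interactions = exhaustive_search(pairs, data, K, alpha0, M)
    elif strategy == "aco":
        interactions = aco_search(pairs, data, K, config, alpha0, M)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return Stage2Result(
        interactions=interactions,
        strategy=strategy,
        W=W,
        bonferroni_level=bonferroni_level(alpha0, M, K),
    )
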