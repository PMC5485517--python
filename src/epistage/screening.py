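"""Stage 1: pairwise screening of all C(M,2) SNP combinations.

Every pair is chi-squared-tested on its 9x2 joint-genotype table (8 df).
Pairs with a statistic above the relaxed critical value chi2(alpha') are
kept: above chi2(alpha) they are "significant", between the two thresholds
"intermediate".  Pairs containing a SNP with a strong main effect are then
re-examined with a logistic likelihood-ratio deviance and dropped when the
pair adds nothing beyond the main effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .association_stats import (
    SignificanceScheme,
    chi_squared_stats_batch,
    chi_squared_test,
    lrt_deviance,
)
from .genotype_data import (
    BitEncodedDataset,
    GenotypeDataset,
    class_onehot,
    contingency_table,
)

__all__ = ["PairResult", "PairGroups", "ScreenResult", "pairwise_scan",
           "flag_strong_main_effects", "screen"]

BAND_SIGNIFICANT = "significant"
BAND_INTERMEDIATE = "intermediate"


@dataclass
class PairResult:
    snp_a: int
    snp_b: int
    statistic: float
    p_value: float
    band: str
    lrt_p: float | None = None

    @property
    def pair(self) -> tuple[int, int]:
        return (self.snp_a, self.snp_b)


@dataclass
class PairGroups:
    """Retained pairs (the G1 group); pairs below chi2(alpha') are implicit."""

    pairs: list[PairResult]
    scheme: SignificanceScheme

    @property
    def W(self) -> int:
        return len(self.pairs)

    @property
    def n_significant(self) -> int:
        return sum(p.band == BAND_SIGNIFICANT for p in self.pairs)

    @property
    def n_intermediate(self) -> int:
        return sum(p.band == BAND_INTERMEDIATE for p in self.pairs)


@dataclass
class ScreenResult:
    candidates: list[PairResult]
    scheme: SignificanceScheme
    flagged: frozenset[int]
    n_pairs_scanned: int
    n_significant: int
    n_intermediate: int
    n_lrt_tested: int = 0
    n_lrt_discarded: int = 0


def _scan_dense(ds: GenotypeDataset, scheme: SignificanceScheme) -> list[PairResult]:
    xc, xu = class_onehot(ds)
    n_snps = ds.n_snps
    retained: list[PairResult] = []
    for i in range(n_snps - 1):
        tail = n_snps - i - 1
        gc = xc[:, i, :].T @ xc[:, i + 1 :, :].reshape(xc.shape[0], -1)
        gu = xu[:, i, :].T @ xu[:, i + 1 :, :].reshape(xu.shape[0], -1)
        # (3, tail*3) -> (9, tail) with row order 3*g_i + g_j
        cc = gc.reshape(3, tail, 3).transpose(0, 2, 1).reshape(9, tail)
        cu = gu.reshape(3, tail, 3).transpose(0, 2, 1).reshape(9, tail)
        counts = np.stack([cc, cu], axis=1)
        stats = chi_squared_stats_batch(counts)
        hits = np.flatnonzero(stats > scheme.chi2_alpha_prime)
        for h in hits:
            stat = float(stats[h])
            band = BAND_SIGNIFICANT if stat > scheme.chi2_alpha else BAND_INTERMEDIATE
            retained.append(
                PairResult(i, i + 1 + int(h), stat, float(chi2_dist.sf(stat, 8)), band)
            )
    return retained


def _scan_bitwise(bits: BitEncodedDataset, scheme: SignificanceScheme) -> list[PairResult]:
    retained: list[PairResult] = []
    for i in range(bits.n_snps - 1):
        for j in range(i + 1, bits.n_snps):
            res = chi_squared_test(contingency_table(bits, (i, j)))
            if res.statistic > scheme.chi2_alpha_prime:
                band = (BAND_SIGNIFICANT if res.statistic > scheme.chi2_alpha
                        else BAND_INTERMEDIATE)
                retained.append(PairResult(i, j, res.statistic, res.p_value, band))
    return retained


def pairwise_scan(
    data: GenotypeDataset | BitEncodedDataset, scheme: SignificanceScheme
) -> PairGroups:
    """Test all C(M,2) pairs and retain those above chi2(alpha').

    Output is ordered by descending statistic with ties broken by the
    (sorted) index pair.  Stage 1 is fully deterministic.
    """
    if isinstance(data, GenotypeDataset):
        if data.n_snps < 2:
            raise ValueError("need at least two SNPs to scan pairs")
        retained = _scan_dense(data, scheme)
    else:
        if data.n_snps < 2:
            raise ValueError("need at least two SNPs to scan pairs")
        retained = _scan_bitwise(data, scheme)
    retained.sort(key=lambda p: (-p.statistic, p.snp_a, p.snp_b))
    return PairGroups(pairs=retained, scheme=scheme)


def flag_strong_main_effects(
    data: GenotypeDataset | BitEncodedDataset, alpha0: float = 0.05
) -> frozenset[int]:
    """SNPs whose single-locus chi-squared (3x2 table, 2 df) p-value is
    below the Bonferroni-corrected level alpha0 / M."""
    if isinstance(data, GenotypeDataset):
        bits = None
        xc, xu = class_onehot(data)
        cc = xc.sum(axis=0).T        # (3, M)
        cu = xu.sum(axis=0).T
        counts = np.stack([cc, cu], axis=1)
        stats = chi_squared_stats_batch(counts)
        m = data.n_snps
        pvals = chi2_dist.sf(stats, 2)
    else:
        bits = data
        m = bits.n_snps
        pvals = np.array([
            chi_squared_test(contingency_table(bits, (i,))).p_value for i in range(m)
        ])
    threshold = alpha0 / m
    return frozenset(int(i) for i in np.flatnonzero(pvals < threshold))


def screen(
    ds: GenotypeDataset,
    alpha0: float = 0.05,
    omega: float = 1e4,
    scheme: SignificanceScheme | None = None,
) -> ScreenResult:
    """Full stage-1 pipeline: scan -> flag main effects -> LRT filter.

    Pairs containing at least one flagged SNP are kept only if the deviance
    p-value of the pair (interaction beyond the flagged main effects) is
    <= alpha'; pairs with no flagged SNP pass through untouched.  When no
    SNP is flagged the LRT stage is skipped entirely.
    """
    if scheme is None:
        scheme = SignificanceScheme(alpha0=alpha0, M=ds.n_snps, omega=omega)
    groups = pairwise_scan(ds, scheme)
    flagged = flag_strong_main_effects(ds, alpha0)

    n_tested = 0
    n_discarded = 0
    candidates: list[PairResult] = []
    for pair in groups.pairs:
        fi, fj = pair.snp_a in flagged, pair.snp_b in flagged
        if flagged and (fi or fj):
            lrt = lrt_deviance(ds, pair.pair, (fi, fj))
            n_tested += 1
            pair.lrt_p = lrt.p_value
            if lrt.p_value > scheme.alpha_prime:
                n_discarded += 1
                continue
        candidates.append(pair)

    return ScreenResult(
        candidates=candidates,
        scheme=scheme,
        flagged=flagged,
        n_pairs_scanned=ds.n_snps * (ds.n_snps - 1) // 2,
        n_significant=groups.n_significant,
        n_intermediate=groups.n_intermediate,
        n_lrt_tested=n_tested,
        n_lrt_discarded=n_discarded,
    )
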