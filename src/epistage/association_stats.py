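"""Chi-squared association tests, Bonferroni machinery and the logistic
likelihood-ratio deviance used to filter main-effect-driven SNP pairs.

The k-locus test treats the 3^k joint genotypes as rows of a 3^k x 2 table
and compares observed cell counts with independence expectations.  Rows
with zero margin are skipped in the summation while the degrees of freedom
stay at 3^k - 1, keeping statistics comparable across tables with empty
genotype combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .genotype_data import MISSING, ContingencyTable, GenotypeDataset

__all__ = [
    "TestResult",
    "SignificanceScheme",
    "LogisticFit",
    "LrtResult",
    "chi_squared_test",
    "chi_squared_stats_batch",
    "bonferroni_level",
    "critical_statistic",
    "fit_logistic",
    "lrt_deviance",
]


@dataclass
class TestResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class SignificanceScheme:
    """Two-threshold significance scheme for the pairwise scan.

    alpha = alpha0 / C(M,2) is the Bonferroni-corrected significant level;
    alpha_prime = omega * alpha (capped at alpha0) is the relaxed level
    admitting pairs with intermediate association.  chi2_alpha and
    chi2_alpha_prime are the matching critical statistics at 8 df.
    """

    alpha0: float
    M: int
    omega: float
    alpha: float = field(init=False)
    alpha_prime: float = field(init=False)
    chi2_alpha: float = field(init=False)
    chi2_alpha_prime: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha0 < 1.0:
            raise ValueError("alpha0 must lie in (0,1)")
        if self.M < 2:
            raise ValueError("need at least two SNPs")
        if self.omega < 1.0:
            raise ValueError("omega must be >= 1")
        self.alpha = bonferroni_level(self.alpha0, self.M, 2)
        # cap: the intermediate band never admits pairs failing the nominal
        # uncorrected level alpha0 (relevant only for small M, where
        # omega * alpha would exceed alpha0 or even 1)
        self.alpha_prime = min(self.omega * self.alpha, self.alpha0)
        self.chi2_alpha = critical_statistic(self.alpha, df=8)
        self.chi2_alpha_prime = critical_statistic(self.alpha_prime, df=8)


@dataclass
class LogisticFit:
    beta: np.ndarray
    log_likelihood: float
    converged: bool
    ridged: bool
    n_iter: int


@dataclass
class LrtResult:
    logL_full: float
    logL_reduced: float
    deviance: float
    df: int
    p_value: float
    flags: tuple[bool, bool]
    pruned_levels: tuple[str, ...] = ()


def chi_squared_test(table: ContingencyTable) -> TestResult:
    """Chi-squared test of joint-genotype/status independence, df = 3^k - 1."""
    counts = np.asarray(table.counts, dtype=float)
    col = counts.sum(axis=0)
    if (col == 0).any():
        raise ValueError("degenerate design: a phenotype class has zero samples in the table")
    n = counts.sum()
    row = counts.sum(axis=1)
    keep = row > 0
    expected = np.outer(row[keep], col) / n
    stat = float(((counts[keep] - expected) ** 2 / expected).sum())
    df = 3 ** table.k - 1
    return TestResult(statistic=stat, df=df, p_value=float(chi2_dist.sf(stat, df)))


def chi_squared_stats_batch(counts: np.ndarray) -> np.ndarray:
    """Vectorized chi-squared statistics for a batch of tables.

    ``counts``: (R, 2, B) float/int array of B tables with R genotype rows.
    Returns (B,) statistics; a table with a zero column margin yields NaN.
    Zero-margin rows are skipped exactly as in :func:`chi_squared_test`.
    """
    c = np.asarray(counts, dtype=np.float64)
    n = c.sum(axis=(0, 1))                       # (B,)
    row = c.sum(axis=1)                          # (R, B)
    col = c.sum(axis=0)                          # (2, B)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = row[:, None, :] * col[None, :, :] / n
        terms = (c - expected) ** 2 / expected
    terms[np.broadcast_to((row == 0)[:, None, :], terms.shape)] = 0.0
    stat = terms.sum(axis=(0, 1))
    stat[(col == 0).any(axis=0)] = np.nan
    return stat


def bonferroni_level(alpha0: float, M: int, k: int = 2) -> float:
    """Bonferroni-corrected level alpha0 / C(M, k) for an order-k scan."""
    if not 0.0 < alpha0 < 1.0:
        raise ValueError("alpha0 must lie in (0,1)")
    if k < 1:
        raise ValueError("order k must be >= 1")
    if M < k:
        raise ValueError(f"M={M} must be >= k={k}")
    return alpha0 / comb(M, k)


def critical_statistic(level: float, df: int) -> float:
    """Inverse upper-tail chi-squared: the statistic whose survival
    probability at ``df`` degrees of freedom equals ``level``."""
    if not 0.0 < level < 1.0:
        raise ValueError("significance level must lie in (0,1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(chi2_dist.isf(level, df))


# ---------------------------------------------------------------------------
# Logistic regression (Newton-Raphson) and the likelihood-ratio deviance
# ---------------------------------------------------------------------------

_MAX_ITER = 50
_TOL = 1e-8
_RIDGE = 1e-6
_SEPARATION_NORM = 30.0


def _binomial_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), computed stably
    return float((y * eta - np.logaddexp(0.0, eta)).sum())


def fit_logistic(design: np.ndarray, y: np.ndarray) -> LogisticFit:
    """Maximum-likelihood logistic fit by Newton-Raphson.

    Converges when the log-likelihood improves by less than 1e-8, with at
    most 50 iterations.  Complete separation (diverging linear predictor or
    a singular Hessian) is resolved by a 1e-6 ridge on the Hessian and
    reported via ``ridged``.
    """
    X = np.asarray(design, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("design rows must match the response length")
    beta = np.zeros(X.shape[1])
    eta = X @ beta
    logl = _binomial_loglik(eta, y)
    ridged = False
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        w = p * (1.0 - p)
        grad = X.T @ (y - p)
        hess = (X.T * w) @ X
        if ridged:
            hess = hess + _RIDGE * np.eye(X.shape[1])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            ridged = True
            hess = hess + _RIDGE * np.eye(X.shape[1])
            step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.linalg.norm(beta) > _SEPARATION_NORM and not ridged:
            ridged = True
        eta = X @ beta
        new_logl = _binomial_loglik(eta, y)
        if abs(new_logl - logl) < _TOL:
            logl = max(new_logl, logl)
            converged = True
            break
        logl = new_logl
    return LogisticFit(beta=beta, log_likelihood=logl, converged=converged,
                       ridged=ridged, n_iter=it)


def _indicators(g: np.ndarray, label: str) -> tuple[list[np.ndarray], list[str]]:
    cols, names = [], []
    for level in (1, 2):
        col = (g == level).astype(np.float64)
        cols.append(col)
        names.append(f"{label}{level}")
    return cols, names


def lrt_deviance(
    ds: GenotypeDataset, pair: tuple[int, int], flags: tuple[bool, bool]
) -> LrtResult:
    """Deviance D = 2(ln L_full - ln L_reduced) for one SNP pair.

    Each SNP enters as two genotype indicators (codes 1 and 2 vs baseline
    0).  The full model holds both SNPs' indicators plus their four
    pairwise products; the reduced model holds only the indicators of the
    flagged (strong-main-effect) SNP(s).  Nominal df is 4 when both SNPs
    are flagged and 6 when exactly one is; indicator columns for genotype
    levels absent from the data are pruned from both models and the df
    reduced accordingly.
    """
    i, j = pair
    fi, fj = flags
    if not (fi or fj):
        raise ValueError("at least one SNP of the pair must be flagged")
    gi = ds.genotypes[:, i]
    gj = ds.genotypes[:, j]
    keep = (gi != MISSING) & (gj != MISSING)
    gi, gj, y = gi[keep], gj[keep], ds.phenotype[keep].astype(np.float64)
    for g, idx in ((gi, i), (gj, j)):
        if np.unique(g).size < 2:
            raise ValueError(f"SNP index {idx} is monomorphic in the analyzed samples")

    cols_i, names_i = _indicators(gi, "xi")
    cols_j, names_j = _indicators(gj, "xj")
    inter_cols = [ci * cj for ci in cols_i for cj in cols_j]
    inter_names = [f"{ni}:{nj}" for ni in names_i for nj in names_j]

    pruned: list[str] = []

    def build(cols: list[np.ndarray], names: list[str]) -> np.ndarray:
        kept = [np.ones_like(y)]
        for c, name in zip(cols, names):
            if c.any():
                kept.append(c)
            elif name not in pruned:
                pruned.append(name)
        return np.column_stack(kept)

    full_cols = cols_i + cols_j + inter_cols
    full_names = names_i + names_j + inter_names
    reduced_cols = (cols_i if fi else []) + (cols_j if fj else [])
    reduced_names = (names_i if fi else []) + (names_j if fj else [])

    X_full = build(full_cols, full_names)
    X_red = build(reduced_cols, reduced_names)

    fit_full = fit_logistic(X_full, y)
    fit_red = fit_logistic(X_red, y)
    deviance = 2.0 * (fit_full.log_likelihood - fit_red.log_likelihood)
    df = X_full.shape[1] - X_red.shape[1]
    if df < 1:
        raise ValueError("full model has no parameters beyond the reduced model")
    return LrtResult(
        logL_full=fit_full.log_likelihood,
        logL_reduced=fit_red.log_likelihood,
        deviance=deviance,
        df=df,
        p_value=float(chi2_dist.sf(max(deviance, 0.0), df)),
        flags=(bool(fi), bool(fj)),
        pruned_levels=tuple(pruned),
    )
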