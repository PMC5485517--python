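"""Simulation of case-control data under multi-locus disease models.

A disease model is a penetrance table f(g1..gk) over the 3^k joint
genotypes of the k disease loci.  Under Hardy-Weinberg genotype
frequencies it induces a prevalence P(D) = E[f(G)], per-locus marginal
penetrances, per-locus marginal effect sizes

    lambda = odds(P_Aa) / odds(P_AA) - 1

(heterozygote vs common-homozygote penetrance odds ratio minus one), and a
heritability on the penetrance scale h2 = Var(f(G)) / (P(D)(1 - P(D))).

Three built-in three-locus families:

* ``multiplicative3``: f = a (1 + theta)^(g1 g2 g3), calibrated so each
  locus' lambda hits its target at the given MAF and baseline prevalence;
* ``threshold3``: f = a (1 + theta) when every locus carries at least one
  minor allele, else a; same calibration;
* ``pure3``: a no-marginal-effect model at MAF 0.5,
  f = P + B sum_{i<j} t_i t_j + A t1 t2 t3 with t(g) = +1 for homozygotes
  and -1 for heterozygotes.  Each t is a zero-mean +-1 variable under HWE
  at MAF 0.5, so every single-locus marginal penetrance equals P exactly
  (lambda = 0) while pairwise marginals remain informative and
  h2 = (3 B^2 + A^2) / (P (1 - P)) hits its target exactly.

Datasets embed the k disease loci (or LD-coupled markers when r2 < 1)
at random columns among M background SNPs drawn at HWE with uniform MAFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt
from typing import Callable, Iterable

import numpy as np
from scipy.optimize import brentq

from .genotype_data import GenotypeDataset

__all__ = [
    "PenetranceModel",
    "SimulationConfig",
    "PowerResult",
    "CalibrationError",
    "genotypes_hwe",
    "genotype_probabilities",
    "marginal_effect_size",
    "build_model",
    "sample_case_control",
    "ld_marker",
    "estimate_power",
]

#: fraction of the pure3 penetrance variance carried by the three-way term
PURE3_THREE_WAY_FRACTION = 0.5


class CalibrationError(ValueError):
    """Requested (lambda / h2, MAF, prevalence) combination is unattainable."""


def genotype_probabilities(maf: float) -> np.ndarray:
    """HWE genotype probabilities ((1-p)^2, 2p(1-p), p^2) at allele freq p."""
    p = float(maf)
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])


def genotypes_hwe(maf: float, count: int, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. genotype draws at HWE: Binomial(2, maf) minor-allele counts."""
    if not 0.0 <= maf <= 0.5:
        raise ValueError("maf must lie in [0, 0.5]")
    return rng.binomial(2, maf, size=count).astype(np.int8)


@dataclass
class PenetranceModel:
    """Penetrance table over the 3^k joint genotypes of k disease loci."""

    mafs: tuple[float, ...]
    table: np.ndarray              # shape (3,) * k, entries in [0, 1]
    family: str = "custom_table"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=np.float64)
        self.mafs = tuple(float(m) for m in self.mafs)
        k = len(self.mafs)
        if self.table.shape != (3,) * k:
            raise ValueError(f"table shape {self.table.shape} does not match k={k} loci")
        if ((self.table < 0) | (self.table > 1)).any():
            raise ValueError("penetrance entries must lie in [0, 1]")
        prev = self.prevalence
        if not 0.0 < prev < 1.0:
            raise ValueError(f"prevalence {prev} must lie in (0, 1)")

    @property
    def k(self) -> int:
        return len(self.mafs)

    def _weights(self) -> np.ndarray:
        w = genotype_probabilities(self.mafs[0])
        for m in self.mafs[1:]:
            w = np.multiply.outer(w, genotype_probabilities(m))
        return w

    @property
    def prevalence(self) -> float:
        return float((self._weights() * self.table).sum())

    def marginal_penetrances(self, locus: int) -> np.ndarray:
        """(P_AA, P_Aa, P_aa) for one locus: the table averaged over the
        other loci at their HWE genotype probabilities."""
        w = self._weights()
        num = np.moveaxis(self.table * w, locus, 0).sum(axis=tuple(range(1, self.k)))
        den = np.moveaxis(w, locus, 0).sum(axis=tuple(range(1, self.k)))
        return num / den

    @property
    def lambdas(self) -> tuple[float, ...]:
        return tuple(marginal_effect_size(self, l) for l in range(self.k))

    @property
    def h2(self) -> float:
        w = self._weights()
        prev = self.prevalence
        var = float((w * (self.table - prev) ** 2).sum())
        return var / (prev * (1.0 - prev))


def marginal_effect_size(model: PenetranceModel, locus: int) -> float:
    """lambda = odds(P_Aa) / odds(P_AA) - 1 for one disease locus."""
    p_aa, p_het, _ = model.marginal_penetrances(locus)
    if p_aa in (0.0, 1.0) or p_het in (0.0, 1.0):
        raise ValueError("marginal penetrance 0 or 1: odds undefined")
    return (p_het / (1 - p_het)) / (p_aa / (1 - p_aa)) - 1.0


# ---------------------------------------------------------------------------
# Model families
# ---------------------------------------------------------------------------

def _combo_grid(k: int) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(3)] * k, indexing="ij")
    return np.stack(grids, axis=-1)  # (3,)*k + (k,)


def _calibrated_family(
    shape_fn: Callable[[np.ndarray, float], np.ndarray],
    maf: float,
    lam_target: float | None,
    prevalence: float,
    family: str,
    theta: float | None = None,
) -> PenetranceModel:
    """Calibrate f = min(a * shape(g; theta), 1): the baseline a is solved
    so the prevalence hits its target at each theta (penetrance saturates
    at 1), then theta by root-finding on lambda(theta) - lam_target."""
    mafs = (maf, maf, maf)
    grid = _combo_grid(3)
    gp = genotype_probabilities(maf)
    w = np.multiply.outer(np.multiply.outer(gp, gp), gp)

    def model_for(theta: float) -> PenetranceModel:
        shape = shape_fn(grid, theta)

        def prev_gap(a: float) -> float:
            return float((w * np.minimum(a * shape, 1.0)).sum()) - prevalence

        if prev_gap(1.0) < 0.0:
            raise CalibrationError(
                f"{family}: prevalence {prevalence} unreachable at theta={theta:g}"
            )
        a = brentq(prev_gap, 0.0, 1.0, xtol=1e-15, rtol=1e-14)
        table = np.minimum(a * shape, 1.0)
        return PenetranceModel(mafs, table, family=family,
                               params={"maf": maf, "lambda": lam_target,
                                       "prevalence": prevalence, "theta": theta,
                                       "baseline": a})

    if theta is not None:
        return model_for(float(theta))

    def gap(theta: float) -> float:
        return marginal_effect_size(model_for(theta), 0) - lam_target

    if lam_target == 0.0:
        return model_for(0.0)
    if lam_target < 0.0:
        raise CalibrationError(f"{family}: lambda target must be >= 0")
    lo, hi = 0.0, 1.0
    while gap(hi) < 0.0:
        hi *= 2.0
        if hi > 1e6:
            raise CalibrationError(
                f"{family}: lambda target {lam_target} unreachable at "
                f"maf={maf}, prevalence={prevalence}"
            )
    theta = brentq(gap, lo, hi, xtol=1e-12, rtol=1e-14)
    return model_for(float(theta))


def _pure3(h2_target: float, prevalence: float | None) -> PenetranceModel:
    c = PURE3_THREE_WAY_FRACTION
    kappa = sqrt(c) + sqrt((1 - c) / 3.0)       # (A + B) per unit sqrt(V)
    if prevalence is None:
        # smallest prevalence at which the two-sided table stays in [0,1]
        prevalence = kappa ** 2 * h2_target / (1.0 + kappa ** 2 * h2_target)
    v = h2_target * prevalence * (1.0 - prevalence)
    a = sqrt(c * v)
    b = sqrt((1 - c) * v / 3.0)
    lo = prevalence - a - b
    hi = prevalence + 3 * b + a
    if lo < -1e-12 or hi > 1.0 + 1e-12:
        p_min = kappa ** 2 * h2_target / (1.0 + kappa ** 2 * h2_target)
        raise CalibrationError(
            f"pure3: h2={h2_target} infeasible at prevalence={prevalence:g}; "
            f"feasible prevalence starts at {p_min:g}"
        )
    t = np.array([1.0, -1.0, 1.0])              # zero-mean at MAF 0.5
    t1, t2, t3 = np.ix_(t, t, t)
    table = prevalence + b * (t1 * t2 + t1 * t3 + t2 * t3) + a * t1 * t2 * t3
    table = np.clip(table, 0.0, 1.0)
    return PenetranceModel((0.5, 0.5, 0.5), table, family="pure3",
                           params={"h2": h2_target, "prevalence": prevalence})


def build_model(family: str, **params) -> PenetranceModel:
    """Build a calibrated penetrance model.

    Families: ``multiplicative3`` (maf, lam, prevalence=0.01),
    ``threshold3`` (maf, lam, prevalence=0.01), ``pure3`` (h2,
    prevalence=None -> minimal feasible), ``custom_table`` (table, mafs).
    """
    if family == "multiplicative3":
        return _calibrated_family(
            lambda g, th: (1.0 + th) ** (g[..., 0] * g[..., 1] * g[..., 2]),
            params["maf"], params.get("lam"), params.get("prevalence", 0.01),
            "multiplicative3", theta=params.get("theta"),
        )
    if family == "threshold3":
        return _calibrated_family(
            lambda g, th: 1.0 + th * (g.min(axis=-1) >= 1),
            params["maf"], params.get("lam"), params.get("prevalence", 0.01),
            "threshold3", theta=params.get("theta"),
        )
    if family == "pure3":
        return _pure3(params["h2"], params.get("prevalence"))
    if family == "custom_table":
        return PenetranceModel(tuple(params["mafs"]), np.asarray(params["table"]),
                               family="custom_table")
    raise ValueError(f"unknown model family {family!r}")


# ---------------------------------------------------------------------------
# Dataset sampling
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    M: int = 100
    n_cases: int = 200
    n_controls: int = 200
    background_maf_range: tuple[float, float] = (0.05, 0.5)
    r2: float = 1.0
    seed: int | None = None
    n_replicates: int = 100
    max_draw_factor: float = 50.0   # budget multiplier on the expected draws

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        if not 0.0 < self.r2 <= 1.0:
            raise ValueError("r2 must lie in (0, 1]")


@dataclass
class PowerResult:
    S: int
    ND: int

    @property
    def power(self) -> float:
        return self.S / self.ND


def ld_marker(
    disease_hap: np.ndarray, r2: float, maf: float, rng: np.random.Generator
) -> np.ndarray:
    """Marker genotypes in LD r2 with a disease locus (equal MAFs).

    ``disease_hap``: (n, 2) binary haplotype alleles of the disease locus.
    Per haplotype the marker allele copies the disease allele with
    probability 1 - eps and is an independent frequency-matched draw with
    probability eps, where eps = 1 - sqrt(r2): the haplotype correlation is
    sqrt(r2), hence squared correlation r2.  r2 = 1 returns the disease
    genotypes themselves.
    """
    hap = np.asarray(disease_hap)
    if r2 == 1.0:
        return hap.sum(axis=1).astype(np.int8)
    eps = 1.0 - sqrt(r2)
    copy = rng.random(hap.shape) >= eps
    fresh = rng.random(hap.shape) < maf
    return np.where(copy, hap, fresh).sum(axis=1).astype(np.int8)


def sample_case_control(
    model: PenetranceModel, cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[GenotypeDataset, dict]:
    """Draw a dataset with exactly n_cases cases and n_controls controls.

    Full genotype vectors are drawn at HWE (disease loci at the model MAFs,
    background SNPs at MAFs uniform in ``background_maf_range``); each draw
    becomes a case with probability f(g_disease).  With r2 < 1 the
    genotyped columns are LD markers of the latent disease loci.  The truth
    record holds the disease-locus column indices.
    """
    k = model.k
    prev = model.prevalence
    need = np.array([cfg.n_cases, cfg.n_controls])
    exp_draws = cfg.n_cases / prev + cfg.n_controls / (1.0 - prev)
    budget = int(cfg.max_draw_factor * exp_draws) + 1000

    disease_cols = np.sort(rng.choice(cfg.M, size=k, replace=False))
    bg_mafs = rng.uniform(*cfg.background_maf_range, size=cfg.M)

    rows_case: list[np.ndarray] = []
    rows_ctrl: list[np.ndarray] = []
    drawn = 0
    while (len(rows_case) < need[0]) or (len(rows_ctrl) < need[1]):
        if drawn >= budget:
            raise RuntimeError(
                f"draw budget {budget} exhausted at prevalence {prev:g}: "
                f"{len(rows_case)}/{need[0]} cases, {len(rows_ctrl)}/{need[1]} controls"
            )
        batch = int(min(budget - drawn, max(256, exp_draws // 4)))
        drawn += batch
        hap = rng.random((batch, k, 2)) < np.array(model.mafs)[None, :, None]
        dg = hap.sum(axis=2).astype(np.int8)          # disease genotypes
        f = model.table[tuple(dg.T)]
        is_case = rng.random(batch) < f
        if cfg.r2 == 1.0:
            marker = dg
        else:
            marker = np.stack(
                [ld_marker(hap[:, l, :], cfg.r2, model.mafs[l], rng) for l in range(k)],
                axis=1,
            )
        for sel, rows, cap in ((is_case, rows_case, need[0]),
                               (~is_case, rows_ctrl, need[1])):
            take = marker[sel][: cap - len(rows)]
            rows.extend(take)

    geno = np.empty((cfg.n_cases + cfg.n_controls, cfg.M), dtype=np.int8)
    n = geno.shape[0]
    for j in range(cfg.M):
        geno[:, j] = genotypes_hwe(bg_mafs[j], n, rng)
    disease_block = np.vstack(rows_case + rows_ctrl)
    geno[:, disease_cols] = disease_block
    phenotype = np.concatenate(
        [np.ones(cfg.n_cases, dtype=np.int8), np.zeros(cfg.n_controls, dtype=np.int8)]
    )
    snp_ids = [f"snp{j}" for j in range(cfg.M)]
    ds = GenotypeDataset(geno, phenotype, snp_ids)
    truth = {
        "disease_loci": tuple(int(c) for c in disease_cols),
        "family": model.family,
        "params": dict(model.params),
        "r2": cfg.r2,
    }
    return ds, truth


def estimate_power(
    detector: Callable[[GenotypeDataset], Iterable[tuple[int, ...]]],
    model: PenetranceModel,
    cfg: SimulationConfig,
) -> PowerResult:
    """Power = S / ND: the fraction of simulated datasets in which the
    detector's reported sets contain the exact planted locus tuple."""
    if cfg.n_replicates < 1:
        raise ValueError("need at least one replicate")
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_replicates)
    s = 0
    for seq in seeds:
        rng = np.random.default_rng(seq)
        ds, truth = sample_case_control(model, cfg, rng)
        target = tuple(sorted(truth["disease_loci"]))
        reported = {tuple(sorted(r)) for r in detector(ds)}
        if target in reported:
            s += 1
    return PowerResult(S=s, ND=cfg.n_replicates)
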