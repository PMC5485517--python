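"""Case-control genotype data: loading, quality control, bitwise encoding.

Genotypes are coded 0/1/2 as the number of minor-allele copies; ``-1``
marks a missing genotype.  The phenotype is binary (1 = case, 0 = control).

Two counting backends are provided and kept in exact agreement:

* a bitwise backend (:class:`BitEncodedDataset`, :func:`contingency_table`)
  that stores one packed bit-array per genotype code per phenotype class and
  counts joint genotypes with AND + popcount;
* dense one-hot helpers (:func:`class_onehot`, :func:`joint_genotype_counts`)
  used by the batched all-pairs scan and the exhaustive subset search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeDataset",
    "BitEncodedDataset",
    "ContingencyTable",
    "QcThresholds",
    "EmptyDatasetError",
    "load_dataset",
    "write_dataset_tsv",
    "hwe_pvalue",
    "quality_control",
    "bit_encode",
    "contingency_table",
    "class_onehot",
    "joint_genotype_counts",
]


class EmptyDatasetError(ValueError):
    """Raised when quality control removes every SNP (or sample)."""


@dataclass
class GenotypeDataset:
    """N samples x M SNPs of genotype codes plus a binary phenotype."""

    genotypes: np.ndarray          # (N, M) int8, codes {0,1,2}, -1 missing
    phenotype: np.ndarray          # (N,) int8, 1 = case, 0 = control
    snp_ids: list[str]
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        n, m = self.genotypes.shape
        if self.phenotype.shape != (n,):
            raise ValueError("phenotype length does not match genotype rows")
        if not np.isin(self.phenotype, [0, 1]).all():
            raise ValueError("phenotype must be binary (0 = control, 1 = case)")
        valid = np.isin(self.genotypes, [MISSING, 0, 1, 2])
        if not valid.all():
            raise ValueError("genotype codes must be in {0,1,2} or -1 (missing)")
        if len(self.snp_ids) != m:
            raise ValueError("snp_ids length does not match genotype columns")
        if len(set(self.snp_ids)) != m:
            raise ValueError("snp_ids must be unique")
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match genotype rows")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotype == 0).sum())


@dataclass
class BitEncodedDataset:
    """Per-SNP, per-genotype-code bit masks split by phenotype class.

    ``case_bits[s, g]`` / ``control_bits[s, g]`` is the packed bit-array
    (np.packbits layout) selecting the samples of that class carrying
    genotype code ``g`` at SNP ``s``.  A missing genotype is 0 in all three
    masks of its class, so AND-based joint counting silently drops samples
    missing at any SNP of the queried set.
    """

    case_bits: np.ndarray      # (M, 3, ceil(na/8)) uint8
    control_bits: np.ndarray   # (M, 3, ceil(nu/8)) uint8
    n_cases: int
    n_controls: int
    snp_ids: list[str]

    @property
    def n_snps(self) -> int:
        return self.case_bits.shape[0]


@dataclass
class ContingencyTable:
    """3^k x 2 table of joint-genotype counts by case/control status.

    Rows are ordered lexicographically over (g1, ..., gk), gi in {0,1,2}.
    """

    counts: np.ndarray  # (3^k, 2) int64; column 0 = case, 1 = control
    k: int

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class QcThresholds:
    snp_call_rate_min: float = 0.95
    sample_call_rate_min: float = 0.98
    hwe_p_min: float = 0.0001
    maf_min: float = 0.1

    def __post_init__(self) -> None:
        for name in ("snp_call_rate_min", "sample_call_rate_min", "hwe_p_min", "maf_min"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def load_dataset(path: str, format: str = "tsv") -> GenotypeDataset:
    """Load a case-control genotype dataset.

    ``tsv``: header row ``sample  phenotype  <snp ids...>``; genotype cells
    in {0,1,2,NA}, phenotype in {0,1}.  Codes are taken as minor-allele
    counts as documented for the dialect.

    ``ped_map``: PLINK text files; ``path`` may be the ``.ped`` file or the
    common prefix.  Alleles are recoded to minor-allele counts with the
    minor allele determined over all samples; ``0`` is the missing allele.
    """
    if format == "tsv":
        return _load_tsv(path)
    if format == "ped_map":
        return _load_ped_map(path)
    raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'ped_map')")


def _load_tsv(path: str) -> GenotypeDataset:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 3:
        raise ValueError("genotype TSV needs sample, phenotype and >=1 SNP column")
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    try:
        phenotype = df.iloc[:, 1].astype(int).to_numpy()
    except ValueError as exc:
        raise ValueError(f"non-integer phenotype in {path}: {exc}") from None
    snp_ids = list(df.columns[2:])
    cells = df.iloc[:, 2:].to_numpy(dtype=object)
    geno = np.empty(cells.shape, dtype=np.int8)
    for j in range(cells.shape[1]):
        for i in range(cells.shape[0]):
            v = cells[i, j]
            if isinstance(v, float) or v in ("NA", "", "nan"):
                geno[i, j] = MISSING
            elif v in ("0", "1", "2"):
                geno[i, j] = int(v)
            else:
                raise ValueError(
                    f"parse error at line {i + 2}, SNP {snp_ids[j]}: bad genotype {v!r}"
                )
    return GenotypeDataset(geno, phenotype, snp_ids, sample_ids)


def _load_ped_map(path: str) -> GenotypeDataset:
    prefix = path[:-4] if path.endswith((".ped", ".map")) else path
    with open(prefix + ".map") as fh:
        snp_ids = []
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 2:
                raise ValueError(f"{prefix}.map line {lineno}: expected >=2 fields")
            snp_ids.append(parts[1])
    m = len(snp_ids)

    allele_rows: list[list[tuple[str, str]]] = []
    phenos: list[int] = []
    sample_ids: list[str] = []
    with open(prefix + ".ped") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{prefix}.ped line {lineno}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            sample_ids.append(parts[1])
            phenos.append(int(parts[5]))
            allele_rows.append(
                [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(m)]
            )

    pheno_set = set(phenos)
    if pheno_set <= {1, 2}:
        phenotype = np.array([p - 1 for p in phenos])
    elif pheno_set <= {0, 1}:
        phenotype = np.array(phenos)
    else:
        raise ValueError(f"unsupported phenotype codes {sorted(pheno_set)} in {prefix}.ped")

    n = len(allele_rows)
    geno = np.full((n, m), MISSING, dtype=np.int8)
    for j in range(m):
        counts: dict[str, int] = {}
        for i in range(n):
            for a in allele_rows[i][j]:
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        if len(counts) > 2:
            raise ValueError(f"non-biallelic SNP {snp_ids[j]}: alleles {sorted(counts)}")
        if not counts:
            continue  # fully missing column
        # minor allele = less frequent over all samples; on a tie the
        # lexicographically later allele is treated as minor (deterministic)
        if len(counts) == 1:
            minor = "\x00"  # no minor allele observed: every genotype codes 0
        else:
            a, b = sorted(counts)
            if counts[a] == counts[b]:
                minor = b
            else:
                minor = a if counts[a] < counts[b] else b
        for i in range(n):
            a1, a2 = allele_rows[i][j]
            if a1 == "0" or a2 == "0":
                continue
            geno[i, j] = (a1 == minor) + (a2 == minor)
    return GenotypeDataset(geno, phenotype, snp_ids, sample_ids)


def write_dataset_tsv(ds: GenotypeDataset, path: str) -> None:
    """Write the genotype TSV dialect read back by :func:`load_dataset`."""
    with open(path, "w") as fh:
        fh.write("sample\tphenotype\t" + "\t".join(ds.snp_ids) + "\n")
        for i in range(ds.n_samples):
            cells = ["NA" if g == MISSING else str(int(g)) for g in ds.genotypes[i]]
            fh.write(f"{ds.sample_ids[i]}\t{int(ds.phenotype[i])}\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def hwe_pvalue(genotype_counts: tuple[int, int, int]) -> float:
    """Hardy-Weinberg goodness-of-fit p-value (1-df chi-squared).

    ``genotype_counts`` = (n0, n1, n2) observed counts of the three genotype
    codes.  A monomorphic SNP (allele frequency 0 or 1) returns p = 1 by
    convention.
    """
    from scipy.stats import chi2

    n0, n1, n2 = (int(c) for c in genotype_counts)
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    p = (2 * n2 + n1) / (2 * n)  # minor-allele frequency in the sample
    if p == 0.0 or p == 1.0:
        return 1.0
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
    observed = np.array([n0, n1, n2], dtype=float)
    stat = float(((observed - expected) ** 2 / expected).sum())
    return float(chi2.sf(stat, df=1))


def quality_control(
    ds: GenotypeDataset, t: QcThresholds | None = None
) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Apply the fixed QC cascade and return (filtered dataset, report).

    Filter order: sample call rate -> SNP call rate -> HWE in controls ->
    MAF, each computed on the data surviving the previous step.  The report
    lists one row per removal: (entity, kind, rule, value, threshold).
    """
    if t is None:
        t = QcThresholds()
    rows: list[tuple[str, str, str, float, float]] = []
    geno = ds.genotypes
    pheno = ds.phenotype
    sample_ids = list(ds.sample_ids)
    snp_ids = list(ds.snp_ids)

    # 1. sample call rate
    call = (geno != MISSING).mean(axis=1)
    keep = call >= t.sample_call_rate_min
    for i in np.flatnonzero(~keep):
        rows.append((sample_ids[i], "sample", "sample_call_rate", float(call[i]),
                     t.sample_call_rate_min))
    geno = geno[keep]
    pheno = pheno[keep]
    sample_ids = [s for s, k in zip(sample_ids, keep) if k]
    if geno.shape[0] == 0:
        raise EmptyDatasetError("all samples removed by QC")

    # 2. SNP call rate
    call = (geno != MISSING).mean(axis=0)
    keep = call >= t.snp_call_rate_min
    for j in np.flatnonzero(~keep):
        rows.append((snp_ids[j], "snp", "snp_call_rate", float(call[j]),
                     t.snp_call_rate_min))
    geno = geno[:, keep]
    snp_ids = [s for s, k in zip(snp_ids, keep) if k]

    # 3. HWE in controls
    controls = geno[pheno == 0]
    keep_mask = np.ones(geno.shape[1], dtype=bool)
    for j in range(geno.shape[1]):
        col = controls[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            continue
        counts = tuple(int((col == g).sum()) for g in (0, 1, 2))
        p = hwe_pvalue(counts)
        if p < t.hwe_p_min:
            keep_mask[j] = False
            rows.append((snp_ids[j], "snp", "hwe_controls", p, t.hwe_p_min))
    geno = geno[:, keep_mask]
    snp_ids = [s for s, k in zip(snp_ids, keep_mask) if k]

    # 4. MAF over all surviving samples
    keep_mask = np.ones(geno.shape[1], dtype=bool)
    for j in range(geno.shape[1]):
        col = geno[:, j]
        col = col[col != MISSING]
        f = float(col.mean()) / 2.0 if col.size else 0.0
        maf = min(f, 1.0 - f)
        if maf < t.maf_min:
            keep_mask[j] = False
            rows.append((snp_ids[j], "snp", "maf", maf, t.maf_min))
    geno = geno[:, keep_mask]
    snp_ids = [s for s, k in zip(snp_ids, keep_mask) if k]

    if geno.shape[1] == 0:
        raise EmptyDatasetError("all SNPs removed by QC")

    report = pd.DataFrame(rows, columns=["entity", "kind", "rule", "value", "threshold"])
    return GenotypeDataset(geno, pheno, snp_ids, sample_ids), report


# ---------------------------------------------------------------------------
# Bitwise encoding and contingency tables
# ---------------------------------------------------------------------------

def bit_encode(ds: GenotypeDataset) -> BitEncodedDataset:
    """Pack per-genotype-class sample masks into bit-arrays per phenotype class."""
    case = ds.genotypes[ds.phenotype == 1]
    ctrl = ds.genotypes[ds.phenotype == 0]

    def pack(block: np.ndarray) -> np.ndarray:
        # block: (n_class, M) -> (M, 3, ceil(n/8)) uint8
        masks = np.stack([(block.T == g) for g in (0, 1, 2)], axis=1)
        return np.packbits(masks, axis=2)

    return BitEncodedDataset(
        case_bits=pack(case),
        control_bits=pack(ctrl),
        n_cases=case.shape[0],
        n_controls=ctrl.shape[0],
        snp_ids=list(ds.snp_ids),
    )


def contingency_table(bits: BitEncodedDataset, snps: tuple[int, ...]) -> ContingencyTable:
    """k-locus joint genotype x case/control table via AND + popcount.

    Samples missing at any of the k SNPs carry no set bit at that SNP and
    are therefore excluded from the whole table (listwise per table).
    """
    snps = tuple(int(s) for s in snps)
    k = len(snps)
    if k < 1:
        raise ValueError("need at least one SNP index")
    if len(set(snps)) != k:
        raise ValueError(f"duplicate SNP indices in {snps}")
    if not all(0 <= s < bits.n_snps for s in snps):
        raise IndexError(f"SNP index out of range in {snps}")

    counts = np.zeros((3 ** k, 2), dtype=np.int64)
    for u in range(3 ** k):
        # lexicographic row order over (g1..gk): g1 most significant digit
        combo = [(u // 3 ** (k - 1 - pos)) % 3 for pos in range(k)]
        for v, block in ((0, bits.case_bits), (1, bits.control_bits)):
            acc = block[snps[0], combo[0]]
            for pos in range(1, k):
                acc = acc & block[snps[pos], combo[pos]]
            counts[u, v] = int(np.bitwise_count(acc).sum())
    return ContingencyTable(counts=counts, k=k)


# ---------------------------------------------------------------------------
# Dense one-hot helpers (exact, vectorized counting for batch scans)
# ---------------------------------------------------------------------------

def class_onehot(ds: GenotypeDataset) -> tuple[np.ndarray, np.ndarray]:
    """One-hot genotype arrays (n_class, M, 3) float32 for cases and controls.

    Missing genotypes one-hot to the all-zero row, so GEMM-based joint
    counting agrees exactly with the bitwise backend.
    """
    def onehot(block: np.ndarray) -> np.ndarray:
        out = np.zeros(block.shape + (3,), dtype=np.float32)
        for g in (0, 1, 2):
            out[..., g] = block == g
        return out

    return onehot(ds.genotypes[ds.phenotype == 1]), onehot(ds.genotypes[ds.phenotype == 0])


def joint_genotype_counts(
    genotypes: np.ndarray, phenotype: np.ndarray, snps: tuple[int, ...]
) -> np.ndarray:
    """(3^k, 2) joint genotype counts via base-3 codes and bincount.

    Fast path for scoring individual SNP sets (ant-colony inner loop);
    exactly matches :func:`contingency_table`.
    """
    k = len(snps)
    cols = genotypes[:, list(snps)]
    valid = (cols != MISSING).all(axis=1)
    code = np.zeros(genotypes.shape[0], dtype=np.int64)
    for pos in range(k):
        code = code * 3 + cols[:, pos]
    code = code[valid] + (3 ** k) * (1 - phenotype[valid])  # case block first
    flat = np.bincount(code, minlength=2 * 3 ** k)
    return np.stack([flat[: 3 ** k], flat[3 ** k :]], axis=1).astype(np.int64)
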