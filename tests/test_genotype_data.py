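import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2 as chi2_dist

from epistage import (
    MISSING,
    EmptyDatasetError,
    GenotypeDataset,
    QcThresholds,
    bit_encode,
    contingency_table,
    hwe_pvalue,
    load_dataset,
    quality_control,
    write_dataset_tsv,
)
from epistage.genotype_data import class_onehot, joint_genotype_counts

from conftest import naive_contingency


# ---------------------------------------------------------------------- load

def test_tsv_identity_readback(tmp_path):
    path = tmp_path / "toy.tsv"
    path.write_text(
        "sample\tphenotype\trs1\trs2\n"
        "a\t1\t0\t2\n"
        "b\t1\t1\tNA\n"
        "c\t0\t2\t0\n"
        "d\t0\t0\t1\n"
    )
    ds = load_dataset(str(path), "tsv")
    assert ds.n_samples == 4 and ds.n_snps == 2
    assert ds.n_cases == 2 and ds.n_controls == 2
    assert ds.genotypes.tolist() == [[0, 2], [1, MISSING], [2, 0], [0, 1]]
    out = tmp_path / "rt.tsv"
    write_dataset_tsv(ds, str(out))
    ds2 = load_dataset(str(out), "tsv")
    assert np.array_equal(ds.genotypes, ds2.genotypes)
    assert np.array_equal(ds.phenotype, ds2.phenotype)


def test_ped_map_minor_allele_coding(tmp_path):
    # G is minor at rs1 (3 of 8 alleles); "0 0" marks a missing genotype
    (tmp_path / "toy.map").write_text("1 rs1 0 100\n")
    (tmp_path / "toy.ped").write_text(
        "f1 s1 0 0 1 2 A A\n"
        "f2 s2 0 0 1 2 A G\n"
        "f3 s3 0 0 1 1 G G\n"
        "f4 s4 0 0 1 1 0 0\n"
    )
    ds = load_dataset(str(tmp_path / "toy.ped"), "ped_map")
    assert ds.genotypes[:, 0].tolist() == [0, 1, 2, MISSING]
    assert ds.phenotype.tolist() == [1, 1, 0, 0]


def test_ped_map_rejects_non_biallelic(tmp_path):
    (tmp_path / "bad.map").write_text("1 rs9 0 1\n")
    (tmp_path / "bad.ped").write_text(
        "f1 s1 0 0 1 1 A A\nf2 s2 0 0 1 2 C G\nf3 s3 0 0 1 2 T T\n"
    )
    with pytest.raises(ValueError, match="rs9"):
        load_dataset(str(tmp_path / "bad.ped"), "ped_map")


def test_tsv_bad_genotype_reports_line(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("sample\tphenotype\trs1\na\t1\t0\nb\t0\t7\n")
    with pytest.raises(ValueError, match="line 3"):
        load_dataset(str(path), "tsv")


# ----------------------------------------------------------------------- HWE

def test_hwe_exact_proportions_give_p_one():
    # exact HWE at p=0.3, N=1000: statistic 0
    assert hwe_pvalue((490, 420, 90)) == pytest.approx(1.0)


def test_hwe_matches_textbook_gof():
    # p = 0.5 -> expected (250, 500, 250); statistic = 250 + 500 + 250
    stat = 1000.0
    assert hwe_pvalue((500, 0, 500)) == pytest.approx(float(chi2_dist.sf(stat, 1)))


def test_hwe_monomorphic_convention():
    assert hwe_pvalue((10, 0, 0)) == 1.0
    assert hwe_pvalue((0, 0, 7)) == 1.0


# ------------------------------------------------------------------------ QC

def _clean_dataset(n=40, m=4, seed=3):
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, 0.3, size=(n, m)).astype(np.int8)
    y = np.zeros(n, dtype=np.int8)
    y[: n // 2] = 1
    return GenotypeDataset(g, y, [f"s{j}" for j in range(m)])


def test_qc_clean_data_unchanged():
    ds = _clean_dataset()
    out, report = quality_control(ds)
    assert report.empty
    assert np.array_equal(out.genotypes, ds.genotypes)


def test_qc_removes_low_call_rate_snp():
    # many SNPs so two missing cells trip the SNP filter, not the sample one
    ds = _clean_dataset(n=20, m=100)
    g = ds.genotypes.copy()
    g[:2, 1] = MISSING  # 90% call rate < 95%; sample call rate stays 99%
    ds = GenotypeDataset(g, ds.phenotype, ds.snp_ids)
    out, report = quality_control(ds)
    assert "s1" not in out.snp_ids
    assert report.loc[report.entity == "s1", "rule"].item() == "snp_call_rate"


def test_qc_removes_low_maf_snp():
    ds = _clean_dataset(n=100, m=3)
    g = ds.genotypes.copy()
    g[:, 2] = 0
    g[:10, 2] = 1  # MAF 0.05 < 0.1
    ds = GenotypeDataset(g, ds.phenotype, ds.snp_ids)
    out, report = quality_control(ds)
    assert "s2" not in out.snp_ids
    assert report.loc[report.entity == "s2", "rule"].item() == "maf"


def test_qc_removes_hwe_violating_snp_in_controls():
    n = 200
    g = np.zeros((n, 2), dtype=np.int8)
    rng = np.random.default_rng(0)
    g[:, 0] = rng.binomial(2, 0.3, n)
    # half 0, half 2 in everyone: max HWE violation at MAF 0.5
    g[: n // 2, 1] = 2
    y = np.zeros(n, dtype=np.int8)
    y[: n // 2] = 1
    rng.shuffle(y)
    ds = GenotypeDataset(g, y, ["ok", "hwe_bad"])
    out, report = quality_control(ds)
    assert "hwe_bad" not in out.snp_ids
    assert (report.rule == "hwe_controls").any()


def test_qc_idempotent():
    rng = np.random.default_rng(5)
    g = rng.binomial(2, 0.3, size=(60, 6)).astype(np.int8)
    g[rng.random((60, 6)) < 0.01] = MISSING
    y = np.zeros(60, dtype=np.int8)
    y[:30] = 1
    ds = GenotypeDataset(g, y, [f"s{j}" for j in range(6)])
    once, _ = quality_control(ds)
    twice, rep2 = quality_control(once)
    assert rep2.empty
    assert np.array_equal(once.genotypes, twice.genotypes)


def test_qc_all_snps_removed_raises():
    g = np.zeros((30, 2), dtype=np.int8)  # MAF 0 everywhere
    y = np.zeros(30, dtype=np.int8)
    y[:15] = 1
    with pytest.raises(EmptyDatasetError):
        quality_control(GenotypeDataset(g, y, ["a", "b"]))


def test_qc_threshold_validation():
    with pytest.raises(ValueError):
        QcThresholds(maf_min=1.5)


# ------------------------------------------------------------- bit encoding

def test_bit_encode_example():
    g = np.array([[0], [0], [1], [2]], dtype=np.int8)
    y = np.ones(4, dtype=np.int8)
    bits = bit_encode(GenotypeDataset(g, y, ["s"], ["a", "b", "c", "d"]))
    unpacked = np.unpackbits(bits.case_bits[0], axis=-1)[:, :4]
    assert unpacked.tolist() == [[1, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1]]


def test_bit_encode_missing_in_no_mask(random_dataset):
    ds = random_dataset(n=30, m=3, seed=2, missing_rate=0.2)
    bits = bit_encode(ds)
    case_rows = ds.genotypes[ds.phenotype == 1]
    missing = np.flatnonzero(case_rows[:, 0] == MISSING)
    unpacked = np.unpackbits(bits.case_bits[0], axis=-1)[:, : case_rows.shape[0]]
    assert (unpacked[:, missing] == 0).all()


def test_popcounts_match_naive_tallies(random_dataset):
    ds = random_dataset(n=50, m=3, seed=7, missing_rate=0.1)
    bits = bit_encode(ds)
    for j in range(3):
        t = contingency_table(bits, (j,))
        assert np.array_equal(t.counts, naive_contingency(ds.genotypes, ds.phenotype, (j,)))


# ------------------------------------------------------- contingency tables

def test_contingency_all_mass_in_first_row():
    g = np.zeros((12, 2), dtype=np.int8)
    y = np.zeros(12, dtype=np.int8)
    y[:5] = 1
    bits = bit_encode(GenotypeDataset(g, y, ["a", "b"]))
    t = contingency_table(bits, (0, 1))
    assert t.counts[0].tolist() == [5, 7]
    assert t.counts[1:].sum() == 0


def test_contingency_duplicate_index_rejected(random_dataset):
    bits = bit_encode(random_dataset())
    with pytest.raises(ValueError):
        contingency_table(bits, (1, 1))


@pytest.mark.parametrize("k", [1, 2, 3, 4])
def test_bitwise_matches_bruteforce_counting(k, random_dataset):
    """Bitwise popcount counting equals nested-loop counting, with and
    without missing genotypes, for every k-subset of SNPs."""
    import itertools
    for seed, missing in [(11, 0.0), (12, 0.15)]:
        ds = random_dataset(n=60, m=5, seed=seed, missing_rate=missing, balanced=False)
        bits = bit_encode(ds)
        for snps in itertools.combinations(range(5), k):
            t = contingency_table(bits, snps)
            expect = naive_contingency(ds.genotypes, ds.phenotype, snps)
            assert np.array_equal(t.counts, expect)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2 ** 16),
    n=st.integers(8, 40),
    k=st.integers(1, 4),
    missing=st.booleans(),
)
def test_counting_invariant_bitwise_equals_naive(seed, n, k, missing):
    """Property: AND/popcount counting and nested-loop counting agree on
    arbitrary datasets, for any subset of up to four SNPs."""
    rng = np.random.default_rng(seed)
    m = 5
    g = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    if missing:
        g[rng.random((n, m)) < 0.2] = MISSING
    y = rng.integers(0, 2, size=n).astype(np.int8)
    ds = GenotypeDataset(g, y, [f"s{j}" for j in range(m)])
    snps = tuple(sorted(rng.choice(m, size=k, replace=False).tolist()))
    t = contingency_table(bit_encode(ds), snps)
    assert np.array_equal(t.counts, naive_contingency(g, y, snps))
    assert t.col_margins.sum() == (g[:, list(snps)] != MISSING).all(axis=1).sum()


def test_complete_data_margins(random_dataset):
    ds = random_dataset(n=80, m=4, seed=9)
    bits = bit_encode(ds)
    t = contingency_table(bits, (0, 1, 2))
    assert t.total == 80
    assert t.col_margins.tolist() == [ds.n_cases, ds.n_controls]


def test_dense_helpers_match_bitwise(random_dataset):
    ds = random_dataset(n=70, m=4, seed=21, missing_rate=0.1, balanced=False)
    bits = bit_encode(ds)
    # joint_genotype_counts (bincount path)
    for snps in [(0,), (1, 3), (0, 2, 3)]:
        assert np.array_equal(
            joint_genotype_counts(ds.genotypes, ds.phenotype, snps),
            contingency_table(bits, snps).counts,
        )
    # one-hot GEMM path for a pair
    xc, xu = class_onehot(ds)
    cc = xc[:, 1, :].T @ xc[:, 3, :]
    cu = xu[:, 1, :].T @ xu[:, 3, :]
    counts = np.stack([cc.reshape(9), cu.reshape(9)], axis=1)
    assert np.array_equal(counts.astype(int), contingency_table(bits, (1, 3)).counts)
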