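import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qmdr.data_io import (
    MISSING,
    GenotypeDataset,
    QCThresholds,
    apply_qc,
    genotype_r2,
    hwe_exact_pvalue,
    minor_allele_frequency,
    pi_hat,
    read_genotypes,
    write_tsv_matrix,
)
from qmdr.errors import (
    EmptyResultError,
    InsufficientDataError,
    ParseError,
    UndefinedValueError,
)

from conftest import hwe_oracle_pvalue, make_dataset


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


class TestReaders:
    def test_ped_map_roundtrip(self, tmp_path):
        (tmp_path / "fix.map").write_text(
            "1 rs1 0 1000\n1 rs2 0 2000\n"
        )
        # rs1 minor allele = G (2 copies of 6); rs2 minor allele = T (2 of 6)
        (tmp_path / "fix.ped").write_text(
            "f1 i1 0 0 1 -9 A G C C\n"
            "f2 i2 0 0 2 -9 A A C T\n"
            "f3 i3 0 0 1 -9 A G C T\n"
        )
        ds = read_genotypes(tmp_path / "fix.ped", "ped_map")
        assert ds.samples == ["i1", "i2", "i3"]
        assert ds.snp_ids == ["rs1", "rs2"]
        assert ds.calls.tolist() == [[1, 0], [0, 1], [1, 1]]

    def test_ped_map_missing_allele(self, tmp_path):
        (tmp_path / "m.map").write_text("1 rs1 0 1\n")
        (tmp_path / "m.ped").write_text(
            "f1 i1 0 0 1 -9 A G\nf2 i2 0 0 1 -9 0 0\n"
        )
        ds = read_genotypes(tmp_path / "m.ped", "ped_map")
        assert ds.calls[1, 0] == MISSING

    def test_ped_bad_field_count(self, tmp_path):
        (tmp_path / "b.map").write_text("1 rs1 0 1\n1 rs2 0 2\n")
        (tmp_path / "b.ped").write_text("f1 i1 0 0 1 -9 A G\n")
        with pytest.raises(ParseError, match="b.ped:1"):
            read_genotypes(tmp_path / "b.ped", "ped_map")

    def test_vcf_missing_genotype(self, tmp_path):
        vcf = tmp_path / "fix.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
            "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/1\t./.\t0/0\n"
        )
        ds = read_genotypes(vcf, "vcf")
        assert ds.calls[0, 0] == 1
        assert ds.calls[1, 0] == MISSING
        assert ds.calls[2, 0] == 0

    def test_vcf_major_alt_is_flipped(self, tmp_path):
        vcf = tmp_path / "flip.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
            "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t1/1\t1/1\t0/1\n"
        )
        ds = read_genotypes(vcf, "vcf")
        # ALT frequency 5/6 > 0.5: calls count REF copies instead
        assert ds.calls[:, 0].tolist() == [0, 0, 1]

    def test_tsv_matrix_header_order(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(
            "sample_id\tsB\tsA\n" "i1\t0\t2\n" "i2\t1\tNA\n" "i3\t2\t1\n"
        )
        ds = read_genotypes(path, "tsv_matrix")
        # independent line-by-line parse of the same file
        lines = [l.split("\t") for l in path.read_text().splitlines()]
        assert ds.snp_ids == lines[0][1:]
        assert ds.samples == [r[0] for r in lines[1:]]
        assert ds.calls[1, 1] == MISSING
        # sB column: 0,1,2 parses with mean freq 0.5, no flip
        assert ds.calls[:, 0].tolist() == [0, 1, 2]

    def test_tsv_roundtrip_identity(self, tmp_path, rng):
        calls = rng.integers(0, 3, size=(6, 4)).astype(np.int8)
        calls[0, 0] = MISSING
        ds = make_dataset(calls)
        write_tsv_matrix(ds, tmp_path / "rt.tsv")
        back = read_genotypes(tmp_path / "rt.tsv", "tsv_matrix")
        # minor-allele recoding may flip columns whose frequency > 0.5
        for j in range(4):
            col, bcol = ds.calls[:, j], back.calls[:, j]
            ok = col != MISSING
            assert (bcol[~ok] == MISSING).all()
            assert (bcol[ok] == col[ok]).all() or (bcol[ok] == 2 - col[ok]).all()

    def test_unknown_format(self, tmp_path):
        (tmp_path / "x").write_text("")
        with pytest.raises(ValueError, match="unknown format"):
            read_genotypes(tmp_path / "x", "bed")


# ---------------------------------------------------------------------------
# per-marker statistics
# ---------------------------------------------------------------------------


class TestMaf:
    @pytest.mark.parametrize(
        "calls,expected",
        [([0, 0, 0, 0], 0.0), ([1, 1, 1, 1], 0.5), ([2, 1, 0, MISSING], 0.5)],
    )
    def test_examples(self, calls, expected):
        assert minor_allele_frequency(np.array(calls)) == pytest.approx(expected)

    def test_all_missing(self):
        with pytest.raises(UndefinedValueError):
            minor_allele_frequency(np.array([MISSING, MISSING]))

    @given(st.lists(st.sampled_from([0, 1, 2]), min_size=1, max_size=30))
    def test_sample_order_invariance(self, calls):
        a = np.array(calls)
        assert minor_allele_frequency(a) == pytest.approx(
            minor_allele_frequency(a[::-1])
        )
        assert 0.0 <= minor_allele_frequency(a) <= 0.5


class TestHweExact:
    def test_monomorphic(self):
        assert hwe_exact_pvalue(0, 0, 50) == 1.0

    def test_all_het_extreme(self):
        assert hwe_exact_pvalue(0, 100, 0) < 1e-6

    def test_balanced_table_vs_oracle(self):
        assert hwe_exact_pvalue(25, 50, 25) == pytest.approx(
            hwe_oracle_pvalue(25, 50, 25), abs=1e-12
        )

    @given(
        st.integers(0, 60), st.integers(0, 60), st.integers(0, 60)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_oracle(self, a, h, b):
        if a + h + b == 0:
            return
        mine = hwe_exact_pvalue(a, h, b)
        assert 0.0 < mine <= 1.0
        assert mine == pytest.approx(hwe_oracle_pvalue(a, h, b), abs=1e-10)

    def test_calibration_under_hwe(self, rng):
        # simulated HWE columns: rejection rate at alpha=0.05 near nominal
        # (the exact test is conservative, so allow the low side)
        n, maf, reps = 5000, 0.2, 1000
        rejected = 0
        for _ in range(reps):
            g = rng.binomial(2, maf, size=n)
            counts = np.bincount(g, minlength=3)
            p = hwe_exact_pvalue(counts[0], counts[1], counts[2])
            rejected += p < 0.05
        assert rejected / reps < 0.07  # nominal 5% + conservatism margin


class TestGenotypeR2:
    def test_identical_columns(self):
        col = np.array([0, 1, 2, 0, 1, 2])
        assert genotype_r2(col, col) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        a = np.array([0, 0, 1, 1, 2, 2])
        assert genotype_r2(a, 2 - a) == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        a = rng.binomial(2, 0.3, size=10_000)
        b = rng.binomial(2, 0.3, size=10_000)
        assert genotype_r2(a, b) < 0.01

    def test_symmetry(self, rng):
        a = rng.binomial(2, 0.3, size=50)
        b = rng.binomial(2, 0.4, size=50)
        assert genotype_r2(a, b) == pytest.approx(genotype_r2(b, a))

    def test_constant_column(self):
        with pytest.raises(UndefinedValueError):
            genotype_r2(np.array([1, 1, 1]), np.array([0, 1, 2]))


class TestPiHat:
    @staticmethod
    def _simulate(rng, n_snps=1000, maf=None):
        mafs = rng.uniform(0.1, 0.5, n_snps) if maf is None else np.full(n_snps, maf)
        return mafs, rng.binomial(2, mafs)

    def test_duplicate_samples(self, rng):
        mafs, g = self._simulate(rng)
        assert pi_hat(g, g.copy(), mafs) > 0.9

    def test_unrelated(self, rng):
        mafs = rng.uniform(0.1, 0.5, 1000)
        g1 = rng.binomial(2, mafs)
        g2 = rng.binomial(2, mafs)
        assert pi_hat(g1, g2, mafs) < 0.1

    def test_parent_offspring(self, rng):
        mafs = rng.uniform(0.1, 0.5, 1000)
        parent = rng.binomial(2, mafs)
        other = rng.binomial(2, mafs)
        # transmit one gamete from each parent
        def gamete(g):
            return np.where(g == 1, rng.integers(0, 2, len(g)), g // 2)

        child = gamete(parent) + gamete(other)
        assert 0.35 <= pi_hat(parent, child, mafs) <= 0.65

    def test_too_few_shared(self, rng):
        mafs, g = self._simulate(rng, n_snps=30)
        with pytest.raises(InsufficientDataError):
            pi_hat(g, g, mafs)


# ---------------------------------------------------------------------------
# apply_qc
# ---------------------------------------------------------------------------


def _clean_calls(rng, n=40, m=8, maf=0.4):
    return rng.binomial(2, maf, size=(n, m)).astype(np.int8)


class TestApplyQc:
    def test_low_call_rate_sample_removed(self, rng):
        calls = _clean_calls(rng, n=30, m=10)
        calls[0, :8] = MISSING  # 20% call rate
        ds = make_dataset(calls)
        thr = QCThresholds(
            sample_call_rate_min=0.90, snp_call_rate_min=None, hwe_p_min=None,
            maf_min=None, ld_r2_max=None, pihat_max=None,
        )
        clean, report = apply_qc(ds, thr)
        assert clean.n_samples == 29
        assert report.stages[0] == {
            "stage": "sample_call_rate", "axis": "samples", "removed": 1,
        }

    def test_duplicate_snp_pruned(self, rng):
        calls = _clean_calls(rng, n=60, m=3)
        calls[:, 2] = calls[:, 0]  # r^2 = 1 pair
        ds = make_dataset(calls)
        thr = QCThresholds(
            sample_call_rate_min=None, snp_call_rate_min=None, hwe_p_min=None,
            maf_min=None, ld_r2_max=0.6, pihat_max=None,
        )
        clean, _ = apply_qc(ds, thr)
        assert clean.snp_ids == ["s1", "s2"]  # later member of the pair dropped

    def test_clean_dataset_noop(self, rng):
        ds = make_dataset(_clean_calls(rng, n=80, m=6))
        clean, report = apply_qc(ds, QCThresholds())
        assert clean.n_samples == ds.n_samples and clean.n_snps == ds.n_snps
        assert all(s["removed"] == 0 for s in report.stages)
        assert (clean.calls == ds.calls).all()

    def test_idempotent(self, rng):
        calls = _clean_calls(rng, n=80, m=8)
        calls[:, 3] = calls[:, 1]
        calls[0, :7] = MISSING
        ds = make_dataset(calls)
        once, _ = apply_qc(ds, QCThresholds())
        twice, report = apply_qc(once, QCThresholds())
        assert (twice.calls == once.calls).all()
        assert all(s["removed"] == 0 for s in report.stages)

    def test_maf_filter(self, rng):
        calls = _clean_calls(rng, n=100, m=4)
        calls[:, 1] = 0
        calls[0, 1] = 1  # MAF 0.005
        ds = make_dataset(calls)
        thr = QCThresholds(
            sample_call_rate_min=None, snp_call_rate_min=None, hwe_p_min=None,
            maf_min=0.05, ld_r2_max=None, pihat_max=None,
        )
        clean, _ = apply_qc(ds, thr)
        assert "s2" not in clean.snp_ids

    def test_all_removed_raises(self, rng):
        calls = _clean_calls(rng, n=10, m=3)
        calls[::2, :] = MISSING  # every SNP at 50% call rate
        ds = make_dataset(calls)
        thr = QCThresholds(
            sample_call_rate_min=None, snp_call_rate_min=0.95, hwe_p_min=None,
            maf_min=None, ld_r2_max=None, pihat_max=None,
        )
        with pytest.raises(EmptyResultError, match="snp_call_rate"):
            apply_qc(ds, thr)

    def test_relatedness_removes_duplicate(self, rng):
        calls = rng.binomial(2, rng.uniform(0.2, 0.5, 200), size=(12, 200)).astype(
            np.int8
        )
        calls[1] = calls[0]  # duplicated individual
        calls[1, :5] = MISSING  # lower call rate loses the tie
        ds = make_dataset(calls)
        thr = QCThresholds(
            sample_call_rate_min=None, snp_call_rate_min=None, hwe_p_min=None,
            maf_min=None, ld_r2_max=None, pihat_max=0.3,
        )
        clean, report = apply_qc(ds, thr)
        assert "i2" not in clean.samples and "i1" in clean.samples
        assert report.removed_total("samples") == 1

    def test_report_reconciles(self, rng):
        calls = _clean_calls(rng, n=50, m=10)
        calls[2, :40 // 4] = MISSING
        ds = make_dataset(calls)
        _, report = apply_qc(ds, QCThresholds())
        assert report.n_samples_out + report.removed_total("samples") == 50
        assert report.n_snps_out + report.removed_total("snps") == 10
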