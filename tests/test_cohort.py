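import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gmdrkit.cohort import (
    MISSING,
    Cohort,
    SnpInfo,
    allele_frequencies,
    encode_model,
    genotype_counts,
    hwe_chi2,
    load_cohort,
    load_report,
    write_cohort_csv,
)
from gmdrkit.simulate import SimulationConfig, simulate_genotypes


def _cohort_from_counts(n_aa, n_het, n_min):
    codes = np.array([0] * n_aa + [1] * n_het + [2] * n_min)[:, None]
    n = len(codes)
    y = np.tile([0.0, 1.0], n)[:n]
    return Cohort([f"S{i}" for i in range(n)], codes, y, pd.DataFrame(index=range(n)))


@pytest.mark.parametrize(
    "model,expected",
    [("dominant", [0, 1, 1]), ("recessive", [0, 0, 1]), ("allelic", [0, 1, 2])],
)
def test_encode_model_codings(model, expected):
    out = encode_model(np.array([0, 1, 2]), model)
    assert out.tolist() == expected


def test_encode_model_missing_propagates_and_unknown_model_rejected():
    out = encode_model(np.array([0, MISSING, 2]), "dominant")
    assert np.isnan(out[1]) and out[2] == 1
    with pytest.raises(ValueError, match="unknown genetic model"):
        encode_model(np.array([0]), "codominant")


@pytest.mark.parametrize(
    "counts,expected_maf",
    [((25, 50, 25), 0.5), ((49, 42, 9), 0.30)],
)
def test_allele_frequencies_closed_form(counts, expected_maf):
    cohort = _cohort_from_counts(*counts)
    maf, got_counts = allele_frequencies(cohort, 0)
    assert got_counts == counts
    assert maf == pytest.approx(expected_maf)


def test_allele_frequencies_subsets_and_all_missing_error():
    G = np.array([[0], [2], [MISSING], [1]])
    y = np.array([0.0, 1.0, 1.0, 0.0])
    c = Cohort(list("abcd"), G, y, pd.DataFrame(index=range(4)))
    maf_cases, counts_cases = allele_frequencies(c, 0, "cases")
    assert counts_cases == (0, 0, 1) and maf_cases == 1.0  # only the '2' subject
    c_missing = Cohort(["a"], np.array([[MISSING]]), np.array([1.0]),
                       pd.DataFrame(index=range(1)))
    with pytest.raises(ValueError, match="missing"):
        allele_frequencies(c_missing, 0)


def test_maf_estimate_converges_to_generating_value():
    config = SimulationConfig(n_total=10_000, mafs=(0.35,), seed=11,
                              sampling="prospective")
    G = simulate_genotypes(config)
    counts = genotype_counts(G[:, 0])
    maf = (counts[1] + 2 * counts[2]) / (2 * sum(counts))
    assert abs(maf - 0.35) < 0.01


class TestHwe:
    def test_exact_proportions_give_zero(self):
        res = hwe_chi2((25, 50, 25))
        assert res.chi2 == 0.0 and res.p_value == 1.0 and res.df == 1
        assert sum(res.expected) == pytest.approx(sum(res.observed))

    def test_no_heterozygotes_closed_form(self):
        assert hwe_chi2((100, 0, 100)).chi2 == pytest.approx(200.0)

    def test_skewed_counts(self):
        # p-hat = 0.85: expected (289, 102, 9), chi2 = 121/289 + 484/102 + 121/9
        assert hwe_chi2((300, 80, 20)).chi2 == pytest.approx(18.608, abs=0.001)

    def test_monomorphic_flagged(self):
        res = hwe_chi2((50, 0, 0))
        assert res.monomorphic and res.chi2 == 0.0 and res.p_value == 1.0

    def test_matches_scipy_oracle_on_random_counts(self, rng):
        for _ in range(200):
            counts = tuple(int(v) + 1 for v in rng.integers(0, 200, 3))
            res = hwe_chi2(counts)
            chi2, p = stats.chisquare(counts, res.expected, ddof=1)
            assert res.chi2 == pytest.approx(chi2)
            assert res.p_value == pytest.approx(p)

    def test_rejection_rate_under_true_hwe(self, rng):
        # n=500, MAF 0.3, 1000 replicates: reject at alpha=0.05 in 5% +/- 1.5%
        q = 0.3
        probs = np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
        counts = rng.multinomial(500, probs, size=1000)
        rejections = sum(hwe_chi2(tuple(c)).p_value <= 0.05 for c in counts)
        assert 0.035 <= rejections / 1000 <= 0.065


class TestLoading:
    def test_csv_minor_allele_counting(self, tmp_path):
        # "AG","GG": 1 A vs 3 G alleles, so A is the empirical minor allele
        # and codes count copies of A
        p = tmp_path / "c.csv"
        p.write_text("subject_id,phenotype,snp1\na,0,AG\nb,1,GG\n")
        c = load_cohort(p, "csv", "binary")
        assert c.snps[0].allele_minor == "A"
        assert c.genotypes[:, 0].tolist() == [1, 0]

    def test_csv_minor_allele_is_empirical(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("subject_id,phenotype,snp1\na,0,AG\nb,1,GG\nc,0,GG\nd,1,AG\n")
        c = load_cohort(p, "csv", "binary")
        # 6 G vs 2 A alleles: A minor; AG -> 1, GG -> 0
        assert c.snps[0].allele_minor == "A"
        assert c.genotypes[:, 0].tolist() == [1, 0, 0, 1]

    def test_csv_missing_and_integer_codes(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("subject_id,phenotype,snp1\na,0,NA\nb,1,2\nc,1,0\nd,0,1\n")
        c = load_cohort(p, "csv", "binary")
        assert c.genotypes[:, 0].tolist() == [MISSING, 2, 0, 1]

    def test_csv_malformed_genotype_names_line_and_column(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("subject_id,phenotype,snp1\na,0,AG\nb,1,AGT\n")
        with pytest.raises(ValueError, match=r"line 3.*snp1"):
            load_cohort(p, "csv", "binary")

    def test_csv_bad_binary_phenotype_rejected(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("subject_id,phenotype,snp1\na,0,AG\nb,3,GG\n")
        with pytest.raises(ValueError, match="binary phenotype"):
            load_cohort(p, "csv", "binary")

    def test_monomorphic_snp_warned_but_retained(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("subject_id,phenotype,snp1\na,0,GG\nb,1,GG\n")
        with pytest.warns(UserWarning, match="monomorphic"):
            c = load_cohort(p, "csv", "binary")
        assert c.n_snps == 1

    def test_ped_map_roundtrip_conventions(self, tmp_path):
        (tmp_path / "d.map").write_text("1 rs1 0 100\n1 rs2 0 200\n")
        (tmp_path / "d.ped").write_text(
            "F1 a 0 0 1 1 A G G G\n"
            "F2 b 0 0 2 2 G G 0 0\n"
        )
        c = load_cohort(tmp_path / "d.ped", "plink_pedmap", "binary", ("sex",))
        assert c.phenotype.tolist() == [0.0, 1.0]  # PLINK 1=control, 2=case
        assert c.genotypes[0, 0] == 1 and c.genotypes[1, 0] == 0  # A minor at rs1
        assert c.genotypes[1, 1] == MISSING  # "0 0" genotype
        assert c.covariates["sex"].tolist() == [0.0, 1.0]

    def test_csv_roundtrip_identity(self, tmp_path, study_cohort_seed1):
        path = tmp_path / "cohort.csv"
        write_cohort_csv(study_cohort_seed1, path)
        back = load_cohort(path, "csv", "binary",
                           tuple(study_cohort_seed1.covariates.columns))
        assert np.array_equal(back.genotypes, study_cohort_seed1.genotypes)
        assert np.array_equal(back.phenotype, study_cohort_seed1.phenotype)
        assert np.allclose(back.covariates.to_numpy(),
                           study_cohort_seed1.covariates.to_numpy())
        assert back.subject_ids == study_cohort_seed1.subject_ids

    def test_load_report_structure(self, study_cohort_seed1):
        rep = load_report(study_cohort_seed1)
        assert rep["n_subjects"] == 697
        entry = rep["snps"]["rs220721"]
        assert 0 < entry["maf"] <= 0.5
        assert "hwe_controls" in entry


def test_snpinfo_rejects_identical_alleles():
    with pytest.raises(ValueError):
        SnpInfo("rs0", allele_minor="A", allele_major="A")


def test_cohort_rejects_bad_codes_and_mismatched_sizes():
    with pytest.raises(ValueError, match="genotype code"):
        Cohort(["a"], np.array([[5]]), np.array([1.0]), pd.DataFrame(index=range(1)))
    with pytest.raises(ValueError):
        Cohort(["a", "b"], np.array([[0]]), np.array([1.0]), pd.DataFrame(index=range(1)))
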