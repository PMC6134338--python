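"""QC cascade: each filter against constructed fixtures, the HWE exact
test against an integer enumeration oracle, and cascade idempotence."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sctdh import qc
from sctdh.containers import MISSING, GenotypeMatrix


def make_matrix(dosages, chrom="1", genes=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{j}" for j in range(m)],
            "chrom": chrom,
            "pos": np.arange(1, m + 1) * 100,
            "gene": genes if genes is not None else "G1",
            "allele_minor": "A",
            "allele_major": "G",
        }
    )
    return GenotypeMatrix(dosages, [f"ind{i}" for i in range(n)], snps)


# ----------------------------------------------------------------------
# HWE exact test vs enumeration oracle
# ----------------------------------------------------------------------

def hwe_oracle(n_AA, n_Aa, n_aa):
    """Exact-rational enumeration of the conditional heterozygote
    distribution; independent of the implementation under test."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    if n_a == 0 or n_a == 2 * n:
        return Fraction(1)
    weights = {}
    for het in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2):
        hom_a = (n_a - het) // 2
        hom_A = n - het - hom_a
        if hom_A < 0:
            continue
        weights[het] = (
            math.comb(n, hom_A) * math.comb(n - hom_A, het) * 2 ** het
        )
    total = sum(weights.values())
    obs_w = weights[n_Aa]
    return Fraction(sum(w for w in weights.values() if w <= obs_w), total)


def test_hwe_matches_enumeration_oracle_exhaustively():
    """All genotype-count triples with total <= 50, to machine precision."""
    for n in range(1, 51):
        for n_AA in range(n + 1):
            for n_Aa in range(n - n_AA + 1):
                n_aa = n - n_AA - n_Aa
                expected = float(hwe_oracle(n_AA, n_Aa, n_aa))
                got = qc.hwe_exact_test(n_AA, n_Aa, n_aa)
                assert got == pytest.approx(expected, abs=1e-10), (n_AA, n_Aa, n_aa)


def test_hwe_perfect_proportions_modal():
    assert qc.hwe_exact_test(25, 50, 25) == pytest.approx(1.0, abs=1e-9)


def test_hwe_all_hets_fires_filter():
    assert qc.hwe_exact_test(0, 100, 0) < 1e-6


def test_hwe_monomorphic_is_one():
    assert qc.hwe_exact_test(80, 0, 0) == 1.0


@settings(max_examples=200, derandomize=True)
@given(
    st.integers(min_value=0, max_value=40),
    st.integers(min_value=0, max_value=40),
    st.integers(min_value=0, max_value=40),
)
def test_hwe_symmetric_in_homozygote_labels(a, b, c):
    """Swapping which allele is 'minor' cannot change the p-value."""
    if a + b + c == 0:
        return
    assert qc.hwe_exact_test(a, b, c) == pytest.approx(qc.hwe_exact_test(c, b, a), abs=1e-12)


# ----------------------------------------------------------------------
# Sample filters
# ----------------------------------------------------------------------

class TestCallRate:
    def test_engineered_low_call_samples_removed(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(10, 40)).astype(np.int8)
        d[0, :3] = MISSING   # 37/40 = 92.5% < 95%
        d[7, :4] = MISSING   # 90%
        G = make_matrix(d)
        G2, step = qc.sample_call_rate_filter(G, qc.QCThresholds())
        assert step.n_removed == 2
        assert set(step.removed_ids) == {"ind0", "ind7"}
        assert (G2.sample_call_rate() >= 0.95).all()

    def test_no_missingness_no_removal(self):
        d = np.ones((5, 10), dtype=np.int8)
        G2, step = qc.sample_call_rate_filter(make_matrix(d), qc.QCThresholds())
        assert step.n_removed == 0

    def test_boundary_is_inclusive(self):
        d = np.ones((4, 20), dtype=np.int8)
        d[0, 0] = MISSING  # 19/20 = 95% exactly
        G2, step = qc.sample_call_rate_filter(make_matrix(d), qc.QCThresholds())
        assert step.n_removed == 0


class TestHeterozygosity:
    def test_outlier_removed(self):
        rng = np.random.default_rng(1)
        d = rng.choice([0, 1, 2], p=[0.45, 0.2, 0.35], size=(30, 200)).astype(np.int8)
        d[4] = 1  # 100% het: far outside 2 SD
        G2, step = qc.heterozygosity_filter(make_matrix(d), qc.QCThresholds())
        assert "ind4" in step.removed_ids

    def test_zero_variance_warns_not_removes(self):
        d = np.tile(np.array([0, 1, 2, 1], dtype=np.int8), (5, 1))
        with pytest.warns(UserWarning, match="zero variance"):
            G2, step = qc.heterozygosity_filter(make_matrix(d), qc.QCThresholds())
        assert step.n_removed == 0

    def test_gaussian_tail_mass(self):
        # het counts ~ Binomial around a common rate: ~4.6% outside 2 SD
        rng = np.random.default_rng(2)
        n = 4000
        d = rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25], size=(n, 400)).astype(np.int8)
        G2, step = qc.heterozygosity_filter(make_matrix(d), qc.QCThresholds())
        assert step.n_removed / n == pytest.approx(0.046, abs=0.015)


class TestMaf:
    def test_rare_snp_removed(self):
        d = np.zeros((200, 2), dtype=np.int8)
        d[0, 0] = 1          # MAF 0.0025
        d[:80, 1] = 1        # MAF 0.2
        G2, step = qc.maf_filter(make_matrix(d), qc.QCThresholds())
        assert step.removed_ids == ["snp0"]

    def test_boundary_maf_retained(self):
        d = np.zeros((100, 1), dtype=np.int8)
        d[:2, 0] = 1  # MAF exactly 0.01
        G2, step = qc.maf_filter(make_matrix(d), qc.QCThresholds())
        assert step.n_removed == 0

    def test_five_of_fortyseven_rare(self, genotypes_500):
        G = genotypes_500.copy()
        # engineer 5 SNPs to near-monomorphic
        for j in range(5):
            G.dosages[:, j] = 0
            G.dosages[0, j] = 1
        G2, step = qc.maf_filter(G, qc.QCThresholds())
        assert G2.n_snps == 42


class TestMendel:
    def _trio_matrix(self, child, mother, father, n_snps=1):
        d = np.array([[child] * n_snps, [mother] * n_snps, [father] * n_snps], dtype=np.int8)
        G = make_matrix(d)
        ped = pd.DataFrame({"child": ["ind0"], "mother": ["ind1"], "father": ["ind2"]})
        return G, ped

    @pytest.mark.parametrize(
        "child,mother,father,consistent",
        [(2, 0, 0, False), (1, 0, 2, True), (0, 2, 2, False),
         (1, 1, 1, True), (2, 1, 2, True), (0, 0, 2, False)],
    )
    def test_trio_consistency_rules(self, child, mother, father, consistent):
        assert qc._mendel_consistent(child, mother, father) is consistent

    def test_high_error_snp_removed_and_genotypes_blanked(self):
        n_trios = 100
        # consistent background: mother 0, father 2 -> child must be 1
        d = np.tile(np.array([[1], [0], [2]], dtype=np.int8), (n_trios, 3))
        ped = pd.DataFrame(
            {
                "child": [f"ind{3 * t}" for t in range(n_trios)],
                "mother": [f"ind{3 * t + 1}" for t in range(n_trios)],
                "father": [f"ind{3 * t + 2}" for t in range(n_trios)],
            }
        )
        # SNP0: make 3% of trios impossible (child 2, parents 0)
        for t in range(3):
            d[3 * t, 0], d[3 * t + 1, 0], d[3 * t + 2, 0] = 2, 0, 0
        # SNP1: exactly one inconsistent trio (1% -> at threshold, retained)
        d[3 * 50, 1], d[3 * 50 + 1, 1], d[3 * 50 + 2, 1] = 2, 0, 0
        G = make_matrix(d)
        G2, step = qc.mendelian_error_filter(G, ped, qc.QCThresholds())
        assert step.removed_ids == ["snp0"]
        # the surviving inconsistent trio at snp1 was set missing
        j1 = G2.snp_ids.index("snp1")
        assert (G2.dosages[[150, 151, 152], j1] == MISSING).all()

    def test_no_trios_skips_with_warning(self):
        d = np.ones((4, 2), dtype=np.int8)
        ped = pd.DataFrame({"child": ["nope"], "mother": ["x"], "father": ["y"]})
        with pytest.warns(UserWarning, match="skipped"):
            G2, step = qc.mendelian_error_filter(make_matrix(d), ped, qc.QCThresholds())
        assert step.n_removed == 0


# ----------------------------------------------------------------------
# LD reporting
# ----------------------------------------------------------------------

class TestPairwiseR2:
    def test_duplicated_column_r2_one(self):
        rng = np.random.default_rng(4)
        col = rng.integers(0, 3, size=200).astype(np.int8)
        G = make_matrix(np.column_stack([col, col]))
        r2, above = qc.pairwise_r2(G)
        assert r2.iloc[0, 1] == pytest.approx(1.0)
        assert above == 1

    def test_independent_snps_near_zero(self, genotypes_500):
        sub = genotypes_500.subset_snps(np.array([8, 30]))  # cross-gene pair
        r2, above = qc.pairwise_r2(sub)
        assert r2.iloc[0, 1] < 0.05

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, size=(300, 4)).astype(np.int8)
        d[:, 1] = np.clip(d[:, 0] + rng.integers(0, 2, 300), 0, 2)
        G = make_matrix(d)
        r2, _ = qc.pairwise_r2(G)
        for i in range(4):
            for j in range(4):
                expected = np.corrcoef(d[:, i].astype(float), d[:, j].astype(float))[0, 1] ** 2
                assert r2.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_sample_permutation(self, genotypes_500):
        G = genotypes_500
        perm = np.random.default_rng(6).permutation(G.n_samples)
        r2a, na = qc.pairwise_r2(G, region="CNTNAP2")
        r2b, nb = qc.pairwise_r2(G.subset_samples(perm), region="CNTNAP2")
        assert np.allclose(r2a.to_numpy(), r2b.to_numpy())
        assert na == nb

    def test_zero_variance_snp_reported_missing(self):
        d = np.column_stack([
            np.zeros(50, dtype=np.int8),
            np.random.default_rng(7).integers(0, 3, 50).astype(np.int8),
        ])
        r2, _ = qc.pairwise_r2(make_matrix(d))
        assert np.isnan(r2.iloc[0, 1])


# ----------------------------------------------------------------------
# Full cascade
# ----------------------------------------------------------------------

class TestRunQc:
    def _clean_fixture(self):
        # balanced dosages, no missingness, identical het rates: nothing to remove
        base = np.array([0, 1, 2, 1, 0, 1, 2, 1], dtype=np.int8)
        d = np.stack([np.roll(base, i) for i in range(8)])
        return make_matrix(d)

    def test_clean_fixture_untouched(self):
        G = self._clean_fixture()
        with pytest.warns(UserWarning, match="zero variance"):
            G2, report = qc.run_qc(G)
        assert report.output_shape == report.input_shape
        assert all(s.n_removed == 0 for s in report.steps)

    @staticmethod
    def _violation_fixture():
        """Cyclic-shift design: every sample and SNP shares one composition,
        so het rates are near-identical and only the engineered violations
        stand out."""
        n = m = 50
        base = np.array([0] * 18 + [1] * 24 + [2] * 8, dtype=np.int8)
        np.random.default_rng(0).shuffle(base)
        d = np.stack([np.roll(base, i) for i in range(n)])
        d[0, :3] = MISSING                        # call rate 94% < 95%
        d[1, :] = 1                               # all-het outlier
        d[2:, 5] = np.tile([0, 2], (n - 2) // 2)  # het deficit: HWE fires
        d[2:, 6] = 0                              # near-monomorphic: MAF fires
        d[2, 6] = 1
        return make_matrix(d)

    def test_one_violation_per_filter(self):
        thr = qc.QCThresholds(maf_min=0.05)
        G2, report = qc.run_qc(self._violation_fixture(), thresholds=thr)
        by_name = {s.name: s for s in report.steps}
        assert by_name["sample_call_rate"].removed_ids == ["ind0"]
        assert by_name["heterozygosity"].removed_ids == ["ind1"]
        assert by_name["hwe_exact"].removed_ids == ["snp5"]
        assert by_name["maf"].removed_ids == ["snp6"]
        assert G2.dosages.shape == (48, 48)

    def test_cascade_idempotent(self):
        thr = qc.QCThresholds(maf_min=0.05)
        G1, rep1 = qc.run_qc(self._violation_fixture(), thresholds=thr)
        G2, rep2 = qc.run_qc(G1, thresholds=thr)
        assert rep2.removed_count("samples") == 0
        assert rep2.removed_count("snps") == 0
        assert (G1.dosages == G2.dosages).all()

    def test_non_autosomal_rejected(self):
        d = np.ones((5, 2), dtype=np.int8)
        G = make_matrix(d, chrom="X")
        with pytest.raises(ValueError, match="autosom"):
            qc.run_qc(G)

    def test_report_serializes(self):
        G = self._clean_fixture()
        with pytest.warns(UserWarning):
            _, report = qc.run_qc(G)
        text = report.to_json()
        assert '"steps"' in text
        assert "QC input" in report.summary()
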