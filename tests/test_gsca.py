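"""GSCA engine: collapse to Pearson correlation, OLS oracle with
orthogonal components, criterion monotonicity, unit-variance constraints,
permutation determinism and invariances, sequential alpha logic."""

import numpy as np
import pandas as pd
import pytest

from sctdh import gsca, simulate as sim
from tests.conftest import make_single_snp_panel


def _one_snp_design(n=300, effect=0.4, seed=0, maf=0.3):
    specs, ld = make_single_snp_panel(maf=maf)
    G = sim.generate_genotypes(specs, ld, n, seed=seed)
    rng = np.random.default_rng(seed + 1)
    d = G.dosages_float()[:, 0]
    y = effect * (d - d.mean()) / d.std() + rng.standard_normal(n)
    pheno = pd.DataFrame({"sample_id": G.samples, "y": y})
    spec = gsca.GscaSpec({"GENE1": ["s1"]}, phenotype_block=("y",),
                         alpha_sequence=(("GENE1", 0.05),))
    return G, pheno, spec, d, y


class TestFit:
    def test_single_indicator_collapse_equals_pearson(self):
        G, pheno, spec, d, y = _one_snp_design()
        designs = gsca.standardize_blocks(G, pheno, spec)
        model = gsca.fit_gsca(spec, designs)
        r = np.corrcoef(d, y)[0, 1]
        assert model.paths["GENE1"] == pytest.approx(r, abs=1e-10)

    def test_two_orthogonal_single_snp_blocks_match_ols(self):
        # two independent SNPs on different chromosomes: paths = the two
        # coefficients of the bivariate OLS of y on the standardized dosages
        specs = [sim.SnpSpec("a", "1", 1, 0.3, "g1"), sim.SnpSpec("b", "2", 1, 0.4, "g2")]
        ld = sim.LdBlockSpec(np.eye(2))
        G = sim.generate_genotypes(specs, ld, 500, seed=3)
        rng = np.random.default_rng(4)
        z = (G.dosages_float() - G.dosages_float().mean(0)) / G.dosages_float().std(0)
        y = 0.3 * z[:, 0] - 0.2 * z[:, 1] + rng.standard_normal(500)
        pheno = pd.DataFrame({"sample_id": G.samples, "y": y})
        spec = gsca.GscaSpec({"g1": ["a"], "g2": ["b"]}, phenotype_block=("y",),
                             alpha_sequence=(("g1", 0.05), ("g2", 0.025)))
        designs = gsca.standardize_blocks(G, pheno, spec)
        model = gsca.fit_gsca(spec, designs)
        ys = (y - y.mean()) / y.std()
        X = np.column_stack([z, np.ones(500)])
        ols = np.linalg.lstsq(X, ys, rcond=None)[0]
        assert model.paths["g1"] == pytest.approx(ols[0], abs=1e-6)
        assert model.paths["g2"] == pytest.approx(ols[1], abs=1e-6)

    def test_criterion_monotone_and_components_unit_variance(self, genotypes_500):
        G = genotypes_500
        pheno = sim.generate_phenotypes(G, sim.CohortScenario(gene_effect=0.2), seed=5)
        spec = gsca.GscaSpec.from_genotypes(G)
        designs = gsca.standardize_blocks(G, pheno, spec)
        model = gsca.fit_gsca(spec, designs)
        assert np.all(np.diff(model.criterion_trace) <= 1e-9)
        for gene, Z in designs.Z.items():
            assert (Z @ model.weights[gene]).var() == pytest.approx(1.0, abs=1e-8)
        assert (designs.P @ model.v).var() == pytest.approx(1.0, abs=1e-8)

    def test_parameter_recovery(self, panel):
        specs, ld = panel
        G = sim.generate_genotypes(specs, ld, 2000, seed=6)
        pheno = sim.generate_phenotypes(G, sim.CohortScenario(gene_effect=0.3), seed=7)
        spec = gsca.GscaSpec.from_genotypes(G)
        designs = gsca.standardize_blocks(G, pheno, spec)
        model = gsca.fit_gsca(spec, designs)
        for gene in ("CNTNAP2", "NRXN1"):
            assert model.paths[gene] == pytest.approx(0.3, abs=0.05)

    def test_constant_snp_dropped_with_warning(self):
        G, pheno, spec, *_ = _one_snp_design()
        specs2 = [sim.SnpSpec("s1", "1", 100, 0.3, "GENE1"),
                  sim.SnpSpec("s2", "1", 200, 0.3, "GENE1")]
        G2 = sim.generate_genotypes(specs2, sim.LdBlockSpec(np.eye(2)), 300, seed=0)
        G2.dosages[:, 1] = 1  # constant
        spec2 = gsca.GscaSpec({"GENE1": ["s1", "s2"]}, phenotype_block=("y",),
                              alpha_sequence=(("GENE1", 0.05),))
        with pytest.warns(UserWarning, match="zero-variance"):
            designs = gsca.standardize_blocks(G2, pheno, spec2)
        assert designs.snp_ids["GENE1"] == ["s1"]
        assert designs.dropped == ["s2"]

    def test_standardization_idempotent_and_missing_imputed(self):
        G, pheno, spec, *_ = _one_snp_design(n=200)
        G.dosages[:20, 0] = -1  # 10% missing
        designs = gsca.standardize_blocks(G, pheno, spec)
        z = designs.Z["GENE1"][:, 0]
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)
        # imputed entries sit exactly at the (standardized) column mean
        assert np.allclose(z[:20], 0.0)


class TestPermutation:
    def test_same_seed_identical_null_draws(self):
        G, pheno, spec, *_ = _one_snp_design(n=150)
        designs = gsca.standardize_blocks(G, pheno, spec)
        r1 = gsca.permutation_test(spec, designs, B=200, seed=11)
        r2 = gsca.permutation_test(spec, designs, B=200, seed=11)
        assert np.array_equal(r1.null_draws["GENE1"], r2.null_draws["GENE1"])
        assert r1.p_values == r2.p_values

    def test_perfect_association_hits_p_floor(self):
        # outcome block duplicated from the gene component
        specs, ld = make_single_snp_panel(maf=0.3)
        G = sim.generate_genotypes(specs, ld, 200, seed=12)
        d = G.dosages_float()[:, 0]
        pheno = pd.DataFrame({"sample_id": G.samples, "y": d.copy()})
        spec = gsca.GscaSpec({"GENE1": ["s1"]}, phenotype_block=("y",),
                             alpha_sequence=(("GENE1", 0.05),))
        designs = gsca.standardize_blocks(G, pheno, spec)
        res = gsca.permutation_test(spec, designs, B=999, seed=13)
        assert res.p_values["GENE1"] == pytest.approx(1 / 1000)

    def test_pvalues_invariant_to_snp_relabeling_and_sign_flip(self, genotypes_500):
        G = genotypes_500
        pheno = sim.generate_phenotypes(G, sim.CohortScenario(), seed=14)
        spec = gsca.GscaSpec.from_genotypes(G)
        designs = gsca.standardize_blocks(G, pheno, spec)
        res = gsca.permutation_test(spec, designs, B=100, seed=15)

        # reverse SNP order inside the CNTNAP2 block
        spec_r = gsca.GscaSpec(
            {"CNTNAP2": list(reversed(spec.gene_blocks["CNTNAP2"])),
             "NRXN1": spec.gene_blocks["NRXN1"]},
        )
        designs_r = gsca.standardize_blocks(G, pheno, spec_r)
        res_r = gsca.permutation_test(spec_r, designs_r, B=100, seed=15)
        for gene in ("CNTNAP2", "NRXN1"):
            assert res_r.p_values[gene] == pytest.approx(res.p_values[gene])
            assert abs(res_r.paths_obs[gene]) == pytest.approx(abs(res.paths_obs[gene]), abs=1e-6)

        # sign-flip one indicator (recode dosage on the other allele)
        G_f = G.copy()
        G_f.dosages[:, 3] = 2 - G_f.dosages[:, 3]
        designs_f = gsca.standardize_blocks(G_f, pheno, spec)
        res_f = gsca.permutation_test(spec, designs_f, B=100, seed=15)
        for gene in ("CNTNAP2", "NRXN1"):
            assert res_f.p_values[gene] == pytest.approx(res.p_values[gene])

    def test_small_B_warns(self):
        G, pheno, spec, *_ = _one_snp_design(n=100)
        designs = gsca.standardize_blocks(G, pheno, spec)
        with pytest.warns(UserWarning, match="unstable"):
            gsca.permutation_test(spec, designs, B=50, seed=16)


class TestDecisions:
    def _result(self, p_cntnap2, p_nrxn1):
        return gsca.PermutationResult(
            paths_obs={"CNTNAP2": 0.1, "NRXN1": 0.1},
            null_draws={}, p_values={"CNTNAP2": p_cntnap2, "NRXN1": p_nrxn1},
            B=5000, seed=0, tails="two",
        )

    def test_study_pattern_both_nonsignificant(self):
        verdicts = gsca.sequential_alpha_decision(self._result(0.268, 0.703))
        assert not verdicts["significant"].any()

    @pytest.mark.parametrize(
        "p1,p2,sig1,sig2",
        [(0.04, 0.02, True, True), (0.04, 0.03, True, False), (0.06, 0.01, False, True)],
    )
    def test_sequential_alphas_applied_per_path(self, p1, p2, sig1, sig2):
        verdicts = gsca.sequential_alpha_decision(self._result(p1, p2)).set_index("gene")
        assert verdicts.loc["CNTNAP2", "significant"] == sig1
        assert verdicts.loc["NRXN1", "significant"] == sig2

    def test_missing_alpha_errors(self):
        res = self._result(0.5, 0.5)
        with pytest.raises(KeyError):
            gsca.sequential_alpha_decision(res, alpha_sequence=(("CNTNAP2", 0.05),))


class TestGroups:
    def test_karyotype_subgroups_exclude_postnatal(self, small_cohort):
        coh = small_cohort
        spec = gsca.GscaSpec.from_genotypes(coh.genotypes)
        table = gsca.run_group_analyses(
            coh.genotypes, coh.phenotypes, coh.design, spec,
            B=100, seed=17, karyotype_subgroups=True, min_n=5,
        )
        sub = table[table["group"].str.startswith("SCT:")]
        expected = coh.design[(coh.design["group"] == "SCT")
                              & (coh.design["ascertainment"] != "postnatal")]
        for karyotype, n_expected in expected["karyotype"].value_counts().items():
            got = sub.loc[sub["group"] == f"SCT:{karyotype}", "n"].unique()
            assert list(got) == [n_expected]

    def test_small_subgroup_skipped_with_warning(self, small_cohort):
        coh = small_cohort
        spec = gsca.GscaSpec.from_genotypes(coh.genotypes)
        with pytest.warns(UserWarning, match="below floor"):
            table = gsca.run_group_analyses(
                coh.genotypes, coh.phenotypes, coh.design, spec,
                B=100, seed=18, karyotype_subgroups=True, min_n=100,
            )
        assert not table["group"].str.startswith("SCT:").any()
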