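"""Trait preparation, association scan, QC filtering and the eQTL scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from transgwas.assoc import (
    TraitConfig,
    Variant,
    eqtl_scan,
    inverse_normal_transform,
    prepare_trait,
    qc_filter,
    run_gwas,
)
from transgwas.simdata import (
    AncestrySpec,
    TraitArchitecture,
    draw_panel,
    simulate_expression,
    simulate_phenotypes,
)


def _raw_frame(values, age=None, sex=None, **extra):
    n = len(values)
    df = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "value": values,
            "age": age if age is not None else np.full(n, 40.0),
            "sex": sex if sex is not None else np.zeros(n, dtype=int),
        }
    )
    for k, v in extra.items():
        df[k] = v
    return df


class TestTraitPreparation:
    def test_inverse_normal_of_three_residuals(self):
        # Phi^-1 at ranks (0.5, 1.5, 2.5)/3
        out = inverse_normal_transform(np.array([-1.0, 0.0, 1.0]))
        expected = stats.norm.ppf([1 / 6, 3 / 6, 5 / 6])
        assert np.allclose(out, expected, atol=1e-4)
        assert np.allclose(out, [-0.9674, 0.0, 0.9674], atol=1e-4)

    def test_inverse_normal_antisymmetric(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(101)
        assert np.allclose(
            inverse_normal_transform(-x), -inverse_normal_transform(x)
        )

    def test_z_score_divides_by_residual_sd(self):
        # residuals with SD 2 -> outputs are residual / 2
        vals = np.array([38.0, 40.0, 42.0, 38.0, 40.0, 42.0])
        cfg = TraitConfig(trait="height", transformation="z-score",
                          sex_stratified=False)
        out = prepare_trait(_raw_frame(vals), cfg)
        resid = vals - vals.mean()
        assert np.allclose(out.to_numpy(), resid / resid.std(ddof=0))
        one_unit = resid[np.isclose(resid, 2.0)][0]
        sd = resid.std(ddof=0)
        assert np.isclose(one_unit / sd, out.to_numpy()[np.isclose(resid, 2.0)][0])

    def test_whradjbmi_residuals_orthogonal_to_bmi(self):
        rng = np.random.default_rng(1)
        n = 200
        bmi = rng.normal(27, 4, n)
        whr = 0.02 * bmi + rng.normal(0.9, 0.05, n)
        cfg = TraitConfig(
            trait="WHRadjBMI", transformation="z-score",
            adjust_bmi=True, sex_stratified=False,
        )
        out = prepare_trait(_raw_frame(whr, age=rng.uniform(20, 70, n), bmi=bmi), cfg)
        assert abs(np.corrcoef(out.to_numpy(), bmi)[0, 1]) < 1e-10

    def test_sex_stratified_residuals(self):
        rng = np.random.default_rng(2)
        n = 100
        sex = np.repeat([0, 1], n // 2)
        vals = 10.0 * sex + rng.standard_normal(n)
        cfg = TraitConfig(transformation="z-score")
        out = prepare_trait(_raw_frame(vals, sex=sex), cfg).to_numpy()
        # residualizing within sex removes the sex effect entirely
        assert abs(out[sex == 0].mean() - out[sex == 1].mean()) < 0.5

    def test_constant_trait_rejected(self):
        with pytest.raises(ValueError):
            prepare_trait(_raw_frame(np.full(10, 5.0)),
                          TraitConfig(sex_stratified=False))

    def test_tiny_stratum_rejected(self):
        with pytest.raises(ValueError):
            prepare_trait(_raw_frame([1.0, 2.0]), TraitConfig(sex_stratified=False))


class TestGwas:
    def test_noiseless_trait_recovers_exact_beta(self, small_panel):
        y = 0.5 * small_panel.dosages[:, 7].astype(float)
        out = run_gwas(small_panel, y, n_pcs=0)
        assert np.isclose(out.loc[7, "BETA"], 0.5, atol=1e-12)

    def test_matches_full_design_least_squares(self, small_panel):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n = small_panel.n_samples
        cov = rng.standard_normal((n, 2))
        y = rng.standard_normal(n)
        out = run_gwas(small_panel, y, covariates=cov, n_pcs=2)
        from transgwas.assoc import genotype_pcs

        pcs = genotype_pcs(small_panel, 2)
        for j in [0, 13, 59]:
            X = sm.add_constant(
                np.column_stack([small_panel.dosages[:, j].astype(float), cov, pcs])
            )
            fit = sm.OLS(y, X).fit()
            assert np.isclose(out.loc[j, "BETA"], fit.params[1], atol=1e-10)
            assert np.isclose(out.loc[j, "SE"], fit.bse[1], atol=1e-10)

    def test_null_type_one_error(self):
        panel = draw_panel(
            [AncestrySpec("A", 0.0, 1000)], n_variants=1000,
            ld_block_spec=[(1000, 0.0)], seed=11,
        )
        rng = np.random.default_rng(11)
        y = rng.permutation(rng.standard_normal(1000))
        out = run_gwas(panel, y, n_pcs=0)
        frac = (out["P"] < 0.05).mean()
        assert abs(frac - 0.05) < 0.02

    def test_pc_adjustment_removes_stratification(self):
        panel = draw_panel(
            [
                AncestrySpec("A", 0.1, 1000, 0.0),
                AncestrySpec("B", 0.1, 1000, 1.0),
            ],
            n_variants=300,
            ld_block_spec=[(300, 0.0)],
            seed=13,
        )
        pheno, _ = simulate_phenotypes(
            panel, TraitArchitecture(n_causal=0, h2=0.0, strat_delta=0.5), seed=13
        )
        y = pheno["phenotype"].to_numpy()
        naive = run_gwas(panel, y, n_pcs=0)
        adjusted = run_gwas(panel, y, n_pcs=2)
        freqs = panel.pop_freqs
        diff = (freqs["A"] - freqs["B"]).abs().to_numpy()
        j = int(np.argmax(diff))  # most differentiated null variant
        assert naive.loc[j, "P"] < 0.05
        assert adjusted.loc[j, "P"] > 0.05

    def test_monomorphic_variant_flagged(self):
        panel = draw_panel([AncestrySpec("A", 0.0, 50)], n_variants=5, seed=17)
        panel.dosages[:, 2] = 0.0
        y = np.random.default_rng(0).standard_normal(50)
        out = run_gwas(panel, y, n_pcs=0)
        assert np.isnan(out.loc[2, "BETA"])
        assert out.loc[2, "MAC"] == 0


class TestQcFilter:
    def _frame(self, **cols):
        base = {"SNP": [f"v{i}" for i in range(len(next(iter(cols.values()))))]}
        base.update(cols)
        return pd.DataFrame(base)

    def test_low_info_removed_with_reason(self):
        df = self._frame(INFO=[0.39], MAC=[10], N=[1000])
        kept, log = qc_filter(df)
        assert len(kept) == 0
        assert log.loc[0, "reason"] == "info"

    def test_boundary_values_retained(self):
        df = self._frame(INFO=[0.4], MAC=[5], N=[100])
        kept, log = qc_filter(df)
        assert len(kept) == 1 and len(log) == 0

    def test_mac_threshold(self):
        df = self._frame(INFO=[1.0] * 3, MAC=[4, 5, 6], N=[1000] * 3)
        kept, log = qc_filter(df)
        assert len(kept) == 2
        assert len(kept) + len(log) == 3

    def test_counts_partition_input(self):
        rng = np.random.default_rng(5)
        df = self._frame(
            INFO=rng.uniform(0, 1, 50),
            MAC=rng.integers(0, 20, 50),
            N=rng.integers(50, 200, 50),
        )
        kept, log = qc_filter(df)
        assert len(kept) + len(log) == 50


class TestEqtlScan:
    def test_noiseless_eqtl_slope(self, small_panel):
        expr = simulate_expression(small_panel, [("rs5", "g1", 2.0)], noise_sd=0.0)
        lead = Variant("rs5", "1", int(small_panel.variants.loc[4, "POS"]), "G", "A")
        res, thresh = eqtl_scan(expr, small_panel, lead, n_pcs=0)
        row = res.loc[(res["SNP"] == "rs5") & (res["gene"] == "g1")].iloc[0]
        # inverse-normalization preserves a perfect monotone dosage->expression
        # relation's significance, not its slope scale; use raw expression
        assert row["P"] < 1e-10

    def test_bonferroni_counts_snps_in_region(self, small_panel):
        expr = simulate_expression(small_panel, [("rs1", "g1", 1.0)], noise_sd=1.0)
        lead = Variant("rs1", "1", int(small_panel.variants.loc[0, "POS"]), "G", "A")
        # all 60 variants lie within 1 Mb of the lead (5 kb spacing)
        res, thresh = eqtl_scan(expr, small_panel, lead, n_pcs=0)
        assert np.isclose(thresh, 0.05 / 60)

    def test_window_restricts_tested_snps(self, small_panel):
        expr = simulate_expression(small_panel, [("rs1", "g1", 1.0)], noise_sd=1.0)
        lead = Variant("rs1", "1", int(small_panel.variants.loc[0, "POS"]), "G", "A")
        res, thresh = eqtl_scan(expr, small_panel, lead, window=20_000, n_pcs=0)
        assert res["SNP"].nunique() <= 5
        assert np.isclose(thresh, 0.05 / res["SNP"].nunique())

    def test_null_gene_pvalues_uniform(self):
        panel = draw_panel([AncestrySpec("A", 0.0, 300)], n_variants=1, seed=19)
        rng = np.random.default_rng(19)
        expr = pd.DataFrame(
            rng.standard_normal((200, 300)),
            index=[f"g{i}" for i in range(200)],
            columns=panel.sample_ids,
        )
        lead = Variant("rs1", "1", 5000, "G", "A")
        res, _ = eqtl_scan(expr, panel, lead, n_pcs=0)
        frac = (res["P"] < 0.05).mean()
        assert abs(frac - 0.05) < 0.05

    def test_no_genes_in_window_is_empty(self, small_panel):
        expr = simulate_expression(small_panel, [("rs1", "g1", 1.0)], noise_sd=1.0)
        lead = Variant("rs1", "1", 5000, "G", "A")
        res, thresh = eqtl_scan(
            expr, small_panel, lead, gene_positions={"g1": ("2", 5000)}, n_pcs=0
        )
        assert res.empty
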