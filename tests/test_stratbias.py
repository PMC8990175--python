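"""Stratification-bias diagnostics: pruning, PCA, loadings, jackknife."""

import numpy as np
import pandas as pd
import pytest

from transgwas.simdata import AncestrySpec, draw_panel
from transgwas.stratbias import (
    PruneConfig,
    compare_correlations,
    default_n_blocks,
    jackknife_test,
    loading_effect_correlation,
    pc_loadings,
    prune_variants,
    run_pca,
)


def _loadings_frame(values, snps=None, maf=0.25):
    m = len(values)
    return pd.DataFrame(
        {
            "SNP": snps if snps is not None else [f"rs{i}" for i in range(m)],
            "COUNTED": "G",
            "OTHER": "A",
            "MAF": maf,
            "PC1": np.asarray(values, dtype=float),
        }
    )


def _gwas_frame(betas, snps=None, ea="G", oa="A"):
    m = len(betas)
    return pd.DataFrame(
        {
            "SNP": snps if snps is not None else [f"rs{i}" for i in range(m)],
            "EA": ea,
            "OA": oa,
            "BETA": np.asarray(betas, dtype=float),
        }
    )


class TestPrune:
    def test_distance_rule_drops_close_variant(self):
        panel = draw_panel([AncestrySpec("A", 0.0, 200)], n_variants=4,
                           spacing_bp=1500, seed=1)
        kept = prune_variants(panel, PruneConfig(ld_r2_max=0.99))
        pos = panel.variants.set_index("SNP")["POS"]
        kept_pos = sorted(pos[k] for k in kept)
        assert all(b - a >= 2000 for a, b in zip(kept_pos, kept_pos[1:]))

    def test_duplicate_variant_removed_by_ld(self):
        panel = draw_panel([AncestrySpec("A", 0.0, 200)], n_variants=6,
                           spacing_bp=10_000, seed=2)
        panel.dosages[:, 3] = panel.dosages[:, 2]  # r2 = 1 pair
        kept = prune_variants(panel)
        assert not {"rs3", "rs4"} <= set(kept)

    def test_independent_spaced_variants_all_kept(self):
        panel = draw_panel(
            [AncestrySpec("A", 0.0, 500)], n_variants=30,
            ld_block_spec=[(30, 0.0)], spacing_bp=10_000,
            ancestral_maf_dist=lambda r, k: np.full(k, 0.3), seed=3,
        )
        kept = prune_variants(panel)
        assert len(kept) == 30

    def test_low_maf_removed(self):
        panel = draw_panel(
            [AncestrySpec("A", 0.0, 2000)], n_variants=20,
            spacing_bp=10_000,
            ancestral_maf_dist=lambda r, k: np.concatenate(
                [np.full(k - 5, 0.3), np.full(5, 0.01)]
            ),
            seed=4,
        )
        kept = prune_variants(panel)
        freqs = panel.variants.set_index("SNP").index
        maf = dict(zip(panel.variants["SNP"],
                       np.minimum(panel.alt_freqs(), 1 - panel.alt_freqs())))
        assert all(maf[k] > 0.05 for k in kept)

    def test_exclusion_regions_dropped(self):
        panel = draw_panel([AncestrySpec("A", 0.0, 200)], n_variants=10,
                           spacing_bp=10_000, seed=5)
        cfg = PruneConfig(exclusion_regions=(("1", 1, 50_000),))
        kept = prune_variants(panel, cfg)
        pos = panel.variants.set_index("SNP")["POS"]
        assert all(pos[k] >= 50_000 for k in kept)


class TestPca:
    def test_pc1_separates_diverged_populations(self):
        panel = draw_panel(
            [AncestrySpec("A", 0.1, 100, 0.0), AncestrySpec("B", 0.1, 100, 1.0)],
            n_variants=500,
            ld_block_spec=[(500, 0.0)],
            seed=29,
        )
        pcs, eigvals = run_pca(panel, n_pcs=2)
        group = (np.array(panel.sample_ancestry) == "B").astype(float)
        assert abs(np.corrcoef(pcs[:, 0], group)[0, 1]) > 0.9

    def test_pcs_orthogonal_and_eigvals_sorted(self, small_panel):
        pcs, eigvals = run_pca(small_panel, n_pcs=5)
        gram = pcs.T @ pcs
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-6 * np.max(np.diag(gram))
        assert np.all(np.diff(eigvals) <= 1e-9)

    def test_sign_convention(self, small_panel):
        pcs, _ = run_pca(small_panel, n_pcs=3)
        for j in range(3):
            assert pcs[np.argmax(np.abs(pcs[:, j])), j] > 0


class TestLoadings:
    def test_worked_four_sample_slope(self):
        # genotypes {0,1,1,2}, PC {-3,-1,1,3}: centered Sxy/Sxx = 6/2 = 3
        panel = draw_panel([AncestrySpec("A", 0.0, 4)], n_variants=2, seed=6)
        panel.dosages[:, 0] = np.array([0, 1, 1, 2], dtype=panel.dosages.dtype)
        pcs = np.array([[-3.0], [-1.0], [1.0], [3.0]])
        out = pc_loadings(panel, pcs)
        assert np.isclose(out.set_index("SNP").loc["rs1", "PC1"], 3.0)

    def test_linearity_in_pc_scale(self, small_panel):
        pcs, _ = run_pca(small_panel, n_pcs=2)
        l1 = pc_loadings(small_panel, pcs)
        l2 = pc_loadings(small_panel, 2.0 * pcs)
        assert np.allclose(2.0 * l1["PC1"], l2["PC1"])

    def test_uncorrelated_genotype_loading_near_zero(self):
        rng = np.random.default_rng(7)
        panel = draw_panel([AncestrySpec("A", 0.0, 2000)], n_variants=3, seed=7)
        pcs = rng.standard_normal((2000, 1))
        out = pc_loadings(panel, pcs)
        assert np.all(np.abs(out["PC1"]) < 0.1)


class TestCorrelation:
    def test_proportional_betas_give_rho_one(self):
        rng = np.random.default_rng(8)
        lo = rng.standard_normal(100)
        rho = loading_effect_correlation(_loadings_frame(lo), _gwas_frame(2.0 * lo))
        assert np.isclose(rho["PC1"], 1.0)

    def test_independent_betas_give_rho_near_zero(self):
        rng = np.random.default_rng(31)
        m = 10_000
        rho = loading_effect_correlation(
            _loadings_frame(rng.standard_normal(m)),
            _gwas_frame(rng.standard_normal(m)),
        )
        assert abs(rho["PC1"]) < 0.03

    def test_rare_variants_excluded(self):
        rng = np.random.default_rng(9)
        lo = rng.standard_normal(100)
        frame = _loadings_frame(lo)
        frame.loc[:49, "MAF"] = 0.005  # below the MAF > 1% rule
        betas = np.concatenate([np.zeros(50), 2.0 * lo[50:]])
        rho = loading_effect_correlation(frame, _gwas_frame(betas))
        assert np.isclose(rho["PC1"], 1.0)  # rare half played no part

    def test_allele_flip_invariance(self):
        rng = np.random.default_rng(10)
        lo = rng.standard_normal(200)
        base = loading_effect_correlation(
            _loadings_frame(lo), _gwas_frame(2.0 * lo + rng.standard_normal(200))
        )
        # flipping the GWAS allele labels and beta signs leaves rho unchanged
        flipped = loading_effect_correlation(
            _loadings_frame(lo),
            _gwas_frame(-(2.0 * lo + rng.standard_normal(200)), ea="A", oa="G"),
        )
        # same construction up to noise redraw; check the exact identity
        g = _gwas_frame(2.0 * lo)
        g_flip = g.copy()
        g_flip["EA"], g_flip["OA"], g_flip["BETA"] = "A", "G", -g["BETA"]
        r1 = loading_effect_correlation(_loadings_frame(lo), g)
        r2 = loading_effect_correlation(_loadings_frame(lo), g_flip)
        assert np.isclose(r1["PC1"], r2["PC1"])

    def test_affine_beta_rescaling_invariance(self):
        rng = np.random.default_rng(11)
        lo = rng.standard_normal(300)
        betas = lo + rng.standard_normal(300)
        r1 = loading_effect_correlation(_loadings_frame(lo), _gwas_frame(betas))
        r2 = loading_effect_correlation(_loadings_frame(lo),
                                        _gwas_frame(3.0 * betas + 0.7))
        assert np.isclose(r1["PC1"], r2["PC1"])

    def test_too_few_variants_rejected(self):
        with pytest.raises(ValueError):
            loading_effect_correlation(
                _loadings_frame(np.arange(5.0)), _gwas_frame(np.arange(5.0))
            )


class TestJackknife:
    def test_block_scaling_for_small_sets(self):
        assert default_n_blocks(2_000) == 20
        assert default_n_blocks(5_000) == 50
        assert default_n_blocks(20_000) == 1000

    def test_identical_loo_values_floor_p(self):
        # perfectly proportional betas: every leave-one-out rho is 1
        lo = np.linspace(-1, 1, 400)
        jk = jackknife_test(_loadings_frame(lo), _gwas_frame(2.0 * lo))
        assert jk.loc[0, "se"] == 0.0
        assert jk.loc[0, "p"] <= np.finfo(float).tiny * 10

    def test_jackknife_se_close_to_analytic_on_iid_data(self):
        rng = np.random.default_rng(12)
        m = 20_000
        lo = rng.standard_normal(m)
        betas = 0.1 * lo + rng.standard_normal(m)
        jk = jackknife_test(_loadings_frame(lo), _gwas_frame(betas), n_blocks=1000)
        rho = jk.loc[0, "rho"]
        analytic = (1 - rho**2) / np.sqrt(m)
        assert jk.loc[0, "se"] < 1.5 * analytic
        assert analytic < 1.5 * jk.loc[0, "se"]

    def test_detects_true_correlation(self):
        rng = np.random.default_rng(13)
        m = 5_000
        lo = rng.standard_normal(m)
        betas = 0.2 * lo + rng.standard_normal(m)
        jk = jackknife_test(_loadings_frame(lo), _gwas_frame(betas))
        assert jk.loc[0, "rho"] > 0.1
        assert jk.loc[0, "p"] < 1e-6


class TestCompareCorrelations:
    def test_identical_datasets_give_zero_delta(self):
        rng = np.random.default_rng(14)
        lo = rng.standard_normal(1_000)
        g = _gwas_frame(0.3 * lo + rng.standard_normal(1_000))
        out = compare_correlations(g, g.copy(), _loadings_frame(lo))
        assert out.loc[0, "delta_rho"] == 0.0
        assert out.loc[0, "p"] == 1.0

    def test_biased_vs_null_dataset_detected(self):
        rng = np.random.default_rng(41)
        m = 5_000
        lo = rng.standard_normal(m)
        biased = _gwas_frame(0.3 * lo + rng.standard_normal(m))
        null = _gwas_frame(rng.standard_normal(m))
        out = compare_correlations(biased, null, _loadings_frame(lo))
        assert out.loc[0, "delta_rho"] > 0
        assert out.loc[0, "p"] < 0.01

    def test_restriction_to_shared_variants_changes_rho(self):
        rng = np.random.default_rng(15)
        m = 1_000
        lo = rng.standard_normal(m)
        full = _gwas_frame(0.3 * lo + rng.standard_normal(m))
        half = full.iloc[: m // 2]
        rho_full = loading_effect_correlation(_loadings_frame(lo), full)
        rho_half = loading_effect_correlation(_loadings_frame(lo), half)
        assert not np.isclose(rho_full["PC1"], rho_half["PC1"])
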