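"""Lead/proxy selection, locus classification, replication/transferability
decision rules, and the directional-consistency binomial test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from transgwas.assoc import SummaryRecord, Variant
from transgwas.ld import LdMatrix
from transgwas.loci import (
    KnownIndex,
    assess_novelty_two_stage,
    assess_novelty_transancestral,
    assess_transferability,
    binomial_consistency,
    classify_locus,
    select_leads,
    select_proxies,
    tally_transferability,
    transferability_percentage,
)


def srec(beta, p, vid="rs1", pos=100, n=1000):
    se = abs(beta) / stats.norm.isf(p / 2) if beta != 0 else 1.0
    return SummaryRecord(
        variant=Variant(vid, "1", pos, "G", "A"),
        eaf=0.3, beta=beta, se=se, p=p, n=n,
    )


def frame(rows):
    return pd.DataFrame(rows, columns=["SNP", "CHR", "POS", "P"])


class TestSelectLeads:
    def test_distant_independent_snps_both_lead(self):
        df = frame([("a", "1", 100_000, 1e-9), ("b", "1", 700_000, 1e-8)])
        assert select_leads(df) == ["a", "b"]

    def test_nearby_snps_keep_smaller_p(self):
        df = frame([("a", "1", 100_000, 1e-9), ("b", "1", 200_000, 1e-8)])
        assert select_leads(df) == ["a"]

    def test_no_genome_wide_hits(self):
        df = frame([("a", "1", 100_000, 1e-6)])
        assert select_leads(df) == []

    def test_high_ld_distant_snp_removed(self):
        df = frame([("a", "1", 100_000, 1e-9), ("b", "1", 700_000, 1e-8)])
        ld = LdMatrix(["a", "b"], np.array([[1.0, 0.6], [0.6, 1.0]]))
        assert select_leads(df, ld=ld) == ["a"]  # r2 = 0.36 >= 0.2

    def test_pairwise_independence_property(self):
        rng = np.random.default_rng(4)
        pos = np.sort(rng.integers(1, 5_000_000, 30))
        df = frame([(f"v{i}", "1", int(p), 10 ** -rng.uniform(6, 12))
                    for i, p in enumerate(pos)])
        leads = select_leads(df)
        sub = df.set_index("SNP").loc[leads]
        for i in range(len(sub)):
            for j in range(i + 1, len(sub)):
                assert abs(sub["POS"].iloc[i] - sub["POS"].iloc[j]) > 500_000


class TestSelectProxies:
    def _ld(self):
        # one-factor correlation structure: PSD with r2(lead, p_i) as chosen
        load = np.array([1.0, np.sqrt(0.95), np.sqrt(0.92), np.sqrt(0.91)])
        r = np.outer(load, load) + np.diag(1 - load**2)
        return LdMatrix(["lead", "p1", "p2", "p3"], r)

    def test_top_two_by_r2(self):
        got = select_proxies("lead", self._ld())
        assert got == ["p1", "p2"]

    def test_all_below_threshold_empty(self):
        r = np.eye(2)
        r[0, 1] = r[1, 0] = 0.5
        assert select_proxies("a", LdMatrix(["a", "b"], r)) == []

    def test_lead_excluded_despite_perfect_self_ld(self):
        got = select_proxies("lead", self._ld(), k=4)
        assert "lead" not in got


class TestClassifyLocus:
    def _known(self, pos):
        return [KnownIndex("BMI", Variant("k", "2", pos, "G", "A"))]

    def test_within_window_established(self):
        lead = Variant("rs", "2", 1_000_000, "G", "A")
        assert classify_locus(lead, self._known(1_400_000)) == "established"

    def test_outside_window_novel(self):
        lead = Variant("rs", "2", 1_000_000, "G", "A")
        assert classify_locus(lead, self._known(1_600_000)) == "novel"

    def test_boundary_inclusive(self):
        lead = Variant("rs", "2", 1_000_000, "G", "A")
        assert classify_locus(lead, self._known(1_500_000)) == "established"
        assert classify_locus(lead, self._known(500_000)) == "established"

    def test_no_nearby_known_index_is_novel(self):
        # lead far from every published index SNP on its chromosome
        lead = Variant("rs994108", "2", 223_057_288, "C", "A")
        known = [KnownIndex("BMI", Variant("k", "2", 100_000_000, "G", "A"))]
        assert classify_locus(lead, known) == "novel"

    def test_empty_known_list(self):
        lead = Variant("rs", "1", 1, "G", "A")
        assert classify_locus(lead, []) == "novel"


class TestNoveltyRules:
    def test_replicated_improved_signal_is_novel(self):
        v = assess_novelty_two_stage(
            srec(0.041, 1.62e-8), srec(0.030, 5.65e-2), srec(0.038, 2.19e-9)
        )
        assert v == "novel"

    def test_worsened_p_is_not_novel(self):
        v = assess_novelty_two_stage(
            srec(0.041, 2.287e-8), srec(0.005, 7.62e-1), srec(0.035, 1.16e-7)
        )
        assert v == "not-novel"

    def test_sign_flip_is_not_novel(self):
        v = assess_novelty_two_stage(
            srec(0.328, 1.08e-8), srec(-0.339, 6.22e-1), srec(0.308, 5.18e-8)
        )
        assert v == "not-novel"

    def test_missing_stage2_untested(self):
        assert assess_novelty_two_stage(srec(0.04, 1e-9), None, None) == "untested"

    def test_transancestral_replicated(self):
        v = assess_novelty_transancestral(srec(0.019, 2.23e-9), srec(0.006, 1.82e-2))
        assert v == "novel"

    def test_transancestral_failed_replication(self):
        v = assess_novelty_transancestral(srec(0.017, 3.0e-8), srec(0.002, 4.58e-1))
        assert v == "not-novel"

    def test_transancestral_missing_replication(self):
        assert assess_novelty_transancestral(srec(0.02, 1e-9), None) == "untested"


class TestTransferability:
    def test_consistent_significant_transfers(self):
        v = assess_transferability(srec(0.042, 2.6e-8), srec(0.013, 9.9e-4), 0.0)
        assert v == "transferable"

    def test_sign_flip_does_not_transfer(self):
        v = assess_transferability(srec(-0.032, 5.5e-9), srec(0.006, 1.1e-1), 0.0)
        assert v == "not-transferable"

    def test_high_heterogeneity_blocks_transfer(self):
        v = assess_transferability(srec(0.02, 1e-9), srec(0.01, 0.04), 80.0)
        assert v == "not-transferable"

    @pytest.mark.parametrize(
        "nominal,tested,pct",
        [(336, 1247, 26.9), (1177, 3806, 30.9), (143, 694, 20.6), (0, 50, 0.0)],
    )
    def test_percentages(self, nominal, tested, pct):
        assert transferability_percentage(nominal, tested) == pct

    def test_tally_counts_and_ordering(self):
        rng = np.random.default_rng(6)
        n = 200
        df = pd.DataFrame(
            {
                "BETA": rng.normal(0, 0.02, n),
                "KNOWN_SIGN": rng.choice([-1.0, 1.0], n),
                "P": rng.uniform(0, 1, n),
                "I2": rng.uniform(0, 100, n),
            }
        )
        out = tally_transferability(df)
        assert out["bonferroni"] <= out["nominal"] <= out["tested"]
        assert out["percentage"] == round(100 * out["nominal"] / out["tested"], 1)

    def test_empty_tally_rejected(self):
        with pytest.raises(ValueError):
            tally_transferability(pd.DataFrame(columns=["BETA", "KNOWN_SIGN", "P"]))


class TestBinomialConsistency:
    def test_half_consistent_not_significant(self):
        assert binomial_consistency(17, 33) > 0.10

    def test_exact_enumeration_small_case(self):
        # sum of outcome probabilities <= P(X=2), X ~ Bin(7, 1/2): 58/128
        assert np.isclose(binomial_consistency(2, 7), 58 / 128)

    def test_extreme_outcome(self):
        assert np.isclose(binomial_consistency(0, 10), 2 / 1024)

    @given(st.integers(1, 60), st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetry(self, n, data):
        k = data.draw(st.integers(0, n))
        assert np.isclose(
            binomial_consistency(k, n), binomial_consistency(n - k, n)
        )

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            binomial_consistency(0, 0)
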