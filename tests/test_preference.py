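import math

import numpy as np
import pandas as pd
import pytest

from codonpref import preference as pref_mod
from codonpref.genetic_code import (
    ANALYZED_CODONS,
    CodonUsage,
    pooled_codon_counts,
    relative_synonymous_frequencies,
)
from codonpref.neutral import expected_frequencies
from codonpref.preference import (
    PreferenceVector,
    adaptive_preference,
    class_private_preference,
    classify_third_base_skew,
    compare_gene_level_groups,
    expression_associated_preference,
    gene_level_preference,
    rank_expression_classes,
)


@pytest.fixture
def neutral_122():
    return expected_frequencies(gc_eq=0.122)


def usage_from_rel(rel: dict[str, float]) -> CodonUsage:
    full = {c: math.nan for c in ANALYZED_CODONS}
    full.update(rel)
    return CodonUsage(counts={}, rel_freq=full)


class TestAdaptivePreference:
    def test_observed_equal_expected_is_zero(self, neutral_122):
        obs = usage_from_rel(dict(neutral_122.rel_codon_freq))
        pv = adaptive_preference(obs, neutral_122)
        for c in ANALYZED_CODONS:
            assert pv.pref[c] == pytest.approx(0.0, abs=1e-12)

    def test_doubling_gives_plus_one(self, neutral_122):
        rel = dict(neutral_122.rel_codon_freq)
        rel["AAG"] = 2 * rel["AAG"]  # Lys minor codon, expected < 0.5
        pv = adaptive_preference(usage_from_rel(rel), neutral_122)
        assert pv.pref["AAG"] == pytest.approx(1.0)

    def test_zero_frequency_flagged_not_pseudocounted(self, neutral_122):
        rel = dict(neutral_122.rel_codon_freq)
        rel["GCG"] = 0.0
        pv = adaptive_preference(usage_from_rel(rel), neutral_122)
        assert math.isnan(pv.pref["GCG"])

    def test_centering_within_amino_acid(self, neutral_122):
        rng = np.random.default_rng(0)
        rel = dict(neutral_122.rel_codon_freq)
        obs = usage_from_rel(rel)
        pv = adaptive_preference(obs, neutral_122)
        shifted = PreferenceVector(pref={c: v + 3.0 for c, v in pv.pref.items()})
        c1 = pv.centered_within_aa()
        c2 = shifted.centered_within_aa()
        for c in ANALYZED_CODONS:
            assert c1.pref[c] == pytest.approx(c2.pref[c])


class TestGeneLevelPreference:
    def test_zero_pref_codons_give_zero(self):
        pv = PreferenceVector(pref={c: 0.0 for c in ANALYZED_CODONS})
        assert gene_level_preference("ATG" + "AAA" * 10 + "TAA", pv) == 0.0

    def test_single_codon_gene_returns_its_preference(self):
        pv = PreferenceVector(pref={c: 0.0 for c in ANALYZED_CODONS})
        pv.pref["GCT"] = 0.7
        assert gene_level_preference("GCT" * 5, pv) == pytest.approx(0.7)

    def test_occurrence_weighted_mean(self):
        pv = PreferenceVector(pref={c: 0.0 for c in ANALYZED_CODONS})
        pv.pref["AAA"] = 1.0
        pv.pref["GCT"] = -0.5
        # 3 x AAA, 1 x GCT -> (3*1.0 - 0.5) / 4
        cds = "AAA" * 3 + "GCT"
        assert gene_level_preference(cds, pv) == pytest.approx(2.5 / 4)

    def test_gene_without_analyzed_codons_is_nan(self):
        pv = PreferenceVector(pref={c: 0.0 for c in ANALYZED_CODONS})
        assert math.isnan(gene_level_preference("ATGTGGTAA", pv))


class TestClassPrivatePreference:
    def test_whole_genome_equals_genome_vector(self, neutral_122):
        genes = ["AAAAAGGCT" * 4, "GCAGCGGCC" * 3, "AAAGCT" * 5]
        direct = adaptive_preference(
            relative_synonymous_frequencies(pooled_codon_counts(genes)),
            neutral_122,
        )
        via_class = class_private_preference(genes, neutral_122)
        for c in ANALYZED_CODONS:
            if math.isnan(direct.pref[c]):
                assert math.isnan(via_class.pref[c])
            else:
                assert via_class.pref[c] == pytest.approx(direct.pref[c])

    def test_pooling_identity(self, neutral_122):
        """Preference of a union equals the count-pooled computation."""
        rng = np.random.default_rng(1)
        half_a = ["".join(rng.choice(["AAA", "AAG", "GCT", "GCA"], 30)) for _ in range(5)]
        half_b = ["".join(rng.choice(["AAA", "AAG", "GCT", "GCC"], 30)) for _ in range(5)]
        union = class_private_preference(half_a + half_b, neutral_122)
        pooled_counts = pooled_codon_counts(half_a + half_b)
        pooled = adaptive_preference(
            relative_synonymous_frequencies(pooled_counts), neutral_122
        )
        for c in ANALYZED_CODONS:
            if not math.isnan(union.pref[c]):
                assert union.pref[c] == pytest.approx(pooled.pref[c])


class TestExpressionAssociatedPreference:
    def test_identical_usage_gives_zero(self, neutral_122):
        u = usage_from_rel(dict(neutral_122.rel_codon_freq))
        pv = expression_associated_preference(u, u)
        assert all(pv.pref[c] == pytest.approx(0.0) for c in ANALYZED_CODONS)

    def test_doubled_relative_use_gives_plus_one(self):
        hi = usage_from_rel({"AAA": 0.6, "AAG": 0.4})
        lo = usage_from_rel({"AAA": 0.3, "AAG": 0.7})
        pv = expression_associated_preference(hi, lo)
        assert pv.pref["AAA"] == pytest.approx(1.0)

    def test_ranking_excludes_sociality_and_zero_expression(self):
        df = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(10)],
                "expression": [0.0, 5, 4, 3, 9, 8, 7, 2, 1, 6],
                "sociality": [False, True, False, False, False,
                              False, False, False, False, False],
            }
        )
        high, low = rank_expression_classes(df, n_per_class=2)
        assert high == ["g4", "g5"]
        assert low == ["g7", "g8"]
        assert "g0" not in low and "g1" not in high


class TestThirdBaseSkew:
    def test_equal_vectors_give_empty_sets(self):
        pv = PreferenceVector(pref={c: 0.5 for c in ANALYZED_CODONS})
        table, chi2, _ = classify_third_base_skew(pv, pv)
        assert table.to_numpy().sum() == 0

    def test_counts_match_enumeration(self):
        rng = np.random.default_rng(2)
        a = PreferenceVector(pref={c: float(rng.normal()) for c in ANALYZED_CODONS})
        b = PreferenceVector(pref={c: float(rng.normal()) for c in ANALYZED_CODONS})
        table, _, _ = classify_third_base_skew(a, b)
        expected = sum(1 for c in ANALYZED_CODONS if a.pref[c] > b.pref[c])
        assert table["a_greater"].sum() == expected
        assert table["a_greater"].sum() + table["b_greater"].sum() == 59


class TestGroupComparison:
    def test_identical_groups_give_zero_t(self):
        vals = [0.1, 0.2, 0.3, 0.4]
        _, _, t, _ = compare_gene_level_groups(vals, vals)
        assert t == pytest.approx(0.0)

    def test_known_shift_matches_closed_form(self):
        """Equal n, equal variance: t = delta / (s * sqrt(2/n))."""
        rng = np.random.default_rng(3)
        n, delta = 200, 0.3
        base = rng.normal(0, 1, n)
        a = base
        b = base + delta
        ma, mb, t, _ = compare_gene_level_groups(a, b)
        s = np.sqrt(((a - a.mean()) ** 2).sum() / (n - 1))
        expected = (ma - mb) / (s * math.sqrt(2 / n))
        assert t == pytest.approx(expected, rel=1e-6)
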