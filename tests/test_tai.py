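import math

import numpy as np
import pytest

from codonpref import tai
from codonpref.genetic_code import AA_TO_CODONS, ANALYZED_CODONS
from codonpref.preference import PreferenceVector
from codonpref.simulate import generate_trna_table, preference_from_trna


class TestAbsoluteAdaptiveness:
    def test_cognate_only_equals_copies(self):
        # GCT is decoded WC by anticodon AGC; no other anticodon supplied
        W = tai.absolute_adaptiveness({"AGC": 4})
        assert W["GCT"] == pytest.approx(4.0)

    def test_wobble_only_decoding(self):
        # GCT via G:U wobble from anticodon GGC (2 copies): 2 * (1 - 0.41)
        W = tai.absolute_adaptiveness({"GGC": 2})
        assert W["GCT"] == pytest.approx(2 * 0.59)
        # the same anticodon decodes GCC Watson-Crick at full weight
        assert W["GCC"] == pytest.approx(2.0)

    def test_empty_table_all_zero(self):
        W = tai.absolute_adaptiveness({})
        assert all(v == 0.0 for v in W.values())
        with pytest.raises(ValueError):
            tai.geometric_mean_replacement(W)

    def test_invalid_anticodon_rejected(self):
        with pytest.raises(ValueError):
            tai.absolute_adaptiveness({"XYZ": 1})

    def test_watson_crick_decoder_listed_first(self):
        acs = tai.decoding_anticodons("AAA")
        assert acs[0][0] == "TTT"  # revcomp of AAA in DNA alphabet


class TestGeometricMeanReplacement:
    def test_no_zeros_is_identity(self):
        W = {"a": 1.0, "b": 2.0}
        out, replaced = tai.geometric_mean_replacement(W)
        assert out == W and replaced == ()

    def test_zero_replaced_by_geometric_mean(self):
        out, replaced = tai.geometric_mean_replacement({"a": 0.0, "b": 2.0, "c": 8.0})
        assert out["a"] == pytest.approx(4.0)
        assert replaced == ("a",)


class TestRelativeAdaptiveness:
    def test_family_max_is_one(self):
        rng = np.random.default_rng(0)
        W = {c: float(rng.uniform(0.5, 10)) for c in ANALYZED_CODONS}
        w = tai.relative_synonymous_adaptiveness(W)
        for aa, codons in AA_TO_CODONS.items():
            if len(codons) < 2:
                continue
            assert max(w[c] for c in codons) == pytest.approx(1.0)

    def test_two_codon_family(self):
        W = {c: 1.0 for c in ANALYZED_CODONS}
        W["AAA"], W["AAG"] = 4.0, 2.0
        w = tai.relative_synonymous_adaptiveness(W)
        assert w["AAA"] == pytest.approx(1.0)
        assert w["AAG"] == pytest.approx(0.5)

    def test_invariant_to_copy_number_scaling(self):
        rng = np.random.default_rng(1)
        table = generate_trna_table(rng)
        w1 = tai.adaptiveness_from_copies(table).w_ij
        w2 = tai.adaptiveness_from_copies({k: 3 * v for k, v in table.items()}).w_ij
        for c in ANALYZED_CODONS:
            assert w1[c] == pytest.approx(w2[c])


class TestPartition:
    @pytest.fixture
    def w_ij(self):
        rng = np.random.default_rng(2)
        return tai.adaptiveness_from_copies(generate_trna_table(rng)).w_ij

    def test_exact_linear_preference_has_zero_residuals(self, w_ij):
        pref = PreferenceVector(
            pref={c: -1.0 + 2.5 * math.sqrt(w_ij[c]) for c in ANALYZED_CODONS}
        )
        part, fit = tai.partition_preference(pref, w_ij)
        assert fit.r_squared == pytest.approx(1.0)
        for c in ANALYZED_CODONS:
            assert part.trna_indep[c] == pytest.approx(0.0, abs=1e-10)

    def test_components_sum_to_preference(self, w_ij):
        rng = np.random.default_rng(3)
        pref = PreferenceVector(
            pref={c: float(rng.normal()) for c in ANALYZED_CODONS}
        )
        part, _ = tai.partition_preference(pref, w_ij)
        for c in ANALYZED_CODONS:
            assert part.trna_dep[c] + part.trna_indep[c] == pytest.approx(
                pref.pref[c], abs=1e-10
            )

    def test_residuals_orthogonal_to_predictor(self, w_ij):
        rng = np.random.default_rng(4)
        pref = PreferenceVector(
            pref={c: float(rng.normal()) for c in ANALYZED_CODONS}
        )
        part, _ = tai.partition_preference(pref, w_ij)
        resid = np.array([part.trna_indep[c] for c in ANALYZED_CODONS])
        x = np.sqrt([w_ij[c] for c in ANALYZED_CODONS])
        assert resid.sum() == pytest.approx(0.0, abs=1e-8)
        assert float(resid @ x) == pytest.approx(0.0, abs=1e-8)

    def test_orthogonal_preference_gives_zero_slope(self, w_ij):
        """Preference built orthogonal to sqrt(w_ij) leaves the fitted
        component at the intercept."""
        x = np.sqrt([w_ij[c] for c in ANALYZED_CODONS])
        xc = x - x.mean()
        pref = PreferenceVector(
            pref=dict(zip(ANALYZED_CODONS, np.roll(xc, 1) - xc * (xc @ np.roll(xc, 1)) / (xc @ xc)))
        )
        part, fit = tai.partition_preference(pref, w_ij)
        assert fit.slope == pytest.approx(0.0, abs=1e-8)
        for c in ANALYZED_CODONS:
            assert part.trna_dep[c] == pytest.approx(fit.intercept, abs=1e-8)

    def test_recovers_generator_link_within_three_se(self, w_ij):
        """preference = a + b*sqrt(w_ij) + noise recovers (a, b)."""
        rng = np.random.default_rng(5)
        a, b, sd = -0.8, 2.0, 0.3
        pref = PreferenceVector(
            pref=preference_from_trna(w_ij, a=a, b=b, noise_sd=sd, rng=rng)
        )
        part, fit = tai.partition_preference(pref, w_ij)
        import statsmodels.api as sm

        x = np.sqrt([w_ij[c] for c in ANALYZED_CODONS])
        y = np.array([pref.pref[c] for c in ANALYZED_CODONS])
        model = sm.OLS(y, sm.add_constant(x)).fit()
        assert abs(fit.intercept - a) < 3 * model.bse[0]
        assert abs(fit.slope - b) < 3 * model.bse[1]

    def test_constant_predictor_rejected(self):
        pref = PreferenceVector(pref={c: 0.1 for c in ANALYZED_CODONS})
        with pytest.raises(ValueError):
            tai.partition_preference(pref, {c: 1.0 for c in ANALYZED_CODONS})


def test_trna_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(6)
    table = generate_trna_table(rng)
    p = tmp_path / "trna.tsv"
    tai.write_trna_table(table, p)
    back = tai.read_trna_table(p)
    assert back == table
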