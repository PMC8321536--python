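import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from codonpref import selection as sel
from codonpref.genetic_code import ANALYZED_CODONS
from codonpref.preference import PreferenceVector
from codonpref.spectrum import MUT_CLASSES, MutationSpectrum
from conftest import random_spectrum


@pytest.fixture
def worked_example_spectrum():
    """A spectrum with the A-source rates of the alanine worked example."""
    rates = {c: 0.0 for c in MUT_CLASSES}
    rates[("A", "C")] = 0.01
    rates[("A", "G")] = 0.04
    rates[("A", "T")] = 0.04
    rest = [c for c in MUT_CLASSES if c[0] != "A"]
    for c in rest:
        rates[c] = (1 - 0.09) / len(rest)
    return MutationSpectrum(rates=rates)


@pytest.fixture
def worked_example_pref():
    pref = {c: 0.0 for c in ANALYZED_CODONS}
    pref.update({"GCC": 0.82, "GCG": -1.62, "GCT": -0.41, "GCA": 0.31})
    return PreferenceVector(pref=pref)


class TestExpectedProportions:
    def test_raw_weight_is_frequency_times_rate(self, worked_example_spectrum):
        freqs = {c: 0.0164 if c == "GCA" else 0.01 for c in ANALYZED_CODONS}
        df = sel.expected_snp_proportions(freqs, worked_example_spectrum)
        row = df[(df["source"] == "GCA") & (df["target"] == "GCC")].iloc[0]
        assert row["p_raw"] == pytest.approx(0.0164 * 0.01)

    def test_normalization_sums_to_one(self, default_spectrum):
        rng = np.random.default_rng(0)
        freqs = {c: float(rng.random()) for c in ANALYZED_CODONS}
        df = sel.expected_snp_proportions(freqs, default_spectrum)
        assert df["p_hat"].sum() == pytest.approx(1.0)
        assert len(df) == 114

    def test_uniform_inputs_give_uniform_p_hat(self, uniform_spectrum):
        freqs = {c: 1 / 59 for c in ANALYZED_CODONS}
        df = sel.expected_snp_proportions(freqs, uniform_spectrum)
        assert df["p_hat"].nunique() == 1


class TestWithinCodonExpected:
    def test_alanine_worked_example(self, worked_example_spectrum):
        props = sel.within_codon_expected("GCA", worked_example_spectrum)
        assert props["GCC"] == pytest.approx(1 / 9)
        assert props["GCG"] == pytest.approx(4 / 9)
        assert props["GCT"] == pytest.approx(4 / 9)

    def test_two_equal_rate_targets(self, uniform_spectrum):
        # Ile's ATT offers ATC (T>C) and ATA (T>A); equal rates split evenly
        props = sel.within_codon_expected("ATT", uniform_spectrum)
        assert props["ATC"] == pytest.approx(0.5)
        assert props["ATA"] == pytest.approx(0.5)

    def test_single_option_source_rejected(self, uniform_spectrum):
        with pytest.raises(ValueError):
            sel.within_codon_expected("AAA", uniform_spectrum)

    def test_matches_brute_force_normalization(self):
        rng = np.random.default_rng(1)
        sp = random_spectrum(rng)
        props = sel.within_codon_expected("GGA", sp)
        raw = {
            "GGC": sp.rates[("A", "C")],
            "GGG": sp.rates[("A", "G")],
            "GGT": sp.rates[("A", "T")],
        }
        tot = sum(raw.values())
        for t, v in raw.items():
            assert props[t] == pytest.approx(v / tot)

    def test_sums_to_one_for_every_source(self, default_spectrum):
        for m in sel.mutation_set():
            props = sel.within_codon_expected(m.source, default_spectrum)
            assert sum(props.values()) == pytest.approx(1.0)


class TestLog10Deviation:
    def test_matched_proportions_give_zero(self):
        assert sel.log10_deviation(0.4, 0.4) == pytest.approx(0.0)

    def test_tenfold_excess_gives_one(self):
        assert sel.log10_deviation(0.5, 0.05) == pytest.approx(1.0)

    def test_alanine_deviations_near_printed_values(self, worked_example_spectrum):
        props = sel.within_codon_expected("GCA", worked_example_spectrum)
        observed = {"GCC": 0.16, "GCG": 0.43, "GCT": 0.41}
        devs = {t: sel.log10_deviation(observed[t], props[t]) for t in observed}
        assert devs["GCC"] == pytest.approx(0.17, abs=0.02)
        assert devs["GCG"] == pytest.approx(-0.01, abs=0.02)
        assert devs["GCT"] == pytest.approx(-0.04, abs=0.02)

    def test_zero_expected_errors(self):
        with pytest.raises(ValueError):
            sel.log10_deviation(0.5, 0.0)


class TestRelativePreference:
    def test_alanine_worked_example(self, worked_example_pref):
        rel = sel.relative_preference_within_codon("GCA", worked_example_pref)
        mean = (0.82 - 1.62 - 0.41) / 3
        assert mean == pytest.approx(-0.40, abs=0.01)
        assert rel["GCC"] == pytest.approx(1.22, abs=0.02)
        assert rel["GCG"] == pytest.approx(-1.21, abs=0.02)
        assert rel["GCT"] == pytest.approx(-0.01, abs=0.02)

    def test_equal_preferences_give_zeros(self):
        pv = PreferenceVector(pref={c: 0.3 for c in ANALYZED_CODONS})
        rel = sel.relative_preference_within_codon("AAA", pv)
        assert all(v == pytest.approx(0.0) for v in rel.values())

    def test_sums_to_zero_within_codon(self, worked_example_pref):
        rng = np.random.default_rng(2)
        pv = PreferenceVector(
            pref={c: float(rng.normal()) for c in ANALYZED_CODONS}
        )
        for src in {m.source for m in sel.mutation_set()}:
            rel = sel.relative_preference_within_codon(src, pv)
            assert sum(rel.values()) == pytest.approx(0.0, abs=1e-12)

    def test_undefined_preference_excluded(self):
        pref = {c: 0.0 for c in ANALYZED_CODONS}
        pref["GCC"] = math.nan
        with pytest.raises(ValueError):
            sel.relative_preference_within_codon("GCA", PreferenceVector(pref=pref))


class TestZeroReplacement:
    def test_zeros_become_one(self):
        counts = {"a": 0, "b": 5, "c": 7}
        out, replaced = sel.zero_replacement(counts)
        assert out == {"a": 1, "b": 5, "c": 7}
        assert replaced == ["a"]

    def test_no_zeros_is_identity(self):
        counts = {"a": 2, "b": 5}
        out, replaced = sel.zero_replacement(counts)
        assert out == counts and replaced == []


class TestCorrelation:
    def test_identity_gives_perfect_rma(self):
        rng = np.random.default_rng(3)
        import pandas as pd

        v = rng.normal(size=50)
        table = pd.DataFrame({"rel_pref": v, "log10_dev": v})
        res = sel.polymorphism_preference_correlation(table)
        assert res.r == pytest.approx(1.0)
        assert res.rma_slope == pytest.approx(1.0)

    def test_rma_slope_is_sd_ratio(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1.0, 200)
        y = 2.0 * x + rng.normal(0, 0.5, 200)
        slope, intercept = sel.rma_line(x, y)
        assert slope == pytest.approx(np.std(y, ddof=1) / np.std(x, ddof=1))
        assert np.mean(y) == pytest.approx(slope * np.mean(x) + intercept)

    def test_too_few_points_error(self):
        import pandas as pd

        table = pd.DataFrame({"rel_pref": [1.0, 2.0], "log10_dev": [1.0, 2.0]})
        with pytest.raises(ValueError):
            sel.polymorphism_preference_correlation(table)


class TestSynSnpTable:
    def test_table_invariants(self, default_spectrum):
        rng = np.random.default_rng(5)
        freqs = {c: float(rng.random()) for c in ANALYZED_CODONS}
        tot = sum(freqs.values())
        freqs = {c: v / tot for c, v in freqs.items()}
        pv = PreferenceVector(pref={c: float(rng.normal()) for c in ANALYZED_CODONS})
        counts = {
            (m.source, m.target): int(rng.integers(0, 50))
            for m in sel.mutation_set()
        }
        table = sel.build_syn_snp_table(freqs, default_spectrum, counts, pv)
        assert table["p_hat"].sum() == pytest.approx(1.0)
        for _, grp in table.groupby("source"):
            assert grp["exp_within"].sum() == pytest.approx(1.0)
            assert grp["obs_within"].sum() == pytest.approx(1.0)
            assert grp["rel_pref"].sum() == pytest.approx(0.0, abs=1e-10)
        assert (table["obs_count"] >= 1).all()  # zeros replaced


class TestAlleleSpectrumKs:
    def test_identical_samples_give_zero_d(self):
        a = np.linspace(0.01, 0.45, 100)
        d, p = sel.allele_spectrum_ks(a, a.copy())
        assert d == pytest.approx(0.0)

    def test_shifted_class_detected(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(0.0, 0.5, 5000)
        b = np.clip(a + 0.1, 0, 0.5)
        d, p = sel.allele_spectrum_ks(b, a)
        assert p < 1e-6

    def test_empty_class_errors(self):
        with pytest.raises(ValueError):
            sel.allele_spectrum_ks([], [0.1])

    def test_partition_interclass(self):
        recs = [("A", "G", 0.1), ("G", "T", 0.2), ("A", "T", 0.3), ("C", "A", 0.4)]
        at_gc, gc_at = sel.partition_interclass_freqs(recs)
        assert list(at_gc) == [0.1]
        assert sorted(gc_at) == [0.2, 0.4]


@settings(max_examples=50, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_eq4_conservation_property(seed):
    """p_hat sums to 1 and within-codon expectations sum to 1 per source,
    for arbitrary random spectra and codon frequencies."""
    rng = np.random.default_rng(seed)
    sp = random_spectrum(rng)
    freqs = {c: float(rng.random()) + 1e-6 for c in ANALYZED_CODONS}
    df = sel.expected_snp_proportions(freqs, sp)
    assert df["p_hat"].sum() == pytest.approx(1.0)
    for src, grp in df.groupby("source"):
        props = sel.within_codon_expected(src, sp, grp["target"].tolist())
        assert sum(props.values()) == pytest.approx(1.0)
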