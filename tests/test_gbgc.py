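import numpy as np
import pandas as pd
import pytest

from codonpref import gbgc
from codonpref.io import GeneModel, build_region_index


def _index_all_intergenic(lengths):
    return build_region_index([], lengths)


class TestSlidingWindowGc:
    def test_all_g_contig(self):
        genome = {"c1": "G" * 100_000}
        idx = _index_all_intergenic({"c1": 100_000})
        track = gbgc.sliding_window_gc(genome, idx, window=50_000)
        assert (track["gc"] == 1.0).all()

    def test_alternating_blocks_average_to_half(self):
        block = "G" * 25_000 + "A" * 25_000
        genome = {"c1": block * 4}
        idx = _index_all_intergenic({"c1": 200_000})
        track = gbgc.sliding_window_gc(genome, idx, window=50_000)
        assert track["gc"].to_numpy() == pytest.approx([0.5] * 4)

    def test_nonoverlapping_tiling_count(self):
        genome = {"c1": "A" * 130_000}
        idx = _index_all_intergenic({"c1": 130_000})
        track = gbgc.sliding_window_gc(genome, idx, window=50_000)
        assert len(track) == 2  # floor((L - w)/w) + 1 full-step starts

    def test_overlapping_window_count(self):
        L, w, s = 200_000, 50_000, 10_000
        genome = {"c1": "A" * L}
        idx = _index_all_intergenic({"c1": L})
        track = gbgc.sliding_window_gc(genome, idx, window=w, step=s)
        assert len(track) == 1 + (L - w) // s

    def test_short_chromosome_yields_single_truncated_window(self):
        genome = {"c1": "ACGT" * 100}
        idx = _index_all_intergenic({"c1": 400})
        track = gbgc.sliding_window_gc(genome, idx, window=50_000)
        assert len(track) == 1
        assert track.iloc[0]["gc"] == pytest.approx(0.5)

    def test_label_restricted_gc(self, small_sim):
        track = gbgc.sliding_window_gc(
            small_sim.genome, small_sim.region_index, window=20_000
        )
        ok = track.dropna(subset=["gc_coding", "gc_noncoding"])
        # coding sequence is much more GC-rich than AT-rich noncoding
        assert ok["gc_coding"].mean() > ok["gc_noncoding"].mean()


class TestWindowRegression:
    def test_identical_tracks_give_r2_one(self):
        rng = np.random.default_rng(0)
        gc = rng.uniform(0.1, 0.4, 50)
        track = pd.DataFrame(
            {"chrom": "c1", "start": np.arange(50), "end": np.arange(50) + 1,
             "gc_coding": gc, "gc_noncoding": gc}
        )
        res = gbgc.window_gc_regression(track)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)

    def test_anticorrelated_construction(self):
        rng = np.random.default_rng(1)
        gc = rng.uniform(0.1, 0.4, 50)
        track = pd.DataFrame(
            {"chrom": "c1", "start": np.arange(50), "end": np.arange(50) + 1,
             "gc_coding": 0.5 - gc, "gc_noncoding": gc}
        )
        res = gbgc.window_gc_regression(track)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope < 0

    def test_independent_tracks_near_zero(self):
        """Null simulation: unrelated coding/noncoding GC leaves R^2 ~ 0."""
        rng = np.random.default_rng(2)
        r2s = []
        for _ in range(100):
            track = pd.DataFrame(
                {"chrom": "c1", "start": np.arange(60), "end": np.arange(60) + 1,
                 "gc_coding": rng.uniform(0.2, 0.3, 60),
                 "gc_noncoding": rng.uniform(0.1, 0.2, 60)}
            )
            r2s.append(gbgc.window_gc_regression(track).r_squared)
        assert np.mean(r2s) < 0.05

    def test_mask_excludes_windows(self):
        gc = np.linspace(0.1, 0.4, 20)
        track = pd.DataFrame(
            {"chrom": "c1", "start": np.arange(20) * 100,
             "end": np.arange(20) * 100 + 100,
             "gc_coding": gc, "gc_noncoding": gc}
        )
        mask = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [500]})
        res = gbgc.window_gc_regression(track, mask)
        assert res.n == 15


class TestRecombinationGc:
    def _tracks(self, rho, gc):
        n = len(rho)
        base = {"chrom": "c1", "start": np.arange(n) * 5000,
                "end": np.arange(n) * 5000 + 5000}
        return (pd.DataFrame({**base, "rho": rho}),
                pd.DataFrame({**base, "gc": gc,
                              "gc_coding": gc, "gc_noncoding": gc}))

    def test_deterministic_link_gives_r2_one(self):
        gc = np.linspace(0.1, 0.4, 40)
        rho, gct = self._tracks(np.exp(gc) - 1e-6, gc)
        res = gbgc.recombination_gc_correlation(rho, gct)
        assert res["genome"].r_squared > 0.99

    def test_constant_rho_flagged_undefined(self):
        rho, gct = self._tracks(np.full(40, 0.05), np.linspace(0.1, 0.4, 40))
        res = gbgc.recombination_gc_correlation(rho, gct)
        assert res["genome"] is None

    def test_zero_rho_admitted_by_offset(self):
        rng = np.random.default_rng(3)
        rho_vals = rng.lognormal(-4, 1, 40)
        rho_vals[:5] = 0.0
        rho, gct = self._tracks(rho_vals, rng.uniform(0.1, 0.4, 40))
        res = gbgc.recombination_gc_correlation(rho, gct)
        assert res["genome"] is not None and res["genome"].n == 40

    def test_independent_tracks_centered_at_zero(self):
        rng = np.random.default_rng(4)
        r2s = []
        for _ in range(50):
            rho, gct = self._tracks(
                rng.lognormal(-4, 1, 50), rng.uniform(0.1, 0.4, 50)
            )
            r2s.append(gbgc.recombination_gc_correlation(rho, gct)["genome"].r_squared)
        assert np.mean(r2s) < 0.06


class TestProximalDistal:
    def _frame(self, a_gc, b_gc):
        n = len(a_gc)
        return pd.DataFrame(
            {"chrom_half": ["proximal"] * n + ["distal"] * n,
             "gc_total": np.concatenate([a_gc, b_gc]),
             "gc3": np.concatenate([a_gc, b_gc])}
        )

    def test_identical_groups_give_zero_t(self):
        gc = np.linspace(0.2, 0.3, 30)
        res = gbgc.proximal_distal_test(self._frame(gc, gc))
        assert res["gc_total"][0] == pytest.approx(0.0)

    def test_known_shift_matches_analytic_t(self):
        rng = np.random.default_rng(5)
        n = 500
        a = 10 ** rng.normal(-0.6, 0.05, n)
        b = a * 10 ** 0.02  # constant shift of 0.02 on the log10 scale
        res = gbgc.proximal_distal_test(self._frame(a, b))
        la = np.log10(a)
        s = la.std(ddof=1)
        expected = -0.02 / (s * np.sqrt(2 / n))
        assert res["gc_total"][0] == pytest.approx(expected, rel=1e-6)

    def test_permuted_labels_give_null_distribution(self):
        rng = np.random.default_rng(6)
        vals = 10 ** rng.normal(-0.6, 0.05, 400)
        ts = []
        for _ in range(200):
            perm = rng.permutation(vals)
            df = pd.DataFrame(
                {"chrom_half": ["proximal"] * 200 + ["distal"] * 200,
                 "gc_total": perm, "gc3": perm}
            )
            ts.append(gbgc.proximal_distal_test(df)["gc_total"][0])
        assert abs(np.mean(ts)) < 2 * np.std(ts) / np.sqrt(len(ts)) + 0.2
        assert 0.7 < np.std(ts) < 1.4

    def test_empty_group_errors(self):
        df = pd.DataFrame(
            {"chrom_half": ["proximal"] * 5, "gc_total": [0.2] * 5, "gc3": [0.1] * 5}
        )
        with pytest.raises(ValueError):
            gbgc.proximal_distal_test(df)


class TestIntronExonRegression:
    def test_copied_gc_gives_r2_one(self):
        gc = np.linspace(0.05, 0.3, 40)
        df = pd.DataFrame({"gc_intron": gc, "gc3": gc, "gc_total": gc})
        res = gbgc.intron_exon_gc_regression(df)
        assert res["gc3"].r_squared == pytest.approx(1.0)

    def test_known_r2_construction_recovered(self):
        """Noisy log-linear link built for R^2 = 0.5 is recovered +-0.05."""
        rng = np.random.default_rng(7)
        n = 5000
        x = rng.normal(-0.8, 0.1, n)  # log10 intronic GC
        noise_sd = 0.1  # equal signal/noise variance -> R^2 = 0.5
        y = x + rng.normal(0, noise_sd, n)
        df = pd.DataFrame(
            {"gc_intron": 10 ** x, "gc3": 10 ** y, "gc_total": 10 ** y}
        )
        res = gbgc.intron_exon_gc_regression(df)
        assert res["gc3"].r_squared == pytest.approx(0.5, abs=0.05)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {"gc_intron": 10 ** rng.normal(-0.8, 0.1, 2000),
             "gc3": 10 ** rng.normal(-0.8, 0.1, 2000),
             "gc_total": 10 ** rng.normal(-0.55, 0.05, 2000)}
        )
        res = gbgc.intron_exon_gc_regression(df)
        assert res["gc3"].r_squared < 0.01

    def test_no_introns_errors(self):
        df = pd.DataFrame({"gc_intron": [np.nan], "gc3": [0.1], "gc_total": [0.2]})
        with pytest.raises(ValueError):
            gbgc.intron_exon_gc_regression(df)


class TestStabilityRegression:
    def test_stability_tracking_one_predictor(self):
        # tiny noise keeps the residual sums well-conditioned
        rng = np.random.default_rng(9)
        dep = rng.normal(0, 1, 500)
        indep = rng.normal(0, 1, 500)
        y = indep + rng.normal(0, 1e-3, 500)
        df = pd.DataFrame(
            {"stability_per_site": y, "pref_trna_dep": dep,
             "pref_trna_indep": indep}
        )
        fit = gbgc.stability_regression(df)
        assert fit.partial_r2_indep == pytest.approx(1.0, abs=1e-4)
        assert fit.partial_r2_dep == pytest.approx(0.0, abs=0.02)

    def test_zero_noise_two_predictor_coefficients_exact(self):
        rng = np.random.default_rng(10)
        dep = rng.normal(0, 1, 300)
        indep = rng.normal(0, 1, 300)
        y = 1.5 * dep - 2.0 * indep + 0.7
        df = pd.DataFrame(
            {"stability_per_site": y, "pref_trna_dep": dep, "pref_trna_indep": indep}
        )
        fit = gbgc.stability_regression(df)
        assert fit.coef_dep == pytest.approx(1.5)
        assert fit.coef_indep == pytest.approx(-2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_collinear_predictors_rejected(self):
        x = np.linspace(0, 1, 50)
        df = pd.DataFrame(
            {"stability_per_site": x, "pref_trna_dep": x, "pref_trna_indep": 2 * x}
        )
        with pytest.raises(ValueError):
            gbgc.stability_regression(df)


def test_gc_peak_mask_flags_tails():
    rng = np.random.default_rng(11)
    gc = rng.uniform(0.1, 0.2, 100)
    gc[:3] = 0.9
    track = pd.DataFrame(
        {"chrom": "c1", "start": np.arange(100) * 1000,
         "end": np.arange(100) * 1000 + 1000, "gc_noncoding": gc}
    )
    mask = gbgc.gc_peak_mask(track)
    assert {0, 1000, 2000} <= set(mask["start"])
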