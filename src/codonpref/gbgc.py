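"""Diagnostics for GC-biased gene conversion (gBGC) and transcript
stability.

gBGC would couple local GC content to recombination and make coding and
surrounding noncoding composition covary. The screen here: sliding-window
GC (overall / coding / noncoding), regression of coding on noncoding GC
across windows, correlation of log recombination rate with window GC,
proximal-vs-distal chromosome-half comparisons of gene GC, and regression
of exonic GC measures on intronic GC. A separate regression relates
per-site transcript folding stability to the tRNA-dependent and
-independent components of gene-level codon preference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genetic_code import gc_by_position
from .io import CDS, INTERGENIC, INTRON, RegionIndex


def _cum_gc_masks(seq: str, labels: np.ndarray):
    arr = np.frombuffer(seq.encode(), dtype="S1")
    is_gc = np.isin(arr, [b"G", b"C"]).astype(np.int64)
    is_acgt = np.isin(arr, [b"A", b"C", b"G", b"T"]).astype(np.int64)
    coding = labels == CDS
    noncoding = (labels == INTRON) | (labels == INTERGENIC)
    return is_gc, is_acgt, coding, noncoding


def sliding_window_gc(
    genome: dict[str, str],
    index: RegionIndex,
    window: int = 50_000,
    step: int | None = None,
    min_informative: float = 0.1,
) -> pd.DataFrame:
    """Overall, coding and noncoding GC in sliding windows.

    ``step`` defaults to ``window`` (nonoverlapping tiling). A label GC is
    nan (flagged) when fewer than ``min_informative`` of the window's
    bases carry that label.
    """
    step = window if step is None else step
    rows = []
    for chrom, seq in genome.items():
        labels = index.labels[chrom]
        is_gc, is_acgt, coding, noncoding = _cum_gc_masks(seq, labels)
        L = len(seq)
        starts = list(range(0, max(L - window, 0) + 1, step)) or [0]
        cg = np.concatenate([[0], np.cumsum(is_gc)])
        cn = np.concatenate([[0], np.cumsum(is_acgt)])
        cg_cod = np.concatenate([[0], np.cumsum(is_gc * coding)])
        cn_cod = np.concatenate([[0], np.cumsum(is_acgt * coding)])
        cg_non = np.concatenate([[0], np.cumsum(is_gc * noncoding)])
        cn_non = np.concatenate([[0], np.cumsum(is_acgt * noncoding)])
        for s in starts:
            e = min(s + window, L)
            span = e - s

            def frac(cgc, cnt):
                n = cnt[e] - cnt[s]
                if n == 0 or n < min_informative * span:
                    return math.nan
                return (cgc[e] - cgc[s]) / n

            rows.append(
                {
                    "chrom": chrom,
                    "start": s,
                    "end": e,
                    "gc": frac(cg, cn),
                    "gc_coding": frac(cg_cod, cn_cod),
                    "gc_noncoding": frac(cg_non, cn_non),
                }
            )
    return pd.DataFrame(rows)


def gc_peak_mask(
    track: pd.DataFrame, lo_pct: float = 5.0, hi_pct: float = 95.0
) -> pd.DataFrame:
    """BED-like frame of windows whose noncoding GC is in the extreme tails.

    Emulates percentile-based masking of GC peaks (e.g. TE-rich regions)
    from the noncoding GC distribution.
    """
    vals = track["gc_noncoding"].dropna()
    lo, hi = np.percentile(vals, [lo_pct, hi_pct])
    mask = track[(track["gc_noncoding"] < lo) | (track["gc_noncoding"] > hi)]
    return mask[["chrom", "start", "end"]].reset_index(drop=True)


def _apply_mask(track: pd.DataFrame, mask: pd.DataFrame | None) -> pd.DataFrame:
    if mask is None or mask.empty:
        return track
    drop = np.zeros(len(track), bool)
    for _, m in mask.iterrows():
        drop |= (
            (track["chrom"] == m["chrom"])
            & (track["start"] < m["end"])
            & (track["end"] > m["start"])
        ).to_numpy()
    return track[~drop]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n=len(x),
    )


def window_gc_regression(
    track: pd.DataFrame, mask: pd.DataFrame | None = None
) -> RegressionResult:
    """OLS of coding GC on noncoding GC across (nonoverlapping) windows."""
    t = _apply_mask(track, mask).dropna(subset=["gc_coding", "gc_noncoding"])
    if len(t) < 3:
        raise ValueError("fewer than 3 informative windows")
    return _ols(t["gc_noncoding"].to_numpy(), t["gc_coding"].to_numpy())


def recombination_gc_correlation(
    rho_track: pd.DataFrame,
    gc_track: pd.DataFrame,
    offset: float = 1e-6,
) -> dict[str, RegressionResult | None]:
    """Correlation of log(rho + offset) with window GC.

    The small offset admits windows with an estimated recombination rate
    of exactly zero. Returns one result per chromosome plus
    ``"genome"``; a chromosome with constant rho or GC yields None
    (correlation undefined, flagged rather than guessed).
    """
    merged = rho_track.merge(gc_track, on=["chrom", "start", "end"], how="inner")
    if merged.empty:
        raise ValueError("rho and GC tracks share no windows")
    merged = merged.dropna(subset=["rho", "gc"])
    merged["log_rho"] = np.log(merged["rho"] + offset)
    out: dict[str, RegressionResult | None] = {}

    def fit(df):
        x = df["log_rho"].to_numpy()
        y = df["gc"].to_numpy()
        if len(x) < 3 or np.ptp(x) < 1e-12 or np.ptp(y) < 1e-12:
            return None
        return _ols(x, y)

    out["genome"] = fit(merged)
    for chrom, grp in merged.groupby("chrom"):
        out[str(chrom)] = fit(grp)
    return out


def gene_gc_measures(cds_seq: str, intron_seq: str = "") -> dict[str, float]:
    """Per-gene total GC, GC3 and intronic GC (fractions, not yet logged)."""
    gc_total = sum(1 for b in cds_seq if b in "GC") / len(cds_seq)
    _, _, gc3 = gc_by_position(cds_seq)
    if intron_seq:
        gci = sum(1 for b in intron_seq if b in "GC") / len(intron_seq)
    else:
        gci = math.nan
    return {"gc_total": gc_total, "gc3": gc3, "gc_intron": gci}


def _log10_positive(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, float)
    out = np.full_like(v, np.nan)
    ok = v > 0
    out[ok] = np.log10(v[ok])
    return out


def proximal_distal_test(genes: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Two-sample t-tests of log10 gene GC measures, proximal vs distal.

    ``genes`` needs ``chrom_half`` in {proximal, distal} plus ``gc_total``
    and ``gc3``; TE-labelled genes should be excluded by the caller.
    Returns ``{"gc_total": (t, p), "gc3": (t, p)}``.
    """
    out = {}
    for col in ("gc_total", "gc3"):
        vals = _log10_positive(genes[col].to_numpy())
        half = genes["chrom_half"].to_numpy()
        a = vals[(half == "proximal") & ~np.isnan(vals)]
        b = vals[(half == "distal") & ~np.isnan(vals)]
        if len(a) < 2 or len(b) < 2:
            raise ValueError("a chromosome-half group is empty")
        t, p = stats.ttest_ind(a, b, equal_var=True)
        out[col] = (float(t), float(p))
    return out


def intron_exon_gc_regression(genes: pd.DataFrame) -> dict[str, RegressionResult]:
    """Variance in exonic GC measures explained by intronic GC.

    OLS of log10 GC3 and log10 total GC on log10 intronic GC across
    intron-bearing genes. Under gBGC the shared local conversion
    environment would couple them; independence leaves R^2 near zero.
    """
    df = genes.dropna(subset=["gc_intron"])
    df = df[df["gc_intron"] > 0]
    if df.empty:
        raise ValueError("no intron-bearing genes")
    x = _log10_positive(df["gc_intron"].to_numpy())
    out = {}
    for col in ("gc3", "gc_total"):
        y = _log10_positive(df[col].to_numpy())
        ok = ~np.isnan(x) & ~np.isnan(y)
        if ok.sum() < 3:
            raise ValueError("fewer than 3 usable genes")
        out[col] = _ols(x[ok], y[ok])
    return out


@dataclass
class StabilityFit:
    coef_dep: float
    coef_indep: float
    partial_r2_dep: float
    partial_r2_indep: float
    r_squared: float
    n: int


def stability_regression(genes: pd.DataFrame) -> StabilityFit:
    """Regress per-site transcript stability on the preference components.

    ``genes`` needs ``stability_per_site`` (delta G0 / CDS length,
    kcal/mol per base) and gene-level ``pref_trna_dep`` and
    ``pref_trna_indep``. Partial R^2 of each predictor is the fraction of
    the other-predictor-residual variance it explains:
    (SSE_reduced - SSE_full) / SSE_reduced.
    """
    df = genes.dropna(
        subset=["stability_per_site", "pref_trna_dep", "pref_trna_indep"]
    )
    y = df["stability_per_site"].to_numpy(float)
    x1 = df["pref_trna_dep"].to_numpy(float)
    x2 = df["pref_trna_indep"].to_numpy(float)
    if len(y) < 4:
        raise ValueError("too few genes")
    if abs(np.corrcoef(x1, x2)[0, 1]) > 0.999:
        raise ValueError("preference components are collinear")
    X = sm.add_constant(np.column_stack([x1, x2]))
    full = sm.OLS(y, X).fit()
    sse_full = float(full.ssr)

    def partial(drop_col):
        Xr = sm.add_constant(X[:, [c for c in (1, 2) if c != drop_col]])
        red = sm.OLS(y, Xr).fit()
        return (red.ssr - sse_full) / red.ssr

    return StabilityFit(
        coef_dep=float(full.params[1]),
        coef_indep=float(full.params[2]),
        partial_r2_dep=float(partial(1)),
        partial_r2_indep=float(partial(2)),
        r_squared=float(full.rsquared),
        n=len(y),
    )
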