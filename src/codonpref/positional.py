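"""Codon-frequency, preference and SNP-density profiles along genes.

Genes are aligned either at the start codon (positions 1, 2, ... counting
from the codon after the initial Met) or at the stop codon (positions -1,
-2, ... counting backward from the codon before the stop). Profiles are
restricted to the first/last 250 codon positions; to keep the two windows
disjoint, a gene's codons are never counted in the from-stop profile when
they also lie inside its first 250 codons.

Per-position codon frequencies are codon-occurrence weighted (every codon
at that position across the gene set counts once) and defined over the 59
analyzed codons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetic_code import ANALYZED_CODONS, STOP_CODONS
from .preference import PreferenceVector
from .spectrum import MutationSpectrum

MAX_POSITIONS = 250

_CODON_IDX = {c: i for i, c in enumerate(ANALYZED_CODONS)}


@dataclass
class PositionalProfile:
    """Codon counts by position from the start (or back from the stop)."""

    direction: str  # "from_start" | "from_stop"
    counts: np.ndarray  # (MAX_POSITIONS, 59)
    n_excluded_overlap: int = 0  # from_stop codons suppressed by the 5' window

    @property
    def n_codons(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def frequencies(self) -> np.ndarray:
        """Per-position frequency vectors over the 59 analyzed codons."""
        tot = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.counts / tot, np.nan)

    def positions(self) -> np.ndarray:
        if self.direction == "from_start":
            return np.arange(1, MAX_POSITIONS + 1)
        return -np.arange(1, MAX_POSITIONS + 1)


def _analyzed_codon_indices(cds: str) -> list[int]:
    """Indices into ANALYZED_CODONS of a CDS's codons, skipping the initial
    Met, the terminal stop, and non-analyzed codons (marked -1)."""
    codons = [cds[i : i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]
    if codons and codons[0] == "ATG":
        codons = codons[1:]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    return [_CODON_IDX.get(c, -1) for c in codons]


def positional_frequencies(cds_seqs, direction: str) -> PositionalProfile:
    """Per-position codon counts over a gene set.

    ``direction`` is ``from_start`` (position 1 = first codon after the
    initial Met) or ``from_stop`` (position -1 = last codon before the
    stop, counted backward).
    """
    if direction not in ("from_start", "from_stop"):
        raise ValueError(f"unknown direction {direction!r}")
    counts = np.zeros((MAX_POSITIONS, len(ANALYZED_CODONS)), dtype=np.int64)
    n_genes = 0
    n_excluded = 0
    for cds in cds_seqs:
        idx = _analyzed_codon_indices(cds)
        L = len(idx)
        if L == 0:
            continue
        n_genes += 1
        if direction == "from_start":
            for p in range(min(L, MAX_POSITIONS)):
                if idx[p] >= 0:
                    counts[p, idx[p]] += 1
        else:
            for k in range(min(L, MAX_POSITIONS)):
                body_pos = L - 1 - k  # 0-based position from the start
                if body_pos < MAX_POSITIONS:
                    # would also sit in the 5' window; keep windows disjoint
                    n_excluded += 1
                    continue
                if idx[body_pos] >= 0:
                    counts[k, idx[body_pos]] += 1
    if n_genes == 0:
        raise ValueError("empty gene set")
    return PositionalProfile(
        direction=direction, counts=counts, n_excluded_overlap=n_excluded
    )


def _component_values(pref: PreferenceVector, component: str) -> np.ndarray:
    if component == "total":
        src = pref.pref
    elif component == "trna_dep":
        src = pref.trna_dep
    elif component == "trna_indep":
        src = pref.trna_indep
    else:
        raise ValueError(f"unknown component {component!r}")
    return np.array([src.get(c, np.nan) for c in ANALYZED_CODONS], float)


def positional_mean_preference(
    profile: PositionalProfile,
    pref: PreferenceVector,
    genome_codon_counts: dict[str, int],
    component: str = "total",
) -> np.ndarray:
    """Mean codon preference at each position, as deviation from the
    genome-wide mean.

    Positions are frequency-weighted over the 59 codons; codons with
    undefined preference are dropped with renormalization at each
    position (and in the genome-wide mean).
    """
    vals = _component_values(pref, component)
    ok = ~np.isnan(vals)
    counts = profile.counts[:, ok].astype(float)
    v = vals[ok]
    tot = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pos_mean = (counts @ v) / tot
    gcounts = np.array(
        [genome_codon_counts.get(c, 0) for c in ANALYZED_CODONS], float
    )[ok]
    genome_mean = float((gcounts @ v) / gcounts.sum())
    return pos_mean - genome_mean


def zero_crossing(profile_values: np.ndarray) -> float:
    """First position (1-based) where a rising profile crosses zero,
    linearly interpolated; nan if it never crosses."""
    v = np.asarray(profile_values, float)
    for i in range(1, len(v)):
        if np.isnan(v[i - 1]) or np.isnan(v[i]):
            continue
        if v[i - 1] < 0 <= v[i]:
            frac = -v[i - 1] / (v[i] - v[i - 1])
            return float(i + frac)  # between positions i and i+1 (1-based)
    return float("nan")


def ramp_zero_crossing(profile_values: np.ndarray) -> float:
    """Zero crossing of a noisy monotone (5' ramp) profile.

    The per-position deviations of a rising ramp approach zero tangentially,
    so the raw first crossing is dominated by sampling noise. Since the
    underlying curve is nondecreasing, an isotonic fit is the natural
    noise-robust estimate; the crossing is read off the fitted curve.
    """
    from sklearn.isotonic import IsotonicRegression

    v = np.asarray(profile_values, float)
    pos = np.arange(1, len(v) + 1, dtype=float)
    ok = ~np.isnan(v)
    fit = IsotonicRegression(increasing=True).fit(pos[ok], v[ok])
    smooth = np.full_like(v, np.nan)
    smooth[ok] = fit.predict(pos[ok])
    return zero_crossing(smooth)


def positional_snp_density(
    snp_codon_positions,
    profile: PositionalProfile,
    spectrum: MutationSpectrum,
) -> pd.DataFrame:
    """Observed vs expected share of synonymous SNPs by codon position.

    ``snp_codon_positions`` are 1-based codon positions (in the profile's
    direction) of synonymous SNPs. The expected share of position p is
    proportional to the number of codons surveyed there times the average
    mutation rate out of its base composition, so positions with more
    mutable composition expect more SNPs. Deviations (observed share -
    expected share) sum to zero by construction.
    """
    freqs = profile.frequencies()
    n = profile.n_codons.astype(float)
    # per-position base composition over the three codon positions
    rate_out = {b: spectrum.total_rate_from(b) for b in "ACGT"}
    codon_rate = np.array(
        [sum(rate_out[b] for b in c) for c in ANALYZED_CODONS], float
    )
    with np.errstate(invalid="ignore"):
        mean_rate = np.nansum(freqs * codon_rate, axis=1)
    weight = n * mean_rate
    tot_w = weight.sum()
    if tot_w <= 0:
        raise ValueError("no surveyed codons; expected shares undefined")
    expected = weight / tot_w
    obs_counts = np.zeros(MAX_POSITIONS)
    for p in snp_codon_positions:
        p = abs(int(p))
        if 1 <= p <= MAX_POSITIONS:
            obs_counts[p - 1] += 1
    if obs_counts.sum() == 0:
        raise ValueError("no SNPs within the positional window")
    observed = obs_counts / obs_counts.sum()
    return pd.DataFrame(
        {
            "position": profile.positions(),
            "n_codons": profile.n_codons,
            "snp_obs": observed,
            "snp_exp": expected,
            "snp_dev": observed - expected,
        }
    )
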