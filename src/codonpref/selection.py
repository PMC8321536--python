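"""Tests of purifying selection on segregating synonymous polymorphism.

The neutral expectation for the share of synonymous SNPs of a given
directed codon change i->j is the genome frequency of the source codon
times the relative mutation rate of the required nucleotide change,
normalized over the mutation set (p_hat_ij = f_i * m_j / sum f_i * m_j).
Comparing, within each source codon, the observed proportions of the
alternative synonymous changes to the expected ones (as log10 obs/exp
deviations) and correlating these with the relative preference of the
destination codons asks whether mutations toward preferred codons
segregate more freely than mutations toward avoided codons — the
signature of purifying selection on codon choice.

Also here: the two-sample Kolmogorov–Smirnov comparison of derived-allele
frequency spectra of AT->GC vs GC->AT noncoding SNPs, the standard screen
for GC-biased gene conversion (which would push AT->GC alleles upward).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import (
    SynMutation,
    enumerate_synonymous_mutations,
    multi_option_mutations,
)
from .preference import PreferenceVector
from .spectrum import MutationSpectrum


def mutation_set(restrict_multi_option: bool = True) -> list[SynMutation]:
    """The synonymous mutation set for the polymorphism analysis.

    The full directed set has 134 members; restricting to source codons
    with at least two synonymous options (the default, needed for the
    within-codon proportion test) leaves 114.
    """
    muts = enumerate_synonymous_mutations()
    return multi_option_mutations(muts) if restrict_multi_option else muts


def expected_snp_proportions(
    codon_freqs: dict[str, float],
    spectrum: MutationSpectrum,
    mutations: list[SynMutation] | None = None,
) -> pd.DataFrame:
    """Genome-wide expected proportions of synonymous SNP classes.

    ``codon_freqs`` are absolute codon frequencies f_i over the coding
    genome (fractions of all codons). The raw weight of mutation i->j is
    p_ij = f_i * m_j; normalizing over the set gives p_hat summing to 1.
    """
    muts = mutations if mutations is not None else mutation_set()
    if not muts:
        raise ValueError("empty mutation set")
    rows = []
    for m in muts:
        f_i = codon_freqs.get(m.source, 0.0)
        m_j = spectrum.rates[m.nt_change]
        rows.append(
            {
                "source": m.source,
                "target": m.target,
                "codon_position": m.codon_position,
                "nt_change": f"{m.nt_change[0]}>{m.nt_change[1]}",
                "f_i": f_i,
                "m_j": m_j,
                "p_raw": f_i * m_j,
            }
        )
    df = pd.DataFrame(rows)
    tot = df["p_raw"].sum()
    if tot <= 0:
        raise ValueError("all raw proportions are zero")
    df["p_hat"] = df["p_raw"] / tot
    return df


def within_codon_expected(
    source: str, spectrum: MutationSpectrum, targets: list[str] | None = None
) -> dict[str, float]:
    """Expected proportions of the synonymous changes available to a codon.

    The relative mutation rates of the required nucleotide changes,
    normalized to sum to 1 within the source codon.
    """
    if targets is None:
        targets = [m.target for m in mutation_set(False) if m.source == source]
    if len(targets) < 2:
        raise ValueError(f"{source} has fewer than two synonymous options")
    rates = {}
    for t in targets:
        pos = next(i for i in range(3) if source[i] != t[i])
        rates[t] = spectrum.rates[(source[pos], t[pos])]
    tot = sum(rates.values())
    if tot <= 0:
        raise ValueError(f"all mutation rates out of {source} are zero")
    return {t: r / tot for t, r in rates.items()}


def log10_deviation(observed_prop: float, expected_prop: float) -> float:
    """log10 of observed over expected within-codon proportion."""
    if expected_prop <= 0:
        raise ValueError("expected proportion must be positive")
    if observed_prop <= 0:
        raise ValueError("observed proportion must be positive (apply the "
                         "zero-replacement rule first)")
    return math.log10(observed_prop / expected_prop)


def relative_preference_within_codon(
    source: str, pref: PreferenceVector, targets: list[str] | None = None
) -> dict[str, float]:
    """Preference of each destination codon as deviation from the mean.

    Centering within the source codon puts codons with different numbers
    of options on a common scale; the values sum to 0 by construction.
    Raises if any target's preference is undefined.
    """
    if targets is None:
        targets = [m.target for m in mutation_set(False) if m.source == source]
    vals = {t: pref.pref[t] for t in targets}
    if any(math.isnan(v) for v in vals.values()):
        raise ValueError(f"undefined preference among targets of {source}")
    mu = sum(vals.values()) / len(vals)
    return {t: v - mu for t, v in vals.items()}


def zero_replacement(counts: dict, flag_value: int = 1) -> tuple[dict, list]:
    """Replace zero observed SNP counts by one so log deviations exist.

    Returns the adjusted counts and the list of keys that were replaced.
    """
    replaced = [k for k, v in counts.items() if v == 0]
    return ({k: (flag_value if v == 0 else v) for k, v in counts.items()},
            replaced)


def build_syn_snp_table(
    codon_freqs: dict[str, float],
    spectrum: MutationSpectrum,
    observed_counts: dict[tuple[str, str], int],
    pref: PreferenceVector,
    replace_zeros: bool = True,
) -> pd.DataFrame:
    """Assemble the per-mutation table for the polymorphism–preference test.

    One row per multi-option synonymous mutation, with the genome-wide
    expected share (p_hat), within-codon expected and observed
    proportions, the log10 deviation, and the relative preference of the
    destination codon. Mutations from source codons with any
    undefined-preference target are dropped (logged in the ``excluded``
    attribute of the frame).
    """
    df = expected_snp_proportions(codon_freqs, spectrum)
    counts = {(m.source, m.target): 0 for m in mutation_set()}
    for k, v in observed_counts.items():
        if k in counts:
            counts[k] += int(v)
    zero_keys: list = []
    if replace_zeros:
        counts, zero_keys = zero_replacement(counts)
    df["obs_count"] = [
        counts[(s, t)] for s, t in zip(df["source"], df["target"])
    ]
    # within-codon proportions
    exp_within: dict[tuple[str, str], float] = {}
    rel_pref: dict[tuple[str, str], float] = {}
    excluded: list[str] = []
    for source, grp in df.groupby("source"):
        targets = grp["target"].tolist()
        ew = within_codon_expected(source, spectrum, targets)
        try:
            rp = relative_preference_within_codon(source, pref, targets)
        except ValueError:
            excluded.append(source)
            continue
        for t in targets:
            exp_within[(source, t)] = ew[t]
            rel_pref[(source, t)] = rp[t]
    df = df[~df["source"].isin(excluded)].copy()
    key = list(zip(df["source"], df["target"]))
    df["exp_within"] = [exp_within[k] for k in key]
    df["rel_pref"] = [rel_pref[k] for k in key]
    obs_tot = df.groupby("source")["obs_count"].transform("sum")
    df["obs_within"] = df["obs_count"] / obs_tot
    df["log10_dev"] = [
        log10_deviation(o, e) for o, e in zip(df["obs_within"], df["exp_within"])
    ]
    df.attrs["zero_replaced"] = zero_keys
    df.attrs["excluded_sources"] = excluded
    return df


@dataclass
class CorrelationResult:
    r: float
    p: float
    rma_slope: float
    rma_intercept: float
    n: int


def rma_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Reduced major axis line: slope sign(r) * sd_y/sd_x through the means."""
    r = np.corrcoef(x, y)[0, 1]
    slope = float(np.sign(r) * np.std(y, ddof=1) / np.std(x, ddof=1))
    intercept = float(np.mean(y) - slope * np.mean(x))
    return slope, intercept


def polymorphism_preference_correlation(
    table: pd.DataFrame, method: str = "pearson"
) -> CorrelationResult:
    """Correlate within-codon SNP deviation with relative codon preference.

    A positive correlation means mutations toward relatively preferred
    codons are over-represented among segregating SNPs compared with the
    mutational expectation. The best-fit line is reduced major axis (for
    plotting; inference rests on the correlation).
    """
    x = table["rel_pref"].to_numpy(float)
    y = table["log10_dev"].to_numpy(float)
    if len(x) < 3:
        raise ValueError("need at least 3 mutation classes")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    slope, intercept = rma_line(x, y)
    return CorrelationResult(
        r=float(r), p=float(p), rma_slope=slope, rma_intercept=intercept,
        n=len(x),
    )


def allele_spectrum_ks(
    at_to_gc_freqs, gc_to_at_freqs
) -> tuple[float, float]:
    """KS comparison of derived-allele frequencies, AT->GC vs GC->AT SNPs.

    GC-biased gene conversion would shift AT->GC derived alleles to higher
    frequencies than GC->AT ones; under its absence the two spectra are
    exchangeable. Returns ``(D, p)``.
    """
    a = np.asarray(at_to_gc_freqs, float)
    b = np.asarray(gc_to_at_freqs, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty SNP class")
    d, p = stats.ks_2samp(a, b)
    return float(d), float(p)


def partition_interclass_freqs(
    polarized_with_freq: list[tuple[str, str, float]]
) -> tuple[np.ndarray, np.ndarray]:
    """Split (ancestral, derived, derived_freq) records into the two
    interclass sets: derived AT->GC vs derived GC->AT."""
    at_gc, gc_at = [], []
    for anc, der, f in polarized_with_freq:
        if anc in "AT" and der in "GC":
            at_gc.append(f)
        elif anc in "GC" and der in "AT":
            gc_at.append(f)
    return np.asarray(at_gc), np.asarray(gc_at)
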