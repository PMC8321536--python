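"""Expected codon frequencies at mutational equilibrium.

Under mutation–drift balance with independent sites, the expected absolute
frequency of a codon is the product of its three nucleotide equilibrium
frequencies; within-amino-acid relative frequencies follow by rescaling to
the amino-acid total. The default ("symmetric") mode parameterizes the
equilibrium by a single GC content with f(G)=f(C) and f(A)=f(T); a
"stationary" mode solves the full 4-state rate matrix for asymmetric
spectra.

A translation-free null for the same quantity is obtained from noncoding
sequence: triplets counted over all three reading frames ("pseudocodons")
and normalized within the amino acid they would encode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genetic_code import (
    AA_TO_CODONS,
    ANALYZED_CODONS,
    BASES,
    CODON_TO_AA,
    SINGLE_CODON_AA,
    CodonUsage,
)
from .spectrum import MutationSpectrum


@dataclass
class NeutralExpectation:
    """Neutral codon-frequency expectations at a given base composition."""

    gc: float
    nt_freq: dict[str, float]
    abs_codon_freq: dict[str, float]  # all 64 codons, sums to 1
    rel_codon_freq: dict[str, float]  # 59 analyzed codons, sums to 1 per aa


def _codon_expectation(nt_freq: dict[str, float], gc: float) -> NeutralExpectation:
    abs_freq = {
        c: nt_freq[c[0]] * nt_freq[c[1]] * nt_freq[c[2]] for c in CODON_TO_AA
    }
    rel: dict[str, float] = {}
    for aa, codons in AA_TO_CODONS.items():
        if aa in SINGLE_CODON_AA:
            continue
        tot = sum(abs_freq[c] for c in codons)
        for c in codons:
            rel[c] = abs_freq[c] / tot
    return NeutralExpectation(
        gc=gc, nt_freq=dict(nt_freq), abs_codon_freq=abs_freq, rel_codon_freq=rel
    )


def expected_frequencies(
    gc_eq: float | None = None,
    spectrum: MutationSpectrum | None = None,
    mode: str = "symmetric",
) -> NeutralExpectation:
    """Neutral expected codon frequencies.

    ``symmetric`` mode (default) takes a scalar equilibrium GC content and
    assumes strand symmetry: f(G)=f(C)=gc/2, f(A)=f(T)=(1-gc)/2.
    ``stationary`` mode takes a full :class:`MutationSpectrum` and uses the
    stationary distribution of its rate matrix, which need not be
    strand-symmetric.
    """
    if mode == "symmetric":
        if gc_eq is None:
            raise ValueError("symmetric mode requires gc_eq")
        if not 0.0 < gc_eq < 1.0:
            raise ValueError("gc_eq must be strictly between 0 and 1")
        nt = {
            "A": (1 - gc_eq) / 2,
            "T": (1 - gc_eq) / 2,
            "G": gc_eq / 2,
            "C": gc_eq / 2,
        }
        return _codon_expectation(nt, gc_eq)
    if mode == "stationary":
        if spectrum is None:
            raise ValueError("stationary mode requires a spectrum")
        pi = stationary_distribution(spectrum)
        return _codon_expectation(pi, pi["G"] + pi["C"])
    raise ValueError(f"unknown mode {mode!r}")


def stationary_distribution(spectrum: MutationSpectrum) -> dict[str, float]:
    """Stationary base composition of the 4-state mutation rate matrix.

    Solves pi Q = 0 with the off-diagonal generator entries taken from the
    per-site relative rates. For a strand-symmetric matrix the G+C mass of
    the solution coincides with Sueoka's scalar GC_eq.
    """
    q = np.zeros((4, 4))
    for i, x in enumerate(BASES):
        for j, y in enumerate(BASES):
            if x != y:
                q[i, j] = spectrum.rates[(x, y)]
        q[i, i] = -q[i].sum()
    # left null vector of Q
    vals, vecs = np.linalg.eig(q.T)
    k = int(np.argmin(np.abs(vals)))
    if abs(vals[k]) > 1e-8:
        raise ValueError("rate matrix has no stationary distribution")
    pi = np.real(vecs[:, k])
    if np.allclose(pi, 0):
        raise ValueError("degenerate stationary solution")
    pi = pi / pi.sum()
    if np.any(pi < -1e-10):
        raise ValueError("rate matrix appears reducible")
    pi = np.clip(pi, 0, None)
    pi = pi / pi.sum()
    return {b: float(p) for b, p in zip(BASES, pi)}


def pseudocodon_frequencies(
    noncoding_seqs, gene_set_label: str = "pseudocodons"
) -> CodonUsage:
    """Triplet ("pseudocodon") usage of noncoding sequence, all three frames.

    Each sequence (one per chromosome/contig) is scanned in its own three
    frames — frames never span concatenation junctions. Triplets containing
    ambiguity codes are skipped. Counts are converted to within-amino-acid
    relative frequencies by translating the triplets as if they were
    codons, giving a translation-free null for relative synonymous
    frequencies.
    """
    if isinstance(noncoding_seqs, str):
        noncoding_seqs = [noncoding_seqs]
    counts: dict[str, int] = {}
    n_skipped = 0
    n_total = 0
    for seq in noncoding_seqs:
        s = seq.upper()
        for frame in range(3):
            for i in range(frame, len(s) - 2, 3):
                tri = s[i : i + 3]
                n_total += 1
                if tri in CODON_TO_AA:
                    counts[tri] = counts.get(tri, 0) + 1
                else:
                    n_skipped += 1
    if n_total == 0:
        raise ValueError("no triplets in input sequence")
    rel: dict[str, float] = {}
    for aa, codons in AA_TO_CODONS.items():
        if aa in SINGLE_CODON_AA:
            continue
        tot = sum(counts.get(c, 0) for c in codons)
        for c in codons:
            rel[c] = counts.get(c, 0) / tot if tot > 0 else math.nan
    kept = {c: counts.get(c, 0) for c in ANALYZED_CODONS}
    return CodonUsage(counts=kept, rel_freq=rel, gene_set_label=gene_set_label)
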