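"""SNP polarization and the per-site relative mutation-rate matrix.

The mutation spectrum is estimated from biallelic SNPs in putatively
neutral (intronic + intergenic) sequence. Each SNP is polarized by allele
frequency: the major allele is taken as ancestral and the minor as derived,
ties excluded. Counts of each of the 12 directed changes x->y are scaled to
the number of x sites surveyed and renormalized to sum to 1, giving
relative per-site rates m[x->y]. The equilibrium GC content implied by such
a matrix is Sueoka's ratio of AT->GC to total interclass flux.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

BASES = ("A", "C", "G", "T")
MUT_CLASSES: tuple[tuple[str, str], ...] = tuple(
    (x, y) for x in BASES for y in BASES if x != y
)

#: strand-equivalent pairing used when SNPs cannot be assigned to strands
SIX_CLASSES: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {
    "A>C/T>G": (("A", "C"), ("T", "G")),
    "A>G/T>C": (("A", "G"), ("T", "C")),
    "A>T/T>A": (("A", "T"), ("T", "A")),
    "C>G/G>C": (("C", "G"), ("G", "C")),
    "C>A/G>T": (("C", "A"), ("G", "T")),
    "C>T/G>A": (("C", "T"), ("G", "A")),
}


class PolarizationTie(Exception):
    """Raised when both alleles segregate at exactly the same count."""


def polarize(allele_counts: dict[str, int]) -> tuple[str, str]:
    """Infer (ancestral, derived) alleles of a biallelic SNP by frequency.

    The allele at higher count is called ancestral. Equal counts are a
    :class:`PolarizationTie` — direction is unknowable and guessing would
    bias the spectrum.
    """
    if len(allele_counts) != 2:
        raise ValueError("polarize expects a biallelic site")
    (a1, n1), (a2, n2) = allele_counts.items()
    if n1 == n2:
        raise PolarizationTie(f"{a1}={n1} vs {a2}={n2}")
    return (a1, a2) if n1 > n2 else (a2, a1)


@dataclass
class MutationSpectrum:
    """Relative per-site mutation rates over the 12 directed classes.

    ``rates[(x, y)]`` is the rate of x->y mutations per x site, rescaled so
    the 12 rates sum to 1.
    """

    rates: dict[tuple[str, str], float]
    site_counts: dict[str, int] = field(default_factory=dict)
    n_snps: int = 0

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.rates.values()):
            raise ValueError("negative rate")
        s = sum(self.rates.values())
        if not np.isclose(s, 1.0, atol=1e-9):
            raise ValueError(f"rates sum to {s}, expected 1")

    def rate(self, x: str, y: str) -> float:
        return self.rates[(x, y)]

    def total_rate_from(self, base: str) -> float:
        """Total relative mutation rate out of a base."""
        return sum(self.rates[(base, y)] for y in BASES if y != base)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"from": x, "to": y, "rate": self.rates[(x, y)],
             "sites": self.site_counts.get(x, 0)}
            for x, y in MUT_CLASSES
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_rates(cls, rates: dict[tuple[str, str], float]) -> "MutationSpectrum":
        """Build from arbitrary non-negative rates, renormalizing to sum 1."""
        tot = sum(rates.values())
        if tot <= 0:
            raise ValueError("rates must have positive sum")
        return cls(rates={k: v / tot for k, v in rates.items()})

    @classmethod
    def from_tsv(cls, path) -> "MutationSpectrum":
        df = pd.read_csv(path, sep="\t")
        rates = {(r["from"], r["to"]): float(r["rate"]) for _, r in df.iterrows()}
        sites = {r["from"]: int(r["sites"]) for _, r in df.iterrows()}
        return cls(rates=rates, site_counts=sites)


def count_mutation_classes(polarized: list[tuple[str, str]]) -> dict[tuple[str, str], int]:
    counts = {cls: 0 for cls in MUT_CLASSES}
    for anc, der in polarized:
        counts[(anc, der)] += 1
    return counts


def build_spectrum(
    polarized: list[tuple[str, str]],
    site_counts: dict[str, int],
    min_snps: int = 1000,
) -> MutationSpectrum:
    """Estimate the relative per-site mutation-rate matrix.

    Parameters
    ----------
    polarized
        (ancestral, derived) pairs from noncoding SNPs.
    site_counts
        Number of surveyed sites of each base over the same noncoding mask
        used to select the SNPs; ambiguity codes must already be excluded.
    min_snps
        Below this a warning is emitted: a 12-class spectrum from very few
        SNPs is noisy.
    """
    for b in BASES:
        if site_counts.get(b, 0) <= 0:
            raise ValueError(f"zero surveyed sites for base {b}")
    if len(polarized) < min_snps:
        warnings.warn(
            f"spectrum built from only {len(polarized)} SNPs; "
            "per-class rate estimates may be unstable",
            stacklevel=2,
        )
    counts = count_mutation_classes(polarized)
    per_site = {cls: counts[cls] / site_counts[cls[0]] for cls in MUT_CLASSES}
    tot = sum(per_site.values())
    if tot == 0:
        raise ValueError("no SNPs in any mutation class")
    return MutationSpectrum(
        rates={cls: v / tot for cls, v in per_site.items()},
        site_counts=dict(site_counts),
        n_snps=len(polarized),
    )


def gc_eq(spectrum: MutationSpectrum) -> float:
    """Equilibrium GC content implied by the mutation spectrum.

    Sueoka's relation: the AT->GC flux divided by the total interclass
    (AT->GC plus GC->AT) flux. Scale-invariant in the rates.
    """
    m = spectrum.rates
    at_to_gc = m[("A", "G")] + m[("A", "C")] + m[("T", "G")] + m[("T", "C")]
    gc_to_at = m[("G", "A")] + m[("G", "T")] + m[("C", "A")] + m[("C", "T")]
    denom = at_to_gc + gc_to_at
    if denom == 0:
        raise ValueError("no interclass mutation flux; GC_eq undefined")
    return at_to_gc / denom


def collapse_six_classes(spectrum: MutationSpectrum) -> dict[str, float]:
    """Collapse the 12 directed classes into 6 strand-symmetric ones.

    Used where SNPs cannot be assigned to a strand: an A->C on one strand
    is a T->G on the other, so the two are pooled.
    """
    return {
        name: spectrum.rates[a] + spectrum.rates[b]
        for name, (a, b) in SIX_CLASSES.items()
    }


def collapse_six_counts(counts: dict[tuple[str, str], int]) -> dict[str, int]:
    return {
        name: counts[a] + counts[b] for name, (a, b) in SIX_CLASSES.items()
    }


def compare_intron_spectrum(
    target_polarized: list[tuple[str, str]],
    target_site_counts: dict[str, int],
    background: MutationSpectrum,
) -> tuple[float, float]:
    """Chi-square test of a target SNP set against a background spectrum.

    Expected counts per six-class are the background per-site rates applied
    to the target's site composition, rescaled to the target's total SNP
    count (absorbing any difference in overall polymorphism level). Five
    degrees of freedom for the six strand-symmetric classes.

    Returns ``(chi2, p)``.
    """
    obs12 = count_mutation_classes(target_polarized)
    obs = collapse_six_counts(obs12)
    exp12 = {
        cls: background.rates[cls] * target_site_counts[cls[0]]
        for cls in MUT_CLASSES
    }
    exp = collapse_six_counts(exp12)  # type: ignore[arg-type]
    tot_exp = sum(exp.values())
    n = sum(obs.values())
    if tot_exp <= 0:
        raise ValueError("zero total expected count")
    exp_scaled = {k: v / tot_exp * n for k, v in exp.items()}
    if any(v == 0 for v in exp_scaled.values()):
        raise ValueError("expected count of zero in a mutation class")
    keys = sorted(obs)
    chi2, p = stats.chisquare(
        [obs[k] for k in keys], [exp_scaled[k] for k in keys]
    )
    return float(chi2), float(p)
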