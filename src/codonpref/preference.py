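"""Adaptive codon preference: log2 deviation of usage from neutrality.

The preference of a codon is the difference, on a log2 scale, between its
observed within-amino-acid relative frequency and the relative frequency
expected at mutational equilibrium. Positive values mark codons used more
often than mutation–drift alone predicts (interpreted as selectively
preferred), negative values mark avoided codons. Variants of the statistic:

* gene-level preference — mean preference over a gene's codon occurrences;
* class-private preference — the statistic computed on the pooled usage of
  a gene class against the genome-wide neutral expectation;
* expression-associated preference — log2 fold difference in relative
  usage between the most highly and most lowly expressed gene classes,
  independent of any neutral model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import (
    AA_TO_CODONS,
    ANALYZED_CODONS,
    CODON_TO_AA,
    SINGLE_CODON_AA,
    CodonUsage,
    count_codons,
    pooled_codon_counts,
    relative_synonymous_frequencies,
)
from .neutral import NeutralExpectation


@dataclass
class PreferenceVector:
    """Per-codon adaptive preference (log2 obs/exp) on the 59 codons.

    ``trna_dep``/``trna_indep`` hold the fitted and residual components of
    the regression on sqrt tRNA adaptiveness when a partition has been
    computed; they sum to ``pref`` codon-by-codon.
    """

    pref: dict[str, float]
    source_label: str = ""
    trna_dep: dict[str, float] = field(default_factory=dict)
    trna_indep: dict[str, float] = field(default_factory=dict)

    def defined_codons(self) -> list[str]:
        return [c for c in ANALYZED_CODONS if not math.isnan(self.pref[c])]

    def as_series(self) -> pd.Series:
        return pd.Series({c: self.pref[c] for c in ANALYZED_CODONS})

    def centered_within_aa(self) -> "PreferenceVector":
        """Center preference to mean 0 within each amino-acid family.

        Within-amino-acid renormalization of codon frequencies makes an
        injected preference identifiable only up to a per-amino-acid
        additive constant, so recovery comparisons are made on centered
        vectors.
        """
        out: dict[str, float] = {}
        for aa, codons in AA_TO_CODONS.items():
            if aa in SINGLE_CODON_AA:
                continue
            vals = [self.pref[c] for c in codons]
            if any(math.isnan(v) for v in vals):
                mu = math.nan
            else:
                mu = sum(vals) / len(vals)
            for c, v in zip(codons, vals):
                out[c] = v - mu
        return PreferenceVector(pref=out, source_label=self.source_label + " (centered)")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in ANALYZED_CODONS:
            rows.append(
                {
                    "codon": c,
                    "amino_acid": CODON_TO_AA[c],
                    "pref": self.pref[c],
                    "trna_dep": self.trna_dep.get(c, math.nan),
                    "trna_indep": self.trna_indep.get(c, math.nan),
                }
            )
        return pd.DataFrame(rows)


def adaptive_preference(
    observed: CodonUsage, neutral: NeutralExpectation, source_label: str = ""
) -> PreferenceVector:
    """log2(observed relative frequency) - log2(expected relative frequency).

    Codons whose observed relative frequency is zero or undefined get nan
    (no pseudocount is applied here; a zero-replacement rule exists only in
    the SNP-proportion analysis, where it is explicit).
    """
    pref: dict[str, float] = {}
    for c in ANALYZED_CODONS:
        obs = observed.rel_freq.get(c, math.nan)
        exp = neutral.rel_codon_freq[c]
        if obs is None or math.isnan(obs) or obs <= 0.0:
            pref[c] = math.nan
        else:
            pref[c] = math.log2(obs) - math.log2(exp)
    return PreferenceVector(pref=pref, source_label=source_label)


def gene_level_preference(cds: str, pref: PreferenceVector) -> float:
    """Unweighted mean preference over a gene's analyzed codon occurrences.

    Codons outside the 59-codon set (ATG, TGG, stops, ambiguous triplets)
    are skipped; a gene with no analyzed codon occurrences, or only codons
    with undefined preference, returns nan.
    """
    total = 0.0
    n = 0
    for codon, k in count_codons(cds).items():
        p = pref.pref.get(codon)
        if p is None or math.isnan(p):
            continue
        total += p * k
        n += k
    return total / n if n else math.nan


def class_private_preference(
    cds_seqs, neutral: NeutralExpectation, label: str = ""
) -> PreferenceVector:
    """Preference private to a gene class: pooled class usage vs genome null."""
    usage = relative_synonymous_frequencies(pooled_codon_counts(cds_seqs), label)
    return adaptive_preference(usage, neutral, source_label=label)


def expression_associated_preference(
    high_usage: CodonUsage, low_usage: CodonUsage
) -> PreferenceVector:
    """log2 fold difference in relative codon usage, high vs low expression.

    Needs no neutral model; codons with zero or undefined frequency in
    either class are flagged nan.
    """
    pref: dict[str, float] = {}
    for c in ANALYZED_CODONS:
        hi = high_usage.rel_freq.get(c, math.nan)
        lo = low_usage.rel_freq.get(c, math.nan)
        if any(v is None or math.isnan(v) or v <= 0 for v in (hi, lo)):
            pref[c] = math.nan
        else:
            pref[c] = math.log2(hi) - math.log2(lo)
    return PreferenceVector(pref=pref, source_label="expression-associated")


def classify_third_base_skew(
    pref_a: PreferenceVector, pref_b: PreferenceVector
) -> tuple[pd.DataFrame, float, float]:
    """Third-base composition of codons where one preference exceeds the other.

    Splits the 59 codons into those with pref_a > pref_b and the reverse,
    tabulates their third bases, and chi-square-tests the A-greater set's
    third-base counts against the composition of the full 59-codon set.
    Returns ``(table, chi2, p)``.
    """
    bases = ["A", "C", "G", "T"]
    greater: list[str] = []
    lesser: list[str] = []
    for c in ANALYZED_CODONS:
        a, b = pref_a.pref[c], pref_b.pref[c]
        if math.isnan(a) or math.isnan(b):
            continue
        if a > b:
            greater.append(c)
        elif b > a:
            lesser.append(c)
    table = pd.DataFrame(
        {
            "a_greater": [sum(1 for c in greater if c[2] == b) for b in bases],
            "b_greater": [sum(1 for c in lesser if c[2] == b) for b in bases],
        },
        index=bases,
    )
    if not greater:
        return table, math.nan, math.nan
    background = np.array(
        [sum(1 for c in ANALYZED_CODONS if c[2] == b) for b in bases], float
    )
    obs = table["a_greater"].to_numpy(float)
    exp = background / background.sum() * obs.sum()
    chi2, p = stats.chisquare(obs, exp)
    return table, float(chi2), float(p)


def rank_expression_classes(
    genes: pd.DataFrame, n_per_class: int = 1000
) -> tuple[list[str], list[str]]:
    """Top/bottom expression classes among nonconditionally expressed genes.

    ``genes`` needs columns ``gene_id``, ``expression`` and ``sociality``
    (bool). Sociality (conditionally expressed) and zero-expression genes
    are removed, the remainder ranked by expression with ties broken by
    gene id, and the top and bottom ``n_per_class`` gene ids returned.
    """
    df = genes.loc[~genes["sociality"].astype(bool)]
    df = df.loc[df["expression"] > 0]
    df = df.sort_values(["expression", "gene_id"], ascending=[False, True])
    if len(df) < 2 * n_per_class:
        raise ValueError(
            f"only {len(df)} eligible genes for two classes of {n_per_class}"
        )
    high = df.head(n_per_class)["gene_id"].tolist()
    low = df.tail(n_per_class)["gene_id"].tolist()
    return high, low


def compare_gene_level_groups(
    values_a, values_b, equal_var: bool = True
) -> tuple[float, float, float, float]:
    """Two-sample t-test on gene-level preference between two gene groups.

    Returns ``(mean_a, mean_b, t, p)``. Pooled-variance by default (the df
    convention of the classical two-sample test); Welch via
    ``equal_var=False``.
    """
    a = np.asarray([v for v in values_a if not math.isnan(v)], float)
    b = np.asarray([v for v in values_b if not math.isnan(v)], float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two genes per group")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(a.mean()), float(b.mean()), float(t), float(p)
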