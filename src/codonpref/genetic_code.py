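"""Genetic-code bookkeeping for codon-usage analyses.

Provides the standard nuclear code, within-amino-acid relative synonymous
frequencies, GC content by codon position, and exhaustive enumeration of
directed single-nucleotide synonymous mutations.

Conventions used throughout the package:

* codons are upper-case DNA triplets (``"AAA"`` ... ``"TTT"``);
* the "analyzed" codon set is the 59 sense codons left after dropping the
  three stop codons and the single-codon amino acids Met (ATG) and
  Trp (TGG) — single-codon amino acids carry no synonymous information;
* undefined quantities (e.g. the relative frequency of a codon whose amino
  acid was never observed) are ``nan``, never silently 0.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

from Bio.Data import CodonTable

BASES = "ACGT"

_standard = CodonTable.unambiguous_dna_by_id[1]

#: mapping of all 64 codons to one-letter amino acid, "*" for stop
CODON_TO_AA: dict[str, str] = {
    "".join(c): _standard.forward_table.get("".join(c), "*")
    for c in itertools.product(BASES, repeat=3)
}

STOP_CODONS = frozenset(c for c, aa in CODON_TO_AA.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c in CODON_TO_AA if c not in STOP_CODONS))

SINGLE_CODON_AA = frozenset(
    aa
    for aa in set(CODON_TO_AA.values()) - {"*"}
    if sum(1 for a in CODON_TO_AA.values() if a == aa) == 1
)  # {"M", "W"} in the standard code

#: the 59 codons carrying synonymous information
ANALYZED_CODONS = tuple(
    c for c in SENSE_CODONS if CODON_TO_AA[c] not in SINGLE_CODON_AA
)

#: amino acid -> tuple of its codons (sense only), sorted
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _c in SENSE_CODONS:
    AA_TO_CODONS.setdefault(CODON_TO_AA[_c], ())
AA_TO_CODONS = {
    aa: tuple(sorted(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa))
    for aa in AA_TO_CODONS
}


@dataclass(frozen=True)
class SynMutation:
    """A directed single-nucleotide synonymous codon change."""

    source: str
    target: str
    codon_position: int  # 1, 2 or 3
    nt_change: tuple[str, str]  # (from_base, to_base)

    @property
    def amino_acid(self) -> str:
        return CODON_TO_AA[self.source]

    def __post_init__(self) -> None:
        diffs = [i for i in range(3) if self.source[i] != self.target[i]]
        if len(diffs) != 1:
            raise ValueError(f"{self.source}->{self.target}: not a point change")
        if CODON_TO_AA[self.source] != CODON_TO_AA[self.target]:
            raise ValueError(f"{self.source}->{self.target}: not synonymous")
        if CODON_TO_AA[self.source] == "*":
            raise ValueError("stop codons are excluded")


@dataclass
class CodonUsage:
    """Per-codon counts and within-amino-acid relative frequencies.

    ``rel_freq`` is defined on the 59 analyzed codons; codons of an amino
    acid with zero total count get ``nan`` so that downstream log
    transforms skip them instead of hitting log(0).
    """

    counts: dict[str, int]
    rel_freq: dict[str, float]
    gene_set_label: str = ""

    def total(self) -> int:
        return sum(self.counts.values())


def relative_synonymous_frequencies(
    counts: dict[str, int], gene_set_label: str = ""
) -> CodonUsage:
    """Normalize codon counts within each amino acid.

    STOP/ATG/TGG counts may be present in ``counts`` but receive no
    relative frequency. Negative counts are rejected.
    """
    for codon, n in counts.items():
        if codon not in CODON_TO_AA:
            raise ValueError(f"unknown codon {codon!r}")
        if n < 0:
            raise ValueError(f"negative count for {codon}")
    kept = {c: int(counts.get(c, 0)) for c in ANALYZED_CODONS}
    rel: dict[str, float] = {}
    for aa, codons in AA_TO_CODONS.items():
        if aa in SINGLE_CODON_AA:
            continue
        tot = sum(kept[c] for c in codons)
        for c in codons:
            rel[c] = kept[c] / tot if tot > 0 else math.nan
    return CodonUsage(counts=kept, rel_freq=rel, gene_set_label=gene_set_label)


def enumerate_synonymous_mutations() -> list[SynMutation]:
    """All directed single-nucleotide synonymous changes between sense codons.

    In the standard code there are 134 such directed mutations: 126 at the
    third codon position and 8 at the first (the Leu and Arg families);
    none exist at the second position.
    """
    muts: list[SynMutation] = []
    for src in SENSE_CODONS:
        if CODON_TO_AA[src] in SINGLE_CODON_AA:
            continue
        for pos in range(3):
            for base in BASES:
                if base == src[pos]:
                    continue
                tgt = src[:pos] + base + src[pos + 1 :]
                if tgt in STOP_CODONS:
                    continue
                if CODON_TO_AA[tgt] != CODON_TO_AA[src]:
                    continue
                muts.append(
                    SynMutation(
                        source=src,
                        target=tgt,
                        codon_position=pos + 1,
                        nt_change=(src[pos], base),
                    )
                )
    return muts


def multi_option_mutations(mutations: list[SynMutation]) -> list[SynMutation]:
    """Keep mutations whose source codon offers >=2 synonymous targets.

    Codons with a single possible synonymous change carry no information
    about which change is favoured, so analyses of within-codon mutation
    proportions drop them (134 -> 114 mutations in the standard code).
    """
    n_targets: dict[str, int] = {}
    for m in mutations:
        n_targets[m.source] = n_targets.get(m.source, 0) + 1
    return [m for m in mutations if n_targets[m.source] >= 2]


def gc_by_position(
    cds: str, exclude_single_codon_aa_gc3: bool = False
) -> tuple[float, float, float]:
    """GC fraction at each codon position of an in-frame CDS.

    With ``exclude_single_codon_aa_gc3`` the ATG and TGG codons are dropped
    from the third-position tally: their G is forced by the amino acid and
    says nothing about synonymous composition.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    tallies = [[0, 0], [0, 0], [0, 0]]  # per position: [gc, total]
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        for p in range(3):
            if (
                p == 2
                and exclude_single_codon_aa_gc3
                and CODON_TO_AA.get(codon) in SINGLE_CODON_AA
            ):
                continue
            b = codon[p]
            if b not in BASES:
                continue
            tallies[p][1] += 1
            if b in "GC":
                tallies[p][0] += 1
    return tuple(
        gc / tot if tot else math.nan for gc, tot in tallies
    )  # type: ignore[return-value]


def count_codons(cds: str) -> dict[str, int]:
    """Codon counts of one in-frame CDS (ambiguity-containing codons skipped)."""
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    counts: dict[str, int] = {}
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3].upper()
        if codon in CODON_TO_AA:
            counts[codon] = counts.get(codon, 0) + 1
    return counts


def pooled_codon_counts(seqs) -> dict[str, int]:
    """Codon counts pooled over an iterable of in-frame CDS sequences."""
    total: dict[str, int] = {}
    for s in seqs:
        for c, n in count_codons(s).items():
            total[c] = total.get(c, 0) + n
    return total
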