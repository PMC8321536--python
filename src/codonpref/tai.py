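"""tRNA adaptiveness of codons and the tRNA-dependent/independent partition.

Absolute codon adaptiveness W_i sums tRNA gene copy numbers over the
anticodons able to decode a codon, discounting non-Watson–Crick pairings
by the standard tAI wobble penalties. Because interest here is in the
choice *among* synonymous codons, W_i is rescaled within each amino acid
family to its maximum, giving the relative synonymous codon adaptiveness
w_ij in (0, 1] with the family-best codon at exactly 1.

Adaptive codon preference is then partitioned by ordinary least squares on
sqrt(w_ij): the fitted value is the tRNA-dependent component of
preference, the residual the tRNA-independent component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genetic_code import (
    AA_TO_CODONS,
    ANALYZED_CODONS,
    CODON_TO_AA,
    SINGLE_CODON_AA,
)
from .preference import PreferenceVector

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: default wobble selective penalties (tAI parameterization):
#: keys are (anticodon position-34 base, codon third base)
DEFAULT_S: dict[tuple[str, str], float] = {
    ("A", "T"): 0.0,      # Watson–Crick U:A (anticodon A34 written as DNA)
    ("G", "C"): 0.0,      # Watson–Crick
    ("T", "A"): 0.0,      # Watson–Crick
    ("C", "G"): 0.0,      # Watson–Crick
    ("G", "T"): 0.41,     # G:U wobble
    ("A", "C"): 0.28,     # inosine (A34) : C
    ("A", "A"): 0.9999,   # inosine (A34) : A
    ("T", "G"): 0.68,     # U:G wobble
}


def decoding_anticodons(codon: str) -> list[tuple[str, tuple[str, str]]]:
    """Anticodons (DNA alphabet, 5'->3') able to decode a codon.

    Each entry is ``(anticodon, pairing_key)`` where the pairing key
    indexes the penalty table by (anticodon position-34 base, codon third
    base). The Watson–Crick decoder always comes first.
    """
    stem = _COMPLEMENT[codon[1]] + _COMPLEMENT[codon[0]]  # positions 35,36
    third = codon[2]
    wc34 = _COMPLEMENT[third]
    out = [(wc34 + stem, (wc34, third))]
    wobble34 = {"T": "G", "C": "A", "A": "A", "G": "T"}[third]
    out.append((wobble34 + stem, (wobble34, third)))
    return out


def read_trna_table(path) -> dict[str, int]:
    """Read an anticodon -> gene copy number TSV (columns anticodon, copies)."""
    df = pd.read_csv(path, sep="\t")
    table = {}
    for _, row in df.iterrows():
        ac = str(row["anticodon"]).upper().replace("U", "T")
        table[ac] = int(row["copies"])
    return table


def write_trna_table(table: dict[str, int], path) -> None:
    rows = [
        {"anticodon": ac, "amino_acid": CODON_TO_AA.get(_anticodon_to_codon(ac), "?"),
         "copies": n}
        for ac, n in sorted(table.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _anticodon_to_codon(ac: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(ac))


@dataclass
class AdaptivenessVector:
    """Absolute (W) and relative synonymous (w_ij) codon adaptiveness."""

    W: dict[str, float]
    w_ij: dict[str, float]
    s_params: dict[tuple[str, str], float] = field(default_factory=dict)
    n_replaced: int = 0
    replaced_codons: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "codon": list(ANALYZED_CODONS),
                "amino_acid": [CODON_TO_AA[c] for c in ANALYZED_CODONS],
                "W": [self.W[c] for c in ANALYZED_CODONS],
                "w_ij": [self.w_ij[c] for c in ANALYZED_CODONS],
                "sqrt_w_ij": [math.sqrt(self.w_ij[c]) for c in ANALYZED_CODONS],
            }
        )


def absolute_adaptiveness(
    trna_copies: dict[str, int],
    s_params: dict[tuple[str, str], float] | None = None,
) -> dict[str, float]:
    """W_i = sum over decoding anticodons of (1 - s_pairing) * gene copies."""
    s = DEFAULT_S if s_params is None else s_params
    for ac in trna_copies:
        if len(ac) != 3 or any(b not in _COMPLEMENT for b in ac):
            raise ValueError(f"invalid anticodon {ac!r}")
        if trna_copies[ac] < 0:
            raise ValueError(f"negative copy number for {ac}")
    W: dict[str, float] = {}
    for codon in ANALYZED_CODONS:
        total = 0.0
        for anticodon, pairing in decoding_anticodons(codon):
            total += (1.0 - s[pairing]) * trna_copies.get(anticodon, 0)
        W[codon] = total
    return W


def geometric_mean_replacement(
    W: dict[str, float], tol: float = 1e-6
) -> tuple[dict[str, float], tuple[str, ...]]:
    """Replace near-zero W values by the geometric mean of the positive ones.

    Codons left undecodable by the copy table would otherwise get w_ij ~ 0
    and dominate any log-scale fit; pulling them to the geometric mean
    keeps them in the analysis without letting them drive the pattern.
    Returns the adjusted vector and the tuple of replaced codons.
    """
    positive = [v for v in W.values() if v > tol]
    if not positive:
        raise ValueError("all adaptiveness values are zero")
    gm = float(np.exp(np.mean(np.log(positive))))
    replaced = tuple(sorted(c for c, v in W.items() if v <= tol))
    out = {c: (gm if v <= tol else v) for c, v in W.items()}
    return out, replaced


def relative_synonymous_adaptiveness(W: dict[str, float]) -> dict[str, float]:
    """w_ij = W_i / max W over codons of the same amino acid."""
    w: dict[str, float] = {}
    for aa, codons in AA_TO_CODONS.items():
        if aa in SINGLE_CODON_AA:
            continue
        mx = max(W[c] for c in codons)
        if mx <= 0:
            raise ValueError(f"amino acid {aa} has zero maximum adaptiveness")
        for c in codons:
            w[c] = W[c] / mx
    return w


def adaptiveness_from_copies(
    trna_copies: dict[str, int],
    s_params: dict[tuple[str, str], float] | None = None,
    zero_tol: float = 1e-6,
) -> AdaptivenessVector:
    """Full pipeline: copies -> W -> zero replacement -> w_ij."""
    W = absolute_adaptiveness(trna_copies, s_params)
    W_adj, replaced = geometric_mean_replacement(W, tol=zero_tol)
    w_ij = relative_synonymous_adaptiveness(W_adj)
    return AdaptivenessVector(
        W=W_adj,
        w_ij=w_ij,
        s_params=dict(DEFAULT_S if s_params is None else s_params),
        n_replaced=len(replaced),
        replaced_codons=replaced,
    )


@dataclass
class PartitionFit:
    intercept: float
    slope: float
    r_squared: float
    p_value: float
    n: int


def partition_preference(
    pref: PreferenceVector, w_ij: dict[str, float]
) -> tuple[PreferenceVector, PartitionFit]:
    """Split preference into tRNA-dependent and tRNA-independent components.

    OLS of preference on sqrt(w_ij) across the 59 codons (with intercept).
    The fitted value — including the intercept — is the tRNA-dependent
    component; the residual is the tRNA-independent component. The two sum
    to the total preference exactly. Codons with undefined preference are
    excluded from the fit and get nan components.
    """
    codons = [c for c in ANALYZED_CODONS if not math.isnan(pref.pref[c])]
    if len(codons) < 3:
        raise ValueError("too few codons with defined preference")
    x = np.sqrt([w_ij[c] for c in codons])
    if np.ptp(x) < 1e-12:
        raise ValueError("sqrt(w_ij) is constant; partition undefined")
    y = np.array([pref.pref[c] for c in codons])
    model = sm.OLS(y, sm.add_constant(x)).fit()
    fitted = model.fittedvalues
    resid = model.resid
    dep = {c: math.nan for c in ANALYZED_CODONS}
    indep = {c: math.nan for c in ANALYZED_CODONS}
    for c, f, r in zip(codons, fitted, resid):
        dep[c] = float(f)
        indep[c] = float(r)
    out = PreferenceVector(
        pref=dict(pref.pref),
        source_label=pref.source_label,
        trna_dep=dep,
        trna_indep=indep,
    )
    fit = PartitionFit(
        intercept=float(model.params[0]),
        slope=float(model.params[1]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n=len(codons),
    )
    return out, fit
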