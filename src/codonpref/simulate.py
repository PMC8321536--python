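"""Synthetic genomes with known codon-preference structure.

The generator emits everything the analysis pipeline consumes — genome
FASTA, GFF3 annotation, VCF SNPs, expression / tRNA / folding-energy /
recombination side tables — from an explicit model whose every injected
quantity is recorded in a truth table, so each downstream estimator can be
checked by parameter recovery.

Model, in brief:

* noncoding sequence is i.i.d. at the symmetric mutational equilibrium
  composition implied by the configured 12-rate mutation matrix;
* coding sequence draws amino acids from a fixed composition and codons
  within each amino acid at relative frequencies proportional to the
  neutral expectation times 2**(q * s_c), where s is the injected
  per-codon preference vector (centered within amino acids) and q is a
  per-slot selection intensity combining a gene-level multiplier (tied to
  expression, shrunk in conditionally expressed "sociality" genes) with a
  5' positional ramp;
* SNPs arise at sites with probability proportional to the mutation rate
  out of the site's base, with derived alleles drawn from the mutation
  matrix and derived-allele counts from a neutral 1/i site-frequency
  spectrum truncated so the derived allele stays the minor one;
* an optional selection mode biases synonymous coding SNP counts by
  exp(beta * relative preference of the destination codon), creating a
  polymorphism–preference correlation of known sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genetic_code import (
    AA_TO_CODONS,
    ANALYZED_CODONS,
    CODON_TO_AA,
    SINGLE_CODON_AA,
)
from .io import GeneModel, RegionIndex, SnpRecord, build_region_index
from .neutral import expected_frequencies
from .spectrum import MutationSpectrum
from . import tai as _tai

#: default 12-rate relative mutation matrix: strand-symmetric, strongly
#: AT-biased (transitions toward AT dominate), equilibrium GC ~= 0.122.
DEFAULT_MUTATION_RATES: dict[tuple[str, str], float] = {
    ("A", "C"): 0.01, ("T", "G"): 0.01,
    ("A", "G"): 0.04, ("T", "C"): 0.04,
    ("A", "T"): 0.08, ("T", "A"): 0.08,
    ("C", "G"): 0.01, ("G", "C"): 0.01,
    ("C", "A"): 0.08, ("G", "T"): 0.08,
    ("C", "T"): 0.28, ("G", "A"): 0.28,
}

_AA_FAMILIES = tuple(
    sorted(aa for aa in AA_TO_CODONS if aa not in SINGLE_CODON_AA)
)
_FAMILY_CODONS = {aa: AA_TO_CODONS[aa] for aa in _AA_FAMILIES}
_CODON_ID = {c: i for i, c in enumerate(ANALYZED_CODONS)}

_QBIN_WIDTH = 0.02  # quantization of the per-slot selection intensity


@dataclass
class SimConfig:
    """Generator settings; the defaults are the study conditions.

    Sizes follow the emulated system: tens of haploid strains, an AT-rich
    genome split over six chromosomes, genes of a few hundred codons with
    occasional short introns, and a strongly AT-biased mutation matrix
    whose equilibrium GC is ~12%.
    """

    n_genes: int = 2000
    n_chromosomes: int = 6
    n_strains: int = 67
    mutation_rates: dict = field(
        default_factory=lambda: dict(DEFAULT_MUTATION_RATES)
    )
    # gene architecture
    gene_len_log_mean: float = math.log(380.0)  # body codons, log-normal
    gene_len_log_sd: float = 0.35
    gene_len_min: int = 180
    gene_len_max: int = 1400
    intron_rate: float = 1.0          # mean introns per gene (Poisson)
    intron_len_mean: int = 100        # bases (min 30)
    intergenic_len_mean: int = 400    # bases (min 100)
    # selection structure
    pref_sd: float = 0.7              # sd of injected per-codon preference
    delta_expr: float = 0.5           # expression-linked intensity modulation
    frac_sociality: float = 0.2
    sociality_shrink: float = 0.5     # intensity factor in sociality genes
    ramp_len: int = 120               # codons of the 5' ramp
    ramp_depth: float = 0.3           # intensity multiplier at position 1
    # expression model (log-normal)
    expr_log_mean: float = 2.0
    expr_log_sd: float = 1.5
    # SNPs
    n_snps: int = 50_000
    selection_beta: float = 0.0       # coding synonymous SNP selection mode

    def spectrum(self) -> MutationSpectrum:
        return MutationSpectrum.from_rates(self.mutation_rates)

    def gc_eq(self) -> float:
        from .spectrum import gc_eq as _g

        return _g(self.spectrum())


@dataclass
class SimGene:
    gene_id: str
    chrom: str
    strand: str
    body_codon_ids: np.ndarray       # indices into ANALYZED_CODONS
    expression: float
    sociality: bool
    multiplier: float                # gene-level selection intensity

    @property
    def cds_seq(self) -> str:
        body = "".join(ANALYZED_CODONS[i] for i in self.body_codon_ids)
        return "ATG" + body + "TAA"

    @property
    def n_body_codons(self) -> int:
        return len(self.body_codon_ids)


@dataclass
class SimResult:
    config: SimConfig
    genes: list[SimGene]
    truth: dict
    genome: dict[str, str] | None = None
    gene_models: list[GeneModel] | None = None
    region_index: RegionIndex | None = None
    intron_seqs: dict[str, str] | None = None  # gene_id -> concatenated introns


def default_preference_vector(rng: np.random.Generator, sd: float = 0.7) -> dict[str, float]:
    """Injected per-codon preference: N(0, sd^2), centered per amino acid.

    Centering makes the vector identifiable: within-amino-acid
    renormalization of codon frequencies absorbs any per-family constant.
    """
    raw = {c: float(rng.normal(0.0, sd)) for c in ANALYZED_CODONS}
    out: dict[str, float] = {}
    for aa in _AA_FAMILIES:
        codons = _FAMILY_CODONS[aa]
        mu = sum(raw[c] for c in codons) / len(codons)
        for c in codons:
            out[c] = raw[c] - mu
    return out


def preference_from_trna(
    w_ij: dict[str, float],
    a: float,
    b: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Preference built as a + b*sqrt(w_ij) + noise (for partition checks)."""
    return {
        c: a + b * math.sqrt(w_ij[c]) + float(rng.normal(0.0, noise_sd))
        for c in ANALYZED_CODONS
    }


# ---------------------------------------------------------------------------
# gene / codon sampling

def _ramp_factor(cfg: SimConfig, pos: np.ndarray) -> np.ndarray:
    """Selection-intensity factor of the 5' ramp at body position 1.."""
    if cfg.ramp_len <= 0 or cfg.ramp_depth >= 1.0:
        return np.ones_like(pos, dtype=float)
    frac = np.minimum(pos - 1, cfg.ramp_len) / cfg.ramp_len
    return cfg.ramp_depth + (1.0 - cfg.ramp_depth) * frac


def _bin_tables(
    qbins: np.ndarray,
    pref: dict[str, float],
    neutral_rel: dict[str, float],
):
    """Per-intensity-bin codon sampling tables and expected preferences."""
    s = np.array([pref[c] for c in ANALYZED_CODONS])
    base = np.array([neutral_rel[c] for c in ANALYZED_CODONS])
    fam_slices = {}
    for aa in _AA_FAMILIES:
        ids = np.array([_CODON_ID[c] for c in _FAMILY_CODONS[aa]])
        fam_slices[aa] = ids
    tables = {}
    for qb in np.unique(qbins):
        q = qb * _QBIN_WIDTH
        w = base * np.exp2(q * s)
        cum = {}
        exp_pref = 0.0
        for aa, ids in fam_slices.items():
            p = w[ids] / w[ids].sum()
            cum[aa] = (np.cumsum(p), ids)
            exp_pref += (p * s[ids]).sum() / len(_AA_FAMILIES)
        tables[qb] = (cum, exp_pref)
    return tables


def simulate_genes(
    cfg: SimConfig,
    rng: np.random.Generator,
    pref: dict[str, float] | None = None,
) -> SimResult:
    """Draw gene codon content (fast path, no genome assembly).

    Returns a :class:`SimResult` whose truth dict records the injected
    preference, the mutation matrix and its GC_eq, per-gene multipliers,
    and the expected positional mean-preference profile with its
    zero-crossing position.
    """
    if pref is None:
        pref = default_preference_vector(rng, cfg.pref_sd)
    neutral = expected_frequencies(gc_eq=cfg.gc_eq())

    n = cfg.n_genes
    lens = np.exp(rng.normal(cfg.gene_len_log_mean, cfg.gene_len_log_sd, n))
    lens = np.clip(lens.astype(int), cfg.gene_len_min, cfg.gene_len_max)
    z = rng.normal(0.0, 1.0, n)
    expression = np.exp(cfg.expr_log_mean + cfg.expr_log_sd * z)
    sociality = rng.random(n) < cfg.frac_sociality
    mult = 1.0 + cfg.delta_expr * np.clip(z, -2.0, 2.0) / 2.0
    mult = np.where(sociality, mult * cfg.sociality_shrink, mult)
    chroms = np.array(
        [f"chr{(i % cfg.n_chromosomes) + 1}" for i in range(n)]
    )
    strands = np.where(rng.random(n) < 0.5, "+", "-")

    # slot arrays (gene-contiguous)
    gene_idx = np.repeat(np.arange(n), lens)
    pos = np.concatenate([np.arange(1, L + 1) for L in lens])
    q = mult[gene_idx] * _ramp_factor(cfg, pos)
    qbins = np.round(q / _QBIN_WIDTH).astype(np.int64)
    aa_idx = rng.integers(0, len(_AA_FAMILIES), size=len(pos))

    tables = _bin_tables(qbins, pref, neutral.rel_codon_freq)

    codon_ids = np.empty(len(pos), dtype=np.int64)
    order = np.lexsort((aa_idx, qbins))
    sorted_qb = qbins[order]
    sorted_aa = aa_idx[order]
    u = rng.random(len(pos))
    # contiguous (qbin, aa) groups after the lexsort
    group_key = sorted_qb * 100 + sorted_aa
    boundaries = np.concatenate(
        [[0], np.flatnonzero(np.diff(group_key)) + 1, [len(pos)]]
    )
    for b0, b1 in zip(boundaries[:-1], boundaries[1:]):
        qb = sorted_qb[b0]
        aa = _AA_FAMILIES[sorted_aa[b0]]
        cum, _ = tables[qb]
        cumsum, ids = cum[aa]
        picks = np.searchsorted(cumsum, u[b0:b1], side="right")
        picks = np.minimum(picks, len(ids) - 1)
        codon_ids[order[b0:b1]] = ids[picks]

    genes: list[SimGene] = []
    offsets = np.concatenate([[0], np.cumsum(lens)])
    for i in range(n):
        genes.append(
            SimGene(
                gene_id=f"g{i:05d}",
                chrom=str(chroms[i]),
                strand=str(strands[i]),
                body_codon_ids=codon_ids[offsets[i] : offsets[i + 1]],
                expression=float(expression[i]),
                sociality=bool(sociality[i]),
                multiplier=float(mult[i]),
            )
        )

    # expected positional mean-preference profile (truth)
    exp_pref_by_bin = {qb: t[1] for qb, t in tables.items()}
    slot_exp = np.vectorize(exp_pref_by_bin.get)(qbins)
    genome_mean = float(slot_exp.mean())
    max_p = 250
    profile_truth = np.full(max_p, np.nan)
    for p in range(1, max_p + 1):
        sel = pos == p
        if sel.any():
            profile_truth[p - 1] = float(slot_exp[sel].mean()) - genome_mean
    from .positional import zero_crossing

    truth = {
        "preference": dict(pref),
        "mutation_rates": dict(cfg.mutation_rates),
        "gc_eq": cfg.gc_eq(),
        "gene_multipliers": mult,
        "positional_profile": profile_truth,
        "ramp_zero_crossing": zero_crossing(profile_truth),
    }
    return SimResult(config=cfg, genes=genes, truth=truth)


# ---------------------------------------------------------------------------
# genome assembly

_EQ_BASES = np.array(list("ACGT"))


def _random_noncoding(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_EQ_BASES[rng.choice(4, size=length, p=p)])


def _revcomp(s: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(s))


def assemble_genome(sim: SimResult, rng: np.random.Generator) -> None:
    """Place genes on chromosomes with intergenic spacers and introns.

    Mutates ``sim`` in place, filling ``genome``, ``gene_models``,
    ``region_index`` and ``intron_seqs``. Introns are inserted at codon
    boundaries so splicing never breaks the reading frame.
    """
    cfg = sim.config
    gc = cfg.gc_eq()
    parts: dict[str, list[str]] = {f"chr{i+1}": [] for i in range(cfg.n_chromosomes)}
    cursor: dict[str, int] = {c: 0 for c in parts}
    models: list[GeneModel] = []
    intron_seqs: dict[str, str] = {}

    def spacer_len() -> int:
        return 100 + int(rng.exponential(max(cfg.intergenic_len_mean - 100, 1)))

    for gene in sim.genes:
        chrom = gene.chrom
        sp = spacer_len()
        parts[chrom].append(_random_noncoding(sp, gc, rng))
        cursor[chrom] += sp
        cds = gene.cds_seq
        n_introns = int(rng.poisson(cfg.intron_rate))
        n_codons = len(cds) // 3
        cut_sites: list[int] = []
        if n_introns > 0 and n_codons > 3:
            sites = rng.choice(
                np.arange(1, n_codons), size=min(n_introns, n_codons - 1),
                replace=False,
            )
            cut_sites = sorted(int(s) * 3 for s in sites)
        segments: list[str] = []
        prev = 0
        introns: list[str] = []
        for cut in cut_sites:
            segments.append(cds[prev:cut])
            introns.append(
                _random_noncoding(
                    30 + int(rng.exponential(max(cfg.intron_len_mean - 30, 1))),
                    gc, rng,
                )
            )
            prev = cut
        segments.append(cds[prev:])
        # genomic layout: on minus strand the spliced CDS reads right->left
        if gene.strand == "-":
            genomic_segments = [_revcomp(s) for s in reversed(segments)]
            genomic_introns = [_revcomp(s) for s in reversed(introns)]
        else:
            genomic_segments = segments
            genomic_introns = introns
        blocks: list[tuple[int, int]] = []
        at = cursor[chrom]
        for i, seg in enumerate(genomic_segments):
            parts[chrom].append(seg)
            blocks.append((at, at + len(seg)))
            at += len(seg)
            if i < len(genomic_introns):
                parts[chrom].append(genomic_introns[i])
                at += len(genomic_introns[i])
        cursor[chrom] = at
        models.append(
            GeneModel(
                gene_id=gene.gene_id,
                chrom=chrom,
                strand=gene.strand,
                cds_blocks=blocks,
            )
        )
        intron_seqs[gene.gene_id] = "".join(introns)
    for chrom in parts:
        sp = spacer_len()
        parts[chrom].append(_random_noncoding(sp, gc, rng))
        cursor[chrom] += sp
    genome = {c: "".join(p) for c, p in parts.items()}
    sim.genome = genome
    sim.gene_models = models
    sim.intron_seqs = intron_seqs
    sim.region_index = build_region_index(
        models, {c: len(s) for c, s in genome.items()}
    )


# ---------------------------------------------------------------------------
# SNP generation

def sample_sfs_counts(
    n_snps: int,
    n_strains: int,
    rng: np.random.Generator,
    keep_minor: bool = True,
) -> np.ndarray:
    """Derived-allele counts from the neutral 1/i site-frequency spectrum.

    With ``keep_minor`` the spectrum is truncated at floor((n-1)/2) so the
    derived allele is always the minor one and frequency polarization
    recovers the true direction.
    """
    i_max = (n_strains - 1) // 2 if keep_minor else n_strains - 1
    i = np.arange(1, i_max + 1)
    p = (1.0 / i) / (1.0 / i).sum()
    return rng.choice(i, size=n_snps, p=p)


def noncoding_mask(index: RegionIndex, labels=("intron", "intergenic")) -> dict[str, np.ndarray]:
    from .io import LABEL_NAMES

    wanted = {k for k, v in LABEL_NAMES.items() if v in labels}
    return {c: np.isin(lab, list(wanted)) for c, lab in index.labels.items()}


def restrict_mask_to_spans(
    mask: dict[str, np.ndarray], spans: list[tuple[str, int, int]]
) -> dict[str, np.ndarray]:
    """Intersect a per-chromosome mask with a set of genomic spans."""
    out = {c: np.zeros_like(m) for c, m in mask.items()}
    for chrom, s, e in spans:
        out[chrom][s:e] = mask[chrom][s:e]
    return out


def generate_snps(
    genome: dict[str, str],
    mask: dict[str, np.ndarray],
    cfg: SimConfig,
    rng: np.random.Generator,
    n_snps: int | None = None,
) -> list[SnpRecord]:
    """Place SNPs on masked sites with the configured mutation matrix.

    Site choice is proportional to the total mutation rate out of the
    site's base; the derived allele follows the conditional rates; the
    derived count follows the truncated neutral SFS. The reference allele
    written is the ancestral (genome) base.
    """
    n_snps = cfg.n_snps if n_snps is None else n_snps
    spec = cfg.spectrum()
    site_pos: dict[str, list] = {b: [] for b in "ACGT"}
    site_chrom: dict[str, list] = {b: [] for b in "ACGT"}
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode(), dtype="S1")
        m = mask[chrom]
        for b in "ACGT":
            idx = np.flatnonzero(m & (arr == b.encode()))
            site_pos[b].append(idx)
            site_chrom[b].append(np.full(len(idx), chrom, dtype=object))
    pos_by_base = {b: np.concatenate(site_pos[b]) for b in "ACGT"}
    chrom_by_base = {b: np.concatenate(site_chrom[b]) for b in "ACGT"}
    counts = {b: len(pos_by_base[b]) for b in "ACGT"}
    weights = np.array(
        [counts[b] * spec.total_rate_from(b) for b in "ACGT"], float
    )
    if weights.sum() <= 0:
        raise ValueError("mask contains no mutable sites")
    n_per_base = rng.multinomial(n_snps, weights / weights.sum())
    snps: list[SnpRecord] = []
    for b, n_b in zip("ACGT", n_per_base):
        if n_b == 0:
            continue
        if n_b > counts[b]:
            raise ValueError(
                f"region exhausted: {n_b} SNPs requested on {counts[b]} {b} sites"
            )
        chosen = rng.choice(counts[b], size=n_b, replace=False)
        targets = [y for y in "ACGT" if y != b]
        tp = np.array([spec.rates[(b, y)] for y in targets])
        tp = tp / tp.sum()
        der = rng.choice(3, size=n_b, p=tp)
        dac = sample_sfs_counts(n_b, cfg.n_strains, rng)
        for k in range(n_b):
            alt = targets[der[k]]
            i = int(dac[k])
            snps.append(
                SnpRecord(
                    chrom=str(chrom_by_base[b][chosen[k]]),
                    pos=int(pos_by_base[b][chosen[k]]) + 1,
                    ref=b,
                    alt=alt,
                    ref_count=cfg.n_strains - i,
                    alt_count=i,
                )
            )
    snps.sort(key=lambda s: (s.chrom, s.pos))
    return snps


def synonymous_snp_class_counts(
    p_hat: pd.DataFrame,
    n_snps: int,
    rng: np.random.Generator,
    selection_beta: float = 0.0,
    rel_pref: dict[tuple[str, str], float] | None = None,
) -> dict[tuple[str, str], int]:
    """Multinomial counts of synonymous SNPs over directed codon changes.

    Under neutrality (``selection_beta = 0``) class probabilities are the
    expected proportions p_hat; the selection mode tilts them by
    exp(beta * relative preference of the destination codon), emulating
    weaker purifying selection against changes toward preferred codons.
    """
    keys = list(zip(p_hat["source"], p_hat["target"]))
    probs = p_hat["p_hat"].to_numpy(float).copy()
    if selection_beta != 0.0:
        if rel_pref is None:
            raise ValueError("selection mode needs relative preferences")
        tilt = np.exp(selection_beta * np.array([rel_pref[k] for k in keys]))
        probs = probs * tilt
    probs = probs / probs.sum()
    draws = rng.multinomial(n_snps, probs)
    return {k: int(v) for k, v in zip(keys, draws)}


def place_coding_snps(
    sim: SimResult,
    class_counts: dict[tuple[str, str], int],
    rng: np.random.Generator,
) -> list[SnpRecord]:
    """Place per-class synonymous SNP counts onto actual codon occurrences.

    Requires an assembled genome. Each selected codon occurrence yields
    one biallelic SNP whose reference allele is the (ancestral) genome
    base and whose alternate is the derived base of the codon change,
    strand-corrected.
    """
    if sim.gene_models is None:
        raise ValueError("assemble_genome must run first")
    from .io import cds_to_genomic

    cfg = sim.config
    occ: dict[str, list[tuple[int, int]]] = {}
    for gi, gene in enumerate(sim.genes):
        for ci, cid in enumerate(gene.body_codon_ids):
            occ.setdefault(ANALYZED_CODONS[cid], []).append((gi, ci))
    by_source: dict[str, list[tuple[str, int]]] = {}
    for (src, tgt), k in class_counts.items():
        if k > 0:
            by_source.setdefault(src, []).append((tgt, k))
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    models = {g.gene_id: m for g, m in zip(sim.genes, sim.gene_models)}
    snps: list[SnpRecord] = []
    for src, targets in sorted(by_source.items()):
        pool = occ.get(src, [])
        total = sum(k for _, k in targets)
        if total > len(pool):
            raise ValueError(
                f"not enough {src} occurrences ({len(pool)}) for {total} SNPs"
            )
        chosen = rng.choice(len(pool), size=total, replace=False)
        at = 0
        for tgt, k in targets:
            within = next(i for i in range(3) if src[i] != tgt[i])
            dac = sample_sfs_counts(k, cfg.n_strains, rng)
            for j in range(k):
                gi, ci = pool[chosen[at]]
                at += 1
                gene = sim.genes[gi]
                model = models[gene.gene_id]
                cds_pos = 3 * (ci + 1) + within  # +1 skips the start codon
                gpos = cds_to_genomic(model, cds_pos)
                ref, alt = src[within], tgt[within]
                if gene.strand == "-":
                    ref, alt = comp[ref], comp[alt]
                i = int(dac[j])
                snps.append(
                    SnpRecord(
                        chrom=gene.chrom,
                        pos=gpos + 1,
                        ref=ref,
                        alt=alt,
                        ref_count=cfg.n_strains - i,
                        alt_count=i,
                        region_label="CDS",
                    )
                )
    snps.sort(key=lambda s: (s.chrom, s.pos))
    return snps


# ---------------------------------------------------------------------------
# side tables

def generate_trna_table(rng: np.random.Generator) -> dict[str, int]:
    """tRNA gene copy numbers per anticodon.

    Each amino-acid family gets one well-supplied Watson–Crick anticodon
    (its "major" codon) plus sparse copies for a random subset of the
    others, leaving some codons decodable only through wobble — the
    structure that makes w_ij informative.
    """
    table: dict[str, int] = {}
    for aa in _AA_FAMILIES:
        codons = _FAMILY_CODONS[aa]
        major = codons[int(rng.integers(len(codons)))]
        for c in codons:
            wc = _tai.decoding_anticodons(c)[0][0]
            if c == major:
                table[wc] = table.get(wc, 0) + int(rng.integers(4, 10))
            elif rng.random() < 0.5:
                table[wc] = table.get(wc, 0) + int(rng.integers(1, 4))
    return table


def generate_expression_table(sim: SimResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in sim.genes],
            "expression": [g.expression for g in sim.genes],
            "sociality": [g.sociality for g in sim.genes],
        }
    )


def generate_stability_table(
    gene_ids,
    gene_indep_pref,
    cds_lengths,
    rng: np.random.Generator,
    alpha: float = -1.0,
    target_r2: float = 0.4,
) -> tuple[pd.DataFrame, float]:
    """Folding free energies with a known per-site link to preference.

    stability_per_site = alpha * (gene tRNA-independent preference) +
    noise, with the noise variance set so the preference term explains
    ``target_r2`` of the variance; delta G0 is the per-site value scaled
    back by CDS length. Returns the table and the plug-in true R^2
    implied by the realized predictor variance.
    """
    x = np.asarray(gene_indep_pref, float)
    lens = np.asarray(cds_lengths, float)
    signal_var = (alpha ** 2) * x.var(ddof=1)
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must be in (0,1)")
    noise_sd = math.sqrt(signal_var * (1 - target_r2) / target_r2)
    per_site = alpha * x + rng.normal(0.0, noise_sd, len(x))
    true_r2 = signal_var / (signal_var + noise_sd ** 2)
    df = pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "delta_g0": per_site * lens,
            "stability_per_site": per_site,
        }
    )
    return df, float(true_r2)


def generate_rho_track(
    genome: dict[str, str],
    rng: np.random.Generator,
    window: int = 5000,
    log_mean: float = math.log(0.01),
    log_sd: float = 1.0,
    zero_fraction: float = 0.1,
) -> pd.DataFrame:
    """Log-normal per-window recombination rates, independent of GC.

    A configurable fraction of windows gets rho = 0, exercising the
    downstream offset-before-log rule.
    """
    rows = []
    for chrom, seq in genome.items():
        for s in range(0, len(seq) - window + 1, window):
            rho = float(np.exp(rng.normal(log_mean, log_sd)))
            if rng.random() < zero_fraction:
                rho = 0.0
            rows.append({"chrom": chrom, "start": s, "end": s + window, "rho": rho})
    return pd.DataFrame(rows)
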