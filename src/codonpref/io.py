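"""Genome, annotation, variant and side-table input/output.

Readers and writers for multi-record FASTA (Biopython), GFF3 (gffutils),
VCF 4.x (pysam, haploid genotypes — the sampled strains are clonal
isolates), and tab-delimited side tables; plus region classification of
every genomic base as CDS, intron or intergenic, and spliced CDS
extraction.

Coordinates are GFF3 1-based closed on disk and 0-based half-open in
memory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq

from .genetic_code import CODON_TO_AA, STOP_CODONS

log = logging.getLogger(__name__)

INTERGENIC, CDS, INTRON = 0, 1, 2
LABEL_NAMES = {INTERGENIC: "intergenic", CDS: "CDS", INTRON: "intron"}


# ---------------------------------------------------------------------------
# FASTA

def read_genome_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene models / GFF3

@dataclass
class GeneModel:
    """One protein-coding gene: stranded CDS blocks within a gene span."""

    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    cds_blocks: list[tuple[int, int]]  # 0-based half-open, ascending
    gene_start: int = -1
    gene_end: int = -1

    def __post_init__(self) -> None:
        self.cds_blocks = sorted(tuple(b) for b in self.cds_blocks)
        if self.gene_start < 0:
            self.gene_start = self.cds_blocks[0][0]
        if self.gene_end < 0:
            self.gene_end = self.cds_blocks[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_blocks)


def parse_gff(path) -> list[GeneModel]:
    """Read gene models (gene + CDS features) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        blocks = [
            (c.start - 1, c.end)
            for c in db.children(gene, featuretype="CDS", order_by="start")
        ]
        if not blocks:
            continue
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                cds_blocks=blocks,
                gene_start=gene.start - 1,
                gene_end=gene.end,
            )
        )
    return genes


def write_gff(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tcodonpref\tgene\t{g.gene_start + 1}\t{g.gene_end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chrom}\tcodonpref\tmRNA\t{g.gene_start + 1}\t{g.gene_end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.cds_blocks):
                fh.write(
                    f"{g.chrom}\tcodonpref\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t"
                    f".\tID={g.gene_id}.cds{i};Parent={g.gene_id}.t1\n"
                )


# ---------------------------------------------------------------------------
# Region index

@dataclass
class RegionIndex:
    """Per-chromosome per-base region labels (CDS / intron / intergenic).

    Stored as dense int8 arrays so the "every base has exactly one label"
    invariant holds by construction: CDS wins over intron where gene
    models overlap, intron over intergenic.
    """

    labels: dict[str, np.ndarray]

    def label_of(self, chrom: str, pos: int) -> str:
        return LABEL_NAMES[int(self.labels[chrom][pos])]

    def base_counts(self, genome: dict[str, str], which=("intron", "intergenic")) -> dict[str, int]:
        """Counts of A/C/G/T over all bases carrying one of the labels."""
        wanted = {k for k, v in LABEL_NAMES.items() if v in which}
        counts = {b: 0 for b in "ACGT"}
        for chrom, lab in self.labels.items():
            seq = np.frombuffer(genome[chrom].encode(), dtype="S1")
            mask = np.isin(lab, list(wanted))
            sub = seq[mask]
            for b in "ACGT":
                counts[b] += int((sub == b.encode()).sum())
        return counts

    def label_fractions(self) -> dict[str, float]:
        tot = sum(len(v) for v in self.labels.values())
        out = {}
        for code, name in LABEL_NAMES.items():
            out[name] = sum(int((v == code).sum()) for v in self.labels.values()) / tot
        return out

    def sequences_for(self, genome: dict[str, str], which=("intron", "intergenic")) -> list[str]:
        """Maximal runs of sequence carrying the requested labels.

        Runs never span chromosomes, so downstream triplet framing stays
        within a contig.
        """
        wanted = {k for k, v in LABEL_NAMES.items() if v in which}
        out: list[str] = []
        for chrom, lab in self.labels.items():
            mask = np.isin(lab, list(wanted))
            if not mask.any():
                continue
            # run-length extraction of True stretches
            padded = np.concatenate([[False], mask, [False]])
            diff = np.diff(padded.astype(np.int8))
            starts = np.flatnonzero(diff == 1)
            ends = np.flatnonzero(diff == -1)
            seq = genome[chrom]
            out.extend(seq[s:e] for s, e in zip(starts, ends))
        return out


def build_region_index(
    genes: list[GeneModel], chrom_lengths: dict[str, int]
) -> RegionIndex:
    """Partition every base: CDS from gene models, intron = gene span minus
    CDS, intergenic = everything outside gene spans."""
    labels = {c: np.zeros(n, dtype=np.int8) for c, n in chrom_lengths.items()}
    for g in genes:
        if g.chrom not in labels:
            raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
        arr = labels[g.chrom]
        if g.gene_end > len(arr) or g.gene_start < 0:
            raise ValueError(f"gene {g.gene_id} extends beyond chromosome")
        span = arr[g.gene_start : g.gene_end]
        span[span == INTERGENIC] = INTRON
    for g in genes:
        arr = labels[g.chrom]
        for s, e in g.cds_blocks:
            if e > len(arr):
                raise ValueError(f"CDS of {g.gene_id} beyond chromosome end")
            arr[s:e] = CDS
    return RegionIndex(labels=labels)


def extract_cds(gene: GeneModel, genome: dict[str, str]) -> str:
    """Spliced, strand-corrected CDS of one gene.

    Blocks are concatenated in genomic order then reverse-complemented for
    minus-strand genes. An in-frame internal stop flags the gene (warning
    logged); the caller decides whether to exclude it.
    """
    seq = genome[gene.chrom]
    parts = [seq[s:e] for s, e in gene.cds_blocks]
    cds = "".join(parts)
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    for i in range(0, len(cds) - 3, 3):
        if cds[i : i + 3] in STOP_CODONS:
            log.warning("gene %s: internal stop at codon %d", gene.gene_id, i // 3)
            break
    return cds


# ---------------------------------------------------------------------------
# Gene records and filters

@dataclass
class GeneRecord:
    """A gene with everything the downstream analyses consume."""

    gene_id: str
    cds_seq: str
    expression: float = 0.0
    labels: set = field(default_factory=set)  # subset of {high, low, sociality, TE}
    delta_g0: float = np.nan
    chrom: str = ""
    chrom_half: str = ""  # proximal | distal
    intron_seq: str = ""

    @property
    def cds_length(self) -> int:
        return len(self.cds_seq)


def apply_gene_filters(
    genes: list,
    min_len: int = 500,
    n_longest_removed: int = 0,
    exclude_labels: tuple = (),
):
    """Deterministic length/label filter on gene records.

    Genes with CDS length <= ``min_len`` bases are removed, then the
    ``n_longest_removed`` longest of the remainder (ties broken by gene
    id, larger id removed first within a tie), then any gene carrying an
    excluded label.
    """
    kept = [g for g in genes if g.cds_length > min_len]
    if n_longest_removed > 0:
        by_len = sorted(kept, key=lambda g: (g.cds_length, g.gene_id))
        cut = len(by_len) - n_longest_removed
        kept = by_len[:max(cut, 0)]
        kept.sort(key=lambda g: g.gene_id)
    if exclude_labels:
        excl = set(exclude_labels)
        kept = [g for g in kept if not (g.labels & excl)]
    return kept


# ---------------------------------------------------------------------------
# SNPs / VCF

@dataclass
class SnpRecord:
    """One biallelic SNP with per-allele counts over the sampled strains."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    ref_count: int
    alt_count: int
    region_label: str = ""

    @property
    def allele_counts(self) -> dict[str, int]:
        return {self.ref: self.ref_count, self.alt: self.alt_count}

    @property
    def n_called(self) -> int:
        return self.ref_count + self.alt_count


def write_vcf(
    snps: list[SnpRecord], path, chrom_lengths: dict[str, int], n_strains: int
) -> None:
    """Write SNPs as an uncompressed VCF with haploid per-strain genotypes.

    The first ``alt_count`` strains carry the alternate allele; strains
    beyond ``ref_count + alt_count`` are written as missing.
    """
    header = pysam.VariantHeader()
    for chrom, length in chrom_lengths.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    samples = [f"strain{i:03d}" for i in range(n_strains)]
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for snp in sorted(snps, key=lambda s: (s.chrom, s.pos)):
            rec = vf.new_record(
                contig=snp.chrom,
                start=snp.pos - 1,
                stop=snp.pos,
                alleles=(snp.ref, snp.alt),
            )
            for i, s in enumerate(samples):
                if i < snp.alt_count:
                    rec.samples[s]["GT"] = (1,)
                elif i < snp.alt_count + snp.ref_count:
                    rec.samples[s]["GT"] = (0,)
                else:
                    rec.samples[s]["GT"] = (None,)
            vf.write(rec)


def read_vcf(path) -> list[SnpRecord]:
    """Read biallelic SNPs; allele counts tallied from haploid genotypes.

    Multiallelic records and indels are skipped, matching the upstream
    filtering of the consumed variant sets.
    """
    out: list[SnpRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if len(rec.alts or ()) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                continue
            nref = nalt = 0
            for s in rec.samples.values():
                for a in s["GT"]:
                    if a == 0:
                        nref += 1
                    elif a == 1:
                        nalt += 1
            out.append(
                SnpRecord(
                    chrom=rec.chrom, pos=rec.pos, ref=ref, alt=alt,
                    ref_count=nref, alt_count=nalt,
                )
            )
    return out


def annotate_snp_regions(snps: list[SnpRecord], index: RegionIndex) -> None:
    for snp in snps:
        snp.region_label = index.label_of(snp.chrom, snp.pos - 1)


def snp_codon_change(
    snp: SnpRecord, gene: GeneModel, genome: dict[str, str]
) -> tuple[str, str, int] | None:
    """Codon change implied by a CDS SNP, major-allele codon as source.

    Returns ``(source_codon, target_codon, codon_position 1..3)`` on the
    coding strand, or None if the SNP misses this gene's CDS or the counts
    tie. The major (higher-count) allele defines the source codon,
    mirroring the frequency polarization used in noncoding sequence.
    """
    gpos = snp.pos - 1
    offset = 0
    cds_pos = None
    for s, e in gene.cds_blocks:
        if s <= gpos < e:
            cds_pos = offset + (gpos - s)
            break
        offset += e - s
    if cds_pos is None:
        return None
    cds_len = gene.cds_length
    cds = extract_cds(gene, genome)
    ref, alt = snp.ref, snp.alt
    if gene.strand == "-":
        cds_pos = cds_len - 1 - cds_pos
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        ref, alt = comp[ref], comp[alt]
    if snp.ref_count == snp.alt_count:
        return None
    major, minor = (ref, alt) if snp.ref_count > snp.alt_count else (alt, ref)
    ci = cds_pos // 3
    within = cds_pos % 3
    codon = cds[ci * 3 : ci * 3 + 3]
    if len(codon) != 3:
        return None
    if codon[within] not in (ref, alt):
        raise ValueError(
            f"SNP {snp.chrom}:{snp.pos} alleles do not match CDS of {gene.gene_id}"
        )
    src = codon[:within] + major + codon[within + 1 :]
    tgt = codon[:within] + minor + codon[within + 1 :]
    return src, tgt, within + 1


def cds_to_genomic(gene: GeneModel, cds_pos: int) -> int:
    """Genomic (0-based) coordinate of a coding-strand CDS position."""
    if not 0 <= cds_pos < gene.cds_length:
        raise IndexError(f"CDS position {cds_pos} outside {gene.gene_id}")
    if gene.strand == "-":
        cds_pos = gene.cds_length - 1 - cds_pos
    for s, e in gene.cds_blocks:
        if cds_pos < e - s:
            return s + cds_pos
        cds_pos -= e - s
    raise AssertionError("unreachable")


def count_synonymous_codon_changes(
    snps: list[SnpRecord],
    genes: list[GeneModel],
    genome: dict[str, str],
) -> dict[tuple[str, str], int]:
    """Tally directed synonymous codon changes over all CDS SNPs."""
    from .genetic_code import CODON_TO_AA

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    counts: dict[tuple[str, str], int] = {}
    for snp in snps:
        for g in by_chrom.get(snp.chrom, []):
            if not (g.gene_start <= snp.pos - 1 < g.gene_end):
                continue
            change = snp_codon_change(snp, g, genome)
            if change is None:
                continue
            src, tgt, _ = change
            if (
                src in CODON_TO_AA
                and tgt in CODON_TO_AA
                and CODON_TO_AA[src] == CODON_TO_AA[tgt] != "*"
            ):
                counts[(src, tgt)] = counts.get((src, tgt), 0) + 1
            break
    return counts


# ---------------------------------------------------------------------------
# TSV side tables

def read_expression_table(path) -> pd.DataFrame:
    """gene_id, expression[, sociality] TSV."""
    df = pd.read_csv(path, sep="\t")
    if "sociality" not in df.columns:
        df["sociality"] = False
    return df


def read_delta_g_table(path) -> pd.DataFrame:
    """gene_id, delta_g0 TSV (transcript folding free energy, kcal/mol)."""
    return pd.read_csv(path, sep="\t")


def read_rho_table(path) -> pd.DataFrame:
    """chrom, start, end, rho TSV (population recombination per window)."""
    return pd.read_csv(path, sep="\t")
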