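"""Generate the synthetic study system and export its standard-format files.

Writes the genome FASTA, GFF3 annotation, noncoding + coding SNP VCFs and
the expression / tRNA / folding-energy / recombination side tables under
scratch/simdata/, plus a small summary table under results/. Everything
downstream consumes either these files or the cached in-memory system.
"""

import importlib.util
import os
import sys

spec = importlib.util.spec_from_file_location(
    "common", os.path.join(os.path.dirname(__file__), "00_common.py")
)
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

import pandas as pd


def main() -> None:
    args = common.parse_args(__doc__)
    system = common.get_system(args.seed, args.rebuild)
    sim = system.sim

    from codonpref.io import write_genome_fasta, write_gff, write_vcf
    from codonpref.tai import write_trna_table

    outdir = os.path.join(common.SCRATCH, "simdata")
    os.makedirs(outdir, exist_ok=True)
    chrom_lengths = {c: len(s) for c, s in sim.genome.items()}
    write_genome_fasta(sim.genome, os.path.join(outdir, "genome.fa"))
    write_gff(sim.gene_models, os.path.join(outdir, "genes.gff3"))
    write_vcf(system.noncoding_snps, os.path.join(outdir, "noncoding_snps.vcf"),
              chrom_lengths, system.cfg.n_strains)
    write_vcf(system.coding_snps, os.path.join(outdir, "coding_snps.vcf"),
              chrom_lengths, system.cfg.n_strains)
    system.expression.to_csv(os.path.join(outdir, "expression.tsv"),
                             sep="\t", index=False)
    write_trna_table(system.trna_copies, os.path.join(outdir, "trna.tsv"))
    system.stability[["gene_id", "delta_g0"]].to_csv(
        os.path.join(outdir, "delta_g0.tsv"), sep="\t", index=False)
    system.rho.to_csv(os.path.join(outdir, "rho.tsv"), sep="\t", index=False)

    fr = sim.region_index.label_fractions()
    summary = pd.DataFrame(
        [
            {"quantity": "n_genes", "value": len(sim.genes)},
            {"quantity": "n_chromosomes", "value": len(sim.genome)},
            {"quantity": "genome_bases", "value": sum(chrom_lengths.values())},
            {"quantity": "frac_cds", "value": round(fr["CDS"], 4)},
            {"quantity": "frac_intron", "value": round(fr["intron"], 4)},
            {"quantity": "frac_intergenic", "value": round(fr["intergenic"], 4)},
            {"quantity": "n_noncoding_snps", "value": len(system.noncoding_snps)},
            {"quantity": "n_coding_snps", "value": len(system.coding_snps)},
            {"quantity": "gc_eq_truth", "value": round(system.cfg.gc_eq(), 5)},
        ]
    )
    out = common.results_path("01_simulation_summary.tsv")
    summary.to_csv(out, sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"\nStudy system written under {outdir}; summary in {out}")


if __name__ == "__main__":
    main()
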