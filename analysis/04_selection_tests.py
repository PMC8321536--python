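"""Purifying selection on synonymous polymorphism.

Counts the synonymous codon changes segregating in coding sequence,
compares their within-codon proportions to the mutational expectation,
and correlates the log10 deviations with the relative preference of the
destination codons (the study system generates these SNPs under weaker
purifying selection against changes toward preferred codons, so the
correlation should be positive). Also runs the intronic AT->GC vs GC->AT
derived-allele-spectrum KS test — the direct screen for GC-biased gene
conversion. Writes results/04_syn_snp_table.tsv.
"""

import importlib.util
import os

spec_ = importlib.util.spec_from_file_location(
    "common", os.path.join(os.path.dirname(__file__), "00_common.py")
)
common = importlib.util.module_from_spec(spec_)
spec_.loader.exec_module(common)


def main() -> None:
    args = common.parse_args(__doc__)
    system = common.get_system(args.seed, args.rebuild)
    from codonpref.pipeline import (
        analyze_preference,
        analyze_selection,
        analyze_spectrum,
    )

    spec_res = analyze_spectrum(system)
    pref_res = analyze_preference(system, spec_res["gc_eq"])
    res = analyze_selection(system, pref_res["pref"], spec_res["spectrum"])

    table = res["syn_table"]
    cols = ["source", "target", "nt_change", "f_i", "m_j", "p_hat",
            "exp_within", "obs_count", "obs_within", "log10_dev", "rel_pref"]
    table[cols].to_csv(common.results_path("04_syn_snp_table.tsv"),
                       sep="\t", index=False)
    corr = res["correlation"]
    print(f"{len(table)} multi-option synonymous mutation classes; "
          f"{len(table.attrs['zero_replaced'])} zero counts replaced by one.")
    print(f"Polymorphism-preference correlation: R = {corr.r:.3f} "
          f"(p = {corr.p:.2g}); RMA line slope {corr.rma_slope:.3f}.")
    print("Positive R: mutations toward preferred codons segregate more "
          "freely than the mutational expectation — purifying selection on "
          "codon choice.")
    print(f"\nIntronic derived-allele spectra, AT->GC (n={res['n_at_gc']}) vs "
          f"GC->AT (n={res['n_gc_at']}): KS D = {res['ks_d']:.3f}, "
          f"p = {res['ks_p']:.3f} — no gBGC signal, as constructed.")


if __name__ == "__main__":
    main()
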