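"""Estimate the mutation spectrum and equilibrium GC from noncoding SNPs.

Polarizes the noncoding SNPs by allele frequency, builds the per-site
12-class relative mutation-rate matrix, derives the equilibrium GC
content, and runs the six-class chi-square comparison of SNPs in introns
of the most highly expressed genes against the genome-wide noncoding
expectation. Writes results/02_spectrum.tsv and prints the headline
numbers with their generator truths.
"""

import importlib.util
import os

spec_ = importlib.util.spec_from_file_location(
    "common", os.path.join(os.path.dirname(__file__), "00_common.py")
)
common = importlib.util.module_from_spec(spec_)
spec_.loader.exec_module(common)

import pandas as pd


def main() -> None:
    args = common.parse_args(__doc__)
    system = common.get_system(args.seed, args.rebuild)
    from codonpref.pipeline import analyze_spectrum
    from codonpref.spectrum import collapse_six_classes

    res = analyze_spectrum(system)
    spec = res["spectrum"]
    frame = spec.to_frame()
    frame["rate_truth"] = [
        system.cfg.mutation_rates[(r["from"], r["to"])]
        for _, r in frame.iterrows()
    ]
    frame.to_csv(common.results_path("02_spectrum.tsv"), sep="\t", index=False)

    six = collapse_six_classes(spec)
    print("Estimated mutation spectrum (12 directed classes):")
    print(frame.to_string(index=False))
    print("\nSix strand-symmetric classes:",
          {k: round(v, 4) for k, v in six.items()})
    print(f"\nGC_eq estimated: {100 * res['gc_eq']:.2f}%  "
          f"(generator truth {100 * res['gc_eq_truth']:.2f}%)")
    print(f"Max per-class rate error: {res['max_rate_error']:.4f} "
          f"from {res['n_polarized']} polarized SNPs")
    print(f"\nIntrons of the 1,000 most expressed genes vs genome background: "
          f"chi2 = {res['intron_chi2']:.1f} (df=5), p = {res['intron_chi2_p']:.3f} "
          f"on {res['n_top_intron_snps']} SNPs — no mutational difference "
          f"detected, matching the neutral construction.")


if __name__ == "__main__":
    main()
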