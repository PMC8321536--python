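"""The five-part gBGC screen plus the transcript-stability regression.

Runs sliding-window GC, the coding-vs-noncoding window regression, the
recombination-GC correlation (log rho with offset), proximal/distal
chromosome-half t-tests, intron-exon GC regressions, and the regression
of per-site folding stability on the partitioned gene-level preference.
The study system is generated without gene conversion and with an
independent recombination map, so every gBGC diagnostic should be null
while the stability link is real. Writes results/07_gbgc.tsv.
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
    from codonpref.pipeline import (
        analyze_gbgc,
        analyze_preference,
        analyze_spectrum,
        analyze_trna,
    )

    spec_res = analyze_spectrum(system)
    pref_res = analyze_preference(system, spec_res["gc_eq"])
    trna_res = analyze_trna(system, pref_res["pref"])
    res = analyze_gbgc(system, trna_res["partitioned"])

    w = res["window_regression"]
    rho = res["rho_gc"]["genome"]
    prox = res["proximal_distal"]
    ie = res["intron_exon"]
    st = res["stability_fit"]
    rows = [
        ("coding_vs_noncoding_gc_r2", w.r_squared, w.n),
        ("recombination_gc_r2", rho.r_squared if rho else float("nan"),
         rho.n if rho else 0),
        ("proximal_distal_gc_total_t", prox["gc_total"][0], len(res["genes_df"])),
        ("proximal_distal_gc_total_p", prox["gc_total"][1], len(res["genes_df"])),
        ("proximal_distal_gc3_t", prox["gc3"][0], len(res["genes_df"])),
        ("intron_exon_gc3_r2", ie["gc3"].r_squared, ie["gc3"].n),
        ("intron_exon_gc_total_r2", ie["gc_total"].r_squared, ie["gc_total"].n),
        ("stability_partial_r2_trna_dep", st.partial_r2_dep, st.n),
        ("stability_partial_r2_trna_indep", st.partial_r2_indep, st.n),
    ]
    frame = pd.DataFrame(rows, columns=["quantity", "value", "n"])
    frame.to_csv(common.results_path("07_gbgc.tsv"), sep="\t", index=False)
    print(frame.to_string(index=False))
    print("\nAll five gBGC diagnostics are null (no coupling of coding and "
          "noncoding GC, no recombination-GC association, no chromosome-half "
          "or intron-exon structure), while per-site transcript stability "
          "tracks the tRNA-independent preference component "
          f"(partial R^2 = {st.partial_r2_indep:.2f}; generator link "
          f"R^2 = {res['stability_true_r2']:.2f} before estimation "
          "attenuation).")


if __name__ == "__main__":
    main()
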