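# codonpref

Quantifying **adaptive codon preference** — the component of codon usage
bias attributable to natural selection rather than mutation — and testing
it against segregating polymorphism, tRNA pools, gene position and
GC-biased gene conversion (gBGC) diagnostics.

## The problem

Synonymous codons are used unequally. In most genomes it is hard to say
how much of that bias is *selected*, because mutation pressure, GC-biased
gene conversion and selection all push base composition around. In an
extremely AT-rich genome with no detectable gBGC (the motivating system is
the social amoeba *Dictyostelium discoideum*, ~22% GC, 67 sequenced
strains), the neutral expectation can be built directly from the mutation
process, and any residual codon-usage structure can be read as selection.

The package implements that programme end to end and validates every
estimator on synthetic genomes with known ground truth:

1. **Mutation spectrum.** Biallelic noncoding SNPs are polarized by allele
   frequency (major allele ancestral). Counts of the 12 directed changes
   x→y, scaled per surveyed site and renormalized, give relative mutation
   rates m. Sueoka's relation yields the equilibrium GC content

   GC_eq = (AT→GC) / (AT→GC + GC→AT),

   summing the per-site rates of the interclass changes.
2. **Neutral codon frequencies.** At GC_eq with independent sites,
   E[f(codon)] is the product of its three nucleotide frequencies;
   rescaling within each amino acid gives neutral relative synonymous
   frequencies for the 59 codons with synonymous alternatives (stops, Met,
   Trp excluded). A translation-free "pseudocodon" null (triplets of
   noncoding sequence in all three frames) cross-checks the model.
3. **Adaptive preference.** pref(c) = log2 f_obs(c) − log2 f_exp(c),
   the log fold change of relative usage from neutrality. Variants:
   gene-level means, class-private vectors, and expression-associated
   preference (high- vs low-expression classes, no neutral model).
4. **Polymorphism test.** For each of the 114 synonymous point mutations
   whose source codon has ≥2 options, the expected SNP share is
   p̂_ij ∝ f_i·m_j. Within-codon log10(observed/expected) deviations are
   correlated with the relative preference of the destination codons:
   a positive correlation means changes toward preferred codons segregate
   more freely — purifying selection on codon choice.
5. **tRNA partition.** Absolute adaptiveness W_i from tRNA gene copies
   with standard wobble penalties; w_ij = W_i / max within the amino acid;
   OLS of preference on √w_ij splits it into tRNA-dependent (fitted) and
   tRNA-independent (residual) components.
6. **Positional profiles.** Mean preference and synonymous SNP density by
   codon position from the start and stop codons (first/last 250 codons),
   recovering the 5′ "ramp" of reduced preference.
7. **gBGC screen.** Sliding-window GC, coding-vs-noncoding GC regression,
   log-recombination–GC correlation, proximal/distal chromosome halves,
   intron–exon GC regressions, and the AT→GC vs GC→AT derived-allele
   Kolmogorov–Smirnov test; plus regression of per-site transcript
   folding stability (ΔG⁰/length) on the partitioned preference.

The synthetic-data generator (`codonpref.simulate`) is first-class: it
emits FASTA/GFF3/VCF/TSV with an AT-rich genome, SNPs drawn from a
configurable mutation matrix with a neutral 1/i site-frequency spectrum,
codon usage perturbed by an injected preference vector (with expression,
sociality and positional-ramp structure), and truth tables for every
injected quantity.

## Worked example

```python
import numpy as np
from codonpref.pipeline import build_study_system, analyze_spectrum, analyze_preference

system = build_study_system(seed=1)          # 2,000 genes, 50,000 SNPs
spec = analyze_spectrum(system)
pref = analyze_preference(system, spec["gc_eq"])
print(f"GC_eq {100*spec['gc_eq']:.2f}% (truth {100*spec['gc_eq_truth']:.2f}%)")
print(f"neutral model explains {100*pref['neutral_fit_r2']:.1f}% of codon usage")
print(f"injected preference recovered with r = {pref['recovery_r']:.3f}")
```

prints

```
GC_eq 12.28% (truth 12.20%)
neutral model explains 84.8% of codon usage
injected preference recovered with r = 0.999
```

meaning: the mutation spectrum rebuilt from 50,000 simulated noncoding
SNPs implies an equilibrium GC within 0.1 percentage points of the
generator's matrix; mutation–drift balance alone explains ~85% of the
variation in relative synonymous codon usage of this AT-rich genome; and
the log2 deviation from that null recovers the injected selection vector
almost exactly.

The numbered drivers under `analysis/` run the full study narrative on
the same system (`python analysis/01_simulate_genome.py`, then 02–07 in
any order) and write their tables under `results/`; large intermediates
go to `scratch/`.

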