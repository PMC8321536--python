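# Methods

This note records the models, parameter choices and numerical decisions
behind `codonpref`, and what the synthetic-data validation does and does
not establish.

## Mutation spectrum and equilibrium GC

SNPs from putatively neutral sequence (introns + intergenic) are
polarized by frequency: the major allele is ancestral, the minor derived.
Ties are excluded rather than guessed — any tie-breaking rule would bias
the spectrum's symmetry. No derived-frequency cutoff is imposed by
default; `build_spectrum` consumes whatever polarized set it is given.
Rates are per-site: counts of x→y divided by the number of surveyed x
sites (ambiguity codes excluded from both numerator and denominator),
renormalized to sum to 1 over the 12 directed classes. Spectra built from
fewer than 1,000 SNPs trigger a warning (12 estimated classes need
thousands of observations for stability).

Equilibrium GC follows Sueoka's flux-balance ratio, which is invariant to
rescaling of the rates. All 12 directed classes are retained wherever the
reference strand is known; the six-class strand-symmetric collapse is
used only for SNP sets that cannot be assigned to strands (the intron
chi-square comparison, df = 5).

The intron comparison scales expected counts to the target's total SNP
count, so only the *profile* of mutational classes is tested, not the
overall polymorphism level.

## Neutral codon model

Default mode is strand-symmetric: f(G) = f(C) = GC_eq/2 and
f(A) = f(T) = (1−GC_eq)/2; codon expectations are products of the three
base frequencies, renormalized within amino acids. A `stationary` mode
solves πQ = 0 for the full 4-state rate matrix and is preferred when the
spectrum is visibly strand-asymmetric; for a strand-symmetric matrix the
two coincide (asserted in tests).

Pseudocodon frequencies count triplets in all three frames *per contig*
(never across concatenation junctions — the O(1) chimeric triplets a
global concatenation would add are not worth the frame bookkeeping).
Triplets containing ambiguity codes are skipped.

## Adaptive preference

pref(c) = log2(obs_rel) − log2(exp_rel) on the 59 analyzed codons. No
pseudocounts anywhere in the preference path: a zero observed frequency
propagates as a flagged NaN, and downstream consumers either skip the
codon (gene-level means, positional profiles, with renormalization) or
refuse to proceed (within-codon relative preference). The only zero
handling in the package is the explicit observed-SNP-count rule below.

Gene-level preference is the occurrence-weighted mean over a gene's
analyzed codons (each codon occurrence counts once); averaging the
distinct codon values instead would weight rare codons up and is not what
"preference of the codons within a gene" naturally means. Expression
classes are the top/bottom 1,000 genes ranked by normalized expression
after removing conditionally expressed ("sociality") and zero-expression
genes; ties break by gene id. The sociality/nonsociality contrast is a
pooled-variance two-sample t-test (Welch available via `equal_var`).

## Polymorphism–preference test

Expected proportions p̂_ij = f_i·m_j / Σ f_i·m_j over the 114
multi-option synonymous mutations (the 134-mutation full set is available
but carries no within-codon signal for single-option sources). Observed
counts come from CDS SNPs: the codon holding the major allele is the
source, strand-corrected — the same polarization rule as noncoding
sequence. Observed zero counts are replaced by one (flagged); this is the
one deliberate departure from "no pseudocounts", needed for the log
deviations, and its effect is reported by the zero-replacement log.

The correlation is Pearson on log10(obs/exp) vs within-codon-centered
preference; the plotted best-fit line is reduced major axis
(slope = sign(r)·sd_y/sd_x) and never feeds inference.

Two calibration facts, established during validation and respected by the
null tests: (i) conditionally on one genome, the finite-count bias of the
log deviation correlates with that genome's relative-preference vector,
so null calibration must redraw the genome each replicate; (ii) genomes
much smaller than ~1,000 genes leave a small negative bias (≈ −0.015 at
300 genes) in the null correlation — the null helper therefore simulates
1,000-gene genomes, close to the default study scale.

The KS comparison of AT→GC vs GC→AT derived-allele frequencies uses
scipy's two-sample test. With ~67 strains the frequency support is
discrete, which makes the KS p-value conservative under ties; the null
suite therefore checks exact uniformity only on continuous spectra and
type-I-error control on the discrete one.

## tRNA adaptiveness

W_i sums (1−s)·copies over the Watson–Crick decoder and the single
standard wobble decoder of each codon, with the usual tAI penalties
(G:U 0.41, I:C 0.28, I:A 0.9999, U:G 0.68, Watson–Crick 0), all
configurable. Codons left with W ≈ 0 (< 1e-6) by a copy table are pulled
to the geometric mean of the positive values before computing
w_ij = W_i/W_max(amino acid); the replaced codons are recorded so the
count is checkable. The preference partition is OLS of pref on √w_ij
with intercept; the fitted value (including the intercept) is the
tRNA-dependent component, the residual the tRNA-independent one, so the
two sum to the total exactly and the residuals are orthogonal to the
predictor by construction.

## Positional profiles

Position 1 is the first codon after the initial Met; from-stop position
−1 is the codon before the stop. Both windows cap at 250 codons, and a
gene's codons are excluded from the from-stop window whenever they also
lie in its first 250 codons, so no codon is counted twice even in genes
shorter than 500 codons (the excluded fraction is recorded). Frequencies
are codon-occurrence weighted; gene-weighted profiles would be dominated
by positional attrition of short genes in a different way, and the
occurrence convention matches the pooled-usage convention used
everywhere else. Per-position mean preference is reported as a deviation
from the genome-wide (usage-weighted) mean.

The 5′ ramp's zero crossing is estimated from an isotonic (monotone
nondecreasing) fit of the per-position deviations: the profile approaches
zero tangentially, so the raw first sign change is noise-dominated
(errors of tens of positions at 2,000 genes), while the shape-constrained
crossing is stable to ±a few positions. Any display smoothing (the
LOESS-style curves of figure-making) is presentation only; the TSVs hold
raw per-position estimates.

Expected SNP share by position is proportional to surveyed codons ×
average mutation rate out of the position's base composition; deviations
(obs − exp shares) sum to zero by construction.

## gBGC screen and stability

Window GC uses cumulative sums with overall/coding/noncoding restriction;
a label with fewer than 10% informative bases in a window is flagged NaN.
Percentile-based peak masking (default 5th/95th of noncoding GC) emits a
BED-like frame consumed by the regression step. ρ is an input track; the
module only applies the +1e-6 offset (admitting ρ = 0 windows) before the
log and correlates with window GC, genome-wide and per chromosome;
constant inputs yield a flagged None rather than a number. Gene GC
measures (total, GC3, intronic) are log10-transformed before the
proximal/distal t-tests and intron–exon regressions.

Stability: ΔG⁰ is an input per-gene scalar; the module computes
ΔG⁰/CDS-length and regresses it on the two gene-level preference
components, reporting each predictor's partial R²
((SSE_reduced − SSE_full)/SSE_reduced).

## Synthetic study system

The generator's defaults are the study conditions: 2,000 genes on six
chromosomes, 67 haploid strains, a strand-symmetric mutation matrix with
GC_eq ≈ 12.2% (transition rates toward AT dominating, A→C at 0.01 and
A→G at 0.04 matching the within-codon worked example), log-normal gene
lengths around 380 codons (min 180 — above the 500-bp analysis filter),
Poisson(1) introns of ~100 bp at codon boundaries, ~400-bp intergenic
spacers, log-normal expression, 20% sociality genes with selection
intensity halved, a 120-codon 5′ ramp starting at 30% intensity, 50,000
noncoding SNPs and 10,000 synonymous coding SNPs.

The injected preference is N(0, 0.7²) per codon — or, in the default
pipeline system, a + b·√w_ij + noise (b = 2.8, sd = 0.54) so that the
tRNA-predictable share of preference lands near 40% *after* the
within-amino-acid centering that identifiability requires (centering
removes the cross-family √w_ij component, which is why the raw slope is
larger than the target share suggests). Preference vectors are always
centered within amino acids: the within-family renormalization of codon
frequencies makes any per-family constant unobservable.

SNP placement: site probability ∝ mutation rate out of the site's base;
derived allele ∝ conditional rates; derived count from a 1/i neutral SFS
truncated at ⌊(n−1)/2⌋ so the derived allele is always the minor allele
and frequency polarization is exact. The selection mode tilts synonymous
class counts by exp(β·rel_pref), β = 0.75 in the demo system — enough to
produce a clearly positive correlation at 10,000 SNPs without saturating
it. The stability link sets per-site ΔG⁰ = α·(gene tRNA-independent
preference) + noise at a 0.4 variance-explained target; the recovered
partial R² from *estimated* components is attenuated (~0.18 at the
default scale) because estimation replaces the true components — the
machinery itself recovers the constructed R² within ±0.05 when the
regressors are the constructed ones.

What the synthetic system does **not** emulate: linkage and demographic
structure (SNPs are exchangeable draws, not a coalescent with
recombination), context-dependent (di/trinucleotide) mutation, indels and
slippage (hence the pseudocodon null fits near-perfectly here, far better
than it would on real repeat-rich sequence), splice-site constraints,
and real tRNA biology beyond gene-copy counts. Passing recovery tests
therefore shows the estimators are correct and calibrated under the
stated model, not that the model captures every force in a real genome.

## Interface conventions

Coordinates are GFF3 1-based closed on disk, 0-based half-open in memory.
VCFs carry haploid per-strain genotypes (clonal isolates). The numbered
scripts under `analysis/` plus the library functions are the interface;
no console-script CLI is shipped — every step is importable, which is
what the tests and the acceptance script rely on. Genes with annotation
inconsistencies (frame, internal stops) are flagged and excluded, never
repaired.
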