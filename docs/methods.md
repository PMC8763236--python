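# Methods

This note documents the models and procedures implemented in `isburst`, the
parameters that matter, the numerical choices, what the synthetic-data
generators do and do not emulate, and the known limitations.

## Duplicate dating by codon counting (NG86)

Pairwise dS/dN uses the Nei–Gojobori (1986) counting framework. Synonymous
site counts per codon are the per-position fractions of the three possible
single-base changes that preserve the amino acid (bacterial/archaeal code,
table 11), averaged over the two sequences, so S + N = 3 × (compared codons)
exactly; changes that create a stop codon count as nonsynonymous sites. For
codons differing at two or three positions, observed synonymous and
nonsynonymous differences are averaged over all orderings of single-base
steps, excluding paths that pass through a stop codon (if every ordering is
blocked, the exclusion is lifted for that codon — a degenerate case that
essentially never arises in transposase comparisons). Proportions pS, pN are
corrected for multiple hits with the Jukes–Cantor transform
d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 is outside the correction domain and sets a
saturation flag with d undefined. Counting methods and maximum-likelihood
codon models give comparable but not identical estimates; results here are
meant to be compared with other counting-based analyses, not reproduced
bit-for-bit against ML estimators.

Pairs with unequal CDS lengths are codon-aligned by threading the nucleotide
sequences through a global BLOSUM62 protein alignment (gap open −11, extend
−1). Frameshifted pseudogene copies cannot be codon-aligned and are excluded
from divergence pairs (counted in logs); family-level summaries therefore
describe the alignable copies.

## Paralog clustering and family annotation

Clustering is single linkage over the pairwise relation "global-alignment
identity ≥ 50 % of the shorter sequence AND aligned coverage ≥ 50 % of the
target (either direction)" — thresholds chosen to capture transitive
clusters of homologs, with alignment by Biopython's `PairwiseAligner`
(BLOSUM62, affine gaps 11/1). Single linkage is deliberate: paralog families
in heavily duplicated genomes are transitive chains of similarity. Output is
deterministic (lexicographic tie-breaks; representative = longest member).

Family annotation scores each query against a user-supplied reference
transposase set with local alignment and converts scores to E-values under
fixed Karlin–Altschul parameters (λ = 0.267, K = 0.041, the standard gapped
BLOSUM62/11/1 values); the cutoff E ≤ 10⁻⁹ is only meaningful under a
declared model, which is why the parameters are pinned in code. Queries
without a qualifying hit are "unclassified" — the behaviour that surfaces
novel elements absent from the reference set.

## Ambiguity-aware expression quantification

Reads are recruited to a paralog cluster by substitution-only end-to-end
matching (≤ 3 mismatches, either strand; no indels). This is a deliberate
simplification of a two-stage mapper+BLAST workflow: since per-gene
disambiguation requires a perfect full-length match anyway, exact
substitution matching makes `classify_ambiguity` exact and testable. An
exact pigeonhole k-mer prefilter (k = 18; with ≤ 3 substitutions one of 4
disjoint read k-mers must match exactly) keeps recruitment fast without any
approximation. Reads tied across clusters at equal mismatch count are
dropped and counted in a log rather than fractionally assigned. Strand is
resolved against the protocol: under RF (dUTP, the default), a read aligning
to the reverse complement of a gene derives from a sense transcript.

Per-strand TPM is computed per replicate (rate_i = count_i/length_i[kb],
TPM_i = 10⁶·rate_i/Σrate_j) and replicate means/SDs are taken afterwards.
Cluster effective length is the longest member's length. Both choices are
conventions; alternatives (average member length, pooled-then-normalized
replicates) would shift cluster TPMs by a few percent but not the IS share
of the transcriptome, which is count-based.

## Insertion calling

A junction-supporting read splits into a reference-matching segment and an
element-terminus-matching segment, each ≥ m = 12 bases with ≤ 1 mismatch.
Detection anchors an exact 12-mer at the reference end of the read; because
the maximal mismatch-tolerant reference extension can overshoot the true
split by swallowing element bases, split points are scanned downward from
the maximal extension and the longest-reference split wins (deterministic
coordinates). m = 12 gives a ~1-in-4¹² random-match rate per anchor, so a
100–150 bp read supports a junction with high specificity.

Element orientation is read from which terminus matched. Overhangs that lie
entirely within the terminal inverted repeat match both orientations; such
reads still support the junction and are attached to the oriented evidence
group at the same coordinate when it is unique, but cannot themselves orient
the element.

Left and right junction groups pair when they share contig/family/
orientation and their coordinates imply a duplication length |k| ≤ 20 (the
`max_tsd` window); k = a − b + 1 with a the last reference base before the
element and b the first after it. k > 0 yields the TSD sequence, k = 0 a
blunt junction, k < 0 a TARGET_DELETION flag. The reported site is the first
TSD base, 1-based, forward strand.

The frequency estimator is f = (f_L + f_R)/2 with f_side = J/(J+S), J the
junction reads and S the reference-spanning reads crossing that boundary
with ≥ m bases on each side. It is unbiased for the realized fraction of
junction-covering reads from the insertion-bearing genome; against the
nominal population frequency it additionally carries the binomial sampling
noise of the read pool (SD ≈ √(p(1−p)/(2·d·(1−(2m−2)/L))) ≈ 0.04 at p = 0.5,
depth d = 100, read length L = 100). Truth-recovery tests therefore compare
f to the realized read-pool composition recorded in the simulator's truth
table — the quantity the estimator actually estimates — and bound the
nominal-frequency error by its sampling distribution.

Candidate calls are never silently dropped: sub-cutoff frequency (< 2 %),
low support (< 2 junction reads) and single-sided evidence are emitted with
explanatory statuses. The Fisher strand-representation test (two-sided,
exact) and the one-sided two-sample Kolmogorov–Smirnov quality test
(alternative: junction-supporting base qualities stochastically lower; exact
p for both n ≤ 25) annotate calls at p < 0.01; they demote a call only in
`--strict` mode, mirroring a workflow in which flagged calls are inspected
rather than auto-rejected.

## Trajectories

Calls merge across timepoints when family, contig and orientation match and
sites agree within 5 bp (allele matching tolerance; configurable). Undetected
timepoints are null, not zero: population sequencing cannot distinguish
absence from presence below the detection cutoff. "Fixed" means final
frequency ≥ 0.95, encoding fixed-or-near-fixation; "lost" means previously
detected but below 2 % (or undetected) at the final timepoint. The Muller
nesting heuristic (B nests in A iff B's frequency never exceeds A's at
shared timepoints and B arises no earlier) is best-effort: exact genealogy
requires clone sequencing, and siblings whose summed frequency exceeds their
parent are clipped with a warning rather than silently rescaled.

## Growth models

The two-phase model is OD(t) = a·e^{rt} up to a breakpoint t\*, then a
continuous linear segment with slope m. Both phases are two-parameter OLS
fits — the exponential by log-linear regression, which is deterministic and
initialization-free (under strongly heteroscedastic noise a nonlinear fit
would weight points differently). t\* minimizes the summed SSE of the two
fits over observed timepoints with ≥ 4 points per side (ties → earliest);
purely linear data pin t\* at the earliest admissible point with a
degeneracy flag. Optical densities at or below the noise floor carry no
log-scale information; the simulation studies exclude points below 0.01 OD
before fitting, and with that floor the exponential rate is recovered to
within 5 % (median over 200 noisy replicates at noise SD 0.005). The linear
slope inherits an upward bias when the breakpoint lands one interval early
(late-exponential curvature leaks into the linear window) — a known
limitation of SSE-based segmentation on coarse 48-h sampling.

The ancestor comparison defaults to a one-sample one-tailed t of the evolved
per-population means against the ancestor point estimate (alternative:
evolved > ancestor); a Welch two-sample mode is available when ancestor
replicates exist, and the mode used is recorded in the output. The
rate-on-fixed-insertions regression reports Pearson R with
F = R²(n−2)/(1−R²) on (1, n−2) df and its upper-tail p.

## Synthetic-data generators

The generators emulate the study conditions end to end: a multi-contig
genome with 47.5 % GC coding and 41.5 % GC noncoding sequence; an IS family
planted at nine copies, exactly one intact and the rest carrying single-base
frameshift deletions (hence premature stops in the shifted frame); 14-bp
terminal inverted repeats and 8-bp target-site duplications; copy-and-paste
transposition with target weight ∝ exp(β·AT-fraction of the 8-bp window),
with β calibrated by root-finding so the expected TSD GC matches a chosen
value (27 % against the ~41.5 % noncoding background); serial transfer at
150-fold dilution (log₂150 ≈ 7.23 generations/cycle, 7 integer WF
generations per cycle) with multinomial reproduction, phase-specific
selection applied per generation, Poisson transposition mutations, and a
hard bottleneck each transfer; paired-end reads with i.i.d. substitution
errors and Phred+33 qualities encoding the error rate; stranded (RF)
RNA-seq with a configurable antisense fraction; and exponential-then-linear
growth curves with Gaussian measurement noise.

Deliberate simplifications, hence what passing tests do not show about real
data: no indel sequencing errors or quality-score profiles, no PCR
duplicates, no replicative (cut-and-paste) transposition, no ectopic
recombination between IS copies, uniform fragment coverage (no GC bias),
and insertions are only planted at sites outside existing element copies
(±150 bp) — insertions into a repeated element cannot be placed uniquely by
flank sequence and are not modelled. The bottleneck default for simulations
is 10⁴ cells (desk scale); the experimental value of ~4.5×10⁵ is supported
but slower. The TSD length default k = 8 is a convention of this package;
it is configurable per family. Within-cycle demography (lag/exponential/
linear cell counts) is not observed in serial-transfer experiments, so the
phase-specific fitness weighting w = (1+s_e)^{g_e}(1+s_l)^{g_l} with
g_e = g by default is this package's construction.

## Problem sizes used in the shipped studies

The test and acceptance simulations run at desk scale, chosen so the whole
suite completes in minutes on one CPU while keeping every statistical check
well-powered: 20–60 kb genomes, 100× read depth over ~10 kb loci for
calling (20 replicate insertions spanning frequencies 0.05–0.95), 2,000
Wright–Fisher replicates at bottleneck 100 for the neutral fixation check,
10⁵ stranded reads × 5 replicates for the 2 % IS-share recovery, 200-curve
growth simulation studies, and 10,000 replicates for the t-test type-I-error
calibration.
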