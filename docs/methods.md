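# Methods

This note documents the models and procedures implemented in `mycoreg`, the
defaults chosen where the underlying conventions are genuinely open, and
what the synthetic-data tests do and do not demonstrate.

## TAP-MS prey scoring and complex membership

A pulldown experiment yields, per run, the set of identified proteins and
the number of distinct peptides for each.  Reliability filtering keeps a
prey only if it appears in the intersection of all tagged biological
replicates (a union mode is available for exploratory use) and in none of
the untagged-control runs.  The filter output is therefore a subset of
every tagged replicate and provably disjoint from every control set; both
properties are asserted as tests.

Abundance is estimated with emPAI = 10^(N_observed/N_observable) − 1.
`N_observed` is interpreted as distinct peptide sequences, not spectral
counts, matching how PAI was originally defined and how per-run peptide
tables are usually exported.  `N_observable` comes from an in-silico
tryptic digestion: cleavage C-terminal to K or R unless the next residue is
proline, zero missed cleavages by default, counting distinct peptides with
monoisotopic mass in [500, 3000] Da and length ≥ 6 residues.  These window
defaults follow common emPAI practice; mass-filter conventions vary between
tools, so all of them are configurable, and absolute emPAI values should
only be compared within a consistent parameterization.  Cysteine
carbamidomethylation is excluded from peptide mass by default (flag to
enable).  A protein whose digest yields no observable peptide is unscorable
and raises an error rather than scoring zero.

Ranking is by descending emPAI with competition ("1224") rank numbers:
equal scores share a rank, and ties are ordered lexicographically by
protein id for determinism.

Membership classification formalises the exclusivity argument used to
split two complexes that share a core: a prey detected (post-filter) with
baits belonging to ≥2 complexes is *shared*; detected with ≥1 bait of
exactly one complex and zero baits of any other complex it is *specific* to
that complex (a stricter all-baits variant is available); detected with no
bait it is *unassigned*.  Baits that themselves belong to more than one
complex (for example a core ATPase present in both remodelers) cannot
discriminate specificity and are excluded from the exclusivity test; they
remain available to the prey-by-bait co-purification matrix.  Baits with
unequal replicate counts are filtered over whatever replicates they have;
whether to pool single-sample baits of the same complex is left to the
caller rather than decided by the library.

## Co-regulated cluster calling

The pass predicate is |log2FC| ≥ 1 computed from mean FPKM ratios
(`--require-q` additionally demands Q < 0.05; the printed rule uses fold
change alone, so that is the default).  DEG calls use |log2FC| ≥ 1
(inclusive) and Q < 0.05 (strict).

A cluster is a maximal window that is either (a) ≥6 contiguous passing
genes, or (b) ≥8 contiguous genes containing exactly one non-passing gene
at an interior position.  A failing gene at a window edge is not a gap —
the window is simply shorter.  Genes are ordered by start coordinate within
each chromosome; strand is ignored because physical linkage is positional.
Members may mix directions; each cluster reports an up/down/mixed summary.

The production caller works on the run-length encoding: every pair of pass
runs separated by exactly one failing gene with combined size ≥8 yields a
rule-(b) window, and a pass run of ≥6 not absorbed by such a window yields
a rule-(a) window.  Its reference is an independent brute-force enumeration
of every contiguous window, checked exhaustively for all pass/fail patterns
up to length 20 and on seeded random patterns of length 200.  One
consequence of maximality worth stating: two rule-(b) windows may overlap
in a shared pass run (pattern 6-gap-6-gap-6), so called clusters are not
guaranteed disjoint; both windows are reported.

BGC overlap is "complete" when cluster and BGC gene sets are nested in
either direction (the inclusive reading; directionality is configurable in
principle by comparing the reported spans), "partial" for any other
nonempty intersection.

## Promoter CCAAT analysis

Windows are anchored at the annotated feature start (fungal gene models
frequently lack TSS annotation, so the start codon anchor is the robust
default): for plus-strand genes the `length` bases ending immediately
before the start; for minus-strand genes the `length` bases after the end,
reverse-complemented.  Internally coordinates are 1-based inclusive; BED
output is 0-based half-open.  Windows are clipped at chromosome edges with
a warning.

Scanning reports every CCAAT occurrence (overlaps included) and, by
default, every ATTGG occurrence as a reverse-orientation hit — motif
diagrams in this field mark binding-site direction, so both orientations
count.  Proportions are presence/absence per gene: hit multiplicity is
reported but not weighted.  Whether published genome-wide backgrounds
counted both strands is often unstated; single-strand scanning is available
so both conventions can be reported side by side.

The subset-vs-background comparison is a two-sided exact binomial test,
doubling the smaller tail and capping at 1.  The test is an explicit
methodological addition (the comparison this mirrors was qualitative), and
is cross-checked in tests against direct pmf summation.

## qPCR

Standard curves are ordinary least squares of Ct on log10(copies);
amplification efficiency is 10^(−1/slope) − 1.  Copy numbers invert the
curve and are normalized to a reference gene (actin by convention).

ChIP enrichment uses percent of input.  The input aliquot is a fraction
`f` of the chromatin used for IP, so the input Ct is first corrected by
log2(1/f); with the conventional 0.1 mg input against 1 mg IP this is the
log2(10) correction.  The implementation generalises the constant to any
`f ∈ (0, 1]` with default 0.1.  Efficiency is 2^−ΔCt × 100 with
ΔCt = Ct_IP − (Ct_Input − log2(1/f)).  Replicate aggregation reports
mean ± SD and an unpaired two-tailed Student's t-test (pooled variance, as
"Student's t-test" conventionally means; Welch behind a flag), with
significance stars at 0.05/0.01/0.001.  Ct outliers are never auto-removed.

## Phenotype statistics

EAI is the halo-to-colony diameter ratio.  The radial extension rate Ē is
the least-squares slope of colony radius (half the measured diameter,
converted to µm) against time in hours — fitting radius rather than
diameter because the rate describes one advancing margin.  L_hgu (G) pools
total hyphal length over total tip count across the measured elements
(mean-of-ratios behind a flag).  µmax = Ē/G.  For report parity, rates are
conventionally rounded to one decimal, µmax to two, percentages to one;
library functions return full precision.

Published measurements of this kind are not always internally consistent.
In the study design this package mirrors, the wild-type pair Ē = 385.9
µm/h, G = 62.6 µm implies µmax = 6.16/h, not the reported 4.57/h, and
49.1/385.9 implies an 87.3% reduction rather than the reported 82.7%; the
mutant values (171.1/74.9 → 2.28/h, 49.1/88.1 → 0.56/h, 55.7% reduction)
are self-consistent and are the only ones used as reproduction surfaces.
Similarly, DEG tallies of the form "1440 (754 up, 696 down)" do not add
up; the package reports its own consistent tallies.

## Synthetic data: what it emulates and what it does not

The TAP simulator plants a two-complex truth (defaults: six shared
subunits, six specific per complex — the architecture that motivates the
membership logic) and three tagged replicates per bait.  True co-complex
members are detected independently per replicate with probability
`p_detect_member` (default 0.95); a fixed background pool (default 1000
proteins) contaminates tagged and control runs alike with probability
`p_contaminant` (default 0.05), which is exactly the failure mode that
control subtraction addresses.  Distinct-peptide counts for detected
proteins are Binomial(N_observable, q) clipped to ≥1, keeping simulated
emPAI inside (0, 9] and linking the simulation to the digestion module.
Not emulated: correlated detection between replicates, abundance-dependent
detection, peptide misassignment between homologous proteins, or
bait-expression artefacts — so the ≥95% label-recovery result bounds
performance under independent noise only.

The genome simulator lays genes in disjoint slots along chromosomes so
promoter windows never collide, plants clusters whose members receive
|log2FC| ≥ effect size (≥1) with Q < 0.05 (gap positions get background
values), and draws background log2FC from a Gaussian (SD 0.3) truncated
strictly inside (−1, 1).  The truncation guarantees zero spurious
rule-passes, which is what makes "exact recovery, no false positives" a
meaningful test of the caller rather than of the noise level; real
expression noise does cross the threshold, and on real data the caller's
specificity depends on that rate.  CCAAT planting is Bernoulli per promoter
(motif position uniform, orientation by fair coin); all other promoters are
scrubbed motif-free on both strands, so scan recovery can be compared both
to the planted set (exact) and to the nominal fraction (binomial).

The Ct simulator derives IP Cts from the percent-of-input identity plus
Gaussian cycle noise on the IP channel, so the noise-free table inverts to
the planted enrichment at machine precision.

All generators are bit-reproducible for a fixed seed.

## Problem sizes and numerical choices

The exhaustive caller-vs-oracle sweep covers all ~2.1M pass/fail patterns
of length ≤ 20 (the oracle is numba-compiled for this sweep) plus 1000
seeded random length-200 patterns; interactome recovery uses 20 simulation
seeds × 18 labelled subunits; genome recovery uses 10,000 genes over 8
chromosomes at a planted CCAAT fraction of 0.34 with three planted clusters
(sizes 6, 9-with-gap, 14).  Floating-point ties in emPAI ranking are
resolved by protein id; DEG and cluster thresholds are applied with the
stated inclusivity (≥ for fold change, < for Q) so boundary values behave
exactly as printed.  Degenerate inputs (empty digests, all-zero WT FPKM
without pseudocount, zero-variance standard curves, singleton replicate
groups, clipped promoters) raise or flag rather than silently producing
numbers.

## Known limitations

No probabilistic interaction scoring (SAINT/CompPASS), no FDR over
interactions, no protein inference from shared peptides, no DE testing
(Q-values are consumed, not computed), no PWM motif discovery, no ΔΔCt
relative quantitation, no image analysis.  Absolute emPAI values depend on
the digestion window convention and should not be compared across tools
without matching parameters.
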