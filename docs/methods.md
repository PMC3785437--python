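# Methods

This note documents the models, rules and numerical choices behind each
module, what the synthetic-data generator does and does not emulate, and the
known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Reference library and species delimitation

Distances are uncorrected p-distances with pairwise deletion: alignment
columns where either symbol is a gap or `N` are excluded, and at the
remaining columns two symbols match when their IUPAC sets intersect
(an ambiguous base call is given the benefit of the doubt rather than
inflating divergence). A pair with no comparable column has an undefined
distance; operations that need a full distance matrix raise an error naming
the offending pair. When inputs are not rows of a common alignment, the pair
is first globally aligned (match +1, mismatch −1, gap −2) — a convenience
path only; curated analyses should supply an alignment.

Species are single-linkage clusters cut at a fixed threshold
(`d_species`, default 0.10): two sequences fall in different species exactly
when every path between them crosses a distance **greater than** the
threshold (equality merges). Single linkage is the unique partition with
this between-cluster separation guarantee, which is the natural reading of
"clades separated by more than X%". The cut uses the cophenetic criterion of
`scipy.cluster.hierarchy`; cluster ids are assigned deterministically by
each cluster's lexicographically smallest member, so the partition is
invariant to record order. A second, lower threshold (`d_novel`,
default 0.075) marks the divergence beyond which a query sequence is
treated as belonging to a taxon missing from the library.

## Mini-barcode selection

For a window of `w` alignment columns, every sequence is scored against all
others restricted to the window. A sequence is *correctly identified* when
all of its nearest neighbours at the minimum p-distance are conspecific —
ties that include a heterospecific neighbour count as failure. Singleton
species have no conspecific neighbour; a singleton counts as correct when
its minimum heterospecific distance in the window is strictly positive
(diagnosability). Sequences with no defined distance to any other sequence
in the window are excluded from the denominator; a window where nothing can
be evaluated has undefined success rather than an error. The scan uses step
1 in 1-based inclusive alignment coordinates, and selection returns the
smallest `w` (then smallest start) whose success reaches the requirement
(default 1.0). Absence of such a window is a result (`None`), not an error.
Internally all windows are scored from per-pair cumulative mismatch and
comparable-site counts, so the scan over hundreds of columns takes well
under a second for library-sized inputs; a naive per-window oracle in the
test suite checks the fast path exactly.

## Read preparation

Read model: each amplicon is flanked by a short instrument key, a 10 nt MID
sample tag and the degenerate group-specific primers (forward
`AATTMGGTTGGGGCGACSHW`, reverse `AACATCGAGGTGCCAAWCCC`); reads may come from
either strand.

- **Demultiplexing.** A read is assigned to the unique sample whose MID
  occurs, as an exact 10-mer, immediately 5′ of a complete group-primer
  site; both strands are searched, so a read truncated down to one primer
  is still traceable through the tag at that end. Tags pointing at two
  different samples flag the read ambiguous and unassigned. No tag-error
  correction is attempted: exact matching is conservative and the generated
  tags keep pairwise Hamming distance ≥ 3.
- **Primer matching.** IUPAC-set intersection with 0 mismatches by default
  ("complete primer"); the mismatch allowance is configurable.
- **Trimming.** The read is orientation-normalised (forward primer reading
  5′→3′) and cut to the primer-inclusive amplicon. With both primers found,
  that is forward-primer start to reverse-primer end; with one primer, the
  missing side extends to the read end — honouring the keep-if-at-least-one-
  complete-primer rule literally.
- **Filters**, applied in order with rejects attributed to the first
  failing rule: primer (≥1 complete primer) → length (trimmed length in
  [120, 160], inclusive, applied to the primer-inclusive amplicon,
  consistent with a 134 bp primer-to-primer fragment) → quality (mean Phred
  over the trimmed region **strictly greater** than 30; the mean is used
  because the published rule names a per-sequence score). A read with mean
  quality exactly 30 is rejected.
- **Dereplication** groups identical trimmed sequences dataset-wide and
  discards totals below `c_min = 5` *before* any per-sample analysis —
  matching a "detected less than 5 times in total" rule and acting as the
  only chimera control (a deliberate copy-number proxy; no alignment-based
  chimera detector is run).

## Assignment

BLAST-style search is replaced by exact Smith–Waterman local alignment with
affine gaps (match +1, mismatch −2, gap open −5, extend −2; a gap of length
k costs open + (k−1)·extend). At 134 bp queries against a library of a few
hundred short sequences, heuristic seeding buys nothing and an exact score
makes the E-ratio rule exactly testable. Scores come from Biopython's C
`PairwiseAligner`; the test suite pins them to an independent plain-Python
DP and, at tiny lengths, to an exhaustive enumeration of all local
alignment paths.

E-values use ungapped Karlin–Altschul statistics: λ solves
Σᵢⱼ pᵢpⱼ e^{λ sᵢⱼ} = 1 (uniform background by default) and K comes from the
classical random-walk series
K = e^{−2σ}·δ·λ / (H·(1−e^{−λδ})),
σ = Σₖ k⁻¹ [P(Sₖ ≥ 0) + E(e^{λSₖ}; Sₖ < 0)],
with the closed form (p₋−p₊)²/p₋ when scores are ±1. Computed K values
match NCBI blastn's printed ungapped constants to their displayed precision
(frozen in the tests). Applying ungapped (λ, K) to gapped scores is an
approximation, stated as such; the assignment thresholds sit many orders of
magnitude away from the decision boundary for within-library matches, so
the approximation does not move decisions at these scales. The database
length n is the summed length of all library sequences, and m the query
length.

Per species, the hit is the minimum E over the species' cluster members,
over both query strands. Assignment follows the conservative rules exactly:
one significant species (E < 10⁻⁵) → assigned; several significant species
→ assigned to the best only when best/second < 10⁻⁵ (a tie gives ratio 1
and stays unassigned); otherwise unassigned. `second_e` is recorded only
when a second *significant* species exists, keeping the stored fields
consistent with the rule that produced the status.

Unassigned amplicons whose minimum library distance (computed on a global
alignment, better strand) exceeds `d_novel` are clustered among themselves
at `d_species`; each cluster becomes `novel<k>`, numbered by descending
total amplicon count (then smallest amplicon id) so labels are
deterministic. Amplicons within `d_novel` of the library remain unassigned
— plausibly degraded or erroneous copies of known species.

## Diet statistics

The diet matrix covers every sample in the metadata (all-zero rows are the
"negative" samples) and every library species plus novel species, keeping
all-zero columns. Presence is ≥ 1 assigned amplicon after all filters — the
global ≥5-copy filter has already removed low-copy noise, so no further
per-cell threshold is applied. Occurrence denominators default to positive
samples only (configurable to all samples); the richness "±" is the
standard error of the mean (SD/√n).

Richness is tested with a one-way fixed-effects ANOVA computed from the
sum-of-squares decomposition (degenerate inputs handled explicitly: all
observations identical → F = 0, p = 1; zero within-group variance with
distinct means → flagged degenerate with p = 0). Composition is tested with
PERMANOVA implemented from scratch: SS_total = Σd²/N over the full distance
matrix, SS_within summed per group, pseudo-F = (SS_among/(a−1))/(SS_within/(N−a)),
and p = (1 + #{F_perm ≥ F_obs})/(1 + P) under label permutation, so p has
resolution 1/(P+1) and a floor of the same value. Jaccard on
presence/absence is the default distance (the question is *which* species
were consumed, not how many amplicons each produced; amplicon counts are
poor abundance proxies); Bray–Curtis on counts is available. Samples are
ordered canonically by id before permutation, making p reproducible given
the seed and invariant to input order. The test suite checks the pseudo-F
against scikit-bio's implementation and calibrates the null type-I error.

## Synthetic data

The generator's defaults are the study conditions: 15 prey species with 9
sequences each (135 reference sequences), 134 bp amplicons whose 20 nt
primer flanks are conserved realisations of the degenerate primers and
whose 94 bp core evolves; target intra-/inter-specific divergence 3%/15%
(applied half per branch from a common root, so realised pairwise distances
concentrate near the targets); 46 samples of which ~24% are negative;
per-species inclusion probabilities following the strongly uneven profile
typical of these predators (two species never taken); 250 reads per sample
(≈ the per-sample yield of a pooled pyrosequencing run; validation runs use
500); 0.5% per-base substitution error; 2% chimeras spliced at a uniform
breakpoint; 2% truncated reads (planted length failures — homopolymer
indels are not modelled, so truncation injection is what exercises the
length filter); 2% low-quality reads (mean Phred 25 vs 35, SD 5, clipped to
[2, 40]). Substitution errors are drawn independently of the quality
strings; qualities are exact in the FASTQ round-trip but are not coupled to
error positions. All randomness flows through one seeded PCG64 generator;
outputs are byte-identical across runs and platforms.

What passing tests on these data do **not** show about real data: no PCR
amplification bias or primer-template mismatch bias, no homopolymer indel
errors (the dominant 454 error mode), no quantitative read-abundance
realism, no co-amplified non-target DNA, and chimeras form between
full-length templates only. The recovery metrics are therefore upper bounds
on real-data performance, not estimates of it.

Problem sizes used by the default test suite and the acceptance script —
35–46 samples, 250–500 reads per sample, 135-sequence libraries, 500
PERMANOVA null replicates at P = 199 — were chosen as the smallest scales
at which every planted effect is resolvable with comfortable margins.

## Known limitations

- Ungapped (λ, K) applied to gapped scores (see above).
- Exact-match MID demultiplexing discards reads with tag errors rather than
  correcting them (~rate × 10 per tag end); with Hamming-≥3 tags a
  single-error corrector would be a safe extension.
- The quality filter uses the mean Phred over the trimmed region; a
  per-base minimum would be stricter and is not implemented.
- Novel-taxon detection clusters only the amplicons themselves; it cannot
  split novel clusters that straddle the species threshold through chained
  intermediates, which is inherent to single linkage.
- A chimera whose breakpoint falls before the first (or after the last)
  difference between its parents is sequence-identical to a real template
  and is invisible to any sequence-based filter; the truth-check reports
  this as chimera leak-through rather than hiding it.
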