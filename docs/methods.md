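# Methods

This note records the models, conventions and numerical choices behind
`bcrmrd`, and what the synthetic test substrate does and does not
establish about real data.

## Sequence networks and clonality

Unique sequences are vertices; edges require equal length and exactly one
substitution. The "non-indel" rule is operationalised as an equal-length
requirement: amplicons of different lengths never join, so indel variants
(including real V(D)J length variation) always found separate clusters.
An ambiguous base N is treated as matching nothing, including another N;
consequently a sequence containing N can never gain an edge. This is
deliberately conservative — an N base cannot *support* the single-
nucleotide-difference relation an edge asserts.

Neighbour search hashes every sequence under each of its single-position
deletions (length, position, prefix, suffix); two sequences at
substitution distance 1 collide in exactly one bucket. This is provably
equivalent to all-pairs search and is tested against a brute-force
numpy/scipy-csgraph oracle on hundreds of random repertoires.

The clonality call uses read fraction (not vertex fraction): cluster
reads / total repertoire reads, with the 2.5 % threshold inclusive.
Read fraction is the natural choice because vertex size is defined as
read count and detection sensitivity is a property of reads sampled.
`healthy_percentile` uses the linearly interpolated empirical quantile so
that the threshold is defined for small healthy panels.

## MRD mining

A clonotype signature keeps *all* member sequences of a qualifying index
cluster, not only the dominant one: mining then tolerates up to 8
substitutions from the nearest member, which covers both sequencing error
and further somatic hypermutation of any index variant. Matching uses
equal-length Hamming distance, consistent with the network's edge rule; a
Levenshtein mode (same cutoff, via edlib) exists for indel-tolerant
mining but is off by default, since the substitution-only model is what
the statistics downstream assume. Mined fractions are computed over all
reads of the sample. A sequence matching two signatures of one patient is
assigned to the nearer one (tie → lower clone id), so per-clone fractions
never double-count reads. Detection is defined as ≥ 1 matched read;
counts are reported so users can impose their own limit of detection.

External-assay correlation is an ordinary least-squares R² on
(log₁₀ mined fraction, log₁₀ external measure) over pairs where both are
positive; zero/missing pairs are excluded and counted, and a
zero-variance series returns R² = 0 with a degeneracy flag rather than an
error.

## V/J annotation and stems

V and J genes are called by Smith–Waterman local alignment (match +1,
mismatch −1, gap open −4, gap extend −1) of every germline segment
against the read, with score floors 20 (V) and 10 (J); ties break to the
longer aligned span, then alphabetically. All scores are configurable.
The V boundary is the last read position aligned to the best V gene,
0-based internally. The stem starts exactly 3 bases past that boundary
("3 bp downstream" read as exclusive of the boundary base): those 3 bases
are the ones whose assignment to V versus N-addition is least certain, so
excluding them makes the stem robust to one-base boundary wobble. The
stem is treated as an opaque barcode — D genes are not named.

Stem groups are single-linkage components under equal-length Hamming
distance 1, mirroring the network rule; length-shifted stems (boundary
wobble ± indels) land in separate groups and are reported as such.
Per-stem frequencies count reads (not unique sequences) carrying a member
stem as an exact substring. The healthy background threshold is the 99th
empirical percentile of those per-donor frequencies; a patient
observation counts only strictly above it.

## Clone alignment and parsimony

Members require ≥ 2 observations in at least one sample, suppressing
error singletons. The central BCR is the member with the highest summed
count (tie → lexicographically smallest). Alignment is center-star:
pairwise global alignments to the central BCR (same scoring as above)
merged under "once a gap, always a gap", insertions left-aligned within
their slot. The classical 2× sum-of-pairs bound of center-star alignment
is exercised in the tests against an exact small-case dynamic-programming
oracle. Pre-aligned sequence sets can be supplied directly as
`CloneAlignment` rows.

Parsimony is Fitch counting over five states {A, C, G, T, gap}, N
treated as missing (all four bases). Gap-as-fifth-state makes an indel
cost one step, which is appropriate for the within-clone regime where
indels are rare. The search is stepwise addition (deterministic canonical
order plus seeded random orders, best of 5 starts) followed by
best-found nearest-neighbour-interchange to convergence; the reported
score is the exact Fitch length of the returned topology and the
branch lengths come from a most-parsimonious state assignment, so they
sum to the score. `exhaustive_parsimony` enumerates all unrooted
topologies (feasible to 8 tips) and doubles as the optimality oracle:
on thousands of random ≤ 6-tip instances the heuristic has always
reached the enumerated optimum. Bootstrap support is column resampling
with seeded replicates. Likelihood-based phylogenetics and substitution-
model selection are out of scope; parsimony is used throughout.

## Overlap statistics

Shell populations use N(l, d) = C(l, d)·3^d with l the alignment length.
Shells where N < max(n_diag, n_rel) are infeasible under the
substitution-only model (they must contain indel variants) and are
flagged and skipped. Per-shell tail probabilities P(X ≥ k) are exact:
scipy's hypergeometric survival function for N ≤ 10⁸, and an authored
log-space tail sum above that, factoring the pmf into falling factorials
so no large-argument log-gamma differences occur (the scipy
implementation is impractical at the N ~ 10¹⁶ the combinations formula
produces). Both routes are verified against exact rational pmf summation.
Shells are combined with Fisher's method computed in log space; shells
with members on only one side are reported but excluded from the
combination.

The independent-clone mutation-sharing baseline pools V-gene mutation
positions per cluster of ≥ 7 sequences and compares pairs that share a V
gene but differ in J gene or individual. The shared fraction is
|A ∩ B| / min(|A|, |B|) — for equal-size independent mutation sets of
size m on a V gene of length L its expectation is m/L, which the tests
verify against the collision oracle. The diagnosis–relapse comparison
against this baseline is a one-sided Mann–Whitney test, exact for
combined n ≤ 20 and normal-approximated (tie-corrected) otherwise.

Mutation profiles use the standard pyrimidine-centric 96-context
convention (strand-collapsing purine mutations with reverse-complemented
flanks). Terminal-position and ambiguous-base mutations are excluded and
counted. Profile comparison runs one two-sided Fisher exact test per
context on (context count vs rest) × (profile 1 vs profile 2), reporting
raw and Bonferroni-corrected significance at α = 0.005.

PCR/sequencing-error site analysis defines the true sequence of a control
sample as its most frequent sequence, error sites as the positions where
equal-length variants differ from it, and tests pairwise site overlap
with the same hypergeometric tail at N = sequence length.

## The synthetic substrate

The simulator emulates the study regimes: healthy donors as 1 500
independent V(D)J events (uniform segment usage over a 12 V / 6 D / 4 J
toy locus; geometric N-additions, mean 4; log-normal per-cell read
counts, log-mean 1.0, log-sd 1.0; per-read SHM at 10⁻³ per base), giving
≈ 6 700 reads per donor and largest clusters around 0.5–1.5 %, resampled
(and counted) in the rare draw that reaches 2.5 %. Leukemic clones are
one ancestor (400 reads) with a star-like cloud of 40 variants at
truncated-geometric distances (mean 2, max 8) and read counts
2 + Poisson(2), so variants survive the ≥ 2-observation filter the
member analysis assumes. Clone junctions draw N-additions of at least 4
nt: a clone whose stem is pure germline D + J is degenerate as a barcode
(healthy cells can reproduce it by chance — the false-detection
phenomenon the stem background quantifies), and the secondary-
rearrangement recovery guarantees presume junction-specific stems.
Secondary rearrangements splice strictly locus-upstream V genes onto the
identical tail (80 reads each). Sequencing applies binomial read
sampling at the configured depth and independent per-base substitution
errors at 10⁻³ (indel errors are deliberately absent so that the
Hamming-based modules see their assumed noise model). Dilution series
run to 10⁻⁵ at depth 10⁵ in the standard tests — deeper dilutions obey
the same binomial law but need proportionally more reads than a desk-
scale run warrants.

With hotspot modelling on, mutation positions are weighted ×multiplier
at WRC-C and GYW-G motifs and hotspot substitutions follow AID outcomes
(C>T 2/3, C>G 1/3; mirrored at G): a positional weight alone spreads
over too many trinucleotide contexts to be detectable at realistic
mutation totals, and AID's substitution bias is as much a part of its
signature as its positional preference. The signature comparison is
exercised at ≈ 850 mutations per profile (450 variants), the scale at
which a 96-context comparison has per-context power.

What the simulator does **not** model: gene-usage biases, clonal
birth–death dynamics, PCR amplification bias, primer effects, paired-end
artefacts, quality scores, or indel sequencing error by default. Passing
tests therefore establish the pipeline's correctness under its stated
model (substitution noise, oriented amplicons, star-like clones), not
robustness to every artefact of a real library.

## Determinism and sizes

Every stochastic routine takes an explicit seed or Generator; the
simulator derives an independent child stream per stage from one
mandatory seed, so identical configurations are byte-identical.
Acceptance-style checks use: 100 random repertoires (n ≤ 500) for the
network oracle, 50 random parameter sets plus 1 000 independence draws
for the hypergeometric test, a 5-step dilution series at depth 10⁵,
30 planted secondary-rearrangement studies, 50 parsimony instances
(≤ 6 tips), 100 diagnosis–relapse studies and 20 signature comparisons —
sizes chosen to make sampling error small relative to the tested effects
while staying desk-scale.

## Known limitations

- Center-star alignment is a 2-approximation; for badly indel-scattered
  clones a dedicated MSA tool will produce better columns (pre-aligned
  input is accepted for that case).
- The stepwise+NNI parsimony search is a heuristic; optimality is only
  guaranteed where enumeration is feasible (≤ 8 tips), although it has
  not been observed to miss the optimum on star-like clone data.
- The 2.5 % clonality threshold and ≤ 8-mismatch mining radius are
  calibrated for FR1-length IGH amplicons; other amplicon designs may
  need re-calibration against their own healthy background.
- Mined fractions are relative to all reads in a sample; absolute MRD
  quantification requires an external anchor (cell counts or spike-ins).
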