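# bcrmrd

Clonality detection, minimal-residual-disease (MRD) tracking and clonal
phylogenetics for B-cell receptor (BCR) repertoire sequencing of B-cell
acute lymphoblastic leukemia (B-ALL).

In B-ALL, every leukemic cell carries the heavy-chain V(D)J rearrangement
of its founding B cell, so the rearranged IGH sequence is a clone-specific
barcode. Deep amplicon sequencing of the IGH locus therefore supports
(1) diagnosing clonality, (2) quantifying residual disease in follow-up
samples long after it falls below morphological detection, (3) exposing
secondary V-gene rearrangements that create leukemic subclones, and
(4) asking whether the clone's internal variant structure — its cloud of
somatically hypermutated variants — survives therapy into relapse. This
package implements that full analytical pipeline for researchers working
with IGH amplicon data (or its simulator), with every stage testable
against planted ground truth.

## The method

**Clonality via sequence networks.** Each unique read is a vertex with
size equal to its read count; edges join vertices that differ by exactly
one nucleotide substitution (sequences of unequal length are never
joined). Clusters are connected components and approximate a clone plus
its mutational variants. A sample is *clonal* when its largest cluster
holds ≥ 2.5 % of reads — above the 95th percentile of the largest-cluster
sizes seen in healthy repertoires (≈ 0.5–1.5 % in the simulator's healthy
regime).

**MRD mining.** Every cluster ≥ 2.5 % of the index (diagnostic) sample
defines a *clonotype signature*: the full set of its member sequences.
A sequence in any later sample of the same patient matches when its
equal-length Hamming distance to some signature member is ≤ 8; the
matched read fraction is the MRD estimate at that time point.

**Stem-sequence barcoding.** The *stem* is the N-IgHD-N-IgHJ region
starting 3 bp downstream of the IgHV boundary (called by local alignment
against a germline reference). Secondary rearrangements — an upstream
IgHV gene spliced onto a pre-existing D-J join — leave the stem intact,
so one stem group observed with k + 1 distinct V genes reveals k
V-replacement subclones. Stem frequencies in healthy controls (99th
percentile) and in unrelated patients bound the false-detection rate.

**Diagnosis–relapse structure.** Clone members observed ≥ 2 times are
aligned around the *central BCR* (the most frequent member, the inferred
clone ancestor) by center-star alignment, and related by Fitch maximum
parsimony (stepwise addition + nearest-neighbour interchange; exhaustive
enumeration for small clones). With sequence length *l*, a variant at
distance *d* from the central BCR is one of

    N(l, d) = C(l, d) · 3^d

possible sequences. If relapse re-grew from the central BCR alone, the
k sequences shared between the n_diag diagnosis variants and the n_rel
relapse variants at shell d would follow a hypergeometric draw from
N(l, d); P(X ≥ k) per shell, combined across shells by Fisher's method,
tests whether a *population* of variants survived therapy. Mutation
spectra are profiled in the standard 96-trinucleotide pyrimidine-centric
signature space, with a Mann–Whitney comparison against the
mutation-sharing baseline of independent clones.

## Worked example

Generate a seeded synthetic study (toy germline, healthy donors, one
leukemic clone with a secondary rearrangement, follow-up samples), then
run the pipeline:

```bash
$ bcrmrd simulate --seed 5 --clone-fraction 0.3 --secondary 1 --depth 8000 -o study/
$ bcrmrd network study/index.tsv -o clusters.tsv
largest cluster 22.1250%; clonal (>= 2.50%): True

$ bcrmrd track --index study/index.tsv \
    --samples study/followup_d28.tsv --samples study/followup_d84.tsv -o mrd.tsv
2 signature(s), 2 sample(s) -> mrd.tsv
$ cat mrd.tsv
patient_id  clone_id  sample_id     day  matched_reads  total_reads  fraction  detected
P1          1         followup_d28  28   23             8000         0.002875  True
P1          2         followup_d28  28   1              8000         0.000125  True
P1          1         followup_d84  84   0              8000         0.0       False
P1          2         followup_d84  84   0              8000         0.0       False
```

The index sample is clonal (largest cluster 22.1 % ≫ 2.5 %) and defines
two signatures — the main clone and its planted V-replacement subclone.
At day 28 the main clone persists at 0.29 % of reads (MRD-positive); by
day 84 both clones are undetectable at this depth.

Diagnosis–relapse comparison of a simulated pair sharing 80 % of its
variant cloud:

```bash
$ bcrmrd phylo --diag diag.tsv --relapse relapse.tsv -o clone1/
48 members; overlap 0.805; tree length 85; combined p 6.054e-101
```

80.5 % of the unique diagnosis variants recur at relapse; the combined
hypergeometric overlap p-value (~10⁻¹⁰¹) rejects regrowth from the
central BCR alone, and `clone1/tree.nwk` holds the parsimony tree in
Newick form.

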