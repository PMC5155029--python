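"""Statistical layer: mutational combinatorics, overlap tests and signatures.

The diagnosis-relapse overlap question: if relapse re-grew from the central
BCR alone, variant sequences at substitution distance d from the central
BCR would be drawn afresh from the population of all C(l, d)·3^d possible
variants (length l, any position can mutate to any of three other bases).
Observing k of the n_diag diagnosis variants again among the n_rel relapse
variants is then a hypergeometric draw, and P(X >= k) is the evidence that
a *population* of variants — not just the ancestor — survived therapy.
Shells are combined across d with Fisher's method.

The same machinery quantifies PCR/sequencing-error artifacts: within
control-gene samples the true sequence is the most frequent one, variant
positions are error sites, and pairwise site overlap is tested with the
hypergeometric tail (expected null: no significant overlap).  A baseline
for mutation sharing between genuinely independent clones (same V gene,
different J or different individuals) calibrates the diagnosis-relapse
comparison via a one-sided Mann-Whitney test.  Mutations are also profiled
in the standard 96-trinucleotide pyrimidine-centric signature space.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln, logsumexp

from .clonal_network import build_network, cluster_stats
from .clone_phylo import CloneAlignment, ORIGIN_BOTH
from .errors import AnnotationError, InsufficientDataError
from .repertoire_io import GermlineDB, Repertoire
from .vdj_stem import VdjAnnotator

# ---------------------------------------------------------------------------
# combinatorics and the hypergeometric overlap test


def mutational_combinations(l: int, d: int) -> int:
    """Number of length-l sequences at substitution distance exactly d: C(l,d)·3^d."""
    if not 0 <= d <= l:
        raise ValueError(f"need 0 <= d <= l, got l={l}, d={d}")
    return math.comb(l, d) * 3**d


@dataclass(frozen=True)
class OverlapTest:
    """Hypergeometric overlap test at one distance shell from the central BCR."""

    l: int
    d: int
    N: int
    n_diag: int
    n_rel: int
    k: int
    p_value: float

    def __post_init__(self) -> None:
        if self.k > min(self.n_diag, self.n_rel):
            raise ValueError("shared count exceeds a margin")
        if max(self.n_diag, self.n_rel) > self.N:
            raise ValueError("margin exceeds population size")


def overlap_pvalue(N: int, n_diag: int, n_rel: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, n_diag, n_rel).

    For moderate population sizes the exact scipy survival function is
    used.  Beyond N = 1e8 (where that implementation becomes impractical)
    the tail is summed directly in log space over the (tiny) support above
    k, with the pmf factored as

        pmf(x) = C(a, x) · b!/(b-x)! · ff(N-b, a-x) / ff(N, a)

    with a = n_diag, b = n_rel and ff a falling factorial, so every term
    involves only log-gammas of small arguments and sums of log(N - i):
    numerically stable even when N — the number of possible sequence
    variants — is astronomically large.
    """
    if min(N, n_diag, n_rel, k) < 0 or max(n_diag, n_rel) > N or k > min(n_diag, n_rel):
        raise ValueError(
            f"infeasible hypergeometric parameters N={N}, n_diag={n_diag}, "
            f"n_rel={n_rel}, k={k}"
        )
    if k == 0:
        return 1.0
    if N <= 10**8:
        return float(sps.hypergeom.sf(k - 1, N, n_diag, n_rel))
    a, b = n_diag, n_rel
    lo = max(k, a + b - N)
    x = np.arange(lo, min(a, b) + 1, dtype=float)
    # prefix sums of log(N - b - i): S[m] = sum over the first m factors
    m_max = a - lo
    prefix = np.concatenate([[0.0], np.cumsum(np.log(float(N) - b - np.arange(m_max)))])
    s_x = prefix[a - x.astype(int)]
    log_ff_full = float(np.log(float(N) - np.arange(a)).sum())
    log_choose_ax = gammaln(a + 1) - gammaln(x + 1) - gammaln(a - x + 1)
    log_perm_bx = gammaln(b + 1) - gammaln(b - x + 1)
    log_terms = log_choose_ax + log_perm_bx + s_x - log_ff_full
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def combine_pvalues_fisher(p_values: Sequence[float]) -> float:
    """Fisher's method; computed in log space so tiny p-values survive."""
    ps = [p for p in p_values if not math.isnan(p)]
    if not ps:
        raise InsufficientDataError("no p-values to combine")
    stat = -2.0 * sum(math.log(max(p, 5e-324)) for p in ps)
    return float(sps.chi2.sf(stat, 2 * len(ps)))


def clone_overlap_tests(
    aln: CloneAlignment,
) -> tuple[list[OverlapTest], float, list[int]]:
    """Per-shell overlap tests for one aligned clone plus the combined p-value.

    Shells where the substitution-only population size N falls below a
    margin are infeasible (the shell must contain indel variants) and are
    skipped; their distances are returned as the third element.  Only
    shells with members on both sides enter the combination.
    """
    from .clone_phylo import member_shell

    l = aln.length
    shells: dict[int, dict[str, int]] = defaultdict(lambda: {"n_diag": 0, "n_rel": 0, "k": 0})
    for i, m in enumerate(aln.members):
        d = member_shell(aln, i)
        if d == 0:
            continue
        if m.diag_count > 0:
            shells[d]["n_diag"] += 1
        if m.relapse_count > 0:
            shells[d]["n_rel"] += 1
        if m.origin == ORIGIN_BOTH:
            shells[d]["k"] += 1
    tests: list[OverlapTest] = []
    infeasible: list[int] = []
    for d in sorted(shells):
        rec = shells[d]
        N = mutational_combinations(l, d)
        if N < max(rec["n_diag"], rec["n_rel"]):
            infeasible.append(d)
            continue
        p = overlap_pvalue(N, rec["n_diag"], rec["n_rel"], rec["k"])
        tests.append(OverlapTest(l, d, N, rec["n_diag"], rec["n_rel"], rec["k"], p))
    usable = [t.p_value for t in tests if t.n_diag > 0 and t.n_rel > 0]
    combined = combine_pvalues_fisher(usable) if usable else float("nan")
    return tests, combined, infeasible


# ---------------------------------------------------------------------------
# shared-mutation baseline between independent clones


@dataclass(frozen=True)
class CloneMutationRecord:
    """V-gene mutation positions pooled over one clonal cluster."""

    sample_id: str
    v_gene: str
    j_gene: str
    positions: frozenset[int]


@dataclass
class SharedMutationBaseline:
    fractions: list[float]
    labels: list[str]
    n_records: int


def shared_fraction(a: frozenset[int], b: frozenset[int]) -> float:
    """|A ∩ B| / min(|A|, |B|); 0 when either set is empty."""
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def clone_v_mutation_records(
    reps: Sequence[Repertoire],
    db: GermlineDB,
    min_cluster_size: int = 7,
    annotator: VdjAnnotator | None = None,
) -> list[CloneMutationRecord]:
    """V-gene mutation positions for every cluster of >= ``min_cluster_size`` sequences.

    For each qualifying cluster, members sharing the cluster's best V gene
    are aligned to that germline V and their mismatch positions (in V-gene
    coordinates) are pooled.
    """
    annotator = annotator or VdjAnnotator(db)
    records = []
    for rep in reps:
        net = build_network(rep)
        for stat in cluster_stats(net):
            if stat.n_vertices < min_cluster_size:
                continue
            try:
                dom = annotator.annotate(stat.dominant_seq)
            except AnnotationError:
                continue
            positions: set[int] = set()
            for idx in net.clusters[stat.cluster_id - 1]:
                seq = net.vertices[idx].seq
                try:
                    call = annotator.best_v(seq)
                except AnnotationError:
                    continue
                if call.gene != dom.v.gene:
                    continue
                positions |= v_mutation_positions(seq, dom.v.gene, db, annotator)
            records.append(
                CloneMutationRecord(
                    sample_id=rep.meta.sample_id,
                    v_gene=dom.v.gene,
                    j_gene=dom.j.gene,
                    positions=frozenset(positions),
                )
            )
    return records


def v_mutation_positions(
    seq: str,
    v_gene: str,
    db: GermlineDB,
    annotator: VdjAnnotator | None = None,
) -> set[int]:
    """Mismatch positions (germline-V coordinates) of a sequence against one V gene."""
    annotator = annotator or VdjAnnotator(db)
    vseq = db.v_genes[v_gene]
    aln = annotator._aligner.align(seq, vseq)[0]
    positions = set()
    for (ts, te), (qs, qe) in zip(*aln.aligned):
        for t, q in zip(range(ts, te), range(qs, qe)):
            if seq[t] != vseq[q]:
                positions.add(q)
    return positions


def pairwise_shared_fractions(
    records: Sequence[CloneMutationRecord],
) -> SharedMutationBaseline:
    """Shared-mutation fractions over all independent clone pairs.

    Independent pairs share a V gene but differ in J gene ("same V,
    different J") or come from different individuals ("same V, different
    individuals").
    """
    fractions, labels = [], []
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            a, b = records[i], records[j]
            if a.v_gene != b.v_gene:
                continue
            if a.sample_id != b.sample_id:
                label = "same V, different individuals"
            elif a.j_gene != b.j_gene:
                label = "same V, different J"
            else:
                continue
            fractions.append(shared_fraction(a.positions, b.positions))
            labels.append(label)
    if not fractions:
        raise InsufficientDataError("no independent clone pairs with a shared V gene")
    return SharedMutationBaseline(fractions, labels, len(records))


def shared_mutation_baseline(
    healthy_reps: Sequence[Repertoire],
    db: GermlineDB,
    min_cluster_size: int = 7,
    annotator: VdjAnnotator | None = None,
) -> SharedMutationBaseline:
    """Baseline mutation-sharing between independent clones in healthy repertoires."""
    records = clone_v_mutation_records(
        healthy_reps, db, min_cluster_size=min_cluster_size, annotator=annotator
    )
    return pairwise_shared_fractions(records)


def diag_relapse_shared_fraction(aln: CloneAlignment) -> float:
    """Shared fraction of mutated alignment columns between diagnosis and relapse."""
    central = aln.central_row
    diag_sites: set[int] = set()
    rel_sites: set[int] = set()
    for i, m in enumerate(aln.members):
        if i == aln.central_index:
            continue
        sites = {c for c, (x, y) in enumerate(zip(central, aln.rows[i])) if x != y}
        if m.diag_count > 0:
            diag_sites |= sites
        if m.relapse_count > 0:
            rel_sites |= sites
    return shared_fraction(frozenset(diag_sites), frozenset(rel_sites))


def compare_shared_mutations(
    baseline: Sequence[float] | SharedMutationBaseline,
    observed: Sequence[float],
) -> float:
    """One-sided Mann-Whitney p for observed sharing exceeding the baseline.

    Exact distribution for combined n <= 20, normal approximation with tie
    correction otherwise.
    """
    base = baseline.fractions if isinstance(baseline, SharedMutationBaseline) else list(baseline)
    obs = list(observed)
    if not base or not obs:
        raise InsufficientDataError("both groups must be non-empty")
    method = "exact" if len(base) + len(obs) <= 20 else "asymptotic"
    res = sps.mannwhitneyu(obs, base, alternative="greater", method=method)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# 96-context trinucleotide mutation profiles


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PYRIMIDINE_SUBS = tuple(
    f"{ref}>{alt}" for ref in "CT" for alt in "ACGT" if alt != ref
)
CONTEXTS_96 = tuple(
    f"{f5}[{sub}]{f3}" for sub in PYRIMIDINE_SUBS for f5 in "ACGT" for f3 in "ACGT"
)


@dataclass
class MutationProfile:
    """Counts of the 6 pyrimidine-centric substitutions in 16 trinucleotide contexts."""

    counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CONTEXTS_96})
    n_excluded_terminal: int = 0
    n_excluded_ambiguous: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def frequencies(self) -> dict[str, float]:
        total = self.total
        return {c: (n / total if total else 0.0) for c, n in self.counts.items()}

    def add(self, ref: str, alt: str, flank5: str, flank3: str, weight: int = 1) -> None:
        bases = (ref, alt, flank5, flank3)
        if any(b not in _COMPLEMENT for b in bases):
            self.n_excluded_ambiguous += weight
            return
        if ref in "AG":  # collapse to the pyrimidine strand
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
            flank5, flank3 = _COMPLEMENT[flank3], _COMPLEMENT[flank5]
        self.counts[f"{flank5}[{ref}>{alt}]{flank3}"] += weight


def triplet_profile(
    central: str,
    variants: Iterable[tuple[str, int]],
) -> MutationProfile:
    """Classify every mismatch of each (variant, count) against the central sequence.

    Variants must be the same length as the central sequence (aligned).
    Flanking bases are taken from the central sequence; terminal-position
    mutations have no flank and are excluded but counted, as are mutations
    whose reference, alternate or flanking base is not A/C/G/T.
    """
    profile = MutationProfile()
    L = len(central)
    for seq, count in variants:
        if len(seq) != L:
            raise ValueError("variants must be aligned to the central sequence length")
        for i, (ref, alt) in enumerate(zip(central, seq)):
            if ref == alt:
                continue
            if i == 0 or i == L - 1:
                profile.n_excluded_terminal += count
                continue
            profile.add(ref, alt, central[i - 1], central[i + 1], weight=count)
    return profile


def compare_profiles(
    p1: MutationProfile,
    p2: MutationProfile,
    alpha: float = 0.005,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Per-context two-proportion Fisher exact tests between two profiles.

    Each context is tested on the 2x2 table of (context count, remaining
    mutations) in the two profiles.  Returns one row per context with the
    raw p-value and significance flags before and after Bonferroni
    correction (adjusted p = min(1, 96·p)).
    """
    if p1.total == 0 or p2.total == 0:
        raise InsufficientDataError("both profiles must contain mutations")
    if correction != "bonferroni":
        raise ValueError("only Bonferroni correction is supported")
    m = len(CONTEXTS_96)
    rows = []
    for ctx in CONTEXTS_96:
        a, b = p1.counts[ctx], p2.counts[ctx]
        table = [[a, p1.total - a], [b, p2.total - b]]
        p = float(sps.fisher_exact(table, alternative="two-sided")[1])
        rows.append(
            {
                "context": ctx,
                "count_1": a,
                "count_2": b,
                "p_value": p,
                "p_adjusted": min(1.0, m * p),
                "significant_raw": p < alpha,
                "significant_bonferroni": m * p < alpha,
            }
        )
    return pd.DataFrame(rows)


def n_significant(comparison: pd.DataFrame, corrected: bool = True) -> int:
    col = "significant_bonferroni" if corrected else "significant_raw"
    return int(comparison[col].sum())


# ---------------------------------------------------------------------------
# PCR/sequencing-error site overlap in control genes


def error_sites(rep: Repertoire) -> tuple[str, frozenset[int]]:
    """True sequence (most frequent; tie -> lexicographic) and its error-site set.

    Error sites are the positions at which equal-length variants differ
    from the true sequence, pooled over all variants.
    """
    true_seq = min((u.seq for u in rep.sequences), key=lambda s: (-rep.counts[s], s))
    sites: set[int] = set()
    for u in rep.sequences:
        if u.seq == true_seq or len(u.seq) != len(true_seq):
            continue
        sites |= {i for i, (a, b) in enumerate(zip(true_seq, u.seq)) if a != b}
    return true_seq, frozenset(sites)


def error_site_overlap(control_reps: Sequence[Repertoire]) -> pd.DataFrame:
    """Pairwise hypergeometric overlap of PCR/sequencing-error sites.

    For every pair of control samples whose true sequences have equal
    length L, tests whether the error sites overlap more than chance,
    with population size N = L.  Under uniform random error the null holds
    and no pair should be significant after multiple-testing correction.
    """
    per_sample = [(rep.meta.sample_id, *error_sites(rep)) for rep in control_reps]
    rows = []
    for i in range(len(per_sample)):
        for j in range(i + 1, len(per_sample)):
            sid_a, true_a, sites_a = per_sample[i]
            sid_b, true_b, sites_b = per_sample[j]
            if len(true_a) != len(true_b):
                continue
            L = len(true_a)
            k = len(sites_a & sites_b)
            p = overlap_pvalue(L, len(sites_a), len(sites_b), k)
            rows.append(
                {
                    "sample_a": sid_a,
                    "sample_b": sid_b,
                    "length": L,
                    "n_sites_a": len(sites_a),
                    "n_sites_b": len(sites_b),
                    "k_shared": k,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)
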