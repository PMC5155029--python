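"""Clone alignments, maximum-parsimony trees and diagnosis-relapse structure.

Variant sequences mined from one clone at diagnosis and relapse are aligned
around the *central BCR* — the most frequently observed member, taken as
the clone's common ancestor — and related by an unrooted maximum-parsimony
tree.  Leukemic clones expand from a single ancestor, so their trees are
expected to be star-like, with the central BCR adjacent to most tips.

Alignment is center-star: every member is globally aligned to the central
sequence (affine gaps) and the pairwise alignments are merged column-wise
under the "once a gap, always a gap" rule.  Parsimony uses Fitch counting
over the five states {A, C, G, T, gap} (N is treated as missing), with a
stepwise-addition + nearest-neighbor-interchange heuristic search from
several deterministic seeded addition orders; an exhaustive search over all
unrooted topologies is available for small member sets and doubles as the
optimality check for the heuristic.  Only members observed at least twice
are included, which suppresses sequencing-error singletons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats as sps

from .errors import InsufficientDataError
from .mrd_tracker import ClonotypeSignature, match_distances
from .repertoire_io import Repertoire

ORIGIN_DIAG = "diagnosis-only"
ORIGIN_RELAPSE = "relapse-only"
ORIGIN_BOTH = "both"


@dataclass(frozen=True)
class CloneMember:
    """One clone variant with its per-sample read counts."""

    seq: str
    diag_count: int
    relapse_count: int

    @property
    def total_count(self) -> int:
        return self.diag_count + self.relapse_count

    @property
    def origin(self) -> str:
        if self.diag_count and self.relapse_count:
            return ORIGIN_BOTH
        return ORIGIN_DIAG if self.diag_count else ORIGIN_RELAPSE


def collect_clone_members(
    sig: ClonotypeSignature,
    diag_rep: Repertoire,
    relapse_rep: Repertoire,
    max_mismatch: int = 8,
    min_count: int = 2,
    mode: str = "hamming",
) -> list[CloneMember]:
    """Mine both samples with one signature and keep well-supported members.

    A sequence becomes a member when it lies within ``max_mismatch`` of the
    signature in either sample and is observed at least ``min_count`` times
    in at least one sample.  Members are ordered by descending total count,
    then lexicographically.
    """
    counts: dict[str, list[int]] = {}
    for col, rep in ((0, diag_rep), (1, relapse_rep)):
        dist = match_distances(sig.member_seqs, rep, mode=mode)
        for u, d in zip(rep.sequences, dist):
            if d <= max_mismatch:
                counts.setdefault(u.seq, [0, 0])[col] += u.count
    members = [
        CloneMember(seq, dc, rc)
        for seq, (dc, rc) in counts.items()
        if max(dc, rc) >= min_count
    ]
    if len(members) < 2:
        raise InsufficientDataError(
            f"only {len(members)} clone members with count >= {min_count}; need >= 2"
        )
    members.sort(key=lambda m: (-m.total_count, m.seq))
    return members


@dataclass
class CloneAlignment:
    """Equal-length aligned rows over clone members, centred on the central BCR."""

    members: list[CloneMember]
    rows: list[str]
    central_index: int

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("alignment rows must share one length")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def central_seq(self) -> str:
        return self.members[self.central_index].seq

    @property
    def central_row(self) -> str:
        return self.rows[self.central_index]


def _global_aligner() -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="global",
        match_score=1.0,
        mismatch_score=-1.0,
        open_gap_score=-4.0,
        extend_gap_score=-1.0,
    )


def align_members(members: Sequence[CloneMember]) -> CloneAlignment:
    """Center-star multiple alignment of clone members.

    The central BCR is the member with the highest summed count (tie:
    lexicographically smallest sequence).  Each member is globally aligned
    to it; gap columns opened by any pairwise alignment are propagated to
    all rows ("once a gap, always a gap"), with insertions left-aligned
    inside their slot.
    """
    if len(members) < 2:
        raise InsufficientDataError("alignment requires >= 2 members")
    members = list(members)
    central_index = min(
        range(len(members)), key=lambda i: (-members[i].total_count, members[i].seq)
    )
    center = members[central_index].seq
    if len({len(m.seq) for m in members}) == 1:
        return CloneAlignment(members, [m.seq for m in members], central_index)

    aligner = _global_aligner()
    gapped: dict[int, tuple[str, str]] = {}
    ins = [0] * (len(center) + 1)  # max insertion length before each center position
    for i, m in enumerate(members):
        if i == central_index:
            continue
        aln = aligner.align(center, m.seq)[0]
        ca, oa = str(aln[0]), str(aln[1])
        gapped[i] = (ca, oa)
        slot = run = 0
        for ch in ca:
            if ch == "-":
                run += 1
            else:
                ins[slot] = max(ins[slot], run)
                run = 0
                slot += 1
        ins[len(center)] = max(ins[len(center)], run)

    def expand(ca: str, oa: str) -> str:
        parts: list[str] = []
        slot = 0
        pend: list[str] = []
        for cch, och in zip(ca, oa):
            if cch == "-":
                pend.append(och)
            else:
                parts.append("".join(pend) + "-" * (ins[slot] - len(pend)))
                parts.append(och)
                pend = []
                slot += 1
        parts.append("".join(pend) + "-" * (ins[len(center)] - len(pend)))
        return "".join(parts)

    rows = []
    for i, m in enumerate(members):
        if i == central_index:
            rows.append(expand(center, center))
        else:
            rows.append(expand(*gapped[i]))
    return CloneAlignment(members, rows, central_index)


# ---------------------------------------------------------------------------
# Fitch parsimony


_STATE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8, "-": 16, "N": 15}


def _site_patterns(rows: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Compress alignment columns into unique state-mask patterns with weights."""
    pattern_counts: dict[tuple[int, ...], int] = {}
    for col in zip(*rows):
        key = tuple(_STATE_BITS.get(c, 15) for c in col)
        pattern_counts[key] = pattern_counts.get(key, 0) + 1
    informative = {k: w for k, w in pattern_counts.items() if len(set(k)) > 1}
    if not informative:
        return (
            np.zeros((len(rows), 0), dtype=np.uint8),
            np.zeros(0, dtype=np.int64),
        )
    masks = np.array(list(informative.keys()), dtype=np.uint8).T  # (n_tips, P)
    weights = np.array(list(informative.values()), dtype=np.int64)
    return masks, weights


def _postorder(adj: dict[int, list[int]], root: int) -> tuple[list[int], dict[int, int]]:
    parent = {root: -1}
    order = []
    stack = [root]
    while stack:
        u = stack.pop()
        order.append(u)
        for v in adj[u]:
            if v != parent[u]:
                parent[v] = u
                stack.append(v)
    return order, parent


def _lowbit(m: np.ndarray) -> np.ndarray:
    return m & (-m.astype(np.int16)).astype(np.uint8)


def _fitch(
    adj: dict[int, list[int]],
    tip_masks: np.ndarray,
    weights: np.ndarray,
    assign: bool = False,
):
    """Fitch parsimony score, rooted for traversal at tip 0 (score is root-free).

    With ``assign=True`` also returns a most-parsimonious state per node and
    per-edge substitution counts.
    """
    n_tips = tip_masks.shape[0]
    if tip_masks.shape[1] == 0:
        if not assign:
            return 0
        zero = {(u, v): 0 for u, v in _edge_list(adj)}
        return 0, zero
    root = min(adj)  # smallest tip present (partial trees may lack tip 0)
    order, parent = _postorder(adj, root)
    masks: dict[int, np.ndarray] = {}
    score = 0
    for u in reversed(order):
        m: np.ndarray | None = tip_masks[u].copy() if u < n_tips else None
        for v in adj[u]:
            if v == parent[u]:
                continue
            cm = masks[v]
            if m is None:
                m = cm.copy()
                continue
            inter = m & cm
            empty = inter == 0
            score += int(weights[empty].sum())
            m = np.where(empty, m | cm, inter)
        masks[u] = m
    if not assign:
        return score
    states: dict[int, np.ndarray] = {}
    for u in order:  # preorder
        if parent[u] == -1:
            # a tip root keeps its own observed state, not the folded mask
            states[u] = _lowbit(tip_masks[u] if u < n_tips else masks[u])
        else:
            ps = states[parent[u]]
            keep = (ps & masks[u]) != 0
            states[u] = np.where(keep, ps, _lowbit(masks[u]))
    edge_lengths = {}
    for u, v in _edge_list(adj):
        diff = states[u] != states[v]
        edge_lengths[(u, v)] = int(weights[diff].sum())
    return score, edge_lengths


def _edge_list(adj: dict[int, list[int]]) -> list[tuple[int, int]]:
    return sorted({(min(u, v), max(u, v)) for u in adj for v in adj[u]})


def _insert_tip(
    adj: dict[int, list[int]], edge: tuple[int, int], tip: int, new_node: int
) -> dict[int, list[int]]:
    u, v = edge
    out = {k: list(vs) for k, vs in adj.items()}
    out[u].remove(v)
    out[v].remove(u)
    out[u].append(new_node)
    out[v].append(new_node)
    out[new_node] = [u, v, tip]
    out[tip] = [new_node]
    return out


@dataclass
class ParsimonyTree:
    """Unrooted tree over clone members with substitution branch lengths."""

    adjacency: dict[int, list[int]]
    n_tips: int
    tip_labels: list[str]
    edge_lengths: dict[tuple[int, int], int]
    total_length: int

    def newick(self) -> str:
        """Newick string, arbitrarily rooted at the internal node next to tip 0."""
        adj = self.adjacency
        if self.n_tips == 2:
            L = self.edge_lengths[(0, 1)]
            return f"({self.tip_labels[0]}:0,{self.tip_labels[1]}:{L});"
        root = adj[0][0]

        def sub(u: int, parent: int) -> str:
            length = self.edge_lengths[(min(u, parent), max(u, parent))]
            if u < self.n_tips:
                return f"{self.tip_labels[u]}:{length}"
            inner = ",".join(sub(v, u) for v in adj[u] if v != parent)
            return f"({inner}):{length}"

        inner = ",".join(sub(v, root) for v in adj[root])
        return f"({inner});"

    def tips_adjacent_to_central(self, central_tip: int) -> int:
        """Tips effectively adjacent to ``central_tip`` in the unrooted tree.

        A star (multifurcation) appears in a binary representation as a
        chain of zero-length internal edges, so a tip counts as adjacent
        when its path to the central tip crosses only internal edges of
        length 0.
        """
        if self.n_tips == 2:
            return 1
        hub = self.adjacency[central_tip][0]
        seen = {hub}
        stack = [hub]
        count = 0
        while stack:
            u = stack.pop()
            for v in self.adjacency[u]:
                if v == central_tip or v in seen:
                    continue
                if v < self.n_tips:
                    count += 1
                elif self.edge_lengths[(min(u, v), max(u, v))] == 0:
                    seen.add(v)
                    stack.append(v)
        return count


def _stepwise(
    order: Sequence[int], tip_masks: np.ndarray, weights: np.ndarray, n_tips: int
) -> dict[int, list[int]]:
    a, b, c = order[0], order[1], order[2]
    hub = n_tips
    adj = {hub: [a, b, c], a: [hub], b: [hub], c: [hub]}
    next_node = n_tips + 1
    for t in order[3:]:
        best = None
        for edge in _edge_list(adj):
            cand = _insert_tip(adj, edge, t, next_node)
            s = _fitch(cand, tip_masks, weights)
            key = (s, edge)
            if best is None or key < best[0]:
                best = (key, cand)
        adj = best[1]
        next_node += 1
    return adj


def _nni(
    adj: dict[int, list[int]],
    tip_masks: np.ndarray,
    weights: np.ndarray,
    n_tips: int,
    max_rounds: int = 60,
) -> tuple[dict[int, list[int]], int]:
    score = _fitch(adj, tip_masks, weights)
    for _ in range(max_rounds):
        improved = False
        for u, v in _edge_list(adj):
            if u < n_tips or v < n_tips:
                continue
            a, b = sorted(x for x in adj[u] if x != v)
            c, d = sorted(x for x in adj[v] if x != u)
            for x, y in ((b, c), (b, d)):
                cand = {k: list(vs) for k, vs in adj.items()}
                cand[u].remove(x)
                cand[v].remove(y)
                cand[u].append(y)
                cand[v].append(x)
                cand[x].remove(u)
                cand[x].append(v)
                cand[y].remove(v)
                cand[y].append(u)
                s = _fitch(cand, tip_masks, weights)
                if s < score:
                    adj, score = cand, s
                    improved = True
                    break
            if improved:
                break
        if not improved:
            break
    return adj, score


def build_parsimony_tree(
    aln: CloneAlignment,
    seed: int = 0,
    n_starts: int = 5,
    tip_labels: Sequence[str] | None = None,
) -> ParsimonyTree:
    """Heuristic maximum-parsimony tree (stepwise addition + NNI).

    The search runs from the canonical member order plus ``n_starts - 1``
    seeded random addition orders and keeps the best score found; the
    result is deterministic for a fixed seed.  The reported score is the
    exact Fitch length of the returned topology.
    """
    rows = aln.rows
    n = len(rows)
    labels = list(tip_labels) if tip_labels is not None else [f"m{i + 1}" for i in range(n)]
    tip_masks, weights = _site_patterns(rows)
    if n == 2:
        score = _fitch({0: [1], 1: [0]}, tip_masks, weights)
        return ParsimonyTree({0: [1], 1: [0]}, 2, labels, {(0, 1): score}, score)
    rng = np.random.default_rng(seed)
    orders = [list(range(n))]
    for _ in range(max(0, n_starts - 1)):
        orders.append(list(rng.permutation(n)))
    best_adj, best_score = None, None
    for order in orders:
        adj = _stepwise(order, tip_masks, weights, n)
        adj, score = _nni(adj, tip_masks, weights, n)
        if best_score is None or score < best_score:
            best_adj, best_score = adj, score
    score, edge_lengths = _fitch(best_adj, tip_masks, weights, assign=True)
    return ParsimonyTree(best_adj, n, labels, edge_lengths, score)


def _topologies(n_tips: int) -> Iterator[dict[int, list[int]]]:
    """All unrooted (binary) topologies over tips 0..n-1, by recursive insertion."""

    def rec(adj: dict[int, list[int]], next_tip: int, next_node: int):
        if next_tip == n_tips:
            yield adj
            return
        for edge in _edge_list(adj):
            yield from rec(
                _insert_tip(adj, edge, next_tip, next_node), next_tip + 1, next_node + 1
            )

    if n_tips == 2:
        yield {0: [1], 1: [0]}
        return
    hub = n_tips
    start = {hub: [0, 1, 2], 0: [hub], 1: [hub], 2: [hub]}
    yield from rec(start, 3, n_tips + 1)


def exhaustive_parsimony(
    aln: CloneAlignment, max_tips: int = 8, tip_labels: Sequence[str] | None = None
) -> ParsimonyTree:
    """Exact maximum-parsimony tree by enumerating every unrooted topology.

    Feasible for small clones only (105 topologies at 6 tips, 10 395 at 8).
    """
    rows = aln.rows
    n = len(rows)
    if n > max_tips:
        raise ValueError(f"exhaustive search limited to {max_tips} tips, got {n}")
    labels = list(tip_labels) if tip_labels is not None else [f"m{i + 1}" for i in range(n)]
    tip_masks, weights = _site_patterns(rows)
    best_adj, best_score = None, None
    for adj in _topologies(n):
        s = _fitch(adj, tip_masks, weights)
        if best_score is None or s < best_score:
            best_adj, best_score = {k: list(v) for k, v in adj.items()}, s
    score, edge_lengths = _fitch(best_adj, tip_masks, weights, assign=True)
    return ParsimonyTree(best_adj, n, labels, edge_lengths, score)


def _bipartition(adj: dict[int, list[int]], edge: tuple[int, int], n_tips: int) -> frozenset[int]:
    """Tip set on the side of ``edge`` away from tip 0 (canonical form)."""
    u, v = edge
    seen = {u}
    stack = [v]
    side = set()
    seen.add(v)
    while stack:
        x = stack.pop()
        if x < n_tips:
            side.add(x)
        for y in adj[x]:
            if y not in seen:
                seen.add(y)
                stack.append(y)
    if 0 in side:
        side = set(range(n_tips)) - side
    return frozenset(side)


def bootstrap_support(
    aln: CloneAlignment,
    tree: ParsimonyTree,
    n_replicates: int = 100,
    seed: int = 0,
) -> dict[frozenset[int], float]:
    """Column-resampling bootstrap support for each internal bipartition."""
    rng = np.random.default_rng(seed)
    n = len(aln.rows)
    L = aln.length
    target = {
        _bipartition(tree.adjacency, e, n)
        for e in _edge_list(tree.adjacency)
        if e[0] >= n and e[1] >= n
    }
    hits = {bp: 0 for bp in target}
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rows = ["".join(r[c] for c in cols) for r in aln.rows]
        rep_aln = CloneAlignment(aln.members, rows, aln.central_index)
        rep_tree = build_parsimony_tree(rep_aln, seed=int(rng.integers(2**31)), n_starts=1)
        rep_bps = {
            _bipartition(rep_tree.adjacency, e, n)
            for e in _edge_list(rep_tree.adjacency)
            if e[0] >= n and e[1] >= n
        }
        for bp in target:
            if bp in rep_bps:
                hits[bp] += 1
    return {bp: h / n_replicates for bp, h in hits.items()}


# ---------------------------------------------------------------------------
# Diagnosis-relapse structure


def member_shell(aln: CloneAlignment, index: int) -> int:
    """Distance shell of a member: differing columns versus the central row."""
    central = aln.central_row
    row = aln.rows[index]
    return sum(1 for a, b in zip(central, row) if a != b)


@dataclass
class StructureSummary:
    overlap_fraction: float
    n_diag_members: int
    n_rel_members: int
    n_shared: int
    shells: pd.DataFrame
    r_squared_raw: float
    r_squared_cuberoot: float


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(sps.linregress(x, y).rvalue ** 2)


def structure_summary(aln: CloneAlignment) -> StructureSummary:
    """Diagnosis-relapse overlap, per-shell member counts and frequency R².

    Overlap is the fraction of unique diagnosis members recovered at
    relapse.  Shells group members by substitution distance from the
    central BCR.  R² relates member frequencies at relapse to diagnosis, on
    the raw scale and on the cube-root scale (which spreads the heavy-tailed
    frequency distribution).
    """
    diag_total = sum(m.diag_count for m in aln.members)
    rel_total = sum(m.relapse_count for m in aln.members)
    n_diag = sum(1 for m in aln.members if m.diag_count > 0)
    n_rel = sum(1 for m in aln.members if m.relapse_count > 0)
    n_shared = sum(1 for m in aln.members if m.origin == ORIGIN_BOTH)
    shells: dict[int, dict[str, int]] = {}
    for i, m in enumerate(aln.members):
        d = member_shell(aln, i)
        rec = shells.setdefault(d, {"n_diag": 0, "n_rel": 0, "n_shared": 0})
        if m.diag_count > 0:
            rec["n_diag"] += 1
        if m.relapse_count > 0:
            rec["n_rel"] += 1
        if m.origin == ORIGIN_BOTH:
            rec["n_shared"] += 1
    shell_df = (
        pd.DataFrame(
            [{"d": d, **rec} for d, rec in sorted(shells.items())],
        )
        .set_index("d")
        .reset_index()
    )
    diag_freq = np.array(
        [m.diag_count / diag_total if diag_total else 0.0 for m in aln.members]
    )
    rel_freq = np.array(
        [m.relapse_count / rel_total if rel_total else 0.0 for m in aln.members]
    )
    return StructureSummary(
        overlap_fraction=n_shared / n_diag if n_diag else float("nan"),
        n_diag_members=n_diag,
        n_rel_members=n_rel,
        n_shared=n_shared,
        shells=shell_df,
        r_squared_raw=_r_squared(diag_freq, rel_freq),
        r_squared_cuberoot=_r_squared(np.cbrt(diag_freq), np.cbrt(rel_freq)),
    )
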