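"""Unique-sequence networks and clonality calling.

Each vertex of the network is a unique sequence whose size is its read
count.  Edges join vertices that differ by a single nucleotide substitution
— sequences of unequal length are never joined, which operationalises the
"non-indel" rule — and clusters are the connected components.  A cluster is
the working proxy for a B-cell clone together with its mutational variants,
and a sample is called clonal when its largest cluster holds at least 2.5%
of all reads, a cutoff sitting above the 95th percentile of the largest
cluster sizes seen in healthy repertoires.

An ambiguous base (N) mismatches every base including N, so it can never
create an edge; this is deliberately conservative.

Neighbor search uses (length, masked-position) hashing: two sequences at
substitution distance 1 agree exactly on the string obtained by deleting
the differing position, so bucketing every sequence under each of its
single-position deletions enumerates all candidate pairs in
O(total sequence length) expected time.  Equivalence with brute-force
all-pairs search is covered by the test suite.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .errors import EmptyRepertoireError
from .repertoire_io import Repertoire, UniqueSequence


def hamming_distance(a: str, b: str) -> int:
    """Substitution distance between equal-length strings; N mismatches all."""
    if len(a) != len(b):
        raise ValueError("hamming_distance requires equal-length sequences")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def hamming1_pairs(seqs: Sequence[str]) -> list[tuple[int, int]]:
    """All index pairs (i < j) of sequences at substitution distance exactly 1.

    Sequences must be unique.  Uses masked-position hashing; candidate pairs
    containing N are re-verified with the full N-aware distance.
    """
    buckets: dict[tuple[int, int, str, str], list[int]] = defaultdict(list)
    for idx, s in enumerate(seqs):
        L = len(s)
        for pos in range(L):
            buckets[(L, pos, s[:pos], s[pos + 1 :])].append(idx)
    pairs: list[tuple[int, int]] = []
    for (_, pos, _, _), members in buckets.items():
        if len(members) < 2:
            continue
        for ai in range(len(members)):
            i = members[ai]
            si = seqs[i]
            for bi in range(ai + 1, len(members)):
                j = members[bi]
                sj = seqs[j]
                # same bucket => identical outside `pos`, and unique input
                # sequences must differ at `pos`
                if si[pos] == "N" or sj[pos] == "N":
                    continue
                if ("N" in si or "N" in sj) and hamming_distance(si, sj) != 1:
                    continue
                pairs.append((i, j) if i < j else (j, i))
    return sorted(set(pairs))


def hamming1_components(seqs: Sequence[str]) -> list[list[int]]:
    """Connected components (index lists) of the substitution-distance-1 graph."""
    g = nx.Graph()
    g.add_nodes_from(range(len(seqs)))
    g.add_edges_from(hamming1_pairs(seqs))
    return [sorted(c) for c in nx.connected_components(g)]


@dataclass
class SequenceNetwork:
    """The unique-sequence graph of one repertoire.

    ``clusters`` are the connected components, numbered deterministically:
    descending total reads, then lexicographic dominant sequence.
    """

    repertoire: Repertoire
    vertices: list[UniqueSequence]
    edges: list[tuple[int, int]]
    clusters: list[list[int]]

    @property
    def total_reads(self) -> int:
        return self.repertoire.total_reads


@dataclass(frozen=True)
class ClusterStat:
    cluster_id: int
    n_vertices: int
    reads: int
    fraction: float
    dominant_seq: str


def build_network(rep: Repertoire) -> SequenceNetwork:
    """Build the Hamming-1 network of a repertoire."""
    if not rep.sequences:
        raise EmptyRepertoireError("cannot build a network from an empty repertoire")
    vertices = list(rep.sequences)
    seqs = [v.seq for v in vertices]
    edges = hamming1_pairs(seqs)
    comps = hamming1_components(seqs)

    def sort_key(comp: list[int]):
        reads = sum(vertices[i].count for i in comp)
        dominant = min((-vertices[i].count, vertices[i].seq) for i in comp)[1]
        return (-reads, dominant)

    clusters = sorted(comps, key=sort_key)
    return SequenceNetwork(rep, vertices, edges, clusters)


def cluster_stats(net: SequenceNetwork) -> list[ClusterStat]:
    """Per-cluster read counts, read fractions and dominant sequences, largest first."""
    total = net.total_reads
    stats = []
    for cid, comp in enumerate(net.clusters, start=1):
        reads = sum(net.vertices[i].count for i in comp)
        dominant = min((-net.vertices[i].count, net.vertices[i].seq) for i in comp)[1]
        stats.append(
            ClusterStat(
                cluster_id=cid,
                n_vertices=len(comp),
                reads=reads,
                fraction=reads / total,
                dominant_seq=dominant,
            )
        )
    return stats


def is_clonal(stats: Sequence[ClusterStat], threshold: float = 0.025) -> tuple[bool, float]:
    """Call clonality: is the largest cluster fraction >= threshold (inclusive)?"""
    if not stats:
        raise ValueError("is_clonal requires at least one cluster")
    largest = max(s.fraction for s in stats)
    return largest >= threshold, largest


def healthy_percentile(largest_fractions: Iterable[float], q: float) -> float:
    """Empirical q-quantile (linear interpolation) of healthy largest-cluster fractions."""
    values = sorted(largest_fractions)
    if len(values) < 2:
        raise ValueError("healthy_percentile requires at least 2 healthy samples")
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie strictly in (0, 1)")
    return float(np.quantile(values, q, method="linear"))


def edge_table(net: SequenceNetwork) -> "list[tuple[str, str]]":
    """Edge list as (source_seq, target_seq) pairs for external graph viewers."""
    return [(net.vertices[i].seq, net.vertices[j].seq) for i, j in net.edges]
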