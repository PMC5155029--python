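"""V/J annotation, stem-sequence extraction and secondary-rearrangement detection.

The *stem* of a heavy-chain rearrangement is the N-IgHD-N-IgHJ region
beginning 3 bp downstream of the IgHV gene boundary.  Because a secondary
rearrangement (V replacement) splices a new, locus-upstream V gene onto a
pre-existing D-J join, the stem is invariant under such events and serves as
a clone barcode: one stem observed with many different V genes is the
signature of secondary rearrangement within a clone.

V and J genes are called by local alignment (Smith-Waterman via Biopython's
PairwiseAligner) of every germline segment against the read: the V boundary
is the last read position aligned to the best-scoring V gene, and the stem
runs from 3 bases past that boundary to the end of the read.  The 3-base
skip drops bases whose assignment to V versus N-addition is uncertain.
Scoring is match +1 / mismatch -1 / gap open -4 / gap extend -1 with score
floors of 20 (V) and 10 (J); all of these are configurable.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import Align

from .clonal_network import (
    SequenceNetwork,
    build_network,
    cluster_stats,
    hamming1_components,
    healthy_percentile,
)
from .errors import AnnotationError
from .repertoire_io import GermlineDB, Repertoire


@dataclass(frozen=True)
class SegmentCall:
    gene: str
    score: float
    start: int  # 0-based, inclusive, on the read
    end: int  # 0-based, inclusive, on the read


@dataclass(frozen=True)
class VdjAnnotation:
    """V and J calls plus the extracted stem for one sequence."""

    seq: str
    v: SegmentCall
    j: SegmentCall
    stem: str

    @property
    def v_end(self) -> int:
        """0-based position of the last V-aligned base."""
        return self.v.end

    @property
    def j_start(self) -> int:
        return self.j.start


class VdjAnnotator:
    """Caches V/J calls for a fixed germline reference.

    Tie-break between equally scoring genes: longer aligned span on the
    read, then alphabetical gene name.
    """

    def __init__(
        self,
        db: GermlineDB,
        match: float = 1.0,
        mismatch: float = -1.0,
        gap_open: float = -4.0,
        gap_extend: float = -1.0,
        v_score_floor: float = 20.0,
        j_score_floor: float = 10.0,
        min_length: int = 30,
        stem_skip: int = 3,
    ) -> None:
        self.db = db
        self.v_score_floor = v_score_floor
        self.j_score_floor = j_score_floor
        self.min_length = min_length
        self.stem_skip = stem_skip
        self._aligner = Align.PairwiseAligner(
            mode="local",
            match_score=match,
            mismatch_score=mismatch,
            open_gap_score=gap_open,
            extend_gap_score=gap_extend,
        )
        self._cache: dict[str, VdjAnnotation | AnnotationError] = {}
        self._v_cache: dict[str, SegmentCall | AnnotationError] = {}

    def _best_segment(
        self, seq: str, genes: Mapping[str, str], floor: float, label: str
    ) -> SegmentCall:
        scores = []
        for name, gseq in genes.items():
            scores.append((self._aligner.score(seq, gseq), name))
        if not scores:
            raise AnnotationError(f"no {label} genes in reference")
        best_score = max(s for s, _ in scores)
        if best_score < floor:
            raise AnnotationError(
                f"best {label} score {best_score:.1f} below floor {floor:.1f}"
            )
        candidates = sorted(name for s, name in scores if s == best_score)
        best = None
        for name in candidates:
            aln = self._aligner.align(seq, genes[name])[0]
            blocks = aln.aligned[0]
            start, end = int(blocks[0][0]), int(blocks[-1][1]) - 1
            span = end - start + 1
            key = (-span, name)
            if best is None or key < best[0]:
                best = (key, SegmentCall(name, float(best_score), start, end))
        return best[1]

    def best_v(self, seq: str) -> SegmentCall:
        """V call alone (used when tallying V usage per stem)."""
        hit = self._v_cache.get(seq)
        if hit is None:
            try:
                hit = self._best_segment(seq, self.db.v_genes, self.v_score_floor, "V")
            except AnnotationError as exc:
                hit = exc
            self._v_cache[seq] = hit
        if isinstance(hit, AnnotationError):
            raise hit
        return hit

    def annotate(self, seq: str) -> VdjAnnotation:
        hit = self._cache.get(seq)
        if hit is None:
            try:
                hit = self._annotate(seq)
            except AnnotationError as exc:
                hit = exc
            self._cache[seq] = hit
        if isinstance(hit, AnnotationError):
            raise hit
        return hit

    def _annotate(self, seq: str) -> VdjAnnotation:
        if len(seq) < self.min_length:
            raise AnnotationError(f"sequence shorter than {self.min_length} nt")
        v = self._best_segment(seq, self.db.v_genes, self.v_score_floor, "V")
        j = self._best_segment(seq, self.db.j_genes, self.j_score_floor, "J")
        if not v.end < j.start:
            raise AnnotationError(
                f"V/J order violated (v_end={v.end}, j_start={j.start})"
            )
        stem_start = v.end + 1 + self.stem_skip
        stem = seq[stem_start:]
        if not stem:
            raise AnnotationError("empty stem after the 3-base skip")
        return VdjAnnotation(seq=seq, v=v, j=j, stem=stem)


def annotate_vj(seq: str, db: GermlineDB, **kwargs) -> VdjAnnotation:
    """Convenience one-shot wrapper around :class:`VdjAnnotator`."""
    return VdjAnnotator(db, **kwargs).annotate(seq)


@dataclass
class StemGroup:
    """A single-linkage cluster of near-identical stems with observed V usage."""

    group_id: int
    stem_members: frozenset[str]
    v_usage: dict[str, int] = field(default_factory=dict)
    occurrences: dict[str, float] = field(default_factory=dict)

    @property
    def distinct_v_count(self) -> int:
        return len(self.v_usage)


def extract_stems(
    reps: Sequence[Repertoire],
    db: GermlineDB,
    min_reads: int = 3,
    min_cluster_fraction: float = 0.025,
    networks: Sequence[SequenceNetwork] | None = None,
    annotator: VdjAnnotator | None = None,
) -> tuple[dict[tuple[str, int], set[str]], int]:
    """Stems of well-supported members of every qualifying cluster.

    Only sequences with more than 2 reads (``count >= min_reads``) inside
    clusters holding at least ``min_cluster_fraction`` of the repertoire
    contribute.  Returns ``{(sample_id, cluster_id): stems}`` plus the
    number of sequences that could not be annotated.
    """
    annotator = annotator or VdjAnnotator(db)
    if networks is None:
        networks = [build_network(r) for r in reps]
    stems: dict[tuple[str, int], set[str]] = {}
    n_unannotatable = 0
    for rep, net in zip(reps, networks):
        for stat in cluster_stats(net):
            if stat.fraction < min_cluster_fraction:
                continue
            out: set[str] = set()
            for idx in net.clusters[stat.cluster_id - 1]:
                vtx = net.vertices[idx]
                if vtx.count < min_reads:
                    continue
                try:
                    out.add(annotator.annotate(vtx.seq).stem)
                except AnnotationError:
                    n_unannotatable += 1
            if out:
                stems[(rep.meta.sample_id, stat.cluster_id)] = out
    return stems, n_unannotatable


def cluster_stems(stems: Iterable[str]) -> list[StemGroup]:
    """Single-linkage grouping of stems under equal-length Hamming distance 1.

    Groups are ordered by descending member count, then by lexicographic
    smallest member; singleton stems form their own group.
    """
    unique = sorted(set(stems))
    comps = hamming1_components(unique)
    comps.sort(key=lambda c: (-len(c), min(unique[i] for i in c)))
    return [
        StemGroup(group_id=gid, stem_members=frozenset(unique[i] for i in comp))
        for gid, comp in enumerate(comps, start=1)
    ]


def _stem_hits(member_stems: frozenset[str], rep: Repertoire) -> list[int]:
    """Indices of repertoire sequences containing any member stem as substring."""
    hits = []
    stems = sorted(member_stems)
    for i, u in enumerate(rep.sequences):
        if any(stem in u.seq for stem in stems):
            hits.append(i)
    return hits


def v_usage_per_stem(
    group: StemGroup,
    reps: Sequence[Repertoire],
    db: GermlineDB,
    annotator: VdjAnnotator | None = None,
) -> tuple[dict[str, int], int]:
    """Read-weighted V-gene usage among all sequences carrying a member stem.

    Scans every repertoire sequence for an exact-substring stem match,
    annotates the V gene of each hit and tallies read counts per gene.
    Returns the usage map and the distinct-V count; the group's ``v_usage``
    is updated in place.  Secondary rearrangements reveal themselves as a
    distinct-V count above 1.
    """
    annotator = annotator or VdjAnnotator(db)
    usage: dict[str, int] = defaultdict(int)
    for rep in reps:
        for i in _stem_hits(group.stem_members, rep):
            u = rep.sequences[i]
            try:
                call = annotator.best_v(u.seq)
            except AnnotationError:
                continue
            usage[call.gene] += u.count
    group.v_usage = dict(usage)
    return group.v_usage, len(usage)


def stem_background(
    group: StemGroup,
    healthy_reps: Sequence[Repertoire],
    q: float = 0.99,
) -> tuple[dict[str, float], float]:
    """Per-sample stem-carrier read fraction in healthy repertoires + percentile.

    Returns the fraction of reads containing any member stem for each
    healthy sample and the empirical ``q`` percentile (linear interpolation)
    of those fractions.  A patient observation counts as a true secondary-
    rearrangement signal only when it exceeds this threshold.
    """
    if len(healthy_reps) < 2:
        raise ValueError("stem_background requires >= 2 healthy repertoires")
    fractions: dict[str, float] = {}
    for rep in healthy_reps:
        hits = _stem_hits(group.stem_members, rep)
        reads = sum(rep.sequences[i].count for i in hits)
        fractions[rep.meta.sample_id] = reads / rep.total_reads
    threshold = healthy_percentile(fractions.values(), q)
    group.occurrences = dict(fractions)
    return fractions, threshold


def is_flagged(patient_fraction: float, threshold: float) -> bool:
    """A patient stem frequency is flagged only when strictly above the healthy threshold."""
    return patient_fraction > threshold


def false_detection_rate(
    signature_stems: Iterable[str],
    unrelated_reps: Sequence[Repertoire],
) -> float:
    """Fraction of unrelated-patient reads containing any signature stem.

    Estimates the chance that an identical stem arises in an independent
    individual, i.e. the false-positive rate of stem-based clone tracking.
    """
    stems = frozenset(signature_stems)
    hit_reads = 0
    total = 0
    for rep in unrelated_reps:
        total += rep.total_reads
        idx = _stem_hits(stems, rep)
        hit_reads += sum(rep.sequences[i].count for i in idx)
    if total == 0:
        raise ValueError("false_detection_rate requires non-empty unrelated repertoires")
    return hit_reads / total
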