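"""Clonotype signatures and longitudinal minimal-residual-disease mining.

A *clonotype signature* is the full set of unique sequences belonging to one
qualifying cluster (read fraction >= 2.5%) of a patient's index sample.
Every later sample of the same patient is then mined for sequences lying
within <= 8 substitutions (equal-length Hamming distance; unequal lengths
never match) of any signature member, and the matched read fraction is the
sequence-based MRD estimate for that clone at that time point.

Distances are computed with vectorised numpy comparisons over sequences
grouped by length; an ambiguous base (N) mismatches everything, consistent
with the network's edge rule.  An optional Levenshtein mode (same cutoff,
via edlib) is available for users who want indel-tolerant mining.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clonal_network import build_network, cluster_stats
from .errors import InsufficientDataError
from .repertoire_io import Repertoire

_ENCODE = np.full(256, 4, dtype=np.uint8)  # everything unknown behaves like N
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
_N_CODE = 4


def _encode(seqs: Sequence[str], length: int) -> np.ndarray:
    buf = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return _ENCODE[buf].reshape(len(seqs), length)


@dataclass(frozen=True)
class ClonotypeSignature:
    """All sequences of one qualifying index-sample cluster."""

    patient_id: str
    clone_id: int
    member_seqs: frozenset[str]
    dominant_seq: str
    index_fraction: float

    def __post_init__(self) -> None:
        if self.dominant_seq not in self.member_seqs:
            raise ValueError("dominant_seq must be a signature member")


@dataclass(frozen=True)
class MrdResult:
    sample_id: str
    clone_id: int
    matched_reads: int
    total_reads: int
    fraction: float
    detected: bool


def define_signatures(index_rep: Repertoire, threshold: float = 0.025) -> list[ClonotypeSignature]:
    """One signature per index-sample cluster at or above ``threshold`` read fraction.

    Clone ids are assigned by descending index fraction (1 = largest).
    Returns an empty list (with a warning) when no cluster qualifies.
    """
    net = build_network(index_rep)
    stats_ = cluster_stats(net)
    qualifying = [s for s in stats_ if s.fraction >= threshold]
    if not qualifying:
        warnings.warn(
            f"index sample {index_rep.meta.sample_id}: no cluster >= {threshold:.3%}; "
            "sample is not clonal",
            stacklevel=2,
        )
        return []
    qualifying.sort(key=lambda s: (-s.fraction, s.dominant_seq))
    sigs = []
    for clone_id, s in enumerate(qualifying, start=1):
        comp = net.clusters[s.cluster_id - 1]
        members = frozenset(net.vertices[i].seq for i in comp)
        sigs.append(
            ClonotypeSignature(
                patient_id=index_rep.meta.patient_id,
                clone_id=clone_id,
                member_seqs=members,
                dominant_seq=s.dominant_seq,
                index_fraction=s.fraction,
            )
        )
    return sigs


def match_distances(
    member_seqs: Iterable[str], rep: Repertoire, mode: str = "hamming"
) -> np.ndarray:
    """Minimum distance from each repertoire sequence to any signature member.

    Hamming mode: equal-length substitution distance; unequal lengths give
    infinity.  Levenshtein mode: edit distance via edlib.
    """
    seqs = [u.seq for u in rep.sequences]
    dist = np.full(len(seqs), np.inf)
    members = sorted(set(member_seqs))
    if mode == "levenshtein":
        import edlib

        for i, s in enumerate(seqs):
            best = min(edlib.align(s, m, mode="NW")["editDistance"] for m in members)
            dist[i] = best
        return dist
    if mode != "hamming":
        raise ValueError(f"unknown matching mode {mode!r}")
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    for L, idx in by_len.items():
        mems = [m for m in members if len(m) == L]
        if not mems:
            continue
        rep_arr = _encode([seqs[i] for i in idx], L)
        rep_n = rep_arr == _N_CODE
        best = np.full(len(idx), np.inf)
        for m in mems:
            m_arr = _encode([m], L)[0]
            neq = (rep_arr != m_arr[None, :]) | rep_n | (m_arr == _N_CODE)[None, :]
            np.minimum(best, neq.sum(axis=1), out=best)
        dist[idx] = best
    return dist


def mine_sample(
    sig: ClonotypeSignature,
    rep: Repertoire,
    max_mismatch: int = 8,
    mode: str = "hamming",
) -> MrdResult:
    """Sum the reads of all repertoire sequences within ``max_mismatch`` of the signature."""
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    dist = match_distances(sig.member_seqs, rep, mode=mode)
    matched = dist <= max_mismatch
    counts = np.array([u.count for u in rep.sequences])
    matched_reads = int(counts[matched].sum())
    total = int(counts.sum())
    return MrdResult(
        sample_id=rep.meta.sample_id,
        clone_id=sig.clone_id,
        matched_reads=matched_reads,
        total_reads=total,
        fraction=matched_reads / total,
        detected=matched_reads >= 1,
    )


def track_patient(
    sigs: Sequence[ClonotypeSignature],
    samples: Sequence[Repertoire],
    max_mismatch: int = 8,
    mode: str = "hamming",
) -> pd.DataFrame:
    """Mine every sample for every signature; one row per (clone, sample).

    Sequences matching several signatures of the same patient are assigned
    to the signature at the smaller distance (tie -> lower clone id), so
    clone fractions never double-count a read.  The returned table is
    sorted by day then clone id.
    """
    if not sigs:
        raise ValueError("track_patient requires at least one signature")
    patients = {s.patient_id for s in sigs} | {r.meta.patient_id for r in samples}
    if len(patients) != 1:
        raise ValueError(f"mixed patients in tracking request: {sorted(patients)}")
    by_clone = sorted(sigs, key=lambda s: s.clone_id)
    rows = []
    for rep in samples:
        counts = np.array([u.count for u in rep.sequences])
        total = int(counts.sum())
        dists = np.stack([match_distances(s.member_seqs, rep, mode=mode) for s in by_clone])
        best = dists.min(axis=0)
        # ties broken toward the lower clone id by argmin over clone order
        assignment = dists.argmin(axis=0)
        for k, sig in enumerate(by_clone):
            matched = (best <= max_mismatch) & (assignment == k)
            matched_reads = int(counts[matched].sum())
            rows.append(
                {
                    "patient_id": rep.meta.patient_id,
                    "clone_id": sig.clone_id,
                    "sample_id": rep.meta.sample_id,
                    "day": rep.meta.day,
                    "matched_reads": matched_reads,
                    "total_reads": total,
                    "fraction": matched_reads / total,
                    "detected": matched_reads >= 1,
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values(["day", "clone_id"], kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class CorrelationResult:
    r_squared: float
    slope: float
    intercept: float
    n_pairs: int
    n_excluded: int
    degenerate: bool


def correlate_external(
    results: pd.DataFrame | Sequence[MrdResult],
    external: Mapping[str, float],
) -> CorrelationResult:
    """OLS R-squared of log10 mined fraction against log10 external MRD.

    ``external`` maps sample_id to an external disease measure (e.g. a qPCR
    T/C ratio or %-blasts).  Pairs where either value is zero or missing are
    excluded and counted; at least 3 positive pairs are required.  A
    zero-variance external series yields R-squared 0 with the degenerate
    flag set.
    """
    if isinstance(results, pd.DataFrame):
        pairs_iter = zip(results["sample_id"], results["fraction"])
    else:
        pairs_iter = ((r.sample_id, r.fraction) for r in results)
    xs, ys, excluded = [], [], 0
    for sample_id, fraction in pairs_iter:
        ext = external.get(sample_id)
        if ext is None or ext <= 0 or fraction <= 0:
            excluded += 1
            continue
        xs.append(np.log10(fraction))
        ys.append(np.log10(ext))
    if len(xs) < 3:
        raise InsufficientDataError(
            f"correlate_external needs >= 3 paired positive observations, got {len(xs)}"
        )
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return CorrelationResult(0.0, float("nan"), float("nan"), len(xs), excluded, True)
    fit = stats.linregress(xs, ys)
    return CorrelationResult(
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_pairs=len(xs),
        n_excluded=excluded,
        degenerate=False,
    )
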