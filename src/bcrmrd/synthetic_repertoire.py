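"""Seeded synthetic BCR repertoires: the test substrate for the whole pipeline.

The generator emulates the regimes the pipeline is built for, with ground
truth recorded for every read:

* a toy germline locus whose segments are mutually divergent enough
  (pairwise distance >= 20% of length) that V/J annotation is unambiguous,
  with V genes carrying an explicit locus order for V-replacement checks;
* polyclonal healthy repertoires — independent V(D)J events with geometric
  N-additions, log-normal per-cell read counts and light somatic
  hypermutation — whose largest network cluster stays below the 2.5%
  clonality cutoff (around the sub-percent level seen in healthy donors);
* leukemic clones as star-like variant clouds around a single ancestor
  (each variant a truncated-geometric number of substitutions away, at
  most 8 by default, optionally concentrated at WRC/GYW AID hotspots);
* secondary rearrangements: subclones sharing the ancestor's exact
  N-D-N-J tail joined to distinct, strictly locus-upstream V genes;
* serial dilution of clone into healthy background with binomial read
  sampling and independent per-base substitution sequencing error;
* diagnosis/relapse pairs that share a planted fraction of their variant
  clouds.

All randomness flows from one mandatory seed; each stage derives its own
child stream, so identical configurations reproduce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SimulationError
from .mrd_tracker import match_distances
from .repertoire_io import GermlineDB, Repertoire, SampleMeta

_BASES = np.array(list("ACGT"))
_STAGE_KEYS = {
    "germline": 0,
    "healthy": 1,
    "clone": 2,
    "secondary": 3,
    "sequence": 4,
    "relapse": 5,
}


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the simulator; the defaults are the study conditions."""

    seed: int
    # germline locus
    n_v: int = 12
    n_d: int = 6
    n_j: int = 4
    v_length: int = 120
    d_length: int = 16
    j_length: int = 30
    min_segment_divergence: float = 0.2
    max_germline_attempts: int = 5000
    # V(D)J junctions
    n_addition_mean: float = 4.0
    # healthy repertoires
    healthy_cells: int = 1500
    read_count_mu: float = 1.0  # log-normal log-mean of per-cell read counts
    read_count_sigma: float = 1.0
    healthy_shm_rate: float = 0.001  # per base per read
    clonality_threshold: float = 0.025
    # leukemic clones
    clone_ancestor_reads: int = 400
    clone_variants: int = 40
    variant_distance_mean: float = 2.0
    max_variant_distance: int = 8
    variant_read_mean: float = 4.0  # counts are 2 + Poisson(mean - 2): members survive the >=2 filter
    hotspot_multiplier: float = 1.0
    clone_min_n_length: int = 4  # clone stems must contain junction-specific bases
    # secondary rearrangements
    secondary_reads: int = 80
    # sequencing
    error_rate: float = 1e-3
    clone_fraction: float = 0.3
    dilution_ratios: tuple[float, ...] = (1e-1, 1e-2, 1e-3, 1e-4, 1e-5)
    # diagnosis/relapse pairs
    shared_variant_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed is mandatory and must be an integer")
        for name in ("healthy_shm_rate", "error_rate", "clone_fraction",
                     "shared_variant_fraction", "min_segment_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.variant_read_mean < 2:
            raise ValueError("variant_read_mean must be >= 2")

    def rng(self, stage: str, salt: int = 0) -> np.random.Generator:
        """Deterministic child stream for one simulation stage."""
        key = _STAGE_KEYS[stage]
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed), spawn_key=(key, salt))
        )


def _random_segment(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _divergent_segments(
    rng: np.random.Generator, n: int, length: int, min_div: float, max_attempts: int
) -> list[str]:
    min_dist = int(np.ceil(min_div * length))
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise SimulationError(
                f"could not draw {n} segments of length {length} with pairwise "
                f"distance >= {min_dist} in {max_attempts} attempts"
            )
        cand = _random_segment(rng, length)
        if all(sum(a != b for a, b in zip(cand, s)) >= min_dist for s in out):
            out.append(cand)
    return out


def simulate_germline(cfg: SimConfig) -> GermlineDB:
    """Toy germline reference with mutually divergent segments and V locus order.

    V gene names are IGHV1..IGHVn ordered from the D-proximal end of the
    locus outward (IGHV1 sits closest to the D genes).
    """
    rng = cfg.rng("germline")
    vs = _divergent_segments(rng, cfg.n_v, cfg.v_length, cfg.min_segment_divergence,
                             cfg.max_germline_attempts)
    ds = _divergent_segments(rng, cfg.n_d, cfg.d_length, cfg.min_segment_divergence,
                             cfg.max_germline_attempts)
    js = _divergent_segments(rng, cfg.n_j, cfg.j_length, cfg.min_segment_divergence,
                             cfg.max_germline_attempts)
    v_names = [f"IGHV{i + 1}" for i in range(cfg.n_v)]
    return GermlineDB(
        v_genes=dict(zip(v_names, vs)),
        d_genes={f"IGHD{i + 1}": s for i, s in enumerate(ds)},
        j_genes={f"IGHJ{i + 1}": s for i, s in enumerate(js)},
        v_locus_order=tuple(v_names),
    )


@dataclass(frozen=True)
class VdjEvent:
    """One recombination event: segment choices plus junctional N additions."""

    v_name: str
    d_name: str
    j_name: str
    n1: str
    n2: str
    v_locus_index: int

    def tail(self, db: GermlineDB) -> str:
        """Everything 3' of the V gene: N1 + D + N2 + J."""
        return self.n1 + db.d_genes[self.d_name] + self.n2 + db.j_genes[self.j_name]

    def sequence(self, db: GermlineDB) -> str:
        return db.v_genes[self.v_name] + self.tail(db)

    def true_stem(self, db: GermlineDB) -> str:
        """The N-D-N-J region starting 3 bases past the V boundary."""
        return self.tail(db)[3:]


def _draw_event(
    cfg: SimConfig,
    db: GermlineDB,
    rng: np.random.Generator,
    reserve_upstream: int = 0,
    min_n: int = 0,
) -> VdjEvent:
    """Draw one V(D)J event; ``reserve_upstream`` keeps that many V genes
    above the chosen one free for later V-replacement events, and ``min_n``
    truncates the N-addition length distribution from below (leukemic-clone
    events require junction-specific stems; healthy events do not)."""
    order = db.v_locus_order or tuple(db.v_genes)
    if reserve_upstream >= len(order):
        raise SimulationError("reserve_upstream must leave at least one V gene")
    vi = int(rng.integers(len(order) - reserve_upstream))
    p = 1.0 / (1.0 + cfg.n_addition_mean)

    def n_length() -> int:
        for _ in range(1000):
            n = int(rng.geometric(p) - 1)
            if n >= min_n:
                return n
        raise SimulationError("could not draw an N-addition length above the minimum")

    n1 = _random_segment(rng, n_length())
    n2 = _random_segment(rng, n_length())
    return VdjEvent(
        v_name=order[vi],
        d_name=str(rng.choice(sorted(db.d_genes))),
        j_name=str(rng.choice(sorted(db.j_genes))),
        n1=n1,
        n2=n2,
        v_locus_index=vi,
    )


def _mutate(seq: str, positions: Sequence[int], rng: np.random.Generator) -> str:
    chars = list(seq)
    for pos in positions:
        choices = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = choices[int(rng.integers(3))]
    return "".join(chars)


def hotspot_weights(seq: str, multiplier: float) -> np.ndarray:
    """Per-position mutation weights: ``multiplier`` at WRC-C / GYW-G, else 1.

    WRC (W = A/T, R = A/G) marks the mutated C on the top strand; GYW is
    its reverse complement marking the paired G.
    """
    w = np.ones(len(seq))
    if multiplier == 1.0:
        return w
    for i in range(len(seq)):
        if (
            seq[i] == "C"
            and i >= 2
            and seq[i - 2] in "AT"
            and seq[i - 1] in "AG"
        ) or (
            seq[i] == "G"
            and i + 2 < len(seq)
            and seq[i + 1] in "CT"
            and seq[i + 2] in "AT"
        ):
            w[i] = multiplier
    return w


def _apply_read_errors(
    counts: dict[str, int], rate: float, rng: np.random.Generator
) -> dict[str, int]:
    """Independent per-base substitution errors on every read."""
    if rate <= 0:
        return dict(counts)
    out: dict[str, int] = {}
    for seq, c in counts.items():
        L = len(seq)
        p_any = 1.0 - (1.0 - rate) ** L
        n_err = int(rng.binomial(c, p_any))
        if c - n_err:
            out[seq] = out.get(seq, 0) + (c - n_err)
        for _ in range(n_err):
            k = max(1, int(rng.binomial(L, rate)))
            positions = rng.choice(L, size=min(k, L), replace=False)
            mutated = _mutate(seq, positions, rng)
            out[mutated] = out.get(mutated, 0) + 1
    return out


def _meta(sample_id: str, patient_id: str, day: int = 0) -> SampleMeta:
    return SampleMeta(sample_id=sample_id, patient_id=patient_id, day=day,
                      tissue="synthetic", template="RNA")


def simulate_healthy(
    cfg: SimConfig,
    db: GermlineDB,
    sample_id: str = "healthy",
    patient_id: str | None = None,
    salt: int = 0,
) -> tuple[Repertoire, pd.DataFrame]:
    """One polyclonal healthy repertoire plus its per-lineage truth table.

    Cells are independent V(D)J events with log-normal read counts and
    light per-read SHM.  The emitted sample is re-drawn (bounded attempts)
    if its largest network cluster reaches the clonality threshold, which
    the truth table records in ``attrs['n_resampled']``.
    """
    from .clonal_network import build_network, cluster_stats  # local: avoids cycle

    rng = cfg.rng("healthy", salt)
    n_resampled = 0
    for _attempt in range(5):
        counts: dict[str, int] = {}
        truth_rows = []
        for cell in range(cfg.healthy_cells):
            event = _draw_event(cfg, db, rng)
            seq = event.sequence(db)
            c = max(1, int(round(rng.lognormal(cfg.read_count_mu, cfg.read_count_sigma))))
            cell_counts = _apply_read_errors({seq: c}, cfg.healthy_shm_rate, rng)
            for s, n in cell_counts.items():
                counts[s] = counts.get(s, 0) + n
            truth_rows.append(
                {
                    "origin": "healthy",
                    "cell_id": cell,
                    "v_name": event.v_name,
                    "d_name": event.d_name,
                    "j_name": event.j_name,
                    "v_locus_index": event.v_locus_index,
                    "stem_true": event.true_stem(db),
                    "seq": seq,
                    "count": c,
                }
            )
        rep = Repertoire.from_counts(_meta(sample_id, patient_id or sample_id), counts)
        largest = max(s.fraction for s in cluster_stats(build_network(rep)))
        if largest < cfg.clonality_threshold:
            truth = pd.DataFrame(truth_rows)
            truth.attrs["n_resampled"] = n_resampled
            return rep, truth
        n_resampled += 1
    raise SimulationError(
        "healthy repertoire exceeded the clonality threshold in 5 consecutive draws"
    )


@dataclass
class SimulatedClone:
    """A leukemic clone (plus any secondary-rearrangement subclones) with truth."""

    repertoire: Repertoire
    truth: pd.DataFrame
    ancestor_seq: str
    event: VdjEvent
    db: GermlineDB
    subclone_events: list[VdjEvent] = field(default_factory=list)

    @property
    def true_stem(self) -> str:
        return self.event.true_stem(self.db)

    @property
    def member_seqs(self) -> set[str]:
        return {u.seq for u in self.repertoire.sequences}


def _aid_mutate(
    seq: str,
    positions: Sequence[int],
    hot: set[int],
    rng: np.random.Generator,
) -> str:
    """Mutate; hotspot C/G positions follow AID-type deamination outcomes.

    At a WRC hotspot C the substitution is C>T (replication over uracil,
    2/3) or C>G (error-prone repair, 1/3); a GYW hotspot G mirrors this on
    the complementary strand (G>A / G>C).  Elsewhere all three alternate
    bases are equally likely.
    """
    chars = list(seq)
    for pos in positions:
        base = chars[pos]
        if pos in hot and base == "C":
            chars[pos] = "T" if rng.random() < 2 / 3 else "G"
        elif pos in hot and base == "G":
            chars[pos] = "A" if rng.random() < 2 / 3 else "C"
        else:
            choices = [b for b in "ACGT" if b != base]
            chars[pos] = choices[int(rng.integers(3))]
    return "".join(chars)


def _variant_cloud(
    ancestor: str,
    n_variants: int,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> list[tuple[str, int, tuple[int, ...]]]:
    """Star-like cloud: (variant sequence, distance, mutated positions) triples."""
    weights = hotspot_weights(ancestor, cfg.hotspot_multiplier)
    probs = weights / weights.sum()
    hot = {i for i, w in enumerate(weights) if w > 1}
    out = []
    L = len(ancestor)
    p_geom = 1.0 / cfg.variant_distance_mean
    for _ in range(n_variants):
        d = int(rng.geometric(p_geom))
        for _retry in range(100):
            if d <= cfg.max_variant_distance:
                break
            d = int(rng.geometric(p_geom))
        d = min(d, cfg.max_variant_distance)
        positions = tuple(sorted(int(p) for p in rng.choice(L, size=d, replace=False, p=probs)))
        out.append((_aid_mutate(ancestor, positions, hot, rng), d, positions))
    return out


def simulate_clone(
    cfg: SimConfig,
    db: GermlineDB,
    sample_id: str = "clone",
    patient_id: str = "P1",
    clone_id: int = 1,
    salt: int = 0,
    reserve_upstream: int = 0,
) -> SimulatedClone:
    """One clone: an ancestral rearrangement with a star-like SHM variant cloud.

    The ancestor carries the plurality of reads; each variant sits a
    truncated-geometric number of substitutions (<= 8 by default) from the
    ancestor, placed uniformly or with WRC/GYW hotspot weighting, and is
    supported by at least 2 reads.  ``reserve_upstream`` guarantees room in
    the locus for that many later V-replacement subclones.
    """
    rng = cfg.rng("clone", salt)
    event = _draw_event(
        cfg, db, rng, reserve_upstream=reserve_upstream, min_n=cfg.clone_min_n_length
    )
    ancestor = event.sequence(db)
    counts: dict[str, int] = {ancestor: cfg.clone_ancestor_reads}
    truth_rows = [
        {
            "origin": f"clone{clone_id}",
            "role": "ancestor",
            "v_name": event.v_name,
            "v_locus_index": event.v_locus_index,
            "d_name": event.d_name,
            "j_name": event.j_name,
            "stem_true": event.true_stem(db),
            "seq": ancestor,
            "distance": 0,
            "positions": (),
            "count": cfg.clone_ancestor_reads,
        }
    ]
    for seq, d, positions in _variant_cloud(ancestor, cfg.clone_variants, cfg, rng):
        c = 2 + int(rng.poisson(cfg.variant_read_mean - 2))
        counts[seq] = counts.get(seq, 0) + c
        truth_rows.append(
            {
                "origin": f"clone{clone_id}",
                "role": "variant",
                "v_name": event.v_name,
                "v_locus_index": event.v_locus_index,
                "d_name": event.d_name,
                "j_name": event.j_name,
                "stem_true": event.true_stem(db),
                "seq": seq,
                "distance": d,
                "positions": positions,
                "count": c,
            }
        )
    rep = Repertoire.from_counts(_meta(sample_id, patient_id), counts)
    return SimulatedClone(rep, pd.DataFrame(truth_rows), ancestor, event, db)


def add_secondary_rearrangement(
    clone: SimulatedClone,
    cfg: SimConfig,
    k: int,
    salt: int = 0,
) -> SimulatedClone:
    """Add ``k`` subclones sharing the clone's D-J tail with upstream V genes.

    Each subclone splices a distinct V gene that lies strictly upstream of
    the original V (higher locus index) onto the identical N-D-N-J tail,
    so all subclones carry exactly the same stem as the founding clone.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    db = clone.db
    rng = cfg.rng("secondary", salt)
    order = db.v_locus_order
    if order is None:
        raise SimulationError("germline reference lacks a recorded V locus order")
    upstream = [name for i, name in enumerate(order) if i > clone.event.v_locus_index]
    if len(upstream) < k:
        raise SimulationError(
            f"need {k} upstream V genes beyond locus index "
            f"{clone.event.v_locus_index}, only {len(upstream)} available"
        )
    chosen = sorted(rng.choice(upstream, size=k, replace=False).tolist())
    counts = dict(clone.repertoire.counts)
    truth_rows = []
    subclone_events = list(clone.subclone_events)
    for v_name in chosen:
        event = replace(clone.event, v_name=v_name, v_locus_index=order.index(v_name))
        seq = event.sequence(db)
        counts[seq] = counts.get(seq, 0) + cfg.secondary_reads
        subclone_events.append(event)
        truth_rows.append(
            {
                "origin": "secondary",
                "role": "ancestor",
                "v_name": v_name,
                "v_locus_index": event.v_locus_index,
                "d_name": event.d_name,
                "j_name": event.j_name,
                "stem_true": event.true_stem(db),
                "seq": seq,
                "distance": 0,
                "positions": (),
                "count": cfg.secondary_reads,
            }
        )
    rep = Repertoire.from_counts(clone.repertoire.meta, counts)
    truth = pd.concat([clone.truth, pd.DataFrame(truth_rows)], ignore_index=True)
    return SimulatedClone(
        rep, truth, clone.ancestor_seq, clone.event, db, subclone_events
    )


def mix_repertoires(
    components: Sequence[tuple[Repertoire, float]],
    background: Repertoire | None,
    depth: int,
    error_rate: float,
    rng: np.random.Generator,
    sample_id: str = "mixed",
    patient_id: str = "P1",
    day: int = 0,
) -> Repertoire:
    """Binomially resample a mixture of repertoires at a given read depth.

    Each read is assigned to a component with its configured fraction (the
    background absorbs the remainder) and then to a sequence within the
    component according to the component's internal read frequencies;
    independent per-base substitution errors are applied afterwards.
    """
    fracs = [f for _, f in components]
    if any(f < 0 for f in fracs) or sum(fracs) > 1 + 1e-12:
        raise ValueError("component fractions must be non-negative and sum to <= 1")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    probs = list(fracs)
    reps = [r for r, _ in components]
    if background is not None:
        reps.append(background)
        probs.append(max(0.0, 1.0 - sum(fracs)))
    alloc = rng.multinomial(depth, np.array(probs) / sum(probs))
    counts: dict[str, int] = {}
    for rep, n in zip(reps, alloc):
        if n == 0:
            continue
        seqs = [u.seq for u in rep.sequences]
        weights = np.array([u.count for u in rep.sequences], dtype=float)
        draw = rng.multinomial(int(n), weights / weights.sum())
        for s, c in zip(seqs, draw):
            if c:
                counts[s] = counts.get(s, 0) + int(c)
    counts = _apply_read_errors(counts, error_rate, rng)
    return Repertoire.from_counts(_meta(sample_id, patient_id, day), counts)


def dilute_and_sequence(
    clone_rep: Repertoire | None,
    healthy_rep: Repertoire,
    ratio: float,
    depth: int,
    error_rate: float | None = None,
    cfg: SimConfig | None = None,
    salt: int = 0,
    sample_id: str = "diluted",
    day: int = 0,
) -> Repertoire:
    """Dilute a clone into healthy background and resequence at ``depth`` reads.

    Clone reads are drawn binomially with probability ``ratio`` times the
    clone-internal sequence frequency; the expected clonotypic read count
    is ``depth * ratio``.  ``ratio`` may be 0 (or ``clone_rep`` None) for a
    clone-free background.
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("ratio must lie in [0, 1]")
    if error_rate is None:
        error_rate = cfg.error_rate if cfg is not None else 0.0
    rng = cfg.rng("sequence", salt) if cfg is not None else np.random.default_rng(salt)
    components = [] if clone_rep is None or ratio == 0 else [(clone_rep, ratio)]
    patient = healthy_rep.meta.patient_id if clone_rep is None else clone_rep.meta.patient_id
    return mix_repertoires(
        components, healthy_rep, depth, error_rate, rng,
        sample_id=sample_id, patient_id=patient, day=day,
    )


def enforce_signature_separation(
    healthy_rep: Repertoire,
    signature_seqs: Sequence[str],
    min_distance: int = 9,
) -> tuple[Repertoire, int]:
    """Drop healthy sequences within ``min_distance - 1`` substitutions of a signature.

    Guarantees by construction that a clone-free background cannot produce
    false-positive matches when mined at ``min_distance - 1`` mismatches.
    Under the default divergent germline this almost never removes anything;
    the number of dropped unique sequences is returned.
    """
    dist = match_distances(signature_seqs, healthy_rep)
    keep = [u for u, d in zip(healthy_rep.sequences, dist) if d >= min_distance]
    dropped = len(healthy_rep.sequences) - len(keep)
    return Repertoire(healthy_rep.meta, keep), dropped


@dataclass
class DiagnosisRelapsePair:
    """A clone observed at diagnosis and relapse with a planted shared fraction."""

    diagnosis: Repertoire
    relapse: Repertoire
    ancestor_seq: str
    shared_seqs: set[str]
    diag_variant_seqs: set[str]
    relapse_variant_seqs: set[str]
    event: VdjEvent


def simulate_diagnosis_relapse(
    cfg: SimConfig,
    db: GermlineDB,
    patient_id: str = "P1",
    salt: int = 0,
) -> DiagnosisRelapsePair:
    """Diagnosis and relapse clouds around one ancestor, sharing a planted fraction.

    Exactly ``round(shared_variant_fraction * clone_variants)`` diagnosis
    variants recur at relapse (with freshly drawn read counts); the
    remaining relapse variants are new draws from the same star-like cloud.
    """
    rng = cfg.rng("relapse", salt)
    event = _draw_event(cfg, db, rng, min_n=cfg.clone_min_n_length)
    ancestor = event.sequence(db)
    cloud = _variant_cloud(ancestor, cfg.clone_variants, cfg, rng)
    diag_variants = sorted({seq for seq, _, _ in cloud})
    n_shared = int(round(cfg.shared_variant_fraction * len(diag_variants)))
    shared = sorted(rng.choice(diag_variants, size=n_shared, replace=False).tolist())
    n_new = max(0, cfg.clone_variants - n_shared)
    new_cloud = _variant_cloud(ancestor, n_new, cfg, rng)
    relapse_variants = sorted(
        set(shared) | ({s for s, _, _ in new_cloud} - set(diag_variants))
    )

    def _counts(variant_seqs: Sequence[str]) -> dict[str, int]:
        counts = {ancestor: cfg.clone_ancestor_reads}
        for s in variant_seqs:
            counts[s] = counts.get(s, 0) + 2 + int(rng.poisson(cfg.variant_read_mean - 2))
        return counts

    diag = Repertoire.from_counts(_meta("diagnosis", patient_id, day=0), _counts(diag_variants))
    relapse = Repertoire.from_counts(
        _meta("relapse", patient_id, day=1000), _counts(relapse_variants)
    )
    return DiagnosisRelapsePair(
        diagnosis=diag,
        relapse=relapse,
        ancestor_seq=ancestor,
        shared_seqs=set(shared),
        diag_variant_seqs=set(diag_variants),
        relapse_variant_seqs=set(relapse_variants),
        event=event,
    )
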