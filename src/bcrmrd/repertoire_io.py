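"""Reading, collapsing and serialising BCR repertoires and germline references.

A *repertoire* is the collapsed multiset of unique heavy-chain amplicon
sequences observed in one sample, each with the number of identical reads
supporting it, plus the sample metadata (patient, day, tissue, template).
It is the universal currency passed between every stage of the pipeline.

Sequences are canonicalised to uppercase with U mapped to T (RNA-derived
amplicons are sequenced as cDNA).  Reads are used in the orientation given:
the amplicon protocol this emulates produces oriented reads, so there is no
reverse-complement rescue.  Tables are tab-separated with a header, in the
spirit of the community rearrangement-table (AIRR TSV) convention.
"""

from __future__ import annotations

import gzip
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping

import pandas as pd
from Bio import SeqIO

from .errors import EmptyRepertoireError, FormatError, SchemaError

TISSUES = frozenset({"BM", "PB", "CSF", "synthetic"})
TEMPLATES = frozenset({"RNA", "DNA"})
NUCLEOTIDES = frozenset("ACGTN")

#: column order of the repertoire table dialect
TABLE_COLUMNS = (
    "sequence",
    "count",
    "sample_id",
    "patient_id",
    "day",
    "tissue",
    "template",
    "external_mrd",
)

_U_TO_T = str.maketrans("Uu", "Tt")


def canonicalize(seq: str) -> str:
    """Uppercase a nucleotide string and map U to T."""
    return seq.translate(_U_TO_T).upper()


@dataclass(frozen=True)
class SampleMeta:
    """Identity and provenance of one sequenced sample.

    ``external_mrd`` carries an externally measured disease level for the
    same sample — e.g. a fusion-gene qPCR T/C ratio or a %-blasts count —
    used only for correlation against the sequence-based MRD estimate.
    """

    sample_id: str
    patient_id: str
    day: int
    tissue: str
    template: str
    external_mrd: float | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if int(self.day) != self.day or self.day < 0:
            raise ValueError(f"day must be a non-negative integer, got {self.day!r}")
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {sorted(TISSUES)}, got {self.tissue!r}")
        if self.template not in TEMPLATES:
            raise ValueError(f"template must be one of {sorted(TEMPLATES)}, got {self.template!r}")


@dataclass(frozen=True)
class UniqueSequence:
    """One unique nucleotide sequence with its identical-read count."""

    seq: str
    count: int

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("seq must be non-empty")
        if self.seq != self.seq.upper() or not set(self.seq) <= NUCLEOTIDES:
            raise ValueError(f"seq must be uppercase over ACGTN: {self.seq[:30]!r}")
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")


@dataclass
class Repertoire:
    """A sample's collapsed unique-sequence table."""

    meta: SampleMeta
    sequences: list[UniqueSequence]

    def __post_init__(self) -> None:
        seen = set()
        for u in self.sequences:
            if u.seq in seen:
                raise ValueError(f"duplicate sequence in repertoire: {u.seq[:30]!r}")
            seen.add(u.seq)

    @classmethod
    def from_counts(cls, meta: SampleMeta, counts: Mapping[str, int]) -> "Repertoire":
        return cls(meta, [UniqueSequence(s, c) for s, c in counts.items()])

    @property
    def total_reads(self) -> int:
        return sum(u.count for u in self.sequences)

    @property
    def counts(self) -> dict[str, int]:
        return {u.seq: u.count for u in self.sequences}

    def frequencies(self) -> dict[str, float]:
        total = self.total_reads
        return {u.seq: u.count / total for u in self.sequences}

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class GermlineDB:
    """IMGT-style germline segment reference, one map per segment class.

    ``v_locus_order`` (optional) lists V gene names from the D-proximal end
    of the locus outward; it is recorded by the simulator so that the
    directionality of V-replacement events can be checked.
    """

    v_genes: dict[str, str]
    d_genes: dict[str, str]
    j_genes: dict[str, str]
    v_locus_order: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for cls_name, genes in (("V", self.v_genes), ("D", self.d_genes), ("J", self.j_genes)):
            for name, seq in genes.items():
                if not seq:
                    raise ValueError(f"{cls_name} gene {name!r} has an empty sequence")

    @property
    def n_genes(self) -> tuple[int, int, int]:
        return (len(self.v_genes), len(self.d_genes), len(self.j_genes))


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _guess_format(path: Path) -> str:
    name = path.name[:-3] if path.suffix == ".gz" else path.name
    if name.endswith((".fastq", ".fq")):
        return "fastq"
    return "fasta"


def read_reads(
    path: str | Path,
    meta: SampleMeta,
    min_length: int = 100,
    max_n_fraction: float = 0.0,
) -> Repertoire:
    """Read FASTA/FASTQ reads (gz-transparent), filter and collapse.

    Reads shorter than ``min_length`` or with an N fraction above
    ``max_n_fraction`` are dropped; identical surviving reads are collapsed
    with summed counts.  This is a deliberately minimal length/ambiguity
    filter, not a reproduction of any upstream quality pipeline.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    if not 0.0 <= max_n_fraction <= 1.0:
        raise ValueError("max_n_fraction must lie in [0, 1]")
    path = Path(path)
    fmt = _guess_format(path)
    counts: Counter[str] = Counter()
    with _open_text(path) as handle:
        records = SeqIO.parse(handle, fmt)
        i = 0
        while True:
            try:
                record = next(records, None)
            except ValueError as exc:  # Biopython raises ValueError on bad records
                raise FormatError(f"{path}: malformed {fmt} record #{i + 1}: {exc}") from exc
            if record is None:
                break
            i += 1
            seq = canonicalize(str(record.seq))
            if not set(seq) <= NUCLEOTIDES:
                raise FormatError(
                    f"{path}: record #{i} ({record.id}) has non-nucleotide characters"
                )
            if len(seq) < min_length:
                continue
            if seq.count("N") > max_n_fraction * len(seq):
                continue
            counts[seq] += 1
    if not counts:
        raise EmptyRepertoireError(f"{path}: no reads survived filtering")
    return Repertoire.from_counts(meta, counts)


def write_repertoire(rep: Repertoire, path: str | Path) -> Path:
    """Write a repertoire as a TSV table (sequence, count, metadata columns)."""
    path = Path(path)
    m = rep.meta
    df = pd.DataFrame(
        {
            "sequence": [u.seq for u in rep.sequences],
            "count": [u.count for u in rep.sequences],
            "sample_id": m.sample_id,
            "patient_id": m.patient_id,
            "day": m.day,
            "tissue": m.tissue,
            "template": m.template,
            "external_mrd": m.external_mrd,
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_repertoire(path: str | Path) -> Repertoire:
    """Read a repertoire TSV written by :func:`write_repertoire`.

    Duplicate sequence rows are merged (counts summed) with a warning;
    non-positive counts raise a :class:`SchemaError`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str})
    missing = [c for c in TABLE_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    if len(df) == 0:
        raise EmptyRepertoireError(f"{path}: empty repertoire table")
    if (df["count"] < 1).any() or (df["count"] != df["count"].astype(int)).any():
        raise SchemaError(f"{path}: counts must be positive integers")
    if df["sequence"].duplicated().any():
        warnings.warn(f"{path}: duplicate sequence rows merged", stacklevel=2)
        df = df.groupby("sequence", as_index=False, sort=False).agg(
            {c: ("sum" if c == "count" else "first") for c in df.columns if c != "sequence"}
        )
    first = df.iloc[0]
    ext = first.get("external_mrd")
    meta = SampleMeta(
        sample_id=str(first["sample_id"]),
        patient_id=str(first["patient_id"]),
        day=int(first["day"]),
        tissue=str(first["tissue"]),
        template=str(first["template"]),
        external_mrd=None if ext is None or pd.isna(ext) else float(ext),
    )
    seqs = [
        UniqueSequence(canonicalize(s), int(c)) for s, c in zip(df["sequence"], df["count"])
    ]
    return Repertoire(meta, seqs)


def load_germline(
    path: str | Path,
    segment_class_rule: Callable[[str], str] | None = None,
) -> GermlineDB:
    """Load an IMGT-style germline FASTA into a :class:`GermlineDB`.

    The segment class of each record is inferred from its name prefix
    (IGHV / IGHD / IGHJ, case-insensitive) or from ``segment_class_rule``,
    a callable mapping gene name -> one of {"V", "D", "J"}.  Headers may
    carry a ``locus_index=<i>`` tag on V genes recording their position in
    the locus (0 = D-proximal); when every V gene has one, the locus order
    is reconstructed.
    """
    path = Path(path)
    classes: dict[str, dict[str, str]] = {"V": {}, "D": {}, "J": {}}
    locus_index: dict[str, int] = {}
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            name = record.id
            if segment_class_rule is not None:
                cls = segment_class_rule(name)
            else:
                upper = name.upper()
                if upper.startswith("IGHV"):
                    cls = "V"
                elif upper.startswith("IGHD"):
                    cls = "D"
                elif upper.startswith("IGHJ"):
                    cls = "J"
                else:
                    raise FormatError(
                        f"{path}: cannot classify germline record {record.description!r}"
                    )
            if cls not in classes:
                raise FormatError(f"{path}: rule returned invalid class {cls!r} for {name!r}")
            if name in classes[cls]:
                raise FormatError(f"{path}: duplicate gene name {name!r}")
            classes[cls][name] = canonicalize(str(record.seq))
            for token in record.description.split():
                if token.startswith("locus_index="):
                    locus_index[name] = int(token.split("=", 1)[1])
    order = None
    if locus_index and set(locus_index) >= set(classes["V"]):
        order = tuple(sorted(classes["V"], key=lambda n: locus_index[n]))
    return GermlineDB(classes["V"], classes["D"], classes["J"], v_locus_order=order)


def write_germline(db: GermlineDB, path: str | Path) -> Path:
    """Write a germline DB as FASTA, tagging V genes with their locus index."""
    path = Path(path)
    order = {name: i for i, name in enumerate(db.v_locus_order or ())}
    with open(path, "w") as out:
        for name, seq in db.v_genes.items():
            tag = f" locus_index={order[name]}" if name in order else ""
            out.write(f">{name}{tag}\n{seq}\n")
        for genes in (db.d_genes, db.j_genes):
            for name, seq in genes.items():
                out.write(f">{name}\n{seq}\n")
    return path
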