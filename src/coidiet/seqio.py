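"""Readers and writers for the pipeline's external formats.

Formats covered: FASTA, FASTQ (phred+33), newick (plain and the jplace
dialect, via :mod:`coidiet.tree`), jplace JSON documents, and TSV tables
with a header row.

FASTA reading is line-tracked so malformed records can be reported with
their line number; FASTQ goes through Biopython with errors mapped onto
:class:`~coidiet.errors.FormatError`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

from Bio import SeqIO

from .errors import FormatError, ValidationError
from .tree import PhyloTree, read_newick, write_newick

log = logging.getLogger(__name__)

VALID_BASES = set("ACGTN")
ALIGNMENT_CHARS = VALID_BASES | {"-"}

__all__ = [
    "SequenceRecord",
    "PlacementEntry",
    "QueryPlacement",
    "JplaceDocument",
    "JPLACE_FIELDS",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_newick",
    "write_newick",
    "read_jplace",
    "write_jplace",
    "read_table",
]


@dataclass
class SequenceRecord:
    """A single read or reference sequence.

    ``bases`` is uppercase over {A,C,G,T,N} (plus '-' when the record is a
    row of an alignment); ``qualities`` are phred scores aligned 1:1 with
    the bases when present.
    """

    id: str
    bases: str
    sample_id: str = ""
    qualities: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record with empty id")
        if not self.bases:
            raise ValidationError(f"record {self.id!r} has an empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.bases):
            raise ValidationError(
                f"record {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.bases)} bases"
            )

    def __len__(self) -> int:
        return len(self.bases)


def _normalize_bases(raw: str, where: str, allow_gaps: bool) -> str:
    allowed = ALIGNMENT_CHARS if allow_gaps else VALID_BASES
    up = raw.upper()
    if set(up) <= allowed:
        return up
    cleaned = "".join(c if c in allowed else "N" for c in up)
    n_mapped = sum(1 for a, b in zip(up, cleaned) if a != b)
    log.warning("%s: %d non-ACGTN characters mapped to N", where, n_mapped)
    return cleaned


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path, sample_id: str = "", allow_gaps: bool = False) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    header: Optional[str] = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        if not chunks:
            raise FormatError(f"{path}:{header_line}: record {header!r} has no sequence")
        bases = _normalize_bases("".join(chunks), f"{path}:{header_line}", allow_gaps)
        records.append(SequenceRecord(id=header, bases=bases, sample_id=sample_id))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                # the full header (minus '>') is the id: reference labels
                # are binomials and legitimately contain spaces
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"{path}:{lineno}: sequence data before any '>' header")
                chunks.append(line)
        flush()
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"{path}: duplicate record ids {dupes}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.bases), width):
                fh.write(rec.bases[i:i + width] + "\n")


def read_fastq(path, sample_id: Optional[str] = None) -> list[SequenceRecord]:
    """Read a phred+33 FASTQ file; sample id defaults to the file stem."""
    if sample_id is None:
        sample_id = Path(path).stem
    records: list[SequenceRecord] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            bases = _normalize_bases(str(rec.seq), f"{path}:{rec.id}", allow_gaps=False)
            records.append(
                SequenceRecord(
                    id=rec.id,
                    bases=bases,
                    sample_id=sample_id,
                    qualities=list(rec.letter_annotations["phred_quality"]),
                )
            )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return records


def write_fastq(records: Sequence[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            quals = rec.qualities
            if quals is None:
                quals = [40] * len(rec.bases)
            qline = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{rec.id}\n{rec.bases}\n+\n{qline}\n")


# ---------------------------------------------------------------------------
# jplace
# ---------------------------------------------------------------------------

JPLACE_FIELDS = [
    "edge_num",
    "likelihood",
    "like_weight_ratio",
    "distal_length",
    "pendant_length",
]


@dataclass
class PlacementEntry:
    edge_num: int
    likelihood: float
    like_weight_ratio: float
    distal_length: float
    pendant_length: float

    def validate(self) -> None:
        if not (0.0 <= self.like_weight_ratio <= 1.0 + 1e-12):
            raise ValidationError(
                f"like_weight_ratio {self.like_weight_ratio} outside [0,1]"
            )
        if self.pendant_length < 0:
            raise ValidationError(f"negative pendant_length {self.pendant_length}")


@dataclass
class QueryPlacement:
    name: str
    multiplicity: float
    entries: list[PlacementEntry]


@dataclass
class JplaceDocument:
    tree: PhyloTree
    placements: list[QueryPlacement]
    version: int = 3
    metadata: dict = field(default_factory=dict)
    fields: list[str] = field(default_factory=lambda: list(JPLACE_FIELDS))

    def validate(self) -> None:
        edge_nums = {e.edge_num for e in self.tree.edges()}
        for qp in self.placements:
            for entry in qp.entries:
                entry.validate()
                if entry.edge_num not in edge_nums:
                    raise ValidationError(
                        f"placement of {qp.name!r} references unknown edge "
                        f"{entry.edge_num}"
                    )


def read_jplace(path) -> JplaceDocument:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    missing = [k for k in ("tree", "placements", "fields", "version") if k not in doc]
    if missing:
        raise FormatError(f"{path}: missing required jplace keys {missing}")
    missing_fields = [f for f in JPLACE_FIELDS if f not in doc["fields"]]
    if missing_fields:
        raise FormatError(f"{path}: fields list omits {missing_fields}")
    index = {name: doc["fields"].index(name) for name in JPLACE_FIELDS}

    tree = read_newick(doc["tree"], edge_numbers=True)
    placements: list[QueryPlacement] = []
    for p in doc["placements"]:
        if "nm" in p:
            name, mult = p["nm"][0][0], float(p["nm"][0][1])
        elif "n" in p:
            name, mult = p["n"][0], 1.0
        else:
            raise FormatError(f"{path}: placement without 'n' or 'nm' key")
        entries = [
            PlacementEntry(
                edge_num=int(row[index["edge_num"]]),
                likelihood=float(row[index["likelihood"]]),
                like_weight_ratio=float(row[index["like_weight_ratio"]]),
                distal_length=float(row[index["distal_length"]]),
                pendant_length=float(row[index["pendant_length"]]),
            )
            for row in p["p"]
        ]
        placements.append(QueryPlacement(name=name, multiplicity=mult, entries=entries))
    out = JplaceDocument(
        tree=tree,
        placements=placements,
        version=int(doc["version"]),
        metadata=doc.get("metadata", {}),
    )
    out.validate()
    return out


def write_jplace(doc: JplaceDocument, path) -> None:
    doc.validate()
    payload = {
        "version": 3,
        "tree": write_newick(doc.tree, edge_numbers=True),
        "fields": list(JPLACE_FIELDS),
        "placements": [
            {
                "p": [
                    [
                        e.edge_num,
                        e.likelihood,
                        e.like_weight_ratio,
                        e.distal_length,
                        e.pendant_length,
                    ]
                    for e in qp.entries
                ],
                "nm": [[qp.name, qp.multiplicity]],
            }
            for qp in doc.placements
        ],
        "metadata": doc.metadata,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_table(path, schema: dict[str, Callable]) -> list[dict]:
    """Read a TSV with a header row.

    *schema* maps required column names to type constructors. Columns are
    matched by name, so order is irrelevant; unknown columns are kept as
    strings. A missing schema column raises :class:`FormatError`.
    """
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise FormatError(f"{path}: empty file, expected a header row")
        header = header_line.rstrip("\n").split("\t")
        missing = [c for c in schema if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required columns {missing}")
        rows: list[dict] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            values = line.rstrip("\n").split("\t")
            if len(values) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: {len(values)} fields, header has {len(header)}"
                )
            row: dict = {}
            for name, value in zip(header, values):
                if name in schema:
                    try:
                        row[name] = schema[name](value)
                    except ValueError as exc:
                        raise FormatError(f"{path}:{lineno}: column {name!r}: {exc}") from exc
                else:
                    row[name] = value
            rows.append(row)
    return rows


def write_table(rows: Sequence[dict], path, columns: Optional[list[str]] = None) -> None:
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")
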