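"""Sequence and table I/O plus translation utilities shared by all stages.

Sequences are plain nucleotide strings over ``{A, C, G, T, N}``, uppercase.
Internally every coordinate is 0-based half-open; TSV output uses 1-based
inclusive coordinates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

log = logging.getLogger("paleoploid")

VALID_BASES = frozenset("ACGTN")

#: standard genetic code, codon -> one-letter amino acid ('*' for stops)
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"

STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in CODON_TABLE if c not in STOP_CODONS)
)


@dataclass(frozen=True)
class SequenceRecord:
    """A single identified nucleotide sequence (contig / transcript)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class AnnotationTable:
    """Flat term <-> sequence assignments for one sequence set.

    ``total`` is the number of annotated sequences in the set; it may exceed
    the number of distinct seq_ids present in ``rows`` when the table was
    subset to terms of interest.
    """

    rows: pd.DataFrame  # columns: term_id, seq_id
    total: int = 0
    unknown_seq_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if list(self.rows.columns[:2]) != ["term_id", "seq_id"]:
            self.rows = self.rows.rename(
                columns=dict(zip(self.rows.columns[:2], ["term_id", "seq_id"]))
            )
        if self.rows.duplicated(["term_id", "seq_id"]).any():
            raise ValueError("duplicate (term_id, seq_id) annotation rows")
        if self.total == 0:
            self.total = self.rows["seq_id"].nunique()

    def term_counts(self) -> pd.Series:
        return self.rows.groupby("term_id")["seq_id"].nunique()


def _clean_sequence(seq_id: str, raw: str, on_invalid: str = "map") -> str:
    """Uppercase and validate a nucleotide string.

    on_invalid: "map" replaces IUPAC ambiguity codes (and anything else
    non-ACGTN) with N and warns; "strict" raises.
    """
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - VALID_BASES
    if bad:
        if on_invalid == "strict":
            raise ValueError(
                f"sequence {seq_id!r} contains invalid characters {sorted(bad)}"
            )
        warnings.warn(
            f"sequence {seq_id!r}: mapped {sorted(bad)} to N", stacklevel=2
        )
        seq = "".join(c if c in VALID_BASES else "N" for c in seq)
    return seq


def read_fasta(path: str | Path, on_invalid: str = "map") -> list[SequenceRecord]:
    """Read a FASTA file into an ordered list of SequenceRecord.

    Sequences are uppercased; characters outside {A,C,G,T,N} are mapped to N
    (``on_invalid="map"``, default, with a warning) or rejected
    (``on_invalid="strict"``). Duplicate ids raise. An empty file yields an
    empty list with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, _clean_sequence(rec.id, str(rec.seq), on_invalid)))
    if not records:
        warnings.warn(f"FASTA file {path} contains no records", stacklevel=2)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def translate(seq: str, frame: int = 0) -> str:
    """Translate a nucleotide string in the given frame (standard code).

    The trailing partial codon is dropped; stops render ``*``; any codon
    containing N (or another non-ACGT character) renders ``X``.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    seq = seq.upper()
    out = []
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append(CODON_TABLE.get(codon, "X"))
    return "".join(out)


def write_table(rows: Sequence[Mapping] | pd.DataFrame, path: str | Path) -> None:
    """Write tabular records as TSV with a header row.

    Floats are rendered at 6 significant digits; rows are stable-sorted on
    the first column so re-runs are byte-identical.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    if not df.empty:
        df = df.sort_values(df.columns[0], kind="stable")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_annotation_table(path: str | Path, known_ids: set[str] | None = None) -> AnnotationTable:
    """Read a two-column (term_id, seq_id) TSV; flag seq_ids not in known_ids."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    table = AnnotationTable(df)
    if known_ids is not None:
        table.unknown_seq_ids = set(df["seq_id"]) - known_ids
        if table.unknown_seq_ids:
            log.warning(
                "%d annotation seq_ids not found in sequence set", len(table.unknown_seq_ids)
            )
    return table
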