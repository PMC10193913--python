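"""Sequence and segment-annotation I/O.

Residue coordinates throughout the package are 1-based and inclusive at both
ends, the convention used when a segment is written "I663-L673" (both endpoint
residues count).  A :class:`SequenceRecord` may store only a fragment of a
full-length protein; its ``numbering_offset`` records the residue number of
the first stored character minus one, so that segment annotations expressed in
full-length numbering resolve against fragments.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CANONICAL_RESIDUES",
    "ALLOWED_RESIDUES",
    "HELIX_CLASSES",
    "SequenceRecord",
    "SegmentAnnotation",
    "read_fasta",
    "write_fasta",
    "read_segment_table",
    "write_segment_table",
    "extract_segment",
]

#: The 20 canonical amino acids, one-letter codes.
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Residues accepted in a :class:`SequenceRecord`.  ``X`` marks an unknown
#: position and is handled downstream (it contributes the scale mean to a
#: flexibility profile).  Other ambiguity codes (B, Z, U, O, ``*``) are
#: rejected so that profile arithmetic stays well defined.
ALLOWED_RESIDUES = frozenset(CANONICAL_RESIDUES) | {"X"}

#: Helix classes used to label segments: canonical alpha, the two
#: non-canonical forms (pi, ~4.4 residues/turn; three10, i->i+3 hydrogen
#: bonded), plus loop and unknown.
HELIX_CLASSES = ("alpha", "pi", "three10", "loop", "unknown")

_OFFSET_TOKEN = "offset="


class FastaParseError(ValueError):
    """Raised when a file is not FASTA or contains an illegal residue."""


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence (or fragment) with explicit residue numbering.

    Parameters
    ----------
    id : str
        Accession or free-text identifier.
    residues : str
        Uppercase residues over the 20 canonical letters plus ``X``.
    description : str
        Free-text description (FASTA header remainder).
    numbering_offset : int
        Residue number of the first character minus one.  A full-length
        protein has offset 0; a fragment starting at residue 546 has
        offset 545.
    """

    id: str
    residues: str
    description: str = ""
    numbering_offset: int = 0

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord.id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for i, ch in enumerate(self.residues):
            if ch not in ALLOWED_RESIDUES:
                raise ValueError(
                    f"record {self.id!r}: illegal residue {ch!r} at "
                    f"position {i + 1} (allowed: 20 canonical letters + X)"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def first_residue_number(self) -> int:
        return self.numbering_offset + 1

    @property
    def last_residue_number(self) -> int:
        return self.numbering_offset + len(self.residues)

    def residue_at(self, number: int) -> str:
        """Return the residue letter at 1-based residue number ``number``."""
        idx = number - 1 - self.numbering_offset
        if not 0 <= idx < len(self.residues):
            raise IndexError(
                f"residue number {number} outside record {self.id!r} span "
                f"{self.first_residue_number}-{self.last_residue_number}"
            )
        return self.residues[idx]


@dataclass(frozen=True)
class SegmentAnnotation:
    """A named residue range with a helix-class label.

    ``start`` and ``end`` are 1-based residue numbers, both inclusive, in the
    numbering of the protein identified by ``protein_id``.
    """

    protein_id: str
    segment_name: str
    start: int
    end: int
    helix_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"segment {self.segment_name!r} of {self.protein_id!r}: "
                f"start {self.start} > end {self.end}"
            )
        if self.helix_class not in HELIX_CLASSES:
            raise ValueError(
                f"unknown helix_class {self.helix_class!r}; "
                f"allowed values: {', '.join(HELIX_CLASSES)}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


def _parse_offset(description: str) -> int:
    """Extract an ``offset=<int>`` token from a FASTA description, if any."""
    for token in description.split():
        if token.startswith(_OFFSET_TOKEN):
            try:
                return int(token[len(_OFFSET_TOKEN):])
            except ValueError as exc:
                raise FastaParseError(
                    f"malformed numbering token {token!r}"
                ) from exc
    return 0


def _strip_offset(description: str) -> str:
    return " ".join(
        t for t in description.split() if not t.startswith(_OFFSET_TOKEN)
    )


def read_fasta(path: Union[str, Path]) -> List[SequenceRecord]:
    """Read a multi-record FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased; gap characters and non-standard letters are
    rejected with the offending position named.  An ``offset=<int>`` token in
    a header sets the record's ``numbering_offset`` (the token is removed
    from the stored description).  An empty file yields an empty list.
    """
    path = Path(path)
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        first_line = text.splitlines()[0]
        raise FastaParseError(
            f"{path}: not FASTA (first line {first_line!r} does not start "
            "with '>')"
        )
    records: List[SequenceRecord] = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        if any(ch in "-." for ch in seq):
            pos = next(i for i, ch in enumerate(seq) if ch in "-.")
            raise FastaParseError(
                f"{path}, record {rec.id!r}: gap character at position "
                f"{pos + 1}; gapped/aligned sequences are not accepted"
            )
        description = rec.description
        if description.startswith(rec.id):
            description = description[len(rec.id):].strip()
        try:
            records.append(
                SequenceRecord(
                    id=rec.id,
                    residues=seq,
                    description=_strip_offset(description),
                    numbering_offset=_parse_offset(description),
                )
            )
        except ValueError as exc:
            raise FastaParseError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[SequenceRecord], path: Union[str, Path]) -> None:
    """Write records as FASTA, wrapped at 60 columns.

    A non-zero ``numbering_offset`` is stored as an ``offset=<int>`` header
    token so that a write/read round trip preserves the numbering.
    """
    path = Path(path)
    bio_records = []
    for rec in records:
        desc = rec.description
        if rec.numbering_offset:
            desc = f"{desc} {_OFFSET_TOKEN}{rec.numbering_offset}".strip()
        bio_records.append(
            SeqRecord(Seq(rec.residues), id=rec.id, description=desc)
        )
    with path.open("w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(bio_records)


_SEGMENT_COLUMNS = ["protein_id", "segment_name", "start", "end", "helix_class"]


def read_segment_table(path: Union[str, Path]) -> List[SegmentAnnotation]:
    """Read a tab-separated segment-annotation table.

    The file must carry the exact header
    ``protein_id  segment_name  start  end  helix_class`` (tab separated).
    Coordinates are parsed as integers; an inverted range or an unknown
    helix class raises ``ValueError``.
    """
    import pandas as pd

    path = Path(path)
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(table.columns) != _SEGMENT_COLUMNS:
        raise ValueError(
            f"{path}: expected header {_SEGMENT_COLUMNS}, "
            f"found {list(table.columns)}"
        )
    annotations = []
    for row in table.itertuples(index=False):
        try:
            start, end = int(row.start), int(row.end)
        except ValueError as exc:
            raise ValueError(
                f"{path}: non-integer coordinate in row {tuple(row)}"
            ) from exc
        annotations.append(
            SegmentAnnotation(
                protein_id=row.protein_id,
                segment_name=row.segment_name,
                start=start,
                end=end,
                helix_class=row.helix_class,
            )
        )
    return annotations


def write_segment_table(
    annotations: Sequence[SegmentAnnotation], path: Union[str, Path]
) -> None:
    """Write annotations as the tab-separated table `read_segment_table` reads."""
    lines = ["\t".join(_SEGMENT_COLUMNS)]
    for a in annotations:
        lines.append(
            f"{a.protein_id}\t{a.segment_name}\t{a.start}\t{a.end}\t{a.helix_class}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def extract_segment(
    record: SequenceRecord, annotation: SegmentAnnotation
) -> SequenceRecord:
    """Return the inclusive sub-record covered by ``annotation``.

    The returned record keeps the parent's id and gets a ``numbering_offset``
    such that residue numbers are preserved (its first residue is numbered
    ``annotation.start``).
    """
    lo, hi = record.first_residue_number, record.last_residue_number
    if annotation.start < lo or annotation.end > hi:
        raise IndexError(
            f"segment {annotation.segment_name!r} ({annotation.start}-"
            f"{annotation.end}) outside record {record.id!r} numbered span "
            f"{lo}-{hi}"
        )
    i0 = annotation.start - 1 - record.numbering_offset
    i1 = annotation.end - record.numbering_offset
    return SequenceRecord(
        id=record.id,
        residues=record.residues[i0:i1],
        description=f"{record.description} [{annotation.segment_name} "
        f"{annotation.start}-{annotation.end}]".strip(),
        numbering_offset=annotation.start - 1,
    )
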