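"""Packaged example data: ion-channel segment fixtures.

The library ships a small set of transmembrane-segment sequences used for
scale calibration, for the pi-versus-3(10) helix-class comparison, and in the
examples: the six S6 pi-region 11-mers of TRPV3/TRPV6/TRPM4/TRPM8/TRPC3/TRPA1,
two 3(10)-class segments (rat TRPV1 S4b, human hERG S5-PH linker), and two
held-out validation segments.  Some fixture entries are partial
reconstructions with unknown interior residues stored as ``X`` (see the FASTA
headers); they pin the calibration protocol reproducibly but are not
authoritative transcriptions of the underlying accessions.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from typing import Dict, List, Tuple

import pandas as pd

from .seq_io import SegmentAnnotation, SequenceRecord, read_fasta, read_segment_table

__all__ = [
    "channel_segments",
    "helix_class_annotations",
    "calibration_anchors",
    "calibration_anchor_records",
]


def _data_file(name: str):
    return resources.as_file(resources.files("seqflex.data") / name)


@lru_cache(maxsize=None)
def channel_segments() -> Tuple[SequenceRecord, ...]:
    """The packaged channel segment sequences (fragments with numbering)."""
    with _data_file("channel_segments.fasta") as p:
        return tuple(read_fasta(p))


def _segments_by_id() -> Dict[str, SequenceRecord]:
    return {rec.id: rec for rec in channel_segments()}


@lru_cache(maxsize=None)
def helix_class_annotations() -> Tuple[SegmentAnnotation, ...]:
    """Annotations for the pi-versus-3(10) comparison fixture set: six S6
    pi-region windows and two 3(10)-class segments."""
    with _data_file("helix_class_segments.tsv") as p:
        return tuple(read_segment_table(p))


@lru_cache(maxsize=None)
def calibration_anchors() -> pd.DataFrame:
    """Anchor table: segment ranges, printed target mBf values and roles
    (``calibration`` enters the affine fit, ``heldout`` is for validation)."""
    with _data_file("calibration_anchors.tsv") as p:
        return pd.read_csv(p, sep="\t", comment="#")


def calibration_anchor_records() -> List[Tuple[SequenceRecord, float, str]]:
    """Anchor segments resolved to sequence fragments.

    Returns ``(segment_record, target_mbf, role)`` triples; each record spans
    exactly the anchor's residue range.
    """
    by_id = _segments_by_id()
    out: List[Tuple[SequenceRecord, float, str]] = []
    for row in calibration_anchors().itertuples(index=False):
        rec = by_id[row.protein_id]
        if (rec.first_residue_number, rec.last_residue_number) != (row.start, row.end):
            raise ValueError(
                f"fixture mismatch for {row.protein_id}: record spans "
                f"{rec.first_residue_number}-{rec.last_residue_number}, "
                f"anchor {row.start}-{row.end}"
            )
        out.append((rec, float(row.target_mbf), str(row.role)))
    return out
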