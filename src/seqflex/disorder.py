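"""Per-residue intrinsic disorder tracks.

Disorder probabilities (pD, in [0, 1]) are produced by external predictors;
this module parses their per-residue exports and pairs them with sequences.
For offline work it also provides :func:`naive_disorder_score`, a clearly
labelled stand-in that smooths a packaged residue disorder-propensity table.
The stand-in is deliberately naive - it is not a re-implementation of any
machine-learning predictor and is never claimed to reproduce one; it exists
so the full pipeline (pairing, quotients, flagging) can run and be tested
with no external service.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .flexprofile import WindowSpec, _windowed_average, default_window
from .seq_io import SequenceRecord

__all__ = [
    "DisorderProfile",
    "read_disorder_profile",
    "write_disorder_profile",
    "naive_disorder_score",
    "binarize_disorder",
    "load_disorder_propensity",
]

#: Default cutoff for binary order/disorder calls: midpoint of the
#: probability scale.
DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class DisorderProfile:
    """Per-residue disorder probabilities aligned to a sequence."""

    record_id: str
    pd: np.ndarray
    source: str = "generic"
    threshold: float = DEFAULT_THRESHOLD
    residues: Optional[str] = None
    numbering_offset: int = 0

    def __post_init__(self) -> None:
        pd_arr = np.asarray(self.pd, dtype=float)
        if pd_arr.ndim != 1 or len(pd_arr) == 0:
            raise ValueError("pd must be a non-empty 1-D array")
        if np.any((pd_arr < 0) | (pd_arr > 1)):
            bad = int(np.argmax((pd_arr < 0) | (pd_arr > 1)))
            raise ValueError(
                f"pd value {pd_arr[bad]} at position {bad + 1} outside [0, 1]"
            )
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        if self.residues is not None and len(self.residues) != len(pd_arr):
            raise ValueError("residues length must match pd length")
        pd_arr.setflags(write=False)
        object.__setattr__(self, "pd", pd_arr)

    def __len__(self) -> int:
        return len(self.pd)

    @property
    def positions(self) -> np.ndarray:
        return np.arange(1, len(self.pd) + 1) + self.numbering_offset


def read_disorder_profile(
    path: Union[str, Path],
    dialect: str = "generic",
    threshold: float = DEFAULT_THRESHOLD,
) -> DisorderProfile:
    """Read a per-residue disorder track.

    Dialects
    --------
    ``generic``
        Tab-separated with header ``residue_number  residue  pd``.
    ``prdos-export``
        The per-residue CSV a PrDOS-style server offers for download:
        optional ``#`` comment lines, then rows
        ``residue_number,residue_letter,probability[,binary]``.

    Values outside [0, 1] or non-monotone residue numbering raise
    ``ValueError`` naming the offending row.
    """
    path = Path(path)
    if dialect not in ("generic", "prdos-export"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "\t" if dialect == "generic" else ","
    numbers: List[int] = []
    residues: List[str] = []
    values: List[float] = []
    lines = path.read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if stripped.lower().startswith("residue_number"):
            continue
        parts = [p.strip() for p in stripped.split(sep)]
        if len(parts) < 3:
            raise ValueError(
                f"{path}, line {lineno}: expected at least 3 {dialect} columns, "
                f"got {stripped!r}"
            )
        try:
            num = int(parts[0])
            val = float(parts[2])
        except ValueError as exc:
            raise ValueError(f"{path}, line {lineno}: cannot parse {stripped!r}") from exc
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{path}, line {lineno}: pd value {val} outside [0, 1]")
        if numbers and num <= numbers[-1]:
            raise ValueError(
                f"{path}, line {lineno}: residue numbering not strictly increasing"
            )
        numbers.append(num)
        residues.append(parts[1])
        values.append(val)
    if not values:
        raise ValueError(f"{path}: no disorder values found")
    return DisorderProfile(
        record_id=path.stem,
        pd=np.array(values),
        source="prdos-export" if dialect == "prdos-export" else "generic",
        threshold=threshold,
        residues="".join(residues),
        numbering_offset=numbers[0] - 1,
    )


def write_disorder_profile(profile: DisorderProfile, path: Union[str, Path]) -> None:
    """Write a track in the generic tab-separated dialect."""
    residues = profile.residues or "X" * len(profile)
    lines = ["residue_number\tresidue\tpd"]
    for pos, aa, v in zip(profile.positions, residues, profile.pd):
        lines.append(f"{pos}\t{aa}\t{v:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


@lru_cache(maxsize=None)
def load_disorder_propensity() -> Dict[str, float]:
    """The packaged per-residue disorder-propensity table (heuristic)."""
    values: Dict[str, float] = {}
    with resources.as_file(
        resources.files("seqflex.data") / "disorder_propensity.tsv"
    ) as p:
        for line in Path(p).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            aa, raw = line.split()
            values[aa] = float(raw)
    return values


def naive_disorder_score(
    record: SequenceRecord, window: Optional[WindowSpec] = None
) -> DisorderProfile:
    """Deterministic offline stand-in disorder scorer.

    Each residue's propensity is taken from the packaged table (X gets the
    table mean), smoothed with ``window``, and min-max rescaled to [0, 1]
    using the *table's* extrema - not the sequence's - so scores are
    comparable across proteins.  A homopolymer of the maximum-propensity
    residue therefore scores exactly 1 everywhere.
    """
    if window is None:
        window = default_window()
    table = load_disorder_propensity()
    mean = float(np.mean(list(table.values())))
    raw = np.array(
        [mean if ch == "X" else table[ch] for ch in record.residues], dtype=float
    )
    smoothed = _windowed_average(raw, window)
    lo, hi = min(table.values()), max(table.values())
    return DisorderProfile(
        record_id=record.id,
        pd=(smoothed - lo) / (hi - lo),
        source="naive-standin",
        residues=record.residues,
        numbering_offset=record.numbering_offset,
    )


def binarize_disorder(profile: DisorderProfile) -> np.ndarray:
    """Binary order/disorder verdict per residue: ``pd >= threshold``."""
    return profile.pd >= profile.threshold
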