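"""Sequence-derived side-chain flexibility profiles.

The model
---------
Crystallographic B-factors, standardized per structure set as

    nBf_i = (B_i - Bm) / Bsigma,

are a practical per-residue proxy for local mobility.  Averaged over many
structures they yield a 20-value intrinsic flexibility scale: each amino acid
gets a positive value in normalized-B-factor units, larger meaning a more
flexible side chain.  A sequence-only flexibility profile is then the scale
value of each residue smoothed over a short symmetric window (by default the
immediate N- and C-terminal neighbours with weights 1/4, 1/2, 1/4), and a
segment's mean flexibility index mBf is the arithmetic mean of the profile
over the segment.  Reciprocals 1/mBf are sometimes reported as "relative
flexibility"; both are exposed here, as is the literal negated mean for
callers that want the signed convention.

Because published per-residue scales differ from one another by roughly an
affine change of units, the packaged scale can be re-anchored to externally
known segment indices with a single gain/offset fit
(:func:`calibrate_scale`); the fit cannot reorder residues, which is the
scale's scientific content.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .seq_io import CANONICAL_RESIDUES, SequenceRecord

__all__ = [
    "BFactorSeries",
    "FlexibilityScale",
    "WindowSpec",
    "FlexProfile",
    "MeanFlexibility",
    "normalize_bfactors",
    "read_bfactor_series",
    "load_flex_scale",
    "save_flex_scale",
    "default_window",
    "flex_profile",
    "segment_mbf",
    "relative_flexibility",
    "calibrate_scale",
    "write_profile",
    "read_profile",
]

PACKAGED_SCALES = ("default", "vihinen")


# ---------------------------------------------------------------------------
# B-factor normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BFactorSeries:
    """Raw per-residue thermal factors (PDB B column, treated unitless)."""

    values: Tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    @property
    def mean(self) -> float:
        """Bm, the sample mean."""
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        """Bsigma, the sample (n-1) standard deviation."""
        return float(np.std(self.values, ddof=1))


def normalize_bfactors(series: BFactorSeries) -> np.ndarray:
    """Standardize a B-factor series: ``(B - Bm) / Bsigma``.

    The output has mean 0 and sample SD 1 by construction.  The sample
    (n-1) standard deviation is used, the common convention for per-structure
    B-factor normalization.
    """
    if len(series.values) < 2:
        raise ValueError("need at least 2 B-factors to normalize")
    sd = series.sd
    if sd == 0.0:
        raise ValueError("degenerate B-factor series (zero variance)")
    values = np.asarray(series.values, dtype=float)
    return (values - series.mean) / sd


def read_bfactor_series(path: Union[str, Path]) -> BFactorSeries:
    """Read a B-factor series from text: one value per line, or two columns
    (residue_number, B).  Lines starting with ``#`` are comments."""
    values: List[float] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        try:
            values.append(float(parts[-1]))
        except ValueError as exc:
            raise ValueError(f"{path}, line {lineno}: cannot parse {line!r}") from exc
    return BFactorSeries(tuple(values))


# ---------------------------------------------------------------------------
# Flexibility scale
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlexibilityScale:
    """Mapping from the 20 canonical residues to positive flexibility values.

    Values are in normalized-B-factor units; larger means a more flexible
    side chain.  ``provenance`` records the source and calibration state.
    """

    values: Mapping[str, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = sorted(set(CANONICAL_RESIDUES) - set(self.values))
        if missing:
            raise ValueError(f"scale is missing residues: {', '.join(missing)}")
        extra = sorted(set(self.values) - set(CANONICAL_RESIDUES))
        if extra:
            raise ValueError(f"scale has non-canonical entries: {', '.join(extra)}")
        for aa, v in self.values.items():
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"scale value for {aa} must be finite and > 0, got {v}")
        object.__setattr__(self, "values", dict(self.values))

    @property
    def mean(self) -> float:
        """Unweighted mean of the 20 values; assigned to unknown residue X."""
        return float(np.mean(list(self.values.values())))

    @property
    def min_value(self) -> float:
        return min(self.values.values())

    @property
    def max_value(self) -> float:
        return max(self.values.values())

    def value(self, residue: str) -> float:
        """Scale value of one residue letter; X maps to the scale mean."""
        if residue == "X":
            return self.mean
        try:
            return self.values[residue]
        except KeyError:
            raise KeyError(f"unknown residue letter {residue!r}") from None

    def sequence_values(self, residues: str) -> np.ndarray:
        mean = self.mean
        return np.array(
            [mean if ch == "X" else self.values[ch] for ch in residues], dtype=float
        )


def _parse_scale_file(path: Path) -> FlexibilityScale:
    values: Dict[str, float] = {}
    provenance_lines: List[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            provenance_lines.append(stripped.lstrip("# "))
            continue
        parts = stripped.split()
        if len(parts) != 2:
            raise ValueError(f"{path}, line {lineno}: expected 'RESIDUE value', got {line!r}")
        aa, raw = parts
        v = float(raw)
        if v <= 0:
            raise ValueError(f"{path}, line {lineno}: non-positive value {v} for {aa}")
        values[aa] = v
    return FlexibilityScale(values=values, provenance=" ".join(provenance_lines))


def save_flex_scale(scale: FlexibilityScale, path: Union[str, Path]) -> None:
    """Write a scale as two-column text with provenance comment lines."""
    lines = [f"# {scale.provenance}"] if scale.provenance else []
    for aa in CANONICAL_RESIDUES:
        lines.append(f"{aa}\t{scale.values[aa]:.12g}")
    Path(path).write_text("\n".join(lines) + "\n")


def _packaged_path(name: str):
    return resources.files("seqflex.data") / name


@lru_cache(maxsize=None)
def _raw_packaged_scale() -> FlexibilityScale:
    with resources.as_file(_packaged_path("flex_scale_vihinen.tsv")) as p:
        return _parse_scale_file(p)


@lru_cache(maxsize=None)
def _calibrated_default_scale() -> FlexibilityScale:
    # Anchored to the two published calibration segment indices packaged with
    # the library (see seqflex.datasets).  Import is local to avoid a cycle.
    from .datasets import calibration_anchor_records

    anchors = [
        (record, target)
        for record, target, role in calibration_anchor_records()
        if role == "calibration"
    ]
    return calibrate_scale(_raw_packaged_scale(), default_window(), anchors)


def load_flex_scale(source: Union[str, Path] = "default") -> FlexibilityScale:
    """Load a flexibility scale.

    ``source`` may be ``"default"`` (the packaged normalized-B-factor scale,
    affine-anchored to two published ion-channel segment indices),
    ``"vihinen"`` (the same scale uncalibrated), or a path to a two-column
    scale file.
    """
    if source == "default":
        return _calibrated_default_scale()
    if source == "vihinen":
        return _raw_packaged_scale()
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(
            f"unknown scale {source!r}: not a packaged name {PACKAGED_SCALES} "
            "and no such file"
        )
    return _parse_scale_file(path)


# ---------------------------------------------------------------------------
# Windows and profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowSpec:
    """Symmetric smoothing window: odd width, positive weights summing to 1."""

    width: int
    weights: Tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        if self.width < 1 or self.width % 2 == 0:
            raise ValueError(f"window width must be odd and >= 1, got {self.width}")
        if len(self.weights) != self.width:
            raise ValueError("weights length must equal window width")
        if any(w <= 0 for w in self.weights):
            raise ValueError("window weights must be positive")
        if abs(sum(self.weights) - 1.0) > 1e-12:
            raise ValueError("window weights must sum to 1 (within 1e-12)")
        for i in range(self.width):
            if abs(self.weights[i] - self.weights[self.width - 1 - i]) > 1e-12:
                raise ValueError("window weights must be symmetric about the center")

    @property
    def half_width(self) -> int:
        return self.width // 2


def default_window() -> WindowSpec:
    """Width-3 window weighting each residue with its immediate neighbours
    (1/4, 1/2, 1/4)."""
    return WindowSpec(width=3, weights=(0.25, 0.5, 0.25))


@dataclass(frozen=True)
class FlexProfile:
    """Per-residue flexibility track aligned to a sequence."""

    record_id: str
    residues: str
    nbf: np.ndarray
    scale_provenance: str
    window: WindowSpec
    numbering_offset: int = 0

    def __post_init__(self) -> None:
        nbf = np.asarray(self.nbf, dtype=float)
        if nbf.shape != (len(self.residues),):
            raise ValueError("profile length must equal sequence length")
        nbf.setflags(write=False)
        object.__setattr__(self, "nbf", nbf)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def positions(self) -> np.ndarray:
        """1-based residue numbers for each profile value."""
        return np.arange(1, len(self.residues) + 1) + self.numbering_offset

    def index_of(self, residue_number: int) -> int:
        idx = residue_number - 1 - self.numbering_offset
        if not 0 <= idx < len(self.residues):
            raise IndexError(
                f"residue number {residue_number} outside profile "
                f"{self.record_id!r} span {self.numbering_offset + 1}-"
                f"{self.numbering_offset + len(self.residues)}"
            )
        return idx


@dataclass(frozen=True)
class MeanFlexibility:
    """Segment mean flexibility index.

    ``mbf`` is the positive mean of the profile over the segment (larger =
    more flexible).  ``relative`` is its reciprocal 1/mBf, the quantity
    sometimes plotted as "relative flexibility".  ``literal_eq2`` optionally
    carries the signed value -mean(nBf) for callers using the negated
    convention; it is never used in comparisons here.
    """

    mbf: float
    n: int
    literal_eq2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("mean over an empty segment")
        if not (math.isfinite(self.mbf) and self.mbf > 0):
            raise ValueError(f"mbf must be positive and finite, got {self.mbf}")

    @property
    def relative(self) -> float:
        return 1.0 / self.mbf


def _windowed_average(values: np.ndarray, window: WindowSpec) -> np.ndarray:
    """Weighted moving average, truncating the window at the termini and
    renormalizing the remaining weights so each output stays a convex
    combination of the input values."""
    n = len(values)
    h = window.half_width
    num = np.zeros(n)
    den = np.zeros(n)
    for j, w in enumerate(window.weights):
        off = j - h
        lo, hi = max(0, -off), min(n, n - off)
        if lo >= hi:
            continue
        num[lo:hi] += w * values[lo + off:hi + off]
        den[lo:hi] += w
    return num / den


def flex_profile(
    record: SequenceRecord,
    scale: Optional[FlexibilityScale] = None,
    window: Optional[WindowSpec] = None,
) -> FlexProfile:
    """Compute the per-residue flexibility profile of a sequence.

    Each position gets the weight-renormalized windowed average of the scale
    values of the residues inside the window (truncated at the termini).
    Unknown residues (X) contribute the scale mean.
    """
    if scale is None:
        scale = load_flex_scale("default")
    if window is None:
        window = default_window()
    values = scale.sequence_values(record.residues)
    return FlexProfile(
        record_id=record.id,
        residues=record.residues,
        nbf=_windowed_average(values, window),
        scale_provenance=scale.provenance,
        window=window,
        numbering_offset=record.numbering_offset,
    )


def segment_mbf(
    profile: FlexProfile,
    start: int,
    end: int,
    with_literal_eq2: bool = False,
) -> MeanFlexibility:
    """Mean flexibility index over an inclusive residue-number range."""
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    i0 = profile.index_of(start)
    i1 = profile.index_of(end)
    window_slice = profile.nbf[i0:i1 + 1]
    mean = float(np.mean(window_slice))
    return MeanFlexibility(
        mbf=mean,
        n=len(window_slice),
        literal_eq2=-mean if with_literal_eq2 else None,
    )


def relative_flexibility(mf: MeanFlexibility) -> float:
    """Reciprocal 1/mBf of a segment index."""
    if mf.mbf <= 0:
        raise ValueError("relative flexibility undefined for non-positive mBf")
    return 1.0 / mf.mbf


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def _predicted_mbf(
    segment: SequenceRecord, scale: FlexibilityScale, window: WindowSpec
) -> float:
    profile = flex_profile(segment, scale, window)
    return float(np.mean(profile.nbf))


def calibrate_scale(
    scale: FlexibilityScale,
    window: WindowSpec,
    anchors: Sequence[Tuple[SequenceRecord, float]],
    floor: float = 0.05,
) -> FlexibilityScale:
    """Re-anchor a scale with a single affine adjustment (gain + offset).

    The gain/offset pair minimizes the squared error between each anchor
    segment's predicted mBf and its target value.  Because a positive-gain
    affine map cannot reorder residues, the relative flexibility ranking of
    the 20 amino acids is preserved by construction.  With no anchors the
    input scale is returned unchanged.

    The fit is solved under the constraint that every calibrated value stays
    at or above ``floor`` (> 0), so the result is always a valid scale; when
    the unconstrained optimum already satisfies the constraint it is returned
    exactly.  A degenerate fit (no spread among anchor predictions) falls
    back to an offset-only adjustment with a warning.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    if not anchors:
        return scale

    preds = np.array([_predicted_mbf(seg, scale, window) for seg, _ in anchors])
    targets = np.array([float(t) for _, t in anchors])
    vmin = scale.min_value

    spread = float(np.ptp(preds))
    if len(anchors) < 2 or spread < 1e-12:
        warnings.warn(
            "calibration anchors give no prediction spread; "
            "applying offset-only adjustment",
            stacklevel=2,
        )
        gain = 1.0
        offset = float(np.mean(targets) - np.mean(preds))
        if vmin + offset < floor:
            offset = floor - vmin
    else:
        pc = preds - preds.mean()
        gain = float(np.dot(pc, targets - targets.mean()) / np.dot(pc, pc))
        offset = float(targets.mean() - gain * preds.mean())
        if gain <= 0:
            raise ValueError(
                "calibration anchors demand a non-positive gain, which would "
                "invert the residue flexibility ordering; check anchor targets"
            )
        if gain * vmin + offset < floor:
            # Constrained optimum lies on the boundary gain*vmin + offset ==
            # floor; substitute and minimize over the gain alone.
            q = preds - vmin
            gain = float(np.dot(q, targets - floor) / np.dot(q, q))
            if gain <= 0:
                raise ValueError(
                    "constrained calibration demands a non-positive gain; "
                    "check anchor targets"
                )
            offset = floor - gain * vmin

    new_values = {aa: gain * v + offset for aa, v in scale.values.items()}
    provenance = (
        f"{scale.provenance} | affine-calibrated: gain={gain:.6g}, "
        f"offset={offset:.6g}, anchors={len(anchors)}"
    ).strip(" |")
    return FlexibilityScale(values=new_values, provenance=provenance)


# ---------------------------------------------------------------------------
# Profile I/O
# ---------------------------------------------------------------------------

def write_profile(profile: FlexProfile, path: Union[str, Path]) -> None:
    """Write a profile as tab-separated (residue_number, residue, nbf)."""
    lines = [
        f"# record={profile.record_id}",
        f"# scale={profile.scale_provenance}",
        f"# window_width={profile.window.width} "
        f"weights={','.join(f'{w:g}' for w in profile.window.weights)}",
        "residue_number\tresidue\tnbf",
    ]
    for pos, aa, v in zip(profile.positions, profile.residues, profile.nbf):
        lines.append(f"{pos}\t{aa}\t{v:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile(path: Union[str, Path]) -> FlexProfile:
    """Read a profile written by :func:`write_profile`."""
    record_id = str(Path(path).stem)
    scale_provenance = ""
    window = default_window()
    positions: List[int] = []
    residues: List[str] = []
    nbf: List[float] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("# record="):
            record_id = line.split("=", 1)[1]
        elif line.startswith("# scale="):
            scale_provenance = line.split("=", 1)[1]
        elif line.startswith("#") or line.startswith("residue_number"):
            continue
        elif line.strip():
            pos, aa, v = line.split("\t")
            positions.append(int(pos))
            residues.append(aa)
            nbf.append(float(v))
    if positions and np.any(np.diff(positions) != 1):
        raise ValueError(f"{path}: residue numbering is not consecutive")
    return FlexProfile(
        record_id=record_id,
        residues="".join(residues),
        nbf=np.array(nbf),
        scale_provenance=scale_provenance,
        window=window,
        numbering_offset=(positions[0] - 1) if positions else 0,
    )
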