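"""Residue-by-residue contrast of flexibility and disorder.

Side-chain flexibility (nBf) and intrinsic disorder (pD) are related but not
equivalent: a stiff, hydrophobic residue can sit in a disordered loop and a
flexible one in a well-ordered helix.  Aligning the two tracks residue by
residue, the contrast is summarized by a pair of reciprocal quotients -
nBf/pD (the "white" track: flexibility per unit disorder) and pD/nBf (the
"black" track) - together with the dispersion of the white track (sample SD
and its standard error), and by flagging residues whose quotient deviates
markedly from the protein's own baseline.

Flagging operates on the log-quotient scale.  Because white and black are
exact reciprocals, only the log scale treats a residue that is
flexible-but-ordered and one that is rigid-but-disordered symmetrically:
inverting every quotient flips the sign of each log deviation but flags the
same positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np

from .disorder import DisorderProfile
from .flexprofile import FlexProfile

__all__ = [
    "DEFAULT_EPSILON",
    "DEFAULT_FLAG_K",
    "PairedProfile",
    "DiscrepancyQuotients",
    "DispersionStats",
    "DiscrepancyRecord",
    "pair_profiles",
    "discrepancy_quotients",
    "dispersion_stats",
    "flag_discrepant",
    "write_discrepancy_table",
]

#: Lower clamp applied to pD before division; pD can legitimately be 0 and
#: 0.01 sits below the reporting resolution of typical predictor exports.
DEFAULT_EPSILON = 0.01

#: Default flagging threshold in SD units of the log-quotient (a
#: conventional ~2-sigma outlier cut).
DEFAULT_FLAG_K = 2.0


@dataclass(frozen=True)
class PairedProfile:
    """Flexibility and disorder tracks aligned position by position."""

    record_id: str
    positions: np.ndarray
    residues: str
    nbf: np.ndarray
    pd_clamped: np.ndarray
    epsilon: float

    def __post_init__(self) -> None:
        for name in ("positions", "nbf", "pd_clamped"):
            arr = np.asarray(getattr(self, name), dtype=float if name != "positions" else int)
            if len(arr) != len(self.residues):
                raise ValueError(f"{name} length must match residues")
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DiscrepancyQuotients:
    """The two reciprocal per-residue quotient tracks."""

    paired: PairedProfile
    white: np.ndarray  # nBf / pD: flexibility per unit disorder
    black: np.ndarray  # pD / nBf: the opposite quotient
    epsilon: float

    def __len__(self) -> int:
        return len(self.white)


@dataclass(frozen=True)
class DispersionStats:
    """Sample SD of the white quotient track and its standard error."""

    sd: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("dispersion needs at least 2 residues")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class DiscrepancyRecord:
    """A residue flagged for marked flexibility/disorder disproportion."""

    position: int
    residue: str
    quotient: float  # white quotient nBf/pD at this residue
    z: float  # deviation on the log-quotient scale, in SD units
    direction: str  # "flexible-but-ordered" or "rigid-but-disordered"


def pair_profiles(
    flex: FlexProfile,
    dis: DisorderProfile,
    epsilon: float = DEFAULT_EPSILON,
) -> PairedProfile:
    """Align a flexibility and a disorder track residue by residue.

    The tracks must have equal length; when the disorder track carries
    residue letters they must agree with the sequence at every position.
    pD is clamped to ``[epsilon, 1]`` so quotients are defined at pD = 0.
    """
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must lie in (0, 1)")
    if len(flex) != len(dis):
        raise ValueError(
            f"length mismatch: flexibility track has {len(flex)} residues, "
            f"disorder track has {len(dis)}"
        )
    if dis.residues is not None:
        for i, (a, b) in enumerate(zip(flex.residues, dis.residues)):
            if b not in ("X", a):
                raise ValueError(
                    f"residue mismatch at position {flex.numbering_offset + i + 1}: "
                    f"sequence has {a!r}, disorder track has {b!r}"
                )
    return PairedProfile(
        record_id=flex.record_id,
        positions=flex.positions,
        residues=flex.residues,
        nbf=flex.nbf.copy(),
        pd_clamped=np.clip(dis.pd, epsilon, 1.0),
        epsilon=epsilon,
    )


def discrepancy_quotients(paired: PairedProfile) -> DiscrepancyQuotients:
    """Compute the white (nBf/pD) and black (pD/nBf) quotient tracks."""
    if np.any(paired.nbf <= 0):
        bad = int(np.argmax(paired.nbf <= 0))
        raise ValueError(
            f"non-positive nBf at position {int(paired.positions[bad])}: "
            "cannot form the pD/nBf quotient"
        )
    white = paired.nbf / paired.pd_clamped
    return DiscrepancyQuotients(
        paired=paired, white=white, black=1.0 / white, epsilon=paired.epsilon
    )


def dispersion_stats(quotients: DiscrepancyQuotients) -> DispersionStats:
    """Sample SD of the white track and its standard error sd/sqrt(n)."""
    n = len(quotients)
    if n < 2:
        raise ValueError("dispersion needs at least 2 residues")
    sd = float(np.std(quotients.white, ddof=1))
    return DispersionStats(sd=sd, sem=sd / np.sqrt(n), n=n)


def flag_discrepant(
    quotients: DiscrepancyQuotients, k: float = DEFAULT_FLAG_K
) -> List[DiscrepancyRecord]:
    """Flag residues whose log-quotient deviates more than ``k`` SDs from
    the track mean.

    Positions above the mean are ``flexible-but-ordered`` (high nBf relative
    to pD); positions below are ``rigid-but-disordered``.  A track with zero
    log-quotient variance yields no flags (with a warning).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if len(quotients) < 3:
        raise ValueError("flagging needs at least 3 residues")
    log_w = np.log(quotients.white)
    sd = float(np.std(log_w, ddof=1))
    # relative tolerance: an (up to rounding) constant track has no outliers
    if sd <= 1e-12 * max(1.0, float(np.max(np.abs(log_w)))):
        warnings.warn("log-quotient track has zero variance; no flags", stacklevel=2)
        return []
    z = (log_w - log_w.mean()) / sd
    paired = quotients.paired
    records = []
    for i in np.flatnonzero(np.abs(z) > k):
        records.append(
            DiscrepancyRecord(
                position=int(paired.positions[i]),
                residue=paired.residues[i],
                quotient=float(quotients.white[i]),
                z=float(z[i]),
                direction="flexible-but-ordered" if z[i] > 0 else "rigid-but-disordered",
            )
        )
    return records


def write_discrepancy_table(
    quotients: DiscrepancyQuotients,
    path: Union[str, Path],
    k: float = DEFAULT_FLAG_K,
) -> None:
    """Write the per-residue discrepancy table: nbf, pd, both quotients,
    log-scale z, flag and direction."""
    paired = quotients.paired
    log_w = np.log(quotients.white)
    sd = float(np.std(log_w, ddof=1))
    degenerate = sd <= 1e-12 * max(1.0, float(np.max(np.abs(log_w))))
    z = np.zeros_like(log_w) if degenerate else (log_w - log_w.mean()) / sd
    lines = [
        f"# record={paired.record_id} epsilon={quotients.epsilon:g} k={k:g}",
        "residue_number\tresidue\tnbf\tpd\twhite\tblack\tz\tflag\tdirection",
    ]
    for i in range(len(paired)):
        flagged = abs(z[i]) > k and not degenerate
        direction = (
            ("flexible-but-ordered" if z[i] > 0 else "rigid-but-disordered")
            if flagged
            else "."
        )
        lines.append(
            f"{int(paired.positions[i])}\t{paired.residues[i]}\t"
            f"{paired.nbf[i]:.6f}\t{paired.pd_clamped[i]:.6f}\t"
            f"{quotients.white[i]:.6f}\t{quotients.black[i]:.6f}\t"
            f"{z[i]:.4f}\t{int(flagged)}\t{direction}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
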