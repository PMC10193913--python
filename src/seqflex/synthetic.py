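"""Synthetic sequences and disorder tracks with controlled structure.

The generators emulate the statistical situation the discrepancy analysis
assumes: a sequence whose smoothed flexibility profile is correlated with a
disorder track through a noisy logistic link, plus a small number of
"discrepancy" sites where the link is deliberately violated by a stated
effect size (in SD units of the log flexibility/disorder quotient).  Because
every injected site is recorded, the flagging stage can be scored for
sensitivity and precision (:func:`recovery_experiment`).

All generators are seed-deterministic; independent substreams are derived
from the configured seed, so the sequence and its disorder track do not share
random draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
from scipy.special import expit, logit

from .discrepancy import (
    DEFAULT_EPSILON,
    DEFAULT_FLAG_K,
    discrepancy_quotients,
    flag_discrepant,
    pair_profiles,
)
from .disorder import DisorderProfile
from .flexprofile import (
    FlexibilityScale,
    FlexProfile,
    WindowSpec,
    _windowed_average,
    default_window,
    flex_profile,
    load_flex_scale,
)
from .seq_io import CANONICAL_RESIDUES, SequenceRecord

__all__ = [
    "SyntheticConfig",
    "RecoveryReport",
    "generate_sequence",
    "generate_disorder_track",
    "recovery_experiment",
]

#: Baseline disorder probability around which the logistic link operates;
#: transmembrane domains are mostly ordered, so the baseline sits below 0.5.
BASE_DISORDER = 0.3

#: Tolerance for the greedy mBf targeting in :func:`generate_sequence`.
TARGET_MBF_TOL = 0.05

#: Residue-pool specifications: bottom / top quartile of the scale.
POOL_SPECS = ("stiff", "flexible")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic sequence / disorder generator.

    Defaults describe the reference simulation conditions used throughout
    the test-bench: 300-residue sequences, flexibility-disorder correlation
    0.8, moderate link noise, and 5 injected discrepancy sites of 3-SD
    effect.
    """

    length: int = 300
    target_mbf: Optional[Union[float, str]] = None
    rho: float = 0.8
    noise_sd: float = 0.5
    n_sites: int = 5
    effect: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.n_sites <= self.length:
            raise ValueError("n_sites must lie in [0, length]")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if isinstance(self.target_mbf, str) and self.target_mbf not in POOL_SPECS:
            raise ValueError(f"pool spec must be one of {POOL_SPECS}")


@dataclass(frozen=True)
class RecoveryReport:
    """Aggregate flag-recovery scores over simulation replicates."""

    config: SyntheticConfig
    n_seeds: int
    sensitivity: float
    precision: float
    false_positive_rate: float
    per_seed_flagged: Tuple[frozenset, ...]
    per_seed_truth: Tuple[frozenset, ...]

    def __post_init__(self) -> None:
        for name in ("sensitivity", "precision"):
            v = getattr(self, name)
            if not math.isnan(v) and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _mean_coefficients(n: int, window: WindowSpec) -> np.ndarray:
    """Per-position weights c with mbf = c . values (window linearity)."""
    h = window.half_width
    den = np.zeros(n)
    for j, w in enumerate(window.weights):
        off = j - h
        lo, hi = max(0, -off), min(n, n - off)
        if lo < hi:
            den[lo:hi] += w
    c = np.zeros(n)
    for j, w in enumerate(window.weights):
        off = j - h
        lo, hi = max(0, -off), min(n, n - off)
        if lo < hi:
            c[lo + off:hi + off] += w / den[lo:hi]
    return c / n


def generate_sequence(
    config: SyntheticConfig,
    scale: Optional[FlexibilityScale] = None,
    window: Optional[WindowSpec] = None,
) -> SequenceRecord:
    """Generate a random sequence, optionally targeting a mean flexibility.

    With ``target_mbf`` numeric, residues are first sampled uniformly and
    then greedily substituted - always the single substitution that most
    reduces the gap, ties broken leftmost - until the profile mean is within
    0.05 of the target.  With a pool spec (``"stiff"`` / ``"flexible"``)
    residues are drawn from the bottom / top quartile of the scale.  The
    result is deterministic for a fixed config.
    """
    if scale is None:
        scale = load_flex_scale("default")
    if window is None:
        window = default_window()
    if config.length < window.width:
        raise ValueError("length must be at least the window width")
    rng = _rng(config, 0)

    ranked = sorted(CANONICAL_RESIDUES, key=lambda aa: scale.values[aa])
    if isinstance(config.target_mbf, str):
        pool = ranked[:5] if config.target_mbf == "stiff" else ranked[-5:]
        residues = "".join(rng.choice(list(pool), size=config.length))
        return SequenceRecord(id=f"synthetic-{config.seed}", residues=residues)

    letters = list(rng.choice(list(CANONICAL_RESIDUES), size=config.length))
    if config.target_mbf is None:
        return SequenceRecord(id=f"synthetic-{config.seed}", residues="".join(letters))

    target = float(config.target_mbf)
    if not scale.min_value < target < scale.max_value:
        raise ValueError(
            f"target mBf {target} unreachable: outside scale range "
            f"({scale.min_value:.4g}, {scale.max_value:.4g})"
        )
    c = _mean_coefficients(config.length, window)
    values = np.array([scale.values[aa] for aa in letters])
    mbf = float(np.dot(c, values))
    aa_values = np.array([scale.values[aa] for aa in CANONICAL_RESIDUES])
    for _ in range(10 * config.length):
        if abs(mbf - target) <= TARGET_MBF_TOL:
            break
        # candidate gap after swapping position i to letter a:
        # |mbf + c_i * (v_a - v_i) - target|
        deltas = np.abs(
            mbf + c[:, None] * (aa_values[None, :] - values[:, None]) - target
        )
        i, a = np.unravel_index(np.argmin(deltas), deltas.shape)
        if deltas[i, a] >= abs(mbf - target):
            break  # no single swap improves further
        letters[i] = CANONICAL_RESIDUES[a]
        mbf += c[i] * (aa_values[a] - values[i])
        values[i] = aa_values[a]
    if abs(mbf - target) > TARGET_MBF_TOL:
        raise RuntimeError(
            f"greedy adjustment stalled at mBf {mbf:.4f} (target {target})"
        )
    return SequenceRecord(id=f"synthetic-{config.seed}", residues="".join(letters))


def generate_disorder_track(
    profile: FlexProfile,
    config: SyntheticConfig,
    epsilon: float = DEFAULT_EPSILON,
) -> Tuple[DisorderProfile, Dict[int, int]]:
    """Generate a disorder track correlated with the smoothed profile, with
    injected discrepancy sites.

    The link is logistic: pd = expit(a*z + noise + logit(base)), where z is
    the standardized re-smoothed profile and the gain ``a`` is set so the
    latent correlation with z equals ``rho`` (Gaussian noise of SD
    ``noise_sd``; larger noise also saturates the logistic more, degrading
    downstream recovery).  At ``n_sites`` random positions the resulting pd
    is displaced by ``effect`` SDs of the log flexibility/disorder quotient,
    in a random direction per site; direction +1 makes the site
    flexible-but-ordered (pd pushed down).

    Returns the track and a truth mapping {residue_number: direction}.
    """
    n = len(profile)
    if config.n_sites > n:
        raise ValueError("n_sites exceeds profile length")
    rng = _rng(config, 1)

    smoothed = _windowed_average(profile.nbf, profile.window)
    sd_s = float(np.std(smoothed))
    z = np.zeros(n) if sd_s == 0 else (smoothed - smoothed.mean()) / sd_s

    rho, noise_sd = config.rho, config.noise_sd
    if abs(rho) == 1.0 or noise_sd == 0.0:
        latent = np.sign(rho) * max(noise_sd, 1.0) * z
    else:
        gain = rho * noise_sd / math.sqrt(1.0 - rho * rho)
        latent = gain * z + rng.normal(0.0, noise_sd, size=n)

    pd = expit(latent + logit(BASE_DISORDER))

    truth: Dict[int, int] = {}
    if config.n_sites > 0:
        log_white = np.log(profile.nbf) - np.log(np.clip(pd, epsilon, 1.0))
        delta = config.effect * float(np.std(log_white, ddof=1))
        sites = np.sort(rng.choice(n, size=config.n_sites, replace=False))
        directions = rng.choice([-1, 1], size=config.n_sites)
        for idx, direction in zip(sites, directions):
            pd[idx] = float(np.clip(pd[idx] * math.exp(-direction * delta), 0.0, 1.0))
            truth[int(profile.positions[idx])] = int(direction)

    track = DisorderProfile(
        record_id=profile.record_id,
        pd=pd,
        source="synthetic",
        residues=profile.residues,
        numbering_offset=profile.numbering_offset,
    )
    return track, truth


def recovery_experiment(
    config: SyntheticConfig,
    n_seeds: int,
    scale: Optional[FlexibilityScale] = None,
    window: Optional[WindowSpec] = None,
    epsilon: float = DEFAULT_EPSILON,
    k: float = DEFAULT_FLAG_K,
) -> RecoveryReport:
    """Score the discrepancy-flagging stage against injected ground truth.

    For each replicate: generate a sequence and correlated disorder track,
    run pairing / quotients / flagging with the given epsilon and k, and
    compare flagged positions with the truth set.  Sensitivity is the mean
    fraction of injected sites recovered; precision the mean fraction of
    flags that are injected sites (a replicate with no flags scores
    precision 1); the false-positive rate is the mean fraction of
    non-injected residues flagged.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    if scale is None:
        scale = load_flex_scale("default")
    if window is None:
        window = default_window()

    sens: List[float] = []
    prec: List[float] = []
    fprs: List[float] = []
    flagged_sets: List[frozenset] = []
    truth_sets: List[frozenset] = []
    for i in range(n_seeds):
        sub_seed = int(np.random.SeedSequence([config.seed, 2, i]).generate_state(1)[0] % (2**31))
        cfg = replace(config, seed=sub_seed)
        record = generate_sequence(cfg, scale, window)
        profile = flex_profile(record, scale, window)
        track, truth = generate_disorder_track(profile, cfg, epsilon)
        paired = pair_profiles(profile, track, epsilon)
        flags = flag_discrepant(discrepancy_quotients(paired), k)
        flagged = frozenset(f.position for f in flags)
        truth_pos = frozenset(truth)
        tp = len(flagged & truth_pos)
        if cfg.n_sites > 0:
            sens.append(tp / cfg.n_sites)
        prec.append(tp / len(flagged) if flagged else 1.0)
        fprs.append(
            len(flagged - truth_pos) / max(1, len(profile) - cfg.n_sites)
        )
        flagged_sets.append(flagged)
        truth_sets.append(truth_pos)

    return RecoveryReport(
        config=config,
        n_seeds=n_seeds,
        sensitivity=float(np.mean(sens)) if sens else float("nan"),
        precision=float(np.mean(prec)),
        false_positive_rate=float(np.mean(fprs)),
        per_seed_flagged=tuple(flagged_sets),
        per_seed_truth=tuple(truth_sets),
    )
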