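"""Helix-class comparison and the end-to-end pipeline.

Segments annotated with a helix class (alpha / pi / three10 / loop) are
grouped and their mean flexibility indices compared between classes; the
headline contrast is pi-transition regions (S6 mid-helix) versus
3(10)-transition regions (S4 C-terminus), where the pi class is expected to
be the more rigid.  A two-sided rank-sum test is attached as a descriptive
helper; with a single default comparison no multiple-testing correction is
applied, and the all-pairwise mode adjusts p-values by Benjamini-Hochberg.

:func:`run_full_analysis` orchestrates the whole pipeline - profiles,
per-segment indices, the class comparison and (when disorder tracks are
supplied) the per-protein discrepancy tables and dispersion summaries - into
a deterministic on-disk bundle that embeds its resolved configuration.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import yaml
from scipy import stats

from .discrepancy import (
    DEFAULT_EPSILON,
    DEFAULT_FLAG_K,
    DispersionStats,
    DiscrepancyQuotients,
    discrepancy_quotients,
    dispersion_stats,
    flag_discrepant,
    pair_profiles,
    write_discrepancy_table,
)
from .disorder import DEFAULT_THRESHOLD, read_disorder_profile
from .flexprofile import (
    FlexProfile,
    MeanFlexibility,
    WindowSpec,
    flex_profile,
    load_flex_scale,
    segment_mbf,
    write_profile,
)
from .seq_io import (
    HELIX_CLASSES,
    SegmentAnnotation,
    read_fasta,
    read_segment_table,
)

logger = logging.getLogger("seqflex")

__all__ = [
    "GroupMember",
    "HelixClassGroups",
    "ComparisonReport",
    "AnalysisConfig",
    "ReportBundle",
    "group_segments",
    "compare_helix_classes",
    "compare_all_classes",
    "run_full_analysis",
]


@dataclass(frozen=True)
class GroupMember:
    protein_id: str
    segment_name: str
    mean_flexibility: MeanFlexibility


@dataclass(frozen=True)
class HelixClassGroups:
    """Per-segment mean flexibility indices grouped by helix class."""

    groups: Mapping[str, Tuple[GroupMember, ...]]

    def __post_init__(self) -> None:
        unknown = set(self.groups) - set(HELIX_CLASSES)
        if unknown:
            raise ValueError(f"unknown helix classes: {sorted(unknown)}")
        object.__setattr__(self, "groups", dict(self.groups))

    def mbf_values(self, helix_class: str) -> np.ndarray:
        return np.array(
            [m.mean_flexibility.mbf for m in self.groups.get(helix_class, ())]
        )

    def size(self, helix_class: str) -> int:
        return len(self.groups.get(helix_class, ()))


@dataclass(frozen=True)
class ComparisonReport:
    """Descriptive comparison of segment mBf between two helix classes."""

    class_a: str
    class_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    difference: float  # mean_b - mean_a
    statistic: float  # two-sided Mann-Whitney rank-sum helper
    p_value: float
    members: Tuple[Tuple[str, str, str, float], ...] = ()
    p_adjusted: Optional[float] = None


def group_segments(
    profiles: Sequence[FlexProfile],
    annotations: Sequence[SegmentAnnotation],
) -> HelixClassGroups:
    """Compute each annotated segment's mBf and group by helix class."""
    by_id = {p.record_id: p for p in profiles}
    groups: Dict[str, List[GroupMember]] = {}
    for ann in annotations:
        try:
            profile = by_id[ann.protein_id]
        except KeyError:
            raise KeyError(
                f"annotation {ann.segment_name!r} refers to unknown protein "
                f"{ann.protein_id!r}"
            ) from None
        mf = segment_mbf(profile, ann.start, ann.end)
        groups.setdefault(ann.helix_class, []).append(
            GroupMember(ann.protein_id, ann.segment_name, mf)
        )
    return HelixClassGroups(groups={k: tuple(v) for k, v in groups.items()})


def compare_helix_classes(
    groups: HelixClassGroups, class_a: str, class_b: str
) -> ComparisonReport:
    """Compare mean segment flexibility between two helix classes.

    ``difference`` is mean(class_b) - mean(class_a); called as
    ``compare_helix_classes(groups, "pi", "three10")`` it is therefore the
    3(10)-minus-pi contrast, positive when 3(10) segments are on average the
    more flexible.  The rank-sum statistic/p-value are descriptive helpers,
    not an inferential claim about gating.
    """
    a = groups.mbf_values(class_a)
    b = groups.mbf_values(class_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError(
            f"both groups must be non-empty (got {class_a}: {len(a)}, "
            f"{class_b}: {len(b)})"
        )
    statistic, p_value = stats.mannwhitneyu(b, a, alternative="two-sided")
    members = tuple(
        (cls, m.protein_id, m.segment_name, m.mean_flexibility.mbf)
        for cls in (class_a, class_b)
        for m in groups.groups.get(cls, ())
    )
    return ComparisonReport(
        class_a=class_a,
        class_b=class_b,
        n_a=len(a),
        n_b=len(b),
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
        sd_a=float(np.std(a, ddof=1)) if len(a) > 1 else float("nan"),
        sd_b=float(np.std(b, ddof=1)) if len(b) > 1 else float("nan"),
        difference=float(np.mean(b) - np.mean(a)),
        statistic=float(statistic),
        p_value=float(p_value),
        members=members,
    )


def compare_all_classes(groups: HelixClassGroups) -> List[ComparisonReport]:
    """All pairwise class comparisons with Benjamini-Hochberg adjustment."""
    present = [c for c in HELIX_CLASSES if groups.size(c) > 0]
    reports = [
        compare_helix_classes(groups, a, b)
        for a, b in itertools.combinations(present, 2)
    ]
    if not reports:
        return []
    adjusted = stats.false_discovery_control([r.p_value for r in reports])
    return [
        ComparisonReport(**{**asdict_shallow(r), "p_adjusted": float(p)})
        for r, p in zip(reports, adjusted)
    ]


def asdict_shallow(report: ComparisonReport) -> Dict:
    return {f: getattr(report, f) for f in report.__dataclass_fields__}


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisConfig:
    """Flat run configuration; every field is echoed into the output bundle."""

    scale_source: str = "default"
    window_width: int = 3
    window_weights: Tuple[float, ...] = (0.25, 0.5, 0.25)
    epsilon: float = DEFAULT_EPSILON
    flag_k: float = DEFAULT_FLAG_K
    disorder_threshold: float = DEFAULT_THRESHOLD
    disorder_dialect: str = "generic"
    compare_classes: Tuple[str, str] = ("pi", "three10")
    all_pairwise: bool = False

    def window(self) -> WindowSpec:
        return WindowSpec(width=self.window_width, weights=tuple(self.window_weights))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("window_weights", "compare_classes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: Union[str, Path]) -> None:
        data = {f: getattr(self, f) for f in self.__dataclass_fields__}
        for key in ("window_weights", "compare_classes"):
            data[key] = list(data[key])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass
class ReportBundle:
    """In-memory results of a full pipeline run plus their on-disk paths."""

    out_dir: Path
    config: AnalysisConfig
    profiles: Dict[str, FlexProfile]
    segment_mbf: Dict[Tuple[str, str], MeanFlexibility]
    groups: HelixClassGroups
    comparisons: List[ComparisonReport]
    quotients: Dict[str, DiscrepancyQuotients]
    dispersion: Dict[str, DispersionStats]


def _normalize_tracks(
    disorder_tracks: Union[None, str, Path, Mapping[str, Union[str, Path]], Sequence[Union[str, Path]]],
) -> Dict[str, Path]:
    if disorder_tracks is None:
        return {}
    if isinstance(disorder_tracks, Mapping):
        return {k: Path(v) for k, v in disorder_tracks.items()}
    if isinstance(disorder_tracks, (str, Path)):
        root = Path(disorder_tracks)
        if not root.is_dir():
            raise ValueError(f"disorder track path {root} is not a directory")
        return {p.stem: p for p in sorted(root.glob("*.tsv")) + sorted(root.glob("*.csv"))}
    return {Path(p).stem: Path(p) for p in disorder_tracks}


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the failing stage named."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage {name!r}: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_full_analysis(
    fasta: Union[str, Path],
    segments: Union[str, Path],
    out_dir: Union[str, Path],
    disorder_tracks: Union[None, str, Path, Mapping[str, Union[str, Path]], Sequence[Union[str, Path]]] = None,
    config: Optional[AnalysisConfig] = None,
) -> ReportBundle:
    """Run the full flexibility / discrepancy pipeline and write a bundle.

    Writes, under ``out_dir``: per-protein profile tables
    (``profiles/<id>.tsv``), per-segment mBf values (``segments_mbf.tsv``),
    the helix-class comparison (``comparison.tsv``), and - when disorder
    tracks are supplied - per-protein discrepancy tables
    (``discrepancy/<id>.tsv``) and a dispersion summary
    (``dispersion.tsv``); the resolved configuration is echoed to
    ``config_resolved.yaml``.  Output is deterministic for fixed inputs and
    configuration (no timestamps), and every decision parameter is logged.
    """
    config = config or AnalysisConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    with _stage("configuration"):
        scale = load_flex_scale(config.scale_source)
        window = config.window()
        logger.info(
            "run: scale=%r window=%s/%s epsilon=%g k=%g threshold=%g",
            config.scale_source, window.width, window.weights,
            config.epsilon, config.flag_k, config.disorder_threshold,
        )
        config.to_yaml(out_dir / "config_resolved.yaml")

    with _stage("sequence input"):
        records = read_fasta(fasta)
        annotations = read_segment_table(segments)

    with _stage("flexibility profiles"):
        (out_dir / "profiles").mkdir(exist_ok=True)
        profiles: Dict[str, FlexProfile] = {}
        for rec in records:
            prof = flex_profile(rec, scale, window)
            profiles[rec.id] = prof
            write_profile(prof, out_dir / "profiles" / f"{rec.id}.tsv")

    with _stage("segment indices"):
        seg_mbf: Dict[Tuple[str, str], MeanFlexibility] = {}
        lines = ["protein_id\tsegment_name\thelix_class\tstart\tend\tn\tmbf\trelative"]
        for ann in annotations:
            mf = segment_mbf(profiles[ann.protein_id], ann.start, ann.end) \
                if ann.protein_id in profiles else None
            if mf is None:
                raise KeyError(f"no sequence for annotated protein {ann.protein_id!r}")
            seg_mbf[(ann.protein_id, ann.segment_name)] = mf
            lines.append(
                f"{ann.protein_id}\t{ann.segment_name}\t{ann.helix_class}\t"
                f"{ann.start}\t{ann.end}\t{mf.n}\t{mf.mbf:.6f}\t{mf.relative:.6f}"
            )
        (out_dir / "segments_mbf.tsv").write_text("\n".join(lines) + "\n")

    with _stage("helix-class comparison"):
        groups = group_segments(list(profiles.values()), annotations)
        comparisons: List[ComparisonReport] = []
        if config.all_pairwise:
            comparisons = compare_all_classes(groups)
        else:
            a, b = config.compare_classes
            if groups.size(a) > 0 and groups.size(b) > 0:
                comparisons = [compare_helix_classes(groups, a, b)]
            else:
                logger.info(
                    "comparison %s vs %s skipped: empty group(s)", a, b
                )
        header = (
            "class_a\tclass_b\tn_a\tn_b\tmean_a\tmean_b\tsd_a\tsd_b\t"
            "difference\tstatistic\tp_value\tp_adjusted"
        )
        rows = [header]
        for r in comparisons:
            rows.append(
                f"{r.class_a}\t{r.class_b}\t{r.n_a}\t{r.n_b}\t{r.mean_a:.6f}\t"
                f"{r.mean_b:.6f}\t{r.sd_a:.6f}\t{r.sd_b:.6f}\t{r.difference:.6f}\t"
                f"{r.statistic:.6f}\t{r.p_value:.6g}\t"
                f"{'' if r.p_adjusted is None else format(r.p_adjusted, '.6g')}"
            )
        (out_dir / "comparison.tsv").write_text("\n".join(rows) + "\n")

    quotients: Dict[str, DiscrepancyQuotients] = {}
    dispersion: Dict[str, DispersionStats] = {}
    tracks = _normalize_tracks(disorder_tracks)
    if not tracks:
        logger.info("no disorder tracks supplied; discrepancy stage skipped")
    else:
        with _stage("discrepancy"):
            (out_dir / "discrepancy").mkdir(exist_ok=True)
            disp_rows = ["protein_id\tn\tsd\tsem"]
            for rec_id in sorted(tracks):
                if rec_id not in profiles:
                    raise KeyError(
                        f"disorder track {rec_id!r} has no matching sequence"
                    )
                track = read_disorder_profile(
                    tracks[rec_id],
                    dialect=config.disorder_dialect,
                    threshold=config.disorder_threshold,
                )
                paired = pair_profiles(profiles[rec_id], track, config.epsilon)
                q = discrepancy_quotients(paired)
                quotients[rec_id] = q
                write_discrepancy_table(
                    q, out_dir / "discrepancy" / f"{rec_id}.tsv", config.flag_k
                )
                d = dispersion_stats(q)
                dispersion[rec_id] = d
                disp_rows.append(f"{rec_id}\t{d.n}\t{d.sd:.6f}\t{d.sem:.6f}")
            (out_dir / "dispersion.tsv").write_text("\n".join(disp_rows) + "\n")

    return ReportBundle(
        out_dir=out_dir,
        config=config,
        profiles=profiles,
        segment_mbf=seg_mbf,
        groups=groups,
        comparisons=comparisons,
        quotients=quotients,
        dispersion=dispersion,
    )
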