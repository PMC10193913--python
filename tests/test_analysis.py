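"""Helix-class grouping/comparison and the full pipeline bundle."""

import hashlib
import logging
from pathlib import Path

import numpy as np
import pytest

from seqflex.analysis import (
    AnalysisConfig,
    compare_all_classes,
    compare_helix_classes,
    group_segments,
    run_full_analysis,
)
from seqflex.disorder import DisorderProfile, write_disorder_profile
from seqflex.flexprofile import flex_profile, segment_mbf
from seqflex.seq_io import (
    SegmentAnnotation,
    SequenceRecord,
    write_fasta,
    write_segment_table,
)
from seqflex.synthetic import SyntheticConfig, generate_disorder_track, generate_sequence


def _profiles_for(records, scale):
    return [flex_profile(r, scale) for r in records]


class TestGrouping:
    def _fixture(self, default_scale, n_pi=6, n_310=4):
        records, annotations = [], []
        for i in range(n_pi):
            records.append(SequenceRecord(id=f"pi{i}", residues="ILTFVLLLNML"))
            annotations.append(SegmentAnnotation(f"pi{i}", "S6", 1, 11, "pi"))
        for i in range(n_310):
            records.append(SequenceRecord(id=f"t{i}", residues="MEQPHMDSRIGWL"))
            annotations.append(SegmentAnnotation(f"t{i}", "S4b", 1, 13, "three10"))
        return _profiles_for(records, default_scale), annotations

    def test_group_sizes(self, default_scale):
        profiles, annotations = self._fixture(default_scale)
        groups = group_segments(profiles, annotations)
        assert groups.size("pi") == 6
        assert groups.size("three10") == 4
        assert groups.size("alpha") == 0

    def test_empty_annotations_give_empty_groups(self, default_scale):
        profiles, _ = self._fixture(default_scale)
        assert group_segments(profiles, []).groups == {}

    def test_group_values_match_independent_recomputation(self, default_scale):
        profiles, annotations = self._fixture(default_scale)
        groups = group_segments(profiles, annotations)
        by_id = {p.record_id: p for p in profiles}
        for cls, members in groups.groups.items():
            for m, ann in zip(members, [a for a in annotations if a.helix_class == cls]):
                expected = segment_mbf(by_id[ann.protein_id], ann.start, ann.end)
                assert m.mean_flexibility.mbf == pytest.approx(expected.mbf)

    def test_unknown_protein_named_in_error(self, default_scale):
        profiles, _ = self._fixture(default_scale)
        with pytest.raises(KeyError, match="ghost"):
            group_segments(profiles, [SegmentAnnotation("ghost", "S1", 1, 5)])


class TestComparison:
    def test_identical_groups_zero_difference(self, default_scale):
        rec = SequenceRecord(id="a", residues="ILTFVLLLNML")
        profiles = _profiles_for([rec], default_scale)
        anns = [
            SegmentAnnotation("a", "x", 1, 11, "pi"),
            SegmentAnnotation("a", "y", 1, 11, "three10"),
        ]
        rep = compare_helix_classes(group_segments(profiles, anns), "pi", "three10")
        assert rep.difference == pytest.approx(0.0)

    def test_empty_group_rejected(self, default_scale):
        rec = SequenceRecord(id="a", residues="ILTFVLLLNML")
        groups = group_segments(
            _profiles_for([rec], default_scale),
            [SegmentAnnotation("a", "x", 1, 11, "pi")],
        )
        with pytest.raises(ValueError, match="non-empty"):
            compare_helix_classes(groups, "pi", "three10")

    def test_stiff_vs_flexible_pools_sign_recovered(self, default_scale):
        """Segments from the stiff pool score below flexible-pool segments in
        nearly every replicate."""
        hits = 0
        for seed in range(100):
            records, anns = [], []
            for j in range(3):
                stiff = generate_sequence(
                    SyntheticConfig(length=13, target_mbf="stiff", seed=1000 * seed + j),
                    default_scale,
                )
                records.append(SequenceRecord(id=f"pi{j}", residues=stiff.residues))
                anns.append(SegmentAnnotation(f"pi{j}", "s", 1, 13, "pi"))
                flexible = generate_sequence(
                    SyntheticConfig(length=13, target_mbf="flexible", seed=1000 * seed + 500 + j),
                    default_scale,
                )
                records.append(SequenceRecord(id=f"t{j}", residues=flexible.residues))
                anns.append(SegmentAnnotation(f"t{j}", "s", 1, 13, "three10"))
            groups = group_segments(_profiles_for(records, default_scale), anns)
            rep = compare_helix_classes(groups, "pi", "three10")
            hits += rep.difference > 0
        assert hits >= 95

    def test_all_pairwise_applies_bh_adjustment(self, default_scale):
        profiles, anns = TestGrouping()._fixture(default_scale)
        anns = anns + [SegmentAnnotation("pi0", "L", 1, 5, "loop")]
        groups = group_segments(profiles, anns)
        reports = compare_all_classes(groups)
        assert len(reports) == 3  # pi/three10/loop pairwise
        for r in reports:
            assert r.p_adjusted is not None
            assert r.p_adjusted >= r.p_value - 1e-12


def toy_bundle_inputs(tmp_path, default_scale, with_disorder=True):
    """Three proteins, six segments, deterministic synthetic disorder."""
    records, annotations = [], []
    specs = [("protA", 60, 3), ("protB", 80, 4), ("protC", 50, 5)]
    for name, length, seed in specs:
        rec = generate_sequence(SyntheticConfig(length=length, seed=seed), default_scale)
        rec = SequenceRecord(id=name, residues=rec.residues)
        records.append(rec)
        annotations.append(SegmentAnnotation(name, "S6", 5, 15, "pi"))
        annotations.append(SegmentAnnotation(name, "S4b", 20, 32, "three10"))
    fasta = tmp_path / "proteins.fasta"
    segments = tmp_path / "segments.tsv"
    write_fasta(records, fasta)
    write_segment_table(annotations, segments)
    track_dir = None
    if with_disorder:
        track_dir = tmp_path / "tracks"
        track_dir.mkdir()
        for name, length, seed in specs:
            rec = next(r for r in records if r.id == name)
            prof = flex_profile(rec, default_scale)
            track, _ = generate_disorder_track(
                prof, SyntheticConfig(length=length, seed=seed, n_sites=2)
            )
            write_disorder_profile(track, track_dir / f"{name}.tsv")
    return fasta, segments, track_dir, records, annotations


def _dir_digest(root: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(root.rglob("*")):
        if p.is_file():
            h.update(p.relative_to(root).as_posix().encode())
            h.update(p.read_bytes())
    return h.hexdigest()


class TestFullPipeline:
    def test_bundle_byte_identical_across_runs(self, tmp_path, default_scale):
        fasta, segments, tracks, _, _ = toy_bundle_inputs(tmp_path, default_scale)
        out1, out2 = tmp_path / "run1", tmp_path / "run2"
        run_full_analysis(fasta, segments, out1, tracks)
        run_full_analysis(fasta, segments, out2, tracks)
        assert _dir_digest(out1) == _dir_digest(out2)

    def test_bundle_values_match_individual_operations(self, tmp_path, default_scale):
        fasta, segments, tracks, records, annotations = toy_bundle_inputs(
            tmp_path, default_scale
        )
        bundle = run_full_analysis(fasta, segments, tmp_path / "out", tracks)
        for ann in annotations:
            rec = next(r for r in records if r.id == ann.protein_id)
            direct = segment_mbf(flex_profile(rec, default_scale), ann.start, ann.end)
            assert bundle.segment_mbf[(ann.protein_id, ann.segment_name)].mbf == \
                pytest.approx(direct.mbf, abs=1e-12)
        assert (tmp_path / "out" / "dispersion.tsv").exists()
        assert len(bundle.dispersion) == 3
        (rep,) = bundle.comparisons
        assert rep.difference == pytest.approx(rep.mean_b - rep.mean_a, abs=1e-12)

    def test_missing_disorder_skips_discrepancy_with_notice(
        self, tmp_path, default_scale, caplog
    ):
        fasta, segments, _, _, _ = toy_bundle_inputs(
            tmp_path, default_scale, with_disorder=False
        )
        with caplog.at_level(logging.INFO, logger="seqflex"):
            bundle = run_full_analysis(fasta, segments, tmp_path / "out")
        assert bundle.quotients == {}
        assert not (tmp_path / "out" / "discrepancy").exists()
        assert any("skipped" in r.message for r in caplog.records)

    def test_stage_errors_name_the_stage(self, tmp_path, default_scale):
        fasta, _, _, _, _ = toy_bundle_inputs(
            tmp_path, default_scale, with_disorder=False
        )
        bad = tmp_path / "bad_segments.tsv"
        bad.write_text("wrong\theader\n1\t2\n")
        with pytest.raises(RuntimeError, match="sequence input"):
            run_full_analysis(fasta, bad, tmp_path / "out")

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = AnalysisConfig(window_width=5, window_weights=(0.1, 0.2, 0.4, 0.2, 0.1),
                             flag_k=2.5)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        assert AnalysisConfig.from_yaml(p) == cfg

    def test_config_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("scale_source: default\nbogus: 1\n")
        with pytest.raises(ValueError, match="bogus"):
            AnalysisConfig.from_yaml(p)
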