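"""Flexibility scales, profiles, segment indices and calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqflex.flexprofile import (
    BFactorSeries,
    FlexibilityScale,
    WindowSpec,
    calibrate_scale,
    default_window,
    flex_profile,
    load_flex_scale,
    normalize_bfactors,
    read_bfactor_series,
    relative_flexibility,
    save_flex_scale,
    segment_mbf,
)
from seqflex.seq_io import CANONICAL_RESIDUES, SequenceRecord

sequences = st.text(alphabet=CANONICAL_RESIDUES, min_size=1, max_size=40)


def brute_force_profile(residues, scale, window):
    """Independent doubly-looped windowed average (the oracle)."""
    vals = [scale.mean if ch == "X" else scale.values[ch] for ch in residues]
    h = window.width // 2
    out = []
    for i in range(len(vals)):
        num = den = 0.0
        for j, w in enumerate(window.weights):
            k = i + j - h
            if 0 <= k < len(vals):
                num += w * vals[k]
                den += w
        out.append(num / den)
    return np.array(out)


class TestNormalizeBFactors:
    def test_hand_arithmetic(self):
        out = normalize_bfactors(BFactorSeries((10, 20, 30)))
        assert np.allclose(out, [-1, 0, 1])

    def test_value_at_mean_maps_to_zero(self):
        out = normalize_bfactors(BFactorSeries((5, 10, 15)))
        assert out[1] == 0.0

    def test_exact_standardization(self, rng):
        out = normalize_bfactors(BFactorSeries(tuple(rng.normal(30, 8, 50))))
        assert abs(out.mean()) < 1e-9
        assert abs(out.std(ddof=1) - 1) < 1e-9

    def test_degenerate_series_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_bfactors(BFactorSeries((4.0, 4.0, 4.0)))
        with pytest.raises(ValueError, match="at least 2"):
            normalize_bfactors(BFactorSeries((4.0,)))

    def test_read_series_formats(self, tmp_path):
        one = tmp_path / "one.txt"
        one.write_text("# B\n10\n20\n30\n")
        two = tmp_path / "two.txt"
        two.write_text("1\t10\n2\t20\n3\t30\n")
        assert read_bfactor_series(one).values == read_bfactor_series(two).values


class TestScale:
    def test_packaged_ordering_constraints(self, raw_scale, default_scale):
        for scale in (raw_scale, default_scale):
            assert scale.values["L"] > scale.values["F"]
            assert scale.values["K"] > scale.values["R"]

    def test_save_load_round_trip(self, toy_scale, tmp_path):
        p = tmp_path / "scale.tsv"
        save_flex_scale(toy_scale, p)
        assert load_flex_scale(p).values == toy_scale.values

    def test_missing_residue_named(self, tmp_path):
        p = tmp_path / "scale.tsv"
        p.write_text(
            "\n".join(f"{aa}\t1.0" for aa in CANONICAL_RESIDUES if aa != "W") + "\n"
        )
        with pytest.raises(ValueError, match="W"):
            load_flex_scale(p)

    def test_non_positive_value_rejected(self):
        values = {aa: 1.0 for aa in CANONICAL_RESIDUES}
        values["A"] = 0.0
        with pytest.raises(ValueError, match="A"):
            FlexibilityScale(values=values)

    def test_x_gets_scale_mean(self, toy_scale):
        assert toy_scale.value("X") == pytest.approx(toy_scale.mean)


class TestWindowSpec:
    @pytest.mark.parametrize(
        "width,weights",
        [
            (2, (0.5, 0.5)),  # even width
            (3, (0.2, 0.5, 0.3)),  # asymmetric
            (3, (0.3, 0.5, 0.3)),  # does not sum to 1
            (3, (0.5, -0.0, 0.5)),  # non-positive weight
        ],
    )
    def test_invalid_specs_rejected(self, width, weights):
        with pytest.raises(ValueError):
            WindowSpec(width=width, weights=weights)


class TestFlexProfile:
    def test_homopolymer_is_constant(self, toy_scale, window3):
        rec = SequenceRecord(id="g", residues="GGGGG")
        prof = flex_profile(rec, toy_scale, window3)
        assert np.allclose(prof.nbf, 3.0)

    def test_hand_computed_window_average(self, toy_scale, window3):
        prof = flex_profile(SequenceRecord(id="t", residues="GAV"), toy_scale, window3)
        # middle: 0.25*3 + 0.5*1 + 0.25*2; termini renormalize to (2/3, 1/3)
        assert prof.nbf[1] == pytest.approx(1.75)
        assert prof.nbf[0] == pytest.approx(2 / 3 * 3 + 1 / 3 * 1)
        assert prof.nbf[2] == pytest.approx(2 / 3 * 2 + 1 / 3 * 1)

    def test_printed_pi_window_profiles_in_scale_bounds(self, default_scale, window3):
        for seq in (
            "ILTFVLLLNML", "IIATLLMLNLL", "LVANILLVNLL",
            "LSTNILLVNLL", "VTMVVVLLNML", "IFVPIVLMNLL",
        ):
            prof = flex_profile(SequenceRecord(id="s", residues=seq), default_scale, window3)
            assert len(prof) == 11
            assert np.all(prof.nbf >= default_scale.min_value - 1e-12)
            assert np.all(prof.nbf <= default_scale.max_value + 1e-12)

    def test_matches_brute_force_oracle(self, default_scale, rng):
        window = WindowSpec(5, (0.1, 0.2, 0.4, 0.2, 0.1))
        for _ in range(100):
            seq = "".join(rng.choice(list(CANONICAL_RESIDUES), size=rng.integers(1, 31)))
            prof = flex_profile(SequenceRecord(id="r", residues=seq), default_scale, window)
            assert np.allclose(
                prof.nbf, brute_force_profile(seq, default_scale, window), atol=1e-12
            )

    @settings(max_examples=50, derandomize=True)
    @given(seq=sequences)
    def test_convex_combination_bounds(self, default_scale, seq):
        prof = flex_profile(SequenceRecord(id="r", residues=seq), default_scale)
        assert np.all(prof.nbf >= default_scale.min_value - 1e-12)
        assert np.all(prof.nbf <= default_scale.max_value + 1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(seq=sequences)
    def test_reversal_symmetry(self, default_scale, seq):
        fwd = flex_profile(SequenceRecord(id="r", residues=seq), default_scale)
        rev = flex_profile(SequenceRecord(id="r", residues=seq[::-1]), default_scale)
        assert np.allclose(fwd.nbf, rev.nbf[::-1], atol=1e-12)

    @settings(max_examples=30, derandomize=True)
    @given(data=st.data(), seq=sequences)
    def test_substitution_monotonicity(self, default_scale, data, seq):
        """Replacing a residue by a more flexible one never lowers the profile."""
        i = data.draw(st.integers(0, len(seq) - 1))
        old_v = default_scale.values[seq[i]]
        stiffer_or_equal = [aa for aa in CANONICAL_RESIDUES
                            if default_scale.values[aa] >= old_v]
        new = data.draw(st.sampled_from(stiffer_or_equal))
        mutated = seq[:i] + new + seq[i + 1:]
        p0 = flex_profile(SequenceRecord(id="r", residues=seq), default_scale)
        p1 = flex_profile(SequenceRecord(id="r", residues=mutated), default_scale)
        assert np.all(p1.nbf >= p0.nbf - 1e-12)
        assert np.mean(p1.nbf) >= np.mean(p0.nbf) - 1e-12


class TestSegmentMbf:
    def test_single_residue_width1_is_scale_value(self, toy_scale, window1):
        prof = flex_profile(SequenceRecord(id="r", residues="AVG"), toy_scale, window1)
        assert segment_mbf(prof, 2, 2).mbf == pytest.approx(2.0)

    def test_equals_direct_mean_of_slice(self, default_scale, rng):
        seq = "".join(rng.choice(list(CANONICAL_RESIDUES), size=50))
        prof = flex_profile(SequenceRecord(id="r", residues=seq), default_scale)
        mf = segment_mbf(prof, 11, 30)
        assert mf.mbf == pytest.approx(float(np.mean(prof.nbf[10:30])), abs=1e-12)
        assert mf.n == 20

    def test_permutation_invariance_width1(self, default_scale, window1, rng):
        seq = "ACDEFGHIKL"
        perm = "".join(rng.permutation(list(seq)))
        p0 = flex_profile(SequenceRecord(id="r", residues=seq), default_scale, window1)
        p1 = flex_profile(SequenceRecord(id="r", residues=perm), default_scale, window1)
        assert segment_mbf(p0, 1, 10).mbf == pytest.approx(segment_mbf(p1, 1, 10).mbf)

    def test_out_of_range_rejected(self, default_scale):
        prof = flex_profile(SequenceRecord(id="r", residues="ACDEF"), default_scale)
        with pytest.raises(IndexError):
            segment_mbf(prof, 4, 9)

    def test_literal_eq2_and_relative(self, default_scale):
        prof = flex_profile(SequenceRecord(id="r", residues="ACDEF"), default_scale)
        mf = segment_mbf(prof, 1, 5, with_literal_eq2=True)
        assert mf.literal_eq2 == pytest.approx(-mf.mbf)
        assert relative_flexibility(mf) == pytest.approx(1.0 / mf.mbf)
        assert 1.0 / relative_flexibility(mf) == pytest.approx(mf.mbf, abs=1e-12)
        assert mf.relative * mf.mbf == pytest.approx(1.0, abs=1e-12)


class TestCalibration:
    def _segments(self, rng, n=4, length=12):
        return [
            SequenceRecord(
                id=f"s{i}",
                residues="".join(rng.choice(list(CANONICAL_RESIDUES), size=length)),
            )
            for i in range(n)
        ]

    def test_zero_anchors_is_noop(self, raw_scale, window3):
        assert calibrate_scale(raw_scale, window3, []) is raw_scale

    def test_affine_transform_recovered(self, raw_scale, window3, rng):
        gain, offset = 1.8, 0.65
        segments = self._segments(rng)
        anchors = []
        for seg in segments:
            pred = float(np.mean(flex_profile(seg, raw_scale, window3).nbf))
            anchors.append((seg, gain * pred + offset))
        calibrated = calibrate_scale(raw_scale, window3, anchors)
        for aa in CANONICAL_RESIDUES:
            assert calibrated.values[aa] == pytest.approx(
                gain * raw_scale.values[aa] + offset, abs=1e-6
            )

    def test_single_anchor_falls_back_to_offset(self, raw_scale, window3, rng):
        seg = self._segments(rng, n=1)[0]
        with pytest.warns(UserWarning, match="offset-only"):
            calibrated = calibrate_scale(raw_scale, window3, [(seg, 2.0)])
        pred = float(np.mean(flex_profile(seg, calibrated, window3).nbf))
        assert pred == pytest.approx(2.0, abs=1e-9)
        spread = np.ptp(list(calibrated.values.values()))
        assert spread == pytest.approx(np.ptp(list(raw_scale.values.values())))

    def test_floor_constraint_keeps_scale_valid(self, raw_scale, window3):
        # anchors whose spread demands a huge gain push the stiff end of the
        # scale to the floor instead of below zero
        stiff = SequenceRecord(id="a", residues="IIIIIIIIII")
        flexible = SequenceRecord(id="b", residues="EEEEEEEEEE")
        calibrated = calibrate_scale(
            raw_scale, window3, [(stiff, 1.0), (flexible, 10.0)], floor=0.05
        )
        assert calibrated.min_value == pytest.approx(0.05)
        # ordering preserved
        ranked_raw = sorted(CANONICAL_RESIDUES, key=raw_scale.values.get)
        ranked_new = sorted(CANONICAL_RESIDUES, key=calibrated.values.get)
        assert ranked_raw == ranked_new
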