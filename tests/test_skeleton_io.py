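"""Skeleton sequence I/O: dialects, validation, gap repair, label tracks."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import kinescore as ks
from kinescore.skeleton import (
    DIALECTS,
    N_JOINTS,
    LabelSegment,
    LabelTrack,
    SkeletonFormatError,
    read_labels,
    write_labels,
)


def _make_seq(rng, T=5, fps=30.0, invalid_frac=0.0):
    times = np.arange(T) / fps
    xyz = rng.uniform(-1, 2, (T, N_JOINTS, 3))
    valid = rng.random((T, N_JOINTS)) >= invalid_frac
    xyz[~valid] = np.nan
    return ks.SkeletonSequence(times, xyz, valid, fps)


@pytest.mark.parametrize("dialect", DIALECTS)
def test_round_trip_identity(tmp_path, dialect):
    rng = np.random.default_rng(1)
    seq = _make_seq(rng, T=6, invalid_frac=0.15)
    path = tmp_path / f"seq.{dialect}"
    ks.write_sequence(seq, path, dialect)
    back = ks.read_sequence(path, dialect)
    assert back.n_frames == seq.n_frames
    np.testing.assert_array_equal(back.valid, seq.valid)
    np.testing.assert_allclose(
        back.xyz[seq.valid], seq.xyz[seq.valid], atol=1e-6
    )
    np.testing.assert_allclose(back.times, seq.times, atol=1e-9)


@given(
    T=st.integers(min_value=2, max_value=8),
    seed=st.integers(min_value=0, max_value=2**16),
    dialect=st.sampled_from(DIALECTS),
)
def test_round_trip_property(tmp_path_factory, T, seed, dialect):
    rng = np.random.default_rng(seed)
    seq = _make_seq(rng, T=T, invalid_frac=0.2)
    path = tmp_path_factory.mktemp("io") / "seq.any"
    ks.write_sequence(seq, path, dialect)
    back = ks.read_sequence(path, dialect)
    np.testing.assert_array_equal(back.valid, seq.valid)
    np.testing.assert_allclose(back.xyz[seq.valid], seq.xyz[seq.valid], atol=1e-6)


def test_cross_dialect_consistency(tmp_path):
    """All three encodings of the same data decode to the same sequence."""
    rng = np.random.default_rng(3)
    seq = _make_seq(rng, T=5, invalid_frac=0.1)
    decoded = []
    for dialect in DIALECTS:
        path = tmp_path / f"x.{dialect}"
        ks.write_sequence(seq, path, dialect)
        decoded.append(ks.read_sequence(path, dialect))
    for a, b in zip(decoded, decoded[1:]):
        np.testing.assert_array_equal(a.valid, b.valid)
        np.testing.assert_allclose(a.xyz[a.valid], b.xyz[b.valid], atol=1e-6)


def test_schema_error_on_wrong_joint_count(tmp_path):
    rng = np.random.default_rng(4)
    seq = _make_seq(rng, T=3)
    path = tmp_path / "long.csv"
    ks.write_sequence(seq, path, "long-csv")
    lines = path.read_text().splitlines()
    # drop one joint row from frame 1 (19 joints remain)
    drop = next(i for i, l in enumerate(lines) if l.startswith("1,"))
    path.write_text("\n".join(lines[:drop] + lines[drop + 1 :]) + "\n")
    with pytest.raises(SkeletonFormatError, match="frame 1"):
        ks.read_sequence(path, "long-csv")


def test_wide_csv_header_mismatch(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("time,j01_x\n0.0,1.0\n")
    with pytest.raises(SkeletonFormatError):
        ks.read_sequence(path, "wide-csv")


def test_sequence_validation_rejects_bad_times():
    xyz = np.zeros((3, N_JOINTS, 3))
    valid = np.ones((3, N_JOINTS), dtype=bool)
    with pytest.raises(ValueError, match="strictly increasing"):
        ks.SkeletonSequence(np.array([0.0, 0.2, 0.1]), xyz, valid, 30.0)
    with pytest.raises(ValueError, match="spacing"):
        ks.SkeletonSequence(np.array([0.0, 1 / 30, 3 / 30]), xyz, valid, 30.0)


class TestRepairGaps:
    def _seq_with_gap(self, gap_start, gap_len, T=10):
        times = np.arange(T) / 30.0
        xyz = np.zeros((T, N_JOINTS, 3))
        xyz[:, 0, 0] = np.arange(T) * 0.2  # joint 1 moves along x
        valid = np.ones((T, N_JOINTS), dtype=bool)
        valid[gap_start : gap_start + gap_len, 0] = False
        xyz[gap_start : gap_start + gap_len, 0] = np.nan
        return ks.SkeletonSequence(times, xyz, valid, 30.0)

    def test_single_frame_gap_midpoint(self):
        seq = self._seq_with_gap(4, 1)
        fixed = ks.repair_gaps(seq, max_gap=1)
        assert fixed.valid[4, 0]
        np.testing.assert_allclose(fixed.xyz[4, 0], [0.8, 0.0, 0.0], atol=1e-12)

    def test_long_gap_untouched(self):
        seq = self._seq_with_gap(2, 5)
        fixed = ks.repair_gaps(seq, max_gap=2)
        assert not fixed.valid[2:7, 0].any()

    def test_identity_on_valid_input(self):
        rng = np.random.default_rng(5)
        seq = _make_seq(rng, T=6)
        fixed = ks.repair_gaps(seq, max_gap=3)
        np.testing.assert_array_equal(fixed.xyz, seq.xyz)
        np.testing.assert_array_equal(fixed.valid, seq.valid)

    def test_never_alters_valid_samples(self):
        seq = self._seq_with_gap(3, 2)
        fixed = ks.repair_gaps(seq, max_gap=5)
        np.testing.assert_array_equal(
            fixed.xyz[seq.valid], seq.xyz[seq.valid]
        )


class TestLabelTrack:
    def test_rejects_overlap(self):
        with pytest.raises(ValueError, match="overlap"):
            LabelTrack([LabelSegment(0, 5, 1), LabelSegment(4, 8, 2)])

    def test_majority_label(self):
        track = LabelTrack([LabelSegment(2.0, 8.0, 3, 90.0)])
        assert track.majority_label(3.0, 6.0) == 3
        assert track.majority_label(0.0, 3.0) == 0  # 2 s background, 1 s class 3
        assert track.majority_label(6.0, 12.0) == 0

    def test_csv_round_trip(self, tmp_path):
        track = LabelTrack(
            [LabelSegment(0.5, 4.0, 1, 85.0), LabelSegment(5.0, 9.0, 2, None)]
        )
        path = write_labels(track, tmp_path / "labels.csv")
        back = read_labels(path)
        assert len(back.segments) == 2
        assert back.segments[0].score == 85.0
        assert back.segments[1].score is None
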