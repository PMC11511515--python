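"""Angular/NDDI feature extraction: geometry, bank integrity, windowing."""

import numpy as np
import pytest

import kinescore as ks
from kinescore.features import (
    FeatureMatrix,
    WindowError,
    angular_feature,
    default_bank,
    nddi_feature,
    window,
)

# Table-of-record for the shipped bank: (feature_id, kind, nodes)
EXPECTED_BANK = [
    (1, "angular", (2, 5, 13)), (2, "angular", (1, 6, 14)),
    (3, "angular", (3, 10, 8)), (4, "angular", (4, 11, 9)),
    (5, "angular", (6, 16, 11)), (6, "angular", (5, 16, 10)),
    (7, "angular", (5, 16, 11)), (8, "angular", (6, 16, 10)),
    (9, "angular", (11, 16, 10)), (10, "angular", (6, 12, 5)),
    (11, "angular", (2, 12, 1)), (12, "angular", (3, 16, 4)),
    (13, "angular", (2, 16, 3)), (14, "angular", (1, 16, 4)),
    (15, "angular", (2, 16, 4)), (16, "angular", (1, 16, 3)),
    (17, "angular", (5, 12, 16)), (18, "angular", (6, 12, 16)),
    (19, "angular", (10, 16, 12)), (20, "angular", (11, 16, 12)),
    (21, "angular", (2, 12, 16)), (22, "angular", (1, 12, 16)),
    (23, "angular", (3, 16, 12)), (24, "angular", (4, 16, 12)),
    (25, "angular", (12, 5, 1)), (26, "angular", (12, 6, 2)),
    (27, "nddi", (1, 4, 2, 3)), (28, "nddi", (1, 2, 4, 3)),
    (29, "nddi", (6, 11, 5, 10)), (30, "nddi", (6, 5, 11, 10)),
    (31, "nddi", (5, 10, 7, 16)), (32, "nddi", (6, 11, 7, 16)),
    (33, "nddi", (2, 10, 7, 16)), (34, "nddi", (1, 11, 7, 16)),
    (35, "nddi", (2, 3, 7, 16)), (36, "nddi", (1, 4, 7, 16)),
]


class TestAngularFeature:
    def test_equilateral_triangle(self):
        p = [np.array([0.0, 0, 0]), np.array([1.0, 0, 0]), np.array([0.5, np.sqrt(3) / 2, 0])]
        assert angular_feature(p[0], p[1], p[2]) == pytest.approx(60.0, abs=1e-9)

    def test_orthogonal_arms(self):
        a = angular_feature([0.0, 0, 0], [1.0, 0, 0], [1.0, 1, 0])
        assert a == pytest.approx(90.0, abs=1e-9)

    def test_collinear(self):
        a = angular_feature([0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0])
        assert a == pytest.approx(180.0, abs=1e-9)

    def test_degenerate_vertex_is_invalid(self):
        assert np.isnan(angular_feature([1.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0]))


class TestNddiFeature:
    def test_equal_distances(self):
        v = nddi_feature([0.0, 0, 0], [1.0, 0, 0], [5.0, 0, 0], [6.0, 0, 0])
        assert v == pytest.approx(0.0, abs=1e-12)

    def test_three_to_one(self):
        v = nddi_feature([0.0, 0, 0], [3.0, 0, 0], [0.0, 0, 0], [1.0, 0, 0])
        assert v == pytest.approx(0.5)

    def test_zero_numerator_distance(self):
        v = nddi_feature([0.0, 0, 0], [0.0, 0, 0], [0.0, 0, 0], [1.0, 0, 0])
        assert v == pytest.approx(-1.0)

    def test_both_zero_invalid(self):
        assert np.isnan(nddi_feature([0.0] * 3, [0.0] * 3, [1.0, 1, 1], [1.0, 1, 1]))


def test_shipped_bank_matches_reference_table():
    bank = default_bank()
    assert [(s.feature_id, s.kind, s.nodes) for s in bank] == EXPECTED_BANK
    assert sum(s.kind == "angular" for s in bank) == 26
    assert sum(s.kind == "nddi" for s in bank) == 10


def test_extract_features_shape_and_ranges(random_sequence):
    fm = ks.extract_features(random_sequence)
    assert fm.values.shape == (36, random_sequence.n_frames)
    ang = fm.values[:26][fm.valid_mask[:26]]
    nd = fm.values[26:][fm.valid_mask[26:]]
    assert ang.min() >= 0.0 and ang.max() <= 180.0
    assert nd.min() >= -1.0 and nd.max() <= 1.0


def test_rigid_motion_and_scale_invariance(random_sequence):
    """All 36 features are invariant to rotation+translation+uniform scale."""
    from scipy.spatial.transform import Rotation

    fm0 = ks.extract_features(random_sequence)
    R = Rotation.from_euler("zyx", [31.0, -57.0, 112.0], degrees=True).as_matrix()
    t = np.array([3.2, -1.1, 0.7])
    s = 2.37
    moved = ks.SkeletonSequence(
        random_sequence.times,
        s * random_sequence.xyz @ R.T + t,
        random_sequence.valid,
        random_sequence.fps,
    )
    fm1 = ks.extract_features(moved)
    np.testing.assert_allclose(fm1.values, fm0.values, atol=1e-9)


def test_invalid_joint_propagates_to_cell_only(random_sequence):
    seq = random_sequence
    seq.valid[5, 15] = False  # node 16 (spine) missing in frame 6
    seq.xyz[5, 15] = np.nan
    fm = ks.extract_features(seq)
    uses_16 = [i for i, s in enumerate(default_bank()) if 16 in s.nodes]
    assert not fm.valid_mask[uses_16, 5].any()
    others = [i for i in range(36) if i not in uses_16]
    assert fm.valid_mask[others, 5].all()
    assert fm.valid_mask[uses_16, 4].all()  # neighbouring frame untouched


class TestWindow:
    def _fm(self, fps, T):
        vals = np.zeros((36, T))
        valid = np.ones((36, T), dtype=bool)
        kinds = tuple(["angular"] * 26 + ["nddi"] * 10)
        return FeatureMatrix(vals, valid, fps, kinds, tuple(range(1, 37)))

    def test_five_seconds_at_30fps(self):
        fw = window(self._fm(30.0, 300), 0.0, 5.0)
        assert fw.n_samples == 150

    def test_five_seconds_at_4p3fps(self):
        fw = window(self._fm(4.3, 100), 0.0, 5.0)
        assert fw.n_samples == 21  # floor(5 * 4.3)

    def test_inverted_bounds_error(self):
        with pytest.raises(WindowError):
            window(self._fm(30.0, 300), 5.0, 5.0)

    def test_too_short_window_error(self):
        with pytest.raises(WindowError, match=">= 2"):
            window(self._fm(30.0, 300), 0.0, 0.04)

    def test_past_end_error(self):
        with pytest.raises(WindowError):
            window(self._fm(30.0, 300), 8.0, 13.0)


def test_decimation_stride():
    rng = np.random.default_rng(0)
    times = np.arange(300) / 30.0
    xyz = rng.normal(size=(300, 20, 3))
    seq = ks.SkeletonSequence(times, xyz, np.ones((300, 20), bool), 30.0)
    dec = seq.decimate(4.3)  # stride round(30/4.3) = 7
    assert dec.fps == pytest.approx(30.0 / 7)
    np.testing.assert_array_equal(dec.xyz, seq.xyz[::7])
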