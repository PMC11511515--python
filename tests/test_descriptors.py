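"""Pairwise MI/CC descriptors: quantization, estimators, vector assembly."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import kinescore as ks
from kinescore import descriptors as desc
from kinescore.features import FeatureMatrix, window
from tests_oracles import brute_force_mi


class TestPairIndex:
    def test_bijection(self):
        ks_seen = set()
        for i in range(1, 36):
            for j in range(i + 1, 37):
                k = ks.pair_to_index(i, j)
                assert ks.index_to_pair(k) == (i, j)
                ks_seen.add(k)
        assert ks_seen == set(range(1, 631))

    def test_lexicographic_order(self):
        assert ks.index_to_pair(1) == (1, 2)
        assert ks.index_to_pair(35) == (1, 36)
        assert ks.index_to_pair(36) == (2, 3)
        assert ks.index_to_pair(630) == (35, 36)


class TestQuantize:
    def test_angular_bin_edges(self):
        np.testing.assert_array_equal(
            ks.quantize(np.array([0.0, 9.99, 10.0]), "angular"), [1, 1, 2]
        )

    def test_top_edge_inclusive(self):
        assert ks.quantize(np.array([180.0]), "angular")[0] == 18
        assert ks.quantize(np.array([1.0]), "nddi")[0] == 20

    def test_bottom_edge(self):
        assert ks.quantize(np.array([-1.0]), "nddi")[0] == 1

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError, match="outside known range"):
            ks.quantize(np.array([181.0]), "angular")


class TestCcDescriptor:
    def test_identical_streams(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert ks.cc_descriptor(x, x) == pytest.approx(1.0)

    def test_affine_anticorrelation(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert ks.cc_descriptor(x, -2 * x + 5) == pytest.approx(-1.0)

    def test_constant_stream_convention(self):
        x = np.array([1.0, 2.0, 3.0])
        assert ks.cc_descriptor(np.full(3, 7.0), x) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(2, 50))
        assert ks.cc_descriptor(a, b) == pytest.approx(ks.cc_descriptor(b, a))


class TestMiDescriptor:
    def test_self_information(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 180, 400)
        mi = ks.mi_descriptor(x, x, ("angular", "angular"))
        h = desc.entropy_bits(desc.quantize(x, "angular"), 18)
        assert mi == pytest.approx(h, abs=1e-12)

    def test_independent_uniform_near_zero(self):
        rng = np.random.default_rng(123)
        x = rng.uniform(0, 180, 100_000)
        y = rng.uniform(0, 180, 100_000)
        assert ks.mi_descriptor(x, y, ("angular", "angular")) <= 0.02

    def test_hand_histogram_one_bit(self):
        # joint counts {(1,1):2, (2,2):2} -> MI = 1 bit
        x = np.array([5.0, 5.0, 15.0, 15.0])
        assert ks.mi_descriptor(x, x.copy(), ("angular", "angular")) == pytest.approx(1.0)

    @given(seed=st.integers(0, 2**16), n=st.integers(4, 60))
    def test_properties_vs_entropy_bound(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 180, n)
        y = rng.uniform(-1, 1, n)
        mi = ks.mi_descriptor(x, y, ("angular", "nddi"))
        mi_rev = ks.mi_descriptor(y, x, ("nddi", "angular"))
        hx = desc.entropy_bits(desc.quantize(x, "angular"), 18)
        hy = desc.entropy_bits(desc.quantize(y, "nddi"), 20)
        assert mi >= 0.0
        assert mi == pytest.approx(mi_rev, abs=1e-12)
        assert mi <= min(hx, hy) + 1e-12

    def test_matches_brute_force_oracle_on_random_windows(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(5, 80))
            kinds = rng.choice(["angular", "nddi"], size=2)
            lohi = {"angular": (0, 180), "nddi": (-1, 1)}
            fi = rng.uniform(*lohi[kinds[0]], n)
            fj = rng.uniform(*lohi[kinds[1]], n)
            got = ks.mi_descriptor(fi, fj, tuple(kinds))
            want = brute_force_mi(fi, fj, *kinds)
            assert got == pytest.approx(want, abs=1e-12)


def _feature_window(rng, n=60):
    vals = np.vstack(
        [rng.uniform(0, 180, (26, n)), rng.uniform(-1, 1, (10, n))]
    )
    kinds = tuple(["angular"] * 26 + ["nddi"] * 10)
    fm = FeatureMatrix(vals, np.ones((36, n), bool), 30.0, kinds, tuple(range(1, 37)))
    return window(fm, 0.0, n / 30.0)


class TestDescriptorVectors:
    def test_dimensionality(self):
        rng = np.random.default_rng(9)
        mi, cc = ks.descriptor_vectors(_feature_window(rng))
        assert mi.values.shape == (630,)
        assert cc.values.shape == (630,)
        assert mi.values.size + cc.values.size == 1260

    def test_mi_vector_order_blind(self):
        rng = np.random.default_rng(10)
        fw = _feature_window(rng)
        mi1, _ = ks.descriptor_vectors(fw)
        perm = rng.permutation(fw.n_samples)
        fw.values = fw.values[:, perm]
        mi2, _ = ks.descriptor_vectors(fw)
        np.testing.assert_array_equal(mi1.values, mi2.values)

    def test_unusable_window_raises(self):
        rng = np.random.default_rng(11)
        fw = _feature_window(rng)
        fw.valid_mask[3, :20] = False  # 33% invalid in one feature row
        with pytest.raises(desc.WindowUnusableError):
            ks.descriptor_vectors(fw)

    def test_vectorized_cc_matches_scalar_op(self):
        rng = np.random.default_rng(12)
        fw = _feature_window(rng, n=40)
        cc = desc.cc_vector(fw)
        for k0 in rng.integers(0, 630, 25):
            i, j = desc.PAIR_I[k0], desc.PAIR_J[k0]
            assert cc[k0] == pytest.approx(
                ks.cc_descriptor(fw.values[i], fw.values[j]), abs=1e-12
            )

    def test_noise_floor_constancy_zeroes_cc(self):
        rng = np.random.default_rng(13)
        fw = _feature_window(rng, n=50)
        fw.values[0] = 90.0 + rng.normal(0, 0.5, 50)  # below 5-degree floor
        cc = desc.cc_vector(fw)
        involves_0 = (desc.PAIR_I == 0) | (desc.PAIR_J == 0)
        assert (cc[involves_0] == 0.0).all()

    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(14)
        mi, cc = ks.descriptor_vectors(_feature_window(rng))
        path = desc.write_descriptors([mi, cc], tmp_path / "d.csv")
        back = desc.read_descriptors(path)
        assert back[0].kind == "MI" and back[1].kind == "CC"
        np.testing.assert_allclose(back[0].values, mi.values, atol=1e-12)
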