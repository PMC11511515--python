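"""Adaptive CEM kernels: covariance assembly, unit gain, energy minimality."""

import numpy as np
import pytest
from scipy.optimize import minimize

import kinescore as ks
from kinescore.cem import BackgroundBuffer, ClassTemplate


def _template(rng, n_d=3, n_classes=3, n_per=4):
    tsd = {
        c: rng.uniform(0.1, 1.5, (n_per, n_d)) for c in range(1, n_classes + 1)
    }
    return ClassTemplate(1, list(range(1, n_d + 1)), tsd)


class TestAdaptiveCovariance:
    def test_empty_buffer_training_term_only(self):
        rng = np.random.default_rng(0)
        tpl = _template(rng)
        R0 = ks.adaptive_covariance(tpl, None)
        R1 = ks.adaptive_covariance(tpl, BackgroundBuffer(3))
        np.testing.assert_allclose(R0, R1, atol=1e-15)

    def test_degenerate_buffer_average(self):
        rng = np.random.default_rng(1)
        tpl = _template(rng)
        v = np.array([0.3, 0.7, 1.1])
        buf = BackgroundBuffer(3)
        for _ in range(5):
            buf.append(v)
        R = ks.adaptive_covariance(tpl, buf)
        R0 = ks.adaptive_covariance(tpl, None)
        np.testing.assert_allclose(R - R0, np.outer(v, v), atol=1e-12)

    def test_matches_brute_force_double_sum(self):
        rng = np.random.default_rng(2)
        tpl = _template(rng, n_d=4, n_classes=4, n_per=5)
        buf = BackgroundBuffer(4)
        windows = rng.uniform(0, 1, (7, 4))
        for w in windows:
            buf.append(w)
        R = ks.adaptive_covariance(tpl, buf)
        n_t = len(tpl.tsd)
        want = np.zeros((4, 4))
        for arr in tpl.tsd.values():
            inner = np.zeros((4, 4))
            for row in arr:
                inner += np.outer(row, row)
            want += inner / arr.shape[0]
        want /= n_t
        want += sum(np.outer(w, w) for w in windows) / len(windows)
        np.testing.assert_allclose(R, want, atol=1e-12)

    def test_symmetric_psd_and_trace_monotone(self):
        rng = np.random.default_rng(3)
        tpl = _template(rng)
        buf = BackgroundBuffer(3)
        prev_trace = np.trace(ks.adaptive_covariance(tpl, buf))
        for _ in range(4):
            buf.append(rng.uniform(0, 1, 3))
            R = ks.adaptive_covariance(tpl, buf)
            np.testing.assert_allclose(R, R.T, atol=1e-14)
            assert np.linalg.eigvalsh(R).min() >= -1e-12
            assert np.trace(R) >= prev_trace - 1e-12


class TestCemKernel:
    def test_identity_covariance_closed_form(self):
        rng = np.random.default_rng(4)
        tpl = _template(rng)
        g = tpl.g
        kern = ks.cem_kernel(tpl, np.eye(3))
        np.testing.assert_allclose(kern.h, g / (g @ g), atol=1e-12)

    def test_unit_gain_constraint(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            tpl = _template(rng, n_d=int(rng.integers(2, 6)))
            R = ks.adaptive_covariance(tpl, None)
            kern = ks.cem_kernel(tpl, R)
            assert tpl.g @ kern.h == pytest.approx(1.0, abs=1e-8)

    def test_zero_signature_rejected(self):
        tpl = ClassTemplate(1, [1, 2], {1: np.zeros((3, 2)), 2: np.ones((3, 2))})
        with pytest.raises(ValueError, match="zero"):
            ks.cem_kernel(tpl, np.eye(2))

    def test_minimizes_background_energy_vs_qp_oracle(self):
        """Kernel equals the constrained least-squares solution computed by
        an independent numerical optimizer on small fixtures."""
        rng = np.random.default_rng(6)
        for n_d in (2, 3, 4):
            tpl = _template(rng, n_d=n_d)
            R = ks.adaptive_covariance(tpl, None)
            kern = ks.cem_kernel(tpl, R)
            g = tpl.g
            n_t = len(tpl.tsd)

            def energy(h):
                tot = 0.0
                for arr in tpl.tsd.values():
                    tot += np.mean((arr @ h) ** 2) / n_t
                return tot

            res = minimize(
                energy,
                x0=g / (g @ g),
                constraints=[{"type": "eq", "fun": lambda h: g @ h - 1.0}],
                method="SLSQP",
                options={"ftol": 1e-16, "maxiter": 500},
            )
            assert res.success
            np.testing.assert_allclose(kern.h, res.x, atol=1e-6)
            assert energy(kern.h) <= energy(res.x) + 1e-10


class TestDetectorResponse:
    def test_signature_response_is_one(self):
        rng = np.random.default_rng(7)
        tpl = _template(rng)
        kern = ks.cem_kernel(tpl, ks.adaptive_covariance(tpl, None))
        assert ks.detector_response(kern, tpl.g) == pytest.approx(1.0, abs=1e-8)

    def test_linearity_and_zero(self):
        rng = np.random.default_rng(8)
        tpl = _template(rng)
        kern = ks.cem_kernel(tpl, ks.adaptive_covariance(tpl, None))
        assert ks.detector_response(kern, np.zeros(3)) == 0.0
        assert ks.detector_response(kern, 2 * tpl.g) == pytest.approx(2.0, abs=1e-8)

    def test_dimension_mismatch(self):
        rng = np.random.default_rng(9)
        tpl = _template(rng)
        kern = ks.cem_kernel(tpl, ks.adaptive_covariance(tpl, None))
        with pytest.raises(ValueError, match="mismatch"):
            ks.detector_response(kern, np.zeros(5))


class TestBackgroundBuffer:
    def test_capacity_policy(self):
        buf = BackgroundBuffer(2, maxlen=3)
        vecs = [np.array([i, 1.0]) for i in range(5)]
        for v in vecs:
            buf.append(v)
        assert len(buf) == 3
        want = sum(np.outer(v, v) for v in vecs[2:]) / 3
        np.testing.assert_allclose(buf.mean_outer(), want, atol=1e-12)
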