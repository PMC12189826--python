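"""Mean-field CRF smoothing against a brute-force dense reference."""

import numpy as np
import pytest

from psgdetect.crf import (
    CRFFeatures,
    CRFParams,
    crf_smooth,
    kernel_matrix,
    mean_field_dense,
)


def _feats(n, rate=100.0, c=None):
    t = np.arange(n) / rate
    return CRFFeatures(t=t, c=np.zeros(n) if c is None else np.asarray(c, float))


class TestKernelMatrix:
    def test_diagonal_excluded(self):
        k1, k2 = kernel_matrix(_feats(10), 1.0, 0.1, 0.25)
        assert np.all(np.diag(k1) == 0) and np.all(np.diag(k2) == 0)

    def test_smoothness_kernel_closed_form(self):
        theta_g = 0.25
        f = CRFFeatures(t=np.array([0.0, theta_g]), c=np.zeros(2))
        _, k2 = kernel_matrix(f, 1.0, 0.1, theta_g)
        assert k2[0, 1] == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_pairs_beyond_truncation_are_zero(self):
        f = _feats(1000, rate=100.0)
        k1, k2 = kernel_matrix(f, 0.5, 0.1, 0.25, truncation=3.0)
        dt = np.abs(f.t[:, None] - f.t[None, :])
        assert np.all(k1[dt > 1.5 + 1e-6] == 0)
        assert np.all(k2[dt > 1.5 + 1e-6] == 0)
        assert k1[0, 1] > 0  # near pairs survive

    def test_symmetric(self):
        f = _feats(50, c=np.random.default_rng(0).random(50))
        k1, k2 = kernel_matrix(f, 1.0, 0.1, 0.25)
        assert np.allclose(k1, k1.T) and np.allclose(k2, k2.T)


class TestCRFSmooth:
    def test_zero_weights_reduce_to_thresholding(self):
        rng = np.random.default_rng(0)
        p = rng.random(300)
        params = CRFParams(w1=0.0, w2=0.0)
        out = crf_smooth(p, params=params)
        assert np.array_equal(out, (p > 0.5).astype(np.int8))

    def test_single_dip_is_flipped_up(self):
        p = np.array([0.9, 0.9, 0.4, 0.9, 0.9])
        f = CRFFeatures(t=np.arange(5) * 0.01, c=p)
        out = crf_smooth(p, f, CRFParams(mode="potts"))
        assert out.tolist() == [1, 1, 1, 1, 1]

    def test_uniform_half_probability_ties_to_zero(self):
        p = np.full(50, 0.5)
        out = crf_smooth(p, params=CRFParams(mode="potts"))
        assert set(out.tolist()) <= {0, 1}
        assert len(set(out.tolist())) == 1  # one common label
        assert out[0] == 0  # tie broken to "no event"

    def test_fragmentation_suppressed_on_long_run(self):
        p = np.full(200, 0.9)
        p[100] = 0.1
        out = crf_smooth(p, params=CRFParams(mode="potts"))
        assert out.sum() == 200  # the run is returned unbroken

    @pytest.mark.parametrize("mode", ["potts", "literal"])
    def test_matches_dense_reference(self, mode):
        rng = np.random.default_rng(5)
        for n in (50, 200, 500):
            p = rng.random(n)
            f = CRFFeatures(t=np.arange(n) / 100.0, c=p)
            params = CRFParams(mode=mode)
            labels, marg = crf_smooth(p, f, params, return_marginals=True)
            ref_labels, ref_marg = mean_field_dense(p, f, params, return_marginals=True)
            assert np.array_equal(labels, ref_labels)
            assert np.max(np.abs(marg - ref_marg)) < 1e-8

    def test_marginals_stay_normalized(self):
        rng = np.random.default_rng(1)
        p = rng.random(300)
        _, marg = crf_smooth(p, params=CRFParams(), return_marginals=True)
        assert np.allclose(marg.sum(axis=1), 1.0, atol=1e-9)

    def test_truncated_matches_wide_truncation(self):
        rng = np.random.default_rng(2)
        p = rng.random(400)
        f = CRFFeatures(t=np.arange(400) / 100.0, c=p)
        narrow = crf_smooth(p, f, CRFParams(kernel_truncation=6.0))
        wide = crf_smooth(p, f, CRFParams(kernel_truncation=50.0))
        assert np.array_equal(narrow, wide)

    def test_idempotent_on_hard_marginals(self):
        p = np.array([0.9, 0.9, 0.4, 0.9, 0.9, 0.1, 0.1, 0.1])
        f = CRFFeatures(t=np.arange(8) * 0.01, c=p)
        params = CRFParams()
        once = crf_smooth(p, f, params)
        eps = params.prob_clip
        hard = np.where(once == 1, 1 - eps, eps)
        f2 = CRFFeatures(t=f.t, c=hard)
        twice = crf_smooth(hard, f2, params)
        assert np.array_equal(once, twice)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            crf_smooth(np.array([0.5, 1.2]))
        with pytest.raises(ValueError):
            crf_smooth(np.array([[0.5, 0.5]]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            crf_smooth(np.array([0.5, 0.5, 0.5]), _feats(4))

    def test_params_validation(self):
        with pytest.raises(ValueError):
            CRFParams(theta_alpha=0.0)
        with pytest.raises(ValueError):
            CRFParams(iters=0)
        with pytest.raises(ValueError):
            CRFParams(mode="exact")


class TestHandComputedOracle:
    def test_five_point_instance_matches_hand_iteration(self):
        """One mean-field sweep computed explicitly for the 5-point toy case."""
        p = np.array([0.9, 0.9, 0.4, 0.9, 0.9])
        t = np.arange(5) * 0.01
        params = CRFParams(mode="potts", iters=1)
        eps = params.prob_clip
        pc = np.clip(p, eps, 1 - eps)
        u1, u0 = -np.log(pc), -np.log(1 - pc)
        K = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                k1 = np.exp(-((t[i] - t[j]) ** 2) / (2 * params.theta_alpha**2)
                            - ((p[i] - p[j]) ** 2) / (2 * params.theta_beta**2))
                k2 = np.exp(-((t[i] - t[j]) ** 2) / (2 * params.theta_gamma**2))
                K[i, j] = params.w1 * k1 + params.w2 * k2
        q1, q0 = pc, 1 - pc
        e1 = u1 + K @ q0
        e0 = u0 + K @ q1
        z1, z0 = np.exp(-e1), np.exp(-e0)
        expect = (z1 / (z1 + z0) > 0.5).astype(np.int8)
        f = CRFFeatures(t=t, c=p)
        got = crf_smooth(p, f, params)
        assert np.array_equal(got, expect)
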