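"""QTI forward model, fit, and metric derivations."""

import numpy as np
import pytest

import qtimcd as q
from qtimcd.btensor import voigt6, voigt21
from qtimcd.qti import (
    E_SHEAR,
    QTIFit,
    metrics_from_moments,
    moments_of_mixture,
)
from conftest import random_mixture, random_psd_tensor


def eig_variance(d):
    """Independent oracle: population variance of a tensor's eigenvalues."""
    return float(np.var(np.linalg.eigvalsh(d)))


def mixture_metrics_oracle(weights, tensors):
    """Brute-force moment metrics via eigendecompositions (no Voigt algebra)."""
    mds = np.array([np.trace(d) / 3.0 for d in tensors])
    md = float(weights @ mds)
    v_i = float(weights @ mds**2 - md**2)
    v_lam = float(weights @ np.array([eig_variance(d) for d in tensors]))
    d_mean = np.einsum("k,kij->ij", weights, tensors)
    fa = np.sqrt(1.5 * eig_variance(d_mean) / (eig_variance(d_mean) + md**2))
    return md, fa, 3 * v_i / md**2, 1.2 * v_lam / md**2


def theta_of(dist, log_s0=0.0):
    d6, c6 = dist.moments()
    return np.concatenate(([log_s0], d6, voigt21(c6)))


class TestPredictSignal:
    def test_monoexponential_isotropic(self, protocol):
        d = 0.9
        theta = np.concatenate(([0.2], voigt6(d * np.eye(3)), np.zeros(21)))
        s = q.predict_signal(theta, protocol)
        expected = np.exp(0.2) * np.exp(-protocol.bvals * d)
        assert np.allclose(s, expected, rtol=1e-12)

    def test_b0_returns_s0(self, protocol):
        rng = np.random.default_rng(1)
        dist = random_mixture(rng)
        s = q.predict_signal(theta_of(dist, log_s0=0.7), protocol)
        b0 = protocol.bvals < 1e-9
        assert np.allclose(s[b0], np.exp(0.7), rtol=1e-12)

    def test_single_tensor_linear_contraction(self, protocol):
        # s = S0 exp(-b n^T D n), checked against direct matrix contraction
        rng = np.random.default_rng(2)
        D = random_psd_tensor(rng)
        theta = np.concatenate(([0.0], voigt6(D), np.zeros(21)))
        s = q.predict_signal(theta, protocol)
        for bt, si in zip(protocol.btensors, s):
            if bt.shape_tag == "linear" and bt.b > 0:
                n = bt.orientation
                assert np.isclose(si, np.exp(-bt.b * n @ D @ n), rtol=1e-10)


class TestFitQti:
    def test_roundtrip_metrics_and_projection(self, protocol, design):
        """Noiseless cumulant data: the minimum-norm fit reproduces the
        identifiable parameter projection and every derived metric."""
        rng = np.random.default_rng(3)
        U, sv, Vt = np.linalg.svd(design, full_matrices=False)
        r = int((sv > sv[0] * 1e-10).sum())
        P = Vt[:r].T @ Vt[:r]
        for _ in range(20):
            dist = random_mixture(rng)
            theta = theta_of(dist, log_s0=rng.normal(0, 0.3))
            fit = q.fit_qti(q.predict_signal(theta, protocol), protocol, design=design)
            assert fit.valid
            assert np.abs(fit.params - P @ theta).max() < 1e-8
            mt = metrics_from_moments(*dist.moments())
            mf = q.qti_metrics(fit)
            for key in ("md", "fa", "v_i", "v_lambda", "mk_i", "mk_a", "mk_t", "ufa"):
                a, b = getattr(mt, key), getattr(mf, key)
                assert abs(a - b) < 1e-8 * max(abs(a), 1.0), key

    def test_constant_signal_zero_diffusivity(self, protocol):
        fit = q.fit_qti(np.full(len(protocol), 2.0), protocol)
        assert np.isclose(fit.s0, 2.0)
        assert np.abs(fit.d_mean).max() < 1e-10
        assert np.abs(fit.c_cov).max() < 1e-10

    def test_linear_only_protocol_invalid(self):
        p = q.build_protocol(
            [{"shape": "linear", "b": 1.0, "n": 30}], n_b0=2, for_fitting=False
        )
        fit = q.fit_qti(np.ones(len(p)), p)
        assert not fit.valid

    def test_too_few_usable_measurements_invalid(self, protocol):
        s = np.ones(len(protocol))
        s[30:] = -1.0  # masked out
        fit = q.fit_qti(s, protocol)
        assert not fit.valid


class TestMetrics:
    def test_stick_closed_form(self):
        # eigenvalues (1, 0, 0): V_lambda = 2/9, MD = 1/3 -> FA = 1, MK_A = 2.4
        m = metrics_from_moments(np.diag([1.0, 0.0, 0.0]), np.zeros((6, 6)))
        assert abs(m.fa - 1.0) < 1e-10
        assert abs(m.md - 1.0 / 3.0) < 1e-10
        assert abs(m.mk_a - 2.4) < 1e-10
        assert abs(m.ufa - 1.0) < 1e-10

    def test_isotropic_zeroes(self):
        m = metrics_from_moments(0.7 * np.eye(3), np.zeros((6, 6)))
        assert m.fa < 1e-7 and abs(m.mk_a) < 1e-12 and abs(m.mk_i) < 1e-12

    def test_perpendicular_sticks_crossing(self):
        """Equal-weight 90-degree crossing of sticks: mean-tensor FA drops to
        sqrt(1/2) while MK_A stays 2.4 (brute-force mixture moments)."""
        sticks = np.stack([np.diag([1.0, 0, 0]), np.diag([0, 1.0, 0])])
        w = np.array([0.5, 0.5])
        d6, c6 = moments_of_mixture(w, sticks)
        m = metrics_from_moments(d6, c6)
        md, fa, mk_i, mk_a = mixture_metrics_oracle(w, sticks)
        assert abs(m.fa - np.sqrt(0.5)) < 1e-10
        assert abs(m.mk_a - 2.4) < 1e-10
        assert abs(m.fa - fa) < 1e-12 and abs(m.mk_a - mk_a) < 1e-12

    def test_random_mixture_against_eigen_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            dist = random_mixture(rng, k=4)
            m = metrics_from_moments(*dist.moments())
            md, fa, mk_i, mk_a = mixture_metrics_oracle(dist.weights, dist.tensors)
            assert np.allclose([m.md, m.fa, m.mk_i, m.mk_a], [md, fa, mk_i, mk_a], atol=1e-10)
            assert abs(m.mk_t - (m.mk_i + m.mk_a)) < 1e-10

    def test_eshear_self_consistency(self):
        """(D x D)::E_shear equals the eigenvalue variance of D."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            d = random_psd_tensor(rng)
            d6 = voigt6(d)
            assert np.isclose(d6 @ E_SHEAR @ d6, eig_variance(d), atol=1e-12)

    def test_nonpositive_md_undefined(self):
        m = metrics_from_moments(np.zeros((3, 3)), np.zeros((6, 6)))
        assert not m.defined and np.isnan(m.fa)


class TestDispersionInvariance:
    def test_mka_constant_fa_decreasing(self):
        """Mixtures of identical sticks at increasing orientation dispersion:
        MK_A is invariant while FA decreases (the contrast mechanism that
        separates microscopic from macroscopic anisotropy)."""
        from qtimcd.phantom import _dispersed

        fas, mkas = [], []
        for mode in ("coherent", "crossing", "uniform"):
            m = _dispersed(1.0, 0.0, mode).metrics()
            fas.append(m.fa)
            mkas.append(m.mk_a)
        assert np.allclose(mkas, 2.4, atol=1e-10)
        assert abs(fas[0] - 1.0) < 1e-10
        assert abs(fas[1] - np.sqrt(0.5)) < 1e-10
        assert fas[2] < 1e-6  # isotropic mean tensor up to float rounding
        assert fas[0] > fas[1] > fas[2]

    def test_truncation_bias_shrinks_with_bmax(self, protocol):
        """Fitting exact multi-Gaussian (non-cumulant) signals biases MK_A;
        the bias magnitude shrinks monotonically as b_max decreases."""
        from qtimcd.phantom import _dispersed

        dist = _dispersed(2.2, 0.2, "uniform")
        truth = dist.metrics().mk_a
        biases = []
        for bmax in (2.0, 1.0, 0.5):
            p = protocol.scaled(bmax / 2.0)
            fit = q.fit_qti(dist.signal(p), p)
            assert fit.valid
            biases.append(abs(q.qti_metrics(fit).mk_a - truth))
        assert biases[0] > biases[1] > biases[2]


class TestFitVolume:
    def test_noiseless_cumulant_volume_matches_ground_truth(self, protocol):
        """Signals generated from the cumulant form recover the ground-truth
        maps to < 1e-6 everywhere in the mask."""
        rng = np.random.default_rng(11)
        shape = (4, 3, 2)
        dists = [random_mixture(rng) for _ in range(3)]
        ids = rng.integers(0, 3, size=shape)
        data = np.zeros(shape + (len(protocol),))
        gt = {k: np.zeros(shape) for k in ("md", "fa", "mk_a")}
        for k, dist in enumerate(dists):
            s = q.predict_signal(theta_of(dist), protocol)
            m = metrics_from_moments(*dist.moments())
            data[ids == k] = s
            for key in gt:
                gt[key][ids == k] = getattr(m, key)
        out = q.fit_volume(data, protocol)
        assert out["valid"].all()
        for key in gt:
            assert np.abs(out[key] - gt[key]).max() < 1e-6

    def test_empty_mask(self, protocol):
        data = np.ones((2, 2, 2, len(protocol)))
        out = q.fit_volume(data, protocol, mask=np.zeros((2, 2, 2), bool))
        assert not out["valid"].any()
        assert np.isnan(out["md"]).all()

    def test_bad_voxel_isolated(self, protocol):
        rng = np.random.default_rng(12)
        dist = random_mixture(rng)
        s = q.predict_signal(theta_of(dist), protocol)
        data = np.tile(s, (3, 1, 1, 1)).reshape(3, 1, 1, -1)
        data[1, 0, 0, :] = 0.0  # dead voxel
        out = q.fit_volume(data, protocol)
        assert not out["valid"][1, 0, 0]
        assert out["valid"][0, 0, 0] and out["valid"][2, 0, 0]
        truth = metrics_from_moments(*dist.moments()).md
        assert np.isclose(out["md"][0, 0, 0], truth, atol=1e-8)

    def test_grid_mismatch_rejected(self, protocol):
        with pytest.raises(ValueError, match="mask"):
            q.fit_volume(
                np.ones((2, 2, 2, len(protocol))), protocol, mask=np.ones((3, 2, 2), bool)
            )
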