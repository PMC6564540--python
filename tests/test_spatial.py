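"""CCA, templates, spatial filters and the filter bank."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import signal as sps

import vepwin as v


def grid_search_cca_oracle(X, Y, step=0.01):
    """Independent brute-force first canonical correlation.

    Scans X-side unit weight vectors on an angular grid of ``step`` rad
    (3-D sphere here) and, for each candidate direction, takes the best
    achievable correlation with any combination of Y's rows, which is the
    norm of the projection of the centered candidate signal onto the row
    space of centered Y (multiple-correlation identity).  No covariance
    whitening or SVD involved.
    """
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Q, _ = np.linalg.qr(Yc.T)  # orthonormal basis of Y's row space
    az = np.arange(0.0, np.pi, step)
    el = np.arange(-np.pi / 2, np.pi / 2 + step, step)
    A, E = np.meshgrid(az, el, indexing="ij")
    dirs = np.stack(
        [np.cos(E) * np.cos(A), np.cos(E) * np.sin(A), np.sin(E)], axis=-1
    ).reshape(-1, 3)
    cand = dirs @ Xc  # (n_dirs, s) candidate 1-D signals
    cand -= cand.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(cand, axis=1)
    proj = np.linalg.norm(cand @ Q, axis=1)
    ok = norms > 1e-12
    return float(np.max(proj[ok] / norms[ok]))


class TestCca:
    def test_self_correlation_is_one(self, rng):
        X = rng.standard_normal((3, 200))
        rho, _, _ = v.cca(X, X.copy())
        assert rho[0] == pytest.approx(1.0, abs=1e-8)

    def test_independent_noise_near_zero(self, rng):
        x = rng.standard_normal((1, 10_000))
        y = rng.standard_normal((1, 10_000))
        rho, _, _ = v.cca(x, y)
        assert rho[0] < 0.1

    def test_matches_grid_search_oracle(self, rng):
        X = rng.standard_normal((3, 200))
        Y = rng.standard_normal((2, 200))
        rho, _, _ = v.cca(X, Y)
        assert abs(rho[0] - grid_search_cca_oracle(X, Y)) < 1e-2

    def test_matches_sklearn_cross_decomposition(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.standard_normal((4, 300))
        Y = 0.5 * X[:2] + rng.standard_normal((2, 300))
        rho, _, _ = v.cca(X, Y)
        cca2 = sklearn.CCA(n_components=1).fit(X.T, Y.T)
        xs, ys = cca2.transform(X.T, Y.T)
        ref = np.corrcoef(xs[:, 0], ys[:, 0])[0, 1]
        assert rho[0] == pytest.approx(abs(ref), abs=1e-6)

    def test_weight_count_and_ordering(self, rng):
        X = rng.standard_normal((4, 500))
        Y = rng.standard_normal((3, 500))
        rho, wx, wy = v.cca(X, Y)
        assert wx.shape == (4, 3) and wy.shape == (3, 3)
        assert np.all(np.diff(rho) <= 1e-12)

    def test_canonical_variates_maximize_correlation(self, rng):
        X = rng.standard_normal((3, 400))
        Y = np.vstack([X[0] + 0.1 * rng.standard_normal(400), rng.standard_normal(400)])
        rho, wx, wy = v.cca(X, Y)
        achieved = np.corrcoef(wx[:, 0] @ X, wy[:, 0] @ Y)[0, 1]
        assert abs(achieved) == pytest.approx(rho[0], abs=1e-7)

    def test_invariant_under_row_remixing(self, rng):
        X = rng.standard_normal((4, 300))
        Y = rng.standard_normal((3, 300))
        A = rng.standard_normal((4, 4)) + 4 * np.eye(4)  # invertible
        rho1, _, _ = v.cca(X, Y)
        rho2, _, _ = v.cca(A @ X, Y)
        assert rho1[0] == pytest.approx(rho2[0], abs=1e-8)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            v.cca(rng.standard_normal((5, 5)), rng.standard_normal((2, 5)))

    def test_rank_deficient_warns(self, rng):
        X = rng.standard_normal((1, 100))
        X2 = np.vstack([X, X])  # duplicated row -> singular covariance
        with pytest.warns(UserWarning):
            v.cca(X2, rng.standard_normal((2, 100)))


class TestTemplates:
    def test_mean_of_identical_copies(self, rng):
        T = rng.standard_normal((4, 50))
        np.testing.assert_allclose(v.build_template([T, T.copy(), T.copy()]), T)

    def test_symmetric_pair_cancels(self, rng):
        T = rng.standard_normal((4, 50))
        np.testing.assert_allclose(v.build_template([T, -T]), np.zeros_like(T), atol=1e-15)

    def test_matches_elementwise_loop_oracle(self, rng):
        trials = [rng.standard_normal((3, 8)) for _ in range(6)]
        X = v.build_template(trials)
        for i in range(3):
            for j in range(8):
                assert X[i, j] == pytest.approx(
                    sum(t[i, j] for t in trials) / 6, abs=1e-14
                )

    def test_linearity(self, rng):
        trials = [rng.standard_normal((3, 20)) for _ in range(4)]
        np.testing.assert_allclose(
            v.build_template([2.5 * t for t in trials]),
            2.5 * v.build_template(trials),
            atol=1e-12,
        )

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            v.build_template([rng.standard_normal((3, 5)), rng.standard_normal((3, 6))])


class TestSpatialFilter:
    def _single_channel_trials(self, rng, channel=0, n=6):
        sig = np.sin(2 * np.pi * 11 * np.arange(300) / 600)
        trials = []
        for _ in range(n):
            t = 0.02 * rng.standard_normal((5, 300))
            t[channel] += sig
            trials.append(t)
        return trials

    def test_concentrates_on_signal_channel(self, rng):
        trials = self._single_channel_trials(rng)
        w = v.build_spatial_filter(trials, v.build_template(trials))
        assert abs(w[0]) > 0.9
        assert np.linalg.norm(w) == pytest.approx(1.0)

    def test_permutation_equivariance(self, rng):
        trials = self._single_channel_trials(rng)
        w = v.build_spatial_filter(trials, v.build_template(trials))
        perm = np.array([3, 0, 4, 1, 2])
        permuted = [t[perm] for t in trials]
        w_p = v.build_spatial_filter(permuted, v.build_template(permuted))
        np.testing.assert_allclose(np.abs(w_p), np.abs(w[perm]), atol=1e-6)

    def test_filtered_snr_beats_best_channel(self, cvep_session, cvep_bank):
        """Projecting through the learned filter yields at least the
        template-correlation of the best single channel."""
        k = 0
        trials = cvep_session.trials_of_class(k)
        X = v.build_template(trials)
        w = v.build_spatial_filter(trials, X)
        per_channel = []
        for ch in range(X.shape[0]):
            rs = [np.corrcoef(t[ch], X[ch])[0, 1] for t in trials]
            per_channel.append(np.mean(rs))
        filtered = np.mean([np.corrcoef(w @ t, w @ X)[0, 1] for t in trials])
        assert filtered >= max(per_channel) - 0.02

    def test_needs_two_trials(self, rng):
        t = rng.standard_normal((3, 50))
        with pytest.raises(ValueError):
            v.build_spatial_filter([t], t)


class TestSubbandFilter:
    def test_passband_tone_preserved(self):
        t = np.arange(1800) / 600
        tone = np.sin(2 * np.pi * 30 * t)[None, :]
        out = v.subband_filter(tone, (8, 60), 600)
        assert np.mean(out**2) >= 0.9 * np.mean(tone**2)

    def test_stopband_tone_attenuated(self):
        t = np.arange(1800) / 600
        tone = np.sin(2 * np.pi * 4 * t)[None, :]
        out = v.subband_filter(tone, (8, 60), 600)
        assert np.mean(out**2) <= 0.01 * np.mean(tone**2)

    def test_zero_phase(self):
        t = np.arange(1800) / 600
        tone = np.sin(2 * np.pi * 20 * t)
        out = v.subband_filter(tone[None, :], (8, 60), 600)[0]
        a, b = out[200:-200], tone[200:-200]
        lags = sps.correlation_lags(a.size, b.size)
        xc = sps.correlate(a, b)
        assert lags[np.argmax(xc)] == 0

    def test_passband_idempotence(self):
        t = np.arange(3000) / 600
        tone = np.sin(2 * np.pi * 25 * t)[None, :]
        once = v.subband_filter(tone, (8, 60), 600)
        twice = v.subband_filter(once, (8, 60), 600)
        mid = slice(500, 2500)  # away from edges
        assert np.max(np.abs(twice[0, mid] - once[0, mid])) < 0.01

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            v.subband_filter(np.zeros((2, 100)), (60, 8), 600)


class TestSubbandWeights:
    def test_single_band(self):
        np.testing.assert_allclose(v.subband_weights(1), [1.0])

    def test_five_bands_decreasing_normalized(self):
        a = v.subband_weights(5)
        assert a.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(a) < 0)

    def test_matches_scalar_oracle(self):
        a = v.subband_weights(5)
        raw = [m**-1.25 + 0.25 for m in (1, 2, 3, 4, 5)]
        expected = [x / sum(raw) for x in raw]
        np.testing.assert_allclose(a, expected, atol=1e-12)

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            v.subband_weights(0)

    @given(st.integers(min_value=1, max_value=10))
    def test_normalization_and_monotonicity(self, M):
        a = v.subband_weights(M)
        assert a.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(a) <= 0)


class TestTrainBank:
    def test_single_band_shapes(self, cvep_bank):
        assert cvep_bank.M == 1 and cvep_bank.K == 8
        assert len(cvep_bank.templates[0]) == 8
        assert cvep_bank.weights[0].shape == (8, 16)
        assert len(cvep_bank.raw_templates) == 8

    def test_five_band_shapes_and_cutoffs(self, ssvep_codes):
        ts = v.simulate_training_session(
            ssvep_codes, n_b=2, cycles_per_trial=1, config=v.SimConfig(snr_db=10, seed=9)
        )
        bank = v.train_bank(ts, M=5)
        assert bank.M == 5
        assert sum(len(t) for t in bank.templates) == 40
        assert sum(w.shape[0] for w in bank.weights) == 40
        assert bank.bands == [(8, 60), (16, 60), (24, 60), (32, 60), (40, 60)]

    def test_unbalanced_set_rejected(self, cvep_session):
        broken = cvep_session.subset(np.arange(cvep_session.n_trials - 1))
        with pytest.raises(ValueError):
            v.train_bank(broken, M=1)

    def test_template_averaging_consistency(self, cvep_codes):
        """Templates from disjoint seeds converge as the block count grows:
        the template difference norm shrinks from n_b=2 to n_b=6."""
        diffs = {}
        for n_b in (2, 6):
            banks = []
            for seed in (41, 42):
                ts = v.simulate_training_session(
                    cvep_codes,
                    n_b=n_b,
                    cycles_per_trial=1,
                    config=v.SimConfig(snr_db=0, seed=seed),
                )
                banks.append(v.train_bank(ts, M=1))
            diffs[n_b] = np.linalg.norm(
                banks[0].templates[0][0] - banks[1].templates[0][0]
            )
        assert diffs[6] < diffs[2]
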