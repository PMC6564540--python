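"""Dynamic-window decoding: ensemble correlations, buffer regimes,
threshold gating and the online loop."""

import numpy as np
import pytest
from scipy import signal as sps

import vepwin as v
from vepwin.decoder import BlockBuffer, _projected_references
from vepwin.synth import evoked_waveform


def flat_loop_pearson(x, y):
    """Scalar-loop Pearson correlation oracle (no numpy reductions)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sxx = syy = 0.0
    for a, b in zip(x, y):
        sxy += (a - mx) * (b - my)
        sxx += (a - mx) ** 2
        syy += (b - my) ** 2
    return sxy / (sxx * syy) ** 0.5


@pytest.fixture(scope="module")
def dconfig():
    return v.DecoderConfig(n_y_min=270, n_y_max=630, cycle_samples=630, block_samples=30)


class TestReferenceWindow:
    def test_full_window_returns_template(self, rng):
        X = rng.standard_normal((4, 100))
        np.testing.assert_array_equal(v.reference_window(X, 100), X)

    def test_single_column(self, rng):
        X = rng.standard_normal((4, 100))
        np.testing.assert_array_equal(v.reference_window(X, 1), X[:, :1])

    def test_matches_slice_oracle(self, rng):
        X = rng.standard_normal((16, 1890))
        R = v.reference_window(X, 270)
        for i in (0, 7, 15):
            for j in (0, 133, 269):
                assert R[i, j] == X[i, j]

    def test_overlong_window_rejected(self, rng):
        with pytest.raises(ValueError):
            v.reference_window(rng.standard_normal((4, 100)), 101)


class TestEnsembleCorrelation:
    def test_identical_stacks(self, rng):
        Y = rng.standard_normal((4, 50))
        W = rng.standard_normal((3, 4))
        assert v.ensemble_correlation(Y, Y.copy(), W) == pytest.approx(1.0)

    def test_anticorrelated_stacks(self, rng):
        Y = rng.standard_normal((4, 50))
        W = rng.standard_normal((3, 4))
        assert v.ensemble_correlation(Y, -Y, W) == pytest.approx(-1.0)

    def test_matches_flat_loop_oracle(self, rng):
        Y = rng.standard_normal((5, 40))
        R = rng.standard_normal((5, 40))
        W = rng.standard_normal((8, 5))  # K=8 spatial filters
        lam = v.ensemble_correlation(Y, R, W)
        x = [float(w @ Y[:, j]) for w in W for j in range(40)]
        y = [float(w @ R[:, j]) for w in W for j in range(40)]
        assert lam == pytest.approx(flat_loop_pearson(x, y), abs=1e-10)

    def test_zero_variance_yields_zero_with_warning(self):
        Y = np.zeros((3, 20))
        R = np.ones((3, 20))
        W = np.eye(3)
        with pytest.warns(UserWarning):
            assert v.ensemble_correlation(Y, R, W) == 0.0


class TestClassifyWindow:
    def test_template_self_match(self, cvep_session, cvep_bank):
        raw = v.build_template(cvep_session.trials_of_class(3))
        d = v.classify_window(raw, cvep_bank)
        assert d.C == 3
        assert d.lam_tilde[3] == pytest.approx(1.0, abs=1e-9)

    def test_indistinguishable_classes_rejected(self, rng):
        tpl = rng.standard_normal((3, 400))
        noise_trials = [tpl + 0.1 * rng.standard_normal((3, 400)) for _ in range(4)]
        X = v.build_template(noise_trials)
        w = v.build_spatial_filter(noise_trials, X)
        bank = v.TemplateBank(
            templates=[[X, X.copy()]],
            weights=[np.stack([w, w])],
            bands=[(8, 60)],
            a=np.array([1.0]),
            sampling_rate=600.0,
            raw_templates=[X, X.copy()],
        )
        cfg = v.DecoderConfig(
            n_y_min=30, n_y_max=400, cycle_samples=400, block_samples=10, beta=0.05
        )
        d = v.classify_window(rng.standard_normal((3, 400)), bank, cfg)
        assert d.delta == pytest.approx(0.0, abs=1e-12)
        assert not d.accepted

    def test_high_snr_full_cycle_accuracy(self, cvep_session, cvep_bank):
        """At +20 dB a full-cycle window classifies >= 95% of the training
        trials correctly."""
        hits = 0
        for trial, label in zip(cvep_session.trials, cvep_session.labels):
            d = v.classify_window(trial[:, :630], cvep_bank)
            hits += d.C == label
        assert hits / cvep_session.n_trials >= 0.95

    def test_lambda_bounds(self, cvep_session, cvep_bank, rng):
        d = v.classify_window(rng.standard_normal((16, 630)), cvep_bank)
        assert np.all(d.lam_tilde >= -1.0) and np.all(d.lam_tilde <= 1.0)
        assert 0.0 <= d.delta <= 2.0

    def test_channel_mismatch_rejected(self, cvep_bank, rng):
        with pytest.raises(ValueError):
            v.classify_window(rng.standard_normal((4, 630)), cvep_bank)

    def test_matches_naive_from_scratch_oracle(self, cvep_session, cvep_bank):
        """Full-cycle classification equals a naive reimplementation that
        redoes filtering, truncation, projection and Pearson correlation
        step by step."""
        trial = cvep_session.trials[5][:, :630]
        d = v.classify_window(trial, cvep_bank)

        sos = sps.butter(8, [8, 60], btype="bandpass", fs=600, output="sos")
        pad = min(3 * (2 * sos.shape[0] + 1), 629)
        Yb = sps.sosfiltfilt(sos, trial, axis=-1, padlen=pad)
        lam = []
        W = cvep_bank.weights[0]
        for k in range(8):
            Rk = sps.sosfiltfilt(
                sos, cvep_bank.raw_templates[k][:, :630], axis=-1, padlen=pad
            )
            x = np.concatenate([w @ Yb for w in W])
            y = np.concatenate([w @ Rk for w in W])
            lam.append(flat_loop_pearson(list(x), list(y)))
        assert d.C == int(np.argmax(lam))
        np.testing.assert_allclose(d.lam_tilde, lam, atol=1e-10)


class TestStepBuffer:
    def test_no_classification_below_minimum(self, cvep_bank, dconfig, rng):
        buf = BlockBuffer()
        for _ in range(8):  # 240 < 270
            out = v.step_buffer(buf, rng.standard_normal((16, 30)), cvep_bank, dconfig)
            assert out is None
        assert buf.n == 240

    def test_classification_at_nine_blocks(self, cvep_bank, dconfig, rng):
        buf = BlockBuffer()
        out = None
        for _ in range(9):
            out = v.step_buffer(buf, rng.standard_normal((16, 30)), cvep_bank, dconfig)
        assert out is not None
        assert out.n_y_used == 270  # 9 x 30

    def test_trailing_window_starts_at_cycle_boundary(self, cvep_bank, rng):
        """Buffer of 660 with n_y_max = n_c = 630: the classified window is
        the trailing 30 samples starting at column 630 (cycle boundary),
        per the slice-arithmetic rule."""
        cfg = v.DecoderConfig(n_y_min=30, n_y_max=630, cycle_samples=630, block_samples=30)
        buf = BlockBuffer()
        blocks = [rng.standard_normal((16, 30)) for _ in range(22)]  # 660 samples
        out = None
        for b in blocks:
            out = v.step_buffer(buf, b, cvep_bank, cfg)
        assert out.window_start == 630
        assert out.n_y_used == 30
        # equals classifying the slice directly
        direct = v.classify_window(np.concatenate(blocks, axis=1)[:, 630:660], cvep_bank)
        np.testing.assert_allclose(out.lam_tilde, direct.lam_tilde, atol=1e-12)

    def test_trimmed_window_below_minimum_skips(self, cvep_bank, dconfig, rng):
        # n_y_min=270: at 660 samples the trailing window is 30 -> regime 1
        buf = BlockBuffer()
        outs = []
        for _ in range(22):
            outs.append(v.step_buffer(buf, rng.standard_normal((16, 30)), cvep_bank, dconfig))
        assert outs[-1] is None  # 660 buffered, trailing 30 < 270
        assert outs[20] is not None  # 630 buffered = n_y_max

    def test_wrong_block_width_rejected(self, cvep_bank, dconfig, rng):
        with pytest.raises(ValueError):
            v.step_buffer(BlockBuffer(), rng.standard_normal((16, 29)), cvep_bank, dconfig)


class TestDecoderConfig:
    def test_block_must_divide_cycle(self):
        with pytest.raises(ValueError):
            v.DecoderConfig(n_y_min=30, n_y_max=630, cycle_samples=630, block_samples=29)

    def test_max_window_must_be_cycle_multiple(self):
        with pytest.raises(ValueError):
            v.DecoderConfig(n_y_min=30, n_y_max=700, cycle_samples=630, block_samples=30)

    def test_bounds_ordering(self):
        with pytest.raises(ValueError):
            v.DecoderConfig(n_y_min=700, n_y_max=630, cycle_samples=630, block_samples=30)


class TestRunOnline:
    def _stream(self, cvep_codes, targets, snr=20.0, seed=55, **kw):
        return v.simulate_online_stream(
            cvep_codes, targets, config=v.SimConfig(snr_db=snr, seed=seed), **kw
        )

    def test_high_snr_stream_decoded_correctly(self, cvep_codes, cvep_bank):
        targets = [4, 0, 7, 2, 5]
        stream = self._stream(cvep_codes, targets)
        cfg = v.DecoderConfig(
            n_y_min=270, n_y_max=630, cycle_samples=630, block_samples=30, beta=0.1
        )
        decisions, log = v.run_online(stream, cvep_bank, cfg)
        assert [d.C for d in decisions] == targets
        assert all(d.accepted for d in decisions)

    def test_unreachable_threshold_accepts_nothing(self, cvep_codes, cvep_bank):
        stream = self._stream(cvep_codes, [1, 3], max_s_per_target=2.1)
        cfg = v.DecoderConfig(
            n_y_min=270, n_y_max=630, cycle_samples=630, block_samples=30, beta=1.1
        )
        decisions, log = v.run_online(stream, cvep_bank, cfg)
        assert decisions == []
        assert sum(rec.get("reason") == "stream_timeout" for rec in log) == 2

    def test_disabled_gate_accepts_first_window(self, cvep_codes, cvep_bank):
        stream = self._stream(cvep_codes, [6])
        cfg = v.DecoderConfig(
            n_y_min=30, n_y_max=630, cycle_samples=630, block_samples=30, beta=0.0
        )
        decisions, _ = v.run_online(stream, cvep_bank, cfg)
        assert len(decisions) == 1
        assert decisions[0].n_y_used == 30  # first possible window
        assert decisions[0].elapsed_blocks == 1

    def test_accepted_decisions_respect_gates(self, cvep_codes, cvep_bank):
        """Audit over a noisy randomized run: every accepted attempt used
        n_y in [n_y_min, n_y_max] with Delta_C >= beta, and trimmed windows
        start at cycle boundaries."""
        stream = self._stream(cvep_codes, [0, 5, 3, 7], snr=-5.0, seed=91)
        cfg = v.DecoderConfig(
            n_y_min=270, n_y_max=1260, cycle_samples=630, block_samples=30, beta=0.25
        )
        decisions, log = v.run_online(stream, cvep_bank, cfg)
        attempts = [r for r in log if "n_y" in r]
        assert attempts, "no classification attempts logged"
        for rec in attempts:
            assert cfg.n_y_min <= rec["n_y"] <= cfg.n_y_max
            assert rec["window_start"] % cfg.cycle_samples == 0
            if rec["accepted"]:
                assert rec["delta"] >= cfg.beta

    def test_raising_beta_never_increases_acceptances(self, cvep_codes, cvep_bank):
        """Monotone gate on a replayed stream: acceptance count is
        non-increasing in beta and commonly-accepted targets keep their
        class."""
        targets = [2, 6, 1, 4]
        counts = {}
        classes = {}
        for beta in (0.0, 0.15, 0.4, 0.8):
            stream = self._stream(cvep_codes, targets, snr=0.0, seed=77, max_s_per_target=4.0)
            cfg = v.DecoderConfig(
                n_y_min=270, n_y_max=630, cycle_samples=630, block_samples=30, beta=beta
            )
            decisions, _ = v.run_online(stream, cvep_bank, cfg)
            counts[beta] = len(decisions)
            classes[beta] = [d.C for d in decisions]
        betas = sorted(counts)
        assert all(counts[b1] >= counts[b2] for b1, b2 in zip(betas, betas[1:]))
        for b1, b2 in zip(betas, betas[1:]):
            n = min(counts[b1], counts[b2])
            assert classes[b1][:n] == classes[b2][:n]

    def test_max_wait_abort_marks_rejection(self, cvep_codes, cvep_bank):
        stream = self._stream(cvep_codes, [3], snr=-40.0, seed=13, max_s_per_target=6.0)
        cfg = v.DecoderConfig(
            n_y_min=270,
            n_y_max=630,
            cycle_samples=630,
            block_samples=30,
            beta=0.9,
            max_wait_s=2.0,
        )
        decisions, log = v.run_online(stream, cvep_bank, cfg)
        assert decisions == []
        assert any(rec.get("reason") == "max_wait" for rec in log)


class TestReferenceModes:
    def test_full_mode_uses_template_slices(self, cvep_bank):
        refs = _projected_references(cvep_bank, 630, template_filtering="full")
        expected = cvep_bank.weights[0] @ cvep_bank.templates[0][2][:, :630]
        np.testing.assert_allclose(refs[0][2], expected, atol=1e-12)

    def test_modes_converge_for_long_windows(self, cvep_session, cvep_bank):
        trial = cvep_session.trials[0][:, :1890]
        d_window = v.classify_window(trial, cvep_bank, template_filtering="window")
        d_full = v.classify_window(trial, cvep_bank, template_filtering="full")
        assert d_window.C == d_full.C
        np.testing.assert_allclose(d_window.lam_tilde, d_full.lam_tilde, atol=0.02)
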