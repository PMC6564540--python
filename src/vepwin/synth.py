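"""Seeded synthetic multichannel EEG with code- or frequency-locked responses.

The generator emulates the statistical structure of 16-channel, 600 Hz
occipital recordings during visual stimulation:

* SSVEP trials carry a harmonic sum ``sum_h d^(h-1) sin(2*pi*h*f*t + h*phi)``
  (fundamental plus decaying harmonics) locked to the target's flicker.
* c-VEP trials carry the bipolar (+-1) code drive convolved with a
  gamma-shaped single-flash impulse response (default 80 ms latency,
  60 ms width), so every flash evokes a transient and the lag structure of
  the circularly shifted codes separates the targets.

The evoked component is spread over channels by a fixed occipital-like gain
gradient and scaled against additive noise (white + 1/f, band-limited to the
amplifier's 2-60 Hz analog passband) to a prescribed SNR in dB.  All
randomness flows from one root seed; trial ``i`` draws from substream
``(seed, i)`` so any trial is reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .stimcodes import CodeSet, code_waveform

__all__ = [
    "SimConfig",
    "TrialSet",
    "simulate_trial",
    "simulate_training_session",
    "simulate_online_stream",
    "OnlineStream",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic-EEG generator.

    snr_db is the ratio of total evoked power to total noise power across
    channels, in dB.  ``mixing`` is the per-channel evoked gain vector; the
    default rises linearly towards the last (occipital) channels.
    """

    n_channels: int = 16
    sampling_rate: float = 600.0
    snr_db: float = 0.0
    n_harmonics: int = 3
    harmonic_decay: float = 0.5
    kernel_latency_ms: float = 80.0
    kernel_width_ms: float = 60.0
    kernel_amplitude: float = 1.0
    mixing: np.ndarray | None = None
    noise_white_frac: float = 0.3
    noise_band: tuple = (2.0, 60.0)
    latency_jitter_ms: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if self.mixing is None:
            self.mixing = np.linspace(0.2, 1.0, self.n_channels)
        else:
            self.mixing = np.asarray(self.mixing, dtype=float)
            if self.mixing.shape != (self.n_channels,):
                raise ValueError("mixing must be an n_channels vector")
        if not np.any(self.mixing != 0):
            raise ValueError("mixing must have at least one nonzero entry")


@dataclass
class TrialSet:
    """Labeled multichannel EEG trials grouped in blocks.

    All trials share shape ``(n_channels, n_samples)``; in a balanced
    training design every block contains each class exactly once.
    """

    trials: list
    labels: np.ndarray
    blocks: np.ndarray
    sampling_rate: float
    paradigm: str
    codeset: CodeSet | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.blocks = np.asarray(self.blocks, dtype=int)
        shapes = {t.shape for t in self.trials}
        if len(shapes) > 1:
            raise ValueError("all trials must share the same shape")
        if not (len(self.trials) == self.labels.size == self.blocks.size):
            raise ValueError("trials, labels and blocks must align")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_channels(self) -> int:
        return self.trials[0].shape[0]

    @property
    def n_samples(self) -> int:
        return self.trials[0].shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    @property
    def block_ids(self) -> np.ndarray:
        return np.unique(self.blocks)

    def is_balanced(self) -> bool:
        K = self.classes.size
        for b in self.block_ids:
            lab = np.sort(self.labels[self.blocks == b])
            if lab.size != K or not np.array_equal(lab, self.classes):
                return False
        return True

    def subset(self, mask) -> "TrialSet":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return TrialSet(
            trials=[self.trials[i] for i in idx],
            labels=self.labels[idx],
            blocks=self.blocks[idx],
            sampling_rate=self.sampling_rate,
            paradigm=self.paradigm,
            codeset=self.codeset,
            meta=dict(self.meta),
        )

    def trials_of_class(self, label: int) -> list:
        return [t for t, l in zip(self.trials, self.labels) if l == label]


def _trial_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *[int(k) for k in key]])


def gamma_kernel(config: SimConfig) -> np.ndarray:
    """Gamma-shaped single-flash impulse response sampled at the EEG rate.

    Parameterized by the mode (latency) and FWHM (width) of the bump;
    normalized to unit peak amplitude times ``kernel_amplitude``.
    """
    fs = config.sampling_rate
    mode = config.kernel_latency_ms / 1000.0
    sd = config.kernel_width_ms / 1000.0 / 2.355  # FWHM -> Gaussian-equivalent sd
    theta = (-mode + math.sqrt(mode * mode + 4.0 * sd * sd)) / 2.0
    a = mode / theta + 1.0
    t = np.arange(0.0, mode + 6.0 * sd, 1.0 / fs)
    k = spstats.gamma.pdf(t, a, scale=theta)
    return config.kernel_amplitude * k / k.max()


def evoked_waveform(
    codeset: CodeSet,
    target: int,
    n_samples: int,
    config: SimConfig,
    jitter_s: float = 0.0,
) -> np.ndarray:
    """Noise-free single-channel evoked response, phase-locked to
    stimulation onset (sample 0)."""
    fs = config.sampling_rate
    if codeset.paradigm == "cvep":
        drive = 2.0 * code_waveform(codeset, target, fs, n_samples / fs) - 1.0
        ev = np.convolve(drive, gamma_kernel(config))[:n_samples]
        j = int(round(jitter_s * fs))
        if j > 0:
            ev = np.concatenate([np.zeros(j), ev])[:n_samples]
        elif j < 0:
            ev = np.concatenate([ev[-j:], np.zeros(-j)])
    elif codeset.paradigm == "ssvep":
        f, phi = codeset.freq_phase[target]
        t = np.arange(n_samples) / fs + jitter_s
        ev = np.zeros(n_samples)
        for h in range(1, config.n_harmonics + 1):
            amp = config.harmonic_decay ** (h - 1)
            ev += amp * np.sin(2.0 * np.pi * h * f * t + h * phi)
    else:
        raise ValueError(f"unknown paradigm {codeset.paradigm!r}")
    return ev


def _noise(m: int, n: int, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Band-limited white + 1/f noise, unit average power per channel."""
    white = rng.standard_normal((m, n))
    pink = rng.standard_normal((m, n))
    spec = np.fft.rfft(pink, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / config.sampling_rate)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    pink = np.fft.irfft(spec * shaping, n=n, axis=1)

    def _unit(x):
        p = np.mean(x * x, axis=1, keepdims=True)
        return x / np.sqrt(np.maximum(p, 1e-30))

    wf = config.noise_white_frac
    mix = math.sqrt(wf) * _unit(white) + math.sqrt(1.0 - wf) * _unit(pink)
    lo, hi = config.noise_band
    nyq = config.sampling_rate / 2.0
    if 0 < lo < hi < nyq:
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=config.sampling_rate, output="sos")
        mix = sps.sosfiltfilt(sos, mix, axis=1)
    return _unit(mix)


def _compose(ev: np.ndarray, noise: np.ndarray, config: SimConfig) -> np.ndarray:
    """Mix a 1-D evoked waveform over channels and scale to snr_db against
    the realized noise power."""
    evm = np.outer(config.mixing, ev)
    p_ev = float(np.mean(evm * evm))
    p_no = float(np.mean(noise * noise))
    if p_ev <= 0:
        return noise.copy()
    scale = math.sqrt(10.0 ** (config.snr_db / 10.0) * p_no / p_ev)
    return scale * evm + noise


def simulate_trial(
    codeset: CodeSet,
    target: int,
    duration: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One seeded EEG trial: channels x samples, evoked + noise at snr_db."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * config.sampling_rate))
    jitter = 0.0
    if config.latency_jitter_ms > 0:
        jitter = rng.normal(0.0, config.latency_jitter_ms / 1000.0)
    ev = evoked_waveform(codeset, target, n, config, jitter_s=jitter)
    noise = _noise(config.n_channels, n, config, rng)
    return _compose(ev, noise, config)


def simulate_training_session(
    codeset: CodeSet,
    n_b: int = 6,
    cycles_per_trial: int = 3,
    config: SimConfig | None = None,
) -> TrialSet:
    """A cue-guided training session: ``n_b`` blocks, each class attended
    once per block in a seeded random order (6 blocks x 8 targets = 48
    trials at defaults; trial length = cycles_per_trial stimulation
    cycles)."""
    if config is None:
        config = SimConfig()
    if n_b < 2:
        raise ValueError("n_b must be >= 2 (leave-one-block-out needs >= 2 blocks)")
    K = codeset.K
    duration = cycles_per_trial * codeset.cycle_duration()
    trials, labels, blocks = [], [], []
    for b in range(n_b):
        order = _trial_rng(config.seed, 0, b).permutation(K)
        for pos, target in enumerate(order):
            rng = _trial_rng(config.seed, 1, b * K + pos)
            trials.append(simulate_trial(codeset, int(target), duration, config, rng))
            labels.append(int(target))
            blocks.append(b)
    return TrialSet(
        trials=trials,
        labels=np.array(labels),
        blocks=np.array(blocks),
        sampling_rate=config.sampling_rate,
        paradigm=codeset.paradigm,
        codeset=codeset,
        meta={"n_b": n_b, "cycles_per_trial": cycles_per_trial, "seed": config.seed},
    )


class OnlineStream:
    """Pull-based amplifier emulation for the online phase.

    Emits ``(block, tag)`` pairs of shape ``(n_channels, block_samples)``
    where tag is ``"stimulation"`` or ``"gaze_shift"``.  For each intended
    target, stimulation blocks (evoked + noise, code phase locked to the
    stimulation onset) are produced until the consumer calls
    :meth:`decision_made`, after which ``gaze_shift_s`` worth of noise-only
    blocks follow and the next target starts with a fresh stimulation phase.
    If a target runs longer than ``max_s_per_target`` without a decision the
    stream force-advances and emits a ``(None, "timeout")`` marker.
    ``boundaries`` records the ground truth per completed target.
    """

    def __init__(
        self,
        codeset: CodeSet,
        intended_targets,
        config: SimConfig | None = None,
        block_samples: int = 30,
        gaze_shift_s: float = 1.0,
        max_s_per_target: float = 12.0,
    ):
        self.codeset = codeset
        self.config = config if config is not None else SimConfig()
        self.targets = [int(t) for t in intended_targets]
        self.n_a = int(block_samples)
        n_c = codeset.cycle_samples(self.config.sampling_rate)
        if n_c % self.n_a != 0:
            raise ValueError(
                f"block_samples {self.n_a} must divide the cycle length {n_c} "
                "(data collection and stimulus presentation stay synchronized)"
            )
        self.n_c = n_c
        self.gaze_blocks = int(round(gaze_shift_s * self.config.sampling_rate / self.n_a))
        self.max_blocks = int(math.floor(max_s_per_target * self.config.sampling_rate / self.n_a))
        self.boundaries: list[dict] = []
        self._ti = -1
        self._mode = "done"
        self._blocks_emitted = 0
        self._gaze_left = 0
        self._data: np.ndarray | None = None
        if self.targets:
            self._enter_target(0)

    # -- internals ---------------------------------------------------------
    def _enter_target(self, idx: int) -> None:
        self._ti = idx
        self._mode = "stim"
        self._blocks_emitted = 0
        cfg = self.config
        n = self.max_blocks * self.n_a
        ev = evoked_waveform(self.codeset, self.targets[idx], n, cfg)
        rng = _trial_rng(cfg.seed, 2, idx)
        noise = _noise(cfg.n_channels, n + self.gaze_blocks * self.n_a, cfg, rng)
        stim = _compose(ev, noise[:, :n], cfg)
        self._data = np.concatenate([stim, noise[:, n:]], axis=1)

    def _advance(self, n_blocks: int, timeout: bool) -> None:
        self.boundaries.append(
            {
                "target": self.targets[self._ti],
                "stim_blocks": n_blocks,
                "timeout": timeout,
            }
        )
        self._gaze_left = 0 if timeout else self.gaze_blocks
        self._mode = "gaze" if self._gaze_left else "next"

    def decision_made(self) -> None:
        """Consumer accepted a decision: stop flickering, start gaze shift."""
        if self._mode == "stim":
            self._advance(self._blocks_emitted, timeout=False)

    def next_block(self):
        """Next amplifier block, or None when the stream is exhausted."""
        while True:
            if self._mode == "done":
                return None
            if self._mode == "next":
                if self._ti + 1 >= len(self.targets):
                    self._mode = "done"
                    return None
                self._enter_target(self._ti + 1)
            if self._mode == "gaze":
                i = self.gaze_blocks - self._gaze_left
                start = self.max_blocks * self.n_a + i * self.n_a
                block = self._data[:, start : start + self.n_a]
                self._gaze_left -= 1
                if self._gaze_left == 0:
                    self._mode = "next"
                return block, "gaze_shift"
            # stimulation
            if self._blocks_emitted >= self.max_blocks:
                self._advance(self._blocks_emitted, timeout=True)
                return None, "timeout"
            start = self._blocks_emitted * self.n_a
            block = self._data[:, start : start + self.n_a]
            self._blocks_emitted += 1
            return block, "stimulation"


def simulate_online_stream(
    codeset: CodeSet,
    intended_targets,
    config: SimConfig | None = None,
    block_samples: int = 30,
    gaze_shift_s: float = 1.0,
    max_s_per_target: float = 12.0,
) -> OnlineStream:
    """Construct an :class:`OnlineStream` for a sequence of intended
    targets (empty sequence -> exhausted stream)."""
    return OnlineStream(
        codeset,
        intended_targets,
        config=config,
        block_samples=block_samples,
        gaze_shift_s=gaze_shift_s,
        max_s_per_target=max_s_per_target,
    )
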