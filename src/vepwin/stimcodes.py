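"""Stimulus modulation sequences for c-VEP and SSVEP flashing patterns.

Both paradigms drive ``K`` on-screen targets arranged on a 2x4 grid.

* c-VEP: every target flashes the same pseudorandom binary m-sequence at
  different circular time lags.  With a 63-bit code at a 60 Hz refresh rate
  the stimulation cycle lasts 63/60 = 1.05 s.  Adjacent targets are lagged
  by 4 bits and codes are assigned row-wise on the grid.
* SSVEP: each target flickers sinusoidally at its own frequency/phase,
  ``c_i(t) = (1 + sin(2*pi*f_i*t/r + phi_i)) / 2`` evaluated per monitor
  frame ``t``.  Frequencies 8..15 Hz in 1 Hz steps give a common 1 s
  repetition period; frequency/phase pairs are assigned column-wise.

Frame sequences can be upsampled to the EEG sampling rate with
:func:`code_waveform` (zero-order hold, since a monitor holds each frame),
which is what the synthetic-EEG generator consumes.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "M_SEQUENCE_63",
    "CodeSet",
    "build_cvep_codes",
    "build_ssvep_codes",
    "cycle_duration",
    "ssvep_sequence",
    "alpha_levels",
    "assign_ssvep_targets",
    "code_waveform",
]

#: 63-bit binary m-sequence used as the base c-VEP code (target 1; further
#: targets are circular shifts of it).
M_SEQUENCE_63 = "101011001101110110100100111000101111001010001100001000001111110"

#: Grid shape of the stimulus matrix (rows, columns).
GRID_SHAPE = (2, 4)


def _row_major_layout(K: int) -> list[tuple[int, int]]:
    ncol = GRID_SHAPE[1]
    return [(i // ncol, i % ncol) for i in range(K)]


def _column_major_layout(K: int) -> list[tuple[int, int]]:
    nrow = GRID_SHAPE[0]
    return [(i % nrow, i // nrow) for i in range(K)]


@dataclass
class CodeSet:
    """Per-target stimulus sequences plus presentation metadata.

    ``sequences`` holds, per target, either a '0'/'1' bitstring (c-VEP) or a
    1-D float array of per-frame values in [0, 1] covering one stimulation
    cycle (SSVEP).  ``cycle_frames`` is the length of one cycle in monitor
    frames: the code length for c-VEP, the refresh rate for SSVEP (1 s
    repetition period).
    """

    paradigm: str  # "cvep" | "ssvep"
    refresh_rate: float
    sequences: list
    cycle_frames: int
    layout: list = field(default_factory=list)
    freq_phase: list | None = None  # per-target (f Hz, phi rad), SSVEP only
    base_code: str | None = None  # c-VEP only
    shift_bits: int | None = None  # c-VEP only
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.paradigm not in ("cvep", "ssvep"):
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if self.paradigm == "cvep":
            lengths = {len(s) for s in self.sequences}
            if len(lengths) != 1:
                raise ValueError("c-VEP sequences must share one length")
            if self.cycle_frames != lengths.pop():
                raise ValueError("cycle_frames must equal the code length")
        else:
            for s in self.sequences:
                arr = np.asarray(s, dtype=float)
                if arr.min() < -1e-12 or arr.max() > 1 + 1e-12:
                    raise ValueError("SSVEP frame values must lie in [0, 1]")
        if not self.layout:
            self.layout = _row_major_layout(self.K)

    @property
    def K(self) -> int:
        return len(self.sequences)

    def cycle_duration(self) -> float:
        """Duration of one stimulation cycle in seconds."""
        return cycle_duration(self.cycle_frames, self.refresh_rate)

    def cycle_samples(self, sampling_rate: float) -> int:
        """Samples per stimulation cycle at the given EEG sampling rate."""
        n = self.cycle_frames * sampling_rate / self.refresh_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                "sampling_rate must yield an integer number of samples per cycle"
            )
        return int(round(n))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "paradigm": self.paradigm,
            "refresh_rate": self.refresh_rate,
            "K": self.K,
            "cycle_frames": self.cycle_frames,
            "layout": [list(rc) for rc in self.layout],
            "meta": self.meta,
        }
        if self.paradigm == "cvep":
            d["base_code"] = self.base_code
            d["shift_bits"] = self.shift_bits
            d["sequences"] = list(self.sequences)
        else:
            d["freq_phase"] = [list(fp) for fp in self.freq_phase]
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "CodeSet":
        if d["paradigm"] == "cvep":
            return cls(
                paradigm="cvep",
                refresh_rate=d["refresh_rate"],
                sequences=list(d["sequences"]),
                cycle_frames=d["cycle_frames"],
                layout=[tuple(rc) for rc in d["layout"]],
                base_code=d.get("base_code"),
                shift_bits=d.get("shift_bits"),
                meta=d.get("meta", {}),
            )
        fp = [tuple(x) for x in d["freq_phase"]]
        r = d["refresh_rate"]
        seqs = [ssvep_sequence(f, phi, r, d["cycle_frames"]) for f, phi in fp]
        return cls(
            paradigm="ssvep",
            refresh_rate=r,
            sequences=seqs,
            cycle_frames=d["cycle_frames"],
            layout=[tuple(rc) for rc in d["layout"]],
            freq_phase=fp,
            meta=d.get("meta", {}),
        )

    @classmethod
    def from_json(cls, path) -> "CodeSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def rotate_left(code: str, k: int) -> str:
    """Circularly shift a bitstring left by ``k`` positions."""
    k = k % len(code)
    return code[k:] + code[:k]


def build_cvep_codes(
    base_code: str = M_SEQUENCE_63,
    K: int = 8,
    shift_bits: int = 4,
    refresh_rate: float = 60.0,
) -> CodeSet:
    """Build the c-VEP code set: target ``i`` is ``base_code`` rotated left
    by ``(i-1)*shift_bits``, assigned row-wise on the 2x4 grid (target 1
    upper-left)."""
    if not base_code or K <= 0:
        raise ValueError("base_code must be non-empty and K positive")
    if set(base_code) - {"0", "1"}:
        raise ValueError("base_code must be a '0'/'1' string")
    seqs = [rotate_left(base_code, i * shift_bits) for i in range(K)]
    return CodeSet(
        paradigm="cvep",
        refresh_rate=refresh_rate,
        sequences=seqs,
        cycle_frames=len(base_code),
        layout=_row_major_layout(K),
        base_code=base_code,
        shift_bits=shift_bits,
    )


def cycle_duration(code_length: int, refresh_rate: float) -> float:
    """Stimulation-cycle duration: code length divided by monitor refresh
    rate (63 frames at 60 Hz -> 1.05 s)."""
    if refresh_rate <= 0:
        raise ValueError("refresh_rate must be positive")
    return code_length / refresh_rate


def ssvep_sequence(f: float, phi: float, refresh_rate: float, n_frames: int) -> np.ndarray:
    """Per-frame SSVEP modulation values ``(1 + sin(2*pi*f*t/r + phi)) / 2``
    for frames ``t = 0..n_frames-1``; values in [0, 1]."""
    if f <= 0:
        raise ValueError("frequency must be positive")
    if f >= refresh_rate / 2:
        warnings.warn(
            f"stimulus frequency {f} Hz at or above Nyquist of the "
            f"{refresh_rate} Hz refresh rate; the rendered flicker aliases",
            stacklevel=2,
        )
    t = np.arange(n_frames, dtype=float)
    return 0.5 * (1.0 + np.sin(2.0 * np.pi * f * t / refresh_rate + phi))


def alpha_levels(values: np.ndarray) -> np.ndarray:
    """Map modulation values in [0, 1] to 8-bit RGBA alpha levels
    (``round(c * 255)``); 0 = fully transparent (black background shows),
    255 = opaque white."""
    return np.rint(np.asarray(values, dtype=float) * 255.0).astype(int)


def assign_ssvep_targets(
    f0: float = 8.0,
    df: float = 1.0,
    phi0: float = 0.0,
    dphi: float = 0.35 * math.pi,
    K: int = 8,
) -> list[tuple[float, float]]:
    """Per-target SSVEP (frequency, phase) pairs, ``f_i = f0 + (i-1)*df`` and
    ``phi_i = phi0 + (i-1)*dphi``, enumerated column-wise on the 2x4 grid
    (column 1 top, column 1 bottom, column 2 top, ...)."""
    if K > GRID_SHAPE[0] * GRID_SHAPE[1]:
        raise ValueError("K exceeds grid capacity")
    return [(f0 + i * df, phi0 + i * dphi) for i in range(K)]


def build_ssvep_codes(
    f0: float = 8.0,
    df: float = 1.0,
    phi0: float = 0.0,
    dphi: float = 0.35 * math.pi,
    K: int = 8,
    refresh_rate: float = 60.0,
) -> CodeSet:
    """Build the SSVEP code set (default 8..15 Hz, 0.35*pi phase steps,
    1 s repetition period ``cycle_frames = refresh_rate``)."""
    fp = assign_ssvep_targets(f0, df, phi0, dphi, K)
    cycle_frames = int(round(refresh_rate))
    seqs = [ssvep_sequence(f, phi, refresh_rate, cycle_frames) for f, phi in fp]
    return CodeSet(
        paradigm="ssvep",
        refresh_rate=refresh_rate,
        sequences=seqs,
        cycle_frames=cycle_frames,
        layout=_column_major_layout(K),
        freq_phase=fp,
        meta={"within_column_order": "top_first"},
    )


def code_waveform(
    codeset: CodeSet, target: int, sampling_rate: float, duration: float
) -> np.ndarray:
    """Per-sample stimulus drive for one target: the frame sequence repeated
    cyclically and upsampled by zero-order hold to ``sampling_rate``.

    ``sampling_rate`` must be an integer multiple of the refresh rate
    (600 Hz = 10 x 60 Hz here).  Returns ``round(duration*sampling_rate)``
    samples with values in [0, 1].
    """
    spf = sampling_rate / codeset.refresh_rate
    if abs(spf - round(spf)) > 1e-9:
        raise ValueError("sampling_rate must be an integer multiple of refresh_rate")
    spf = int(round(spf))
    n_samples = int(round(duration * sampling_rate))
    if n_samples <= 0:
        return np.zeros(0)
    n_frames = math.ceil(n_samples / spf)
    if codeset.paradigm == "cvep":
        bits = np.array([1.0 if b == "1" else 0.0 for b in codeset.sequences[target]])
        reps = math.ceil(n_frames / bits.size)
        frames = np.tile(bits, reps)[:n_frames]
    else:
        f, phi = codeset.freq_phase[target]
        frames = ssvep_sequence(f, phi, codeset.refresh_rate, n_frames)
    return np.repeat(frames, spf)[:n_samples]
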