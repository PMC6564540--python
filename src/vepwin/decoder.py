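"""Online ensemble classification over a dynamically growing time window.

The amplifier delivers EEG in blocks of ``n_a`` samples which are
accumulated in a buffer.  Three regimes govern classification:

1. buffer shorter than ``n_y_min``  -> no classification;
2. ``n_y_min <= buffer <= n_y_max`` -> classify the whole buffer;
3. buffer longer than ``n_y_max``   -> discard whole stimulation cycles
   (``n_c`` samples) from the front so the window stays within the bounds
   and code phase / data remain synchronized.

Each window is compared against the first ``n_y`` columns of every class
template via the ensemble correlation: the window and the reference are
projected through *all* K spatial filters, the K projections are stacked
into one long vector each, and their Pearson correlation is taken.  With a
filter bank, per-band correlations are combined with decreasing weights
``a_m``.  The winning class is output only once the decision certainty
``Delta_C`` (highest minus second-highest combined correlation) reaches the
threshold ``beta``; otherwise the window keeps growing with the next block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .spatial import TemplateBank, subband_filter

__all__ = [
    "DecoderConfig",
    "Decision",
    "BlockBuffer",
    "reference_window",
    "ensemble_correlation",
    "classify_window",
    "step_buffer",
    "run_online",
]


@dataclass
class DecoderConfig:
    """Runtime parameters of the dynamic-window decoder.

    ``block_samples`` (n_a) must divide ``cycle_samples`` (n_c) and
    ``n_y_max`` must be a multiple of n_c so that front-trimming whole
    cycles keeps stimulus and data synchronized.
    """

    n_y_min: int
    n_y_max: int
    cycle_samples: int
    block_samples: int = 30
    beta: float = 0.0
    gaze_shift_s: float = 1.0
    max_wait_s: float | None = None

    def __post_init__(self) -> None:
        if self.cycle_samples % self.block_samples != 0:
            raise ValueError("block_samples must divide cycle_samples (n_a | n_c)")
        if self.n_y_min > self.n_y_max:
            raise ValueError("n_y_min must not exceed n_y_max")
        if self.n_y_max % self.cycle_samples != 0:
            raise ValueError("n_y_max must be a multiple of the cycle length n_c")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass
class Decision:
    """Outcome of one classification attempt.

    ``accepted`` is true iff the window satisfied the length gate
    (n_y >= n_y_min) and the certainty gate (Delta_C >= beta).
    """

    C: int
    delta: float
    lam_tilde: np.ndarray
    n_y_used: int
    accepted: bool
    elapsed_blocks: int = 0
    window_start: int = 0

    def to_record(self) -> dict:
        return {
            "t_blocks": int(self.elapsed_blocks),
            "n_y": int(self.n_y_used),
            "window_start": int(self.window_start),
            "lam_tilde": [round(float(v), 12) for v in self.lam_tilde],
            "C": int(self.C),
            "delta": round(float(self.delta), 12),
            "accepted": bool(self.accepted),
        }


def reference_window(template: np.ndarray, n_y: int) -> np.ndarray:
    """Reference for a window of n_y samples: the first n_y columns of the
    class template (both are locked to stimulation onset)."""
    if n_y > template.shape[1]:
        raise ValueError("n_y exceeds the template length")
    return template[:, :n_y]


def ensemble_correlation(Y: np.ndarray, R_k: np.ndarray, weights: np.ndarray) -> float:
    """Ensemble correlation lambda_k: Pearson correlation between the
    stacked projections ``[Y^T w_1; ...; Y^T w_K]`` and
    ``[R_k^T w_1; ...; R_k^T w_K]``.

    ``weights`` stacks the K spatial filters as rows (K, m).  A
    zero-variance stack yields 0 with a warning.
    """
    weights = np.atleast_2d(weights)
    x = (weights @ Y).ravel()
    y = (weights @ R_k).ravel()
    return _pearson(x, y)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        warnings.warn("zero-variance stacked vector; correlation set to 0", stacklevel=2)
        return 0.0
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


def _band_correlations(Yb: np.ndarray, proj_templates: np.ndarray, W: np.ndarray) -> np.ndarray:
    """lambda_k for all K classes in one band, vectorized.

    ``proj_templates`` is (K_classes, K_filters, n_t): templates already
    projected through all spatial filters.
    """
    n_y = Yb.shape[1]
    x = (W @ Yb).ravel()
    xc = x - x.mean()
    nx = np.linalg.norm(xc)
    refs = proj_templates[:, :, :n_y].reshape(proj_templates.shape[0], -1)
    rc = refs - refs.mean(axis=1, keepdims=True)
    nr = np.linalg.norm(rc, axis=1)
    lam = np.zeros(refs.shape[0])
    ok = (nx > 0) & (nr > 0)
    if nx == 0 or not np.all(nr > 0):
        warnings.warn("zero-variance stacked vector; correlation set to 0", stacklevel=2)
    if nx > 0:
        lam[ok] = rc[ok] @ xc / (nr[ok] * nx)
    return np.clip(lam, -1.0, 1.0)


def _projected_references(
    bank: TemplateBank,
    n_y: int,
    template_filtering: str = "window",
    cache: dict | None = None,
) -> list[np.ndarray]:
    """Per band: (K, K, n_y) array of all class references projected through
    all spatial filters.

    ``template_filtering="window"`` (default) band-filters the truncated raw
    template with the identical in-window zero-phase filter the data window
    receives, so both carry the same edge transients; ``"full"`` slices the
    full-length band-filtered template (the literal reference-window rule).
    """
    out = []
    for b, band in enumerate(bank.bands):
        key = (b, n_y, template_filtering)
        if cache is not None and key in cache:
            out.append(cache[key])
            continue
        W = bank.weights[b]
        if template_filtering == "window":
            if bank.raw_templates is None:
                raise ValueError("bank lacks raw templates; use template_filtering='full'")
            stacked = np.concatenate([t[:, :n_y] for t in bank.raw_templates], axis=0)
            filt = subband_filter(stacked, band, bank.sampling_rate)
            m = bank.n_channels
            refs = np.stack([W @ filt[k * m : (k + 1) * m] for k in range(bank.K)])
        elif template_filtering == "full":
            refs = np.stack([W @ bank.templates[b][k][:, :n_y] for k in range(bank.K)])
        else:
            raise ValueError("template_filtering must be 'window' or 'full'")
        if cache is not None:
            cache[key] = refs
        out.append(refs)
    return out


def classify_window(
    Y: np.ndarray,
    bank: TemplateBank,
    config: DecoderConfig | None = None,
    template_filtering: str = "window",
    _ref_cache: dict | None = None,
) -> Decision:
    """Classify one window: per-band ensemble correlations combined with the
    sub-band weights; ``C`` is the argmax (ties -> lowest class index) and
    ``Delta_C`` the gap to the runner-up.

    The returned ``accepted`` flag reflects only the certainty gate
    ``Delta_C >= beta``; the window-length gate is applied by
    :func:`step_buffer`.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.shape[0] != bank.n_channels:
        raise ValueError("channel count of window and bank differ")
    n_y = Y.shape[1]
    if n_y > bank.n_t:
        raise ValueError("window longer than the stored templates")
    proj = _projected_references(bank, n_y, template_filtering, cache=_ref_cache)
    lam_tilde = np.zeros(bank.K)
    for b, band in enumerate(bank.bands):
        Yb = subband_filter(Y, band, bank.sampling_rate)
        lam_tilde += bank.a[b] * _band_correlations(Yb, proj[b], bank.weights[b])
    order = np.argsort(-lam_tilde, kind="stable")
    C = int(order[0])
    delta = float(lam_tilde[order[0]] - lam_tilde[order[1]]) if bank.K > 1 else 2.0
    beta = config.beta if config is not None else 0.0
    return Decision(
        C=C,
        delta=delta,
        lam_tilde=lam_tilde,
        n_y_used=n_y,
        accepted=bool(delta >= beta),
    )


class BlockBuffer:
    """Accumulates amplifier blocks of the current selection."""

    def __init__(self) -> None:
        self._blocks: list[np.ndarray] = []
        self.n = 0

    def append(self, block: np.ndarray) -> None:
        self._blocks.append(np.asarray(block, dtype=float))
        self.n += block.shape[1]

    def data(self) -> np.ndarray:
        return np.concatenate(self._blocks, axis=1)

    def clear(self) -> None:
        self._blocks = []
        self.n = 0


def step_buffer(
    buffer: BlockBuffer,
    block: np.ndarray,
    bank: TemplateBank,
    config: DecoderConfig,
    template_filtering: str = "window",
    _ref_cache: dict | None = None,
) -> Decision | None:
    """Append one amplifier block and, when the buffered window allows,
    classify it.

    Returns the classification attempt (a :class:`Decision`, accepted or
    not) or None when no classification was performed.  When the buffer
    exceeds ``n_y_max``, whole cycles are dropped from the front; if the
    remaining trailing window is still shorter than ``n_y_min`` no
    classification is attempted (the window regrows from the last cycle
    boundary).
    """
    block = np.asarray(block, dtype=float)
    if block.shape[1] != config.block_samples:
        raise ValueError("block width differs from config.block_samples")
    buffer.append(block)
    n_hat = buffer.n
    if n_hat < config.n_y_min:
        return None
    if n_hat <= config.n_y_max:
        start = 0
    else:
        # smallest k with n_hat - k*n_c <= n_y_max
        k = -(-(n_hat - config.n_y_max) // config.cycle_samples)
        start = k * config.cycle_samples
        if n_hat - start < config.n_y_min:
            return None
    Y = buffer.data()[:, start:]
    decision = classify_window(
        Y, bank, config, template_filtering=template_filtering, _ref_cache=_ref_cache
    )
    decision.window_start = start
    decision.accepted = bool(
        decision.n_y_used >= config.n_y_min and decision.delta >= config.beta
    )
    return decision


def run_online(stream, bank: TemplateBank, config: DecoderConfig):
    """Consume an online stream block-by-block through the dynamic window.

    On an accepted decision the buffer is cleared, the stream is told to
    stop flickering (it then emits gaze-shift blocks, which are ignored) and
    the stimulation phase resets with the next target.  A stream-side
    timeout, or an optional ``max_wait_s`` horizon, aborts the current
    selection with a rejected marker.

    Returns ``(decisions, log)``: the accepted decisions in order and a
    JSON-serializable event log with one record per classification attempt.
    """
    buffer = BlockBuffer()
    ref_cache: dict = {}
    decisions: list[Decision] = []
    log: list[dict] = []
    t_blocks = 0
    blocks_this_selection = 0
    max_wait_blocks = None
    if config.max_wait_s is not None:
        max_wait_blocks = int(config.max_wait_s * bank.sampling_rate / config.block_samples)
    while True:
        item = stream.next_block()
        if item is None:
            break
        block, tag = item
        t_blocks += 1
        if tag == "gaze_shift":
            continue
        if tag == "timeout":
            buffer.clear()
            blocks_this_selection = 0
            log.append({"t_blocks": t_blocks, "accepted": False, "reason": "stream_timeout"})
            continue
        blocks_this_selection += 1
        decision = step_buffer(buffer, block, bank, config, _ref_cache=ref_cache)
        if decision is not None:
            decision.elapsed_blocks = blocks_this_selection
            rec = decision.to_record()
            rec["reason"] = "accepted" if decision.accepted else "below_threshold"
            log.append(rec)
            if decision.accepted:
                decisions.append(decision)
                buffer.clear()
                blocks_this_selection = 0
                stream.decision_made()
                continue
        if max_wait_blocks is not None and blocks_this_selection >= max_wait_blocks:
            buffer.clear()
            blocks_this_selection = 0
            log.append({"t_blocks": t_blocks, "accepted": False, "reason": "max_wait"})
            stream.decision_made()
    return decisions, log
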