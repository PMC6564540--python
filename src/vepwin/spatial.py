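"""CCA spatial filters, per-class templates and filter-bank decomposition.

Training trials of one class are averaged into a template ``X`` (m x n_t).
A class-specific spatial filter ``w`` is the template-side canonical weight
of a CCA between the horizontal concatenation of all trials,
``T_hat = [T_1 ... T_nb]``, and the template replicated to the same width,
``X_hat = [X ... X]``; projecting EEG through ``w`` maximizes the
correlation between single trials and the class template.

For the filter-bank variant the trials are decomposed into sub-bands with
zero-phase Butterworth band-passes (sub-band m spans m*8 to 60 Hz) before
templates and filters are built, and per-band correlations are later
combined with the decreasing weights ``a_m`` of :func:`subband_weights`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg as spla
from scipy import signal as sps

__all__ = [
    "cca",
    "build_template",
    "build_spatial_filter",
    "subband_filter",
    "subband_weights",
    "subband_spec",
    "train_bank",
    "TemplateBank",
]

#: Ridge added to auto-covariances, as a fraction of their average diagonal.
CCA_RIDGE = 1e-8

#: Butterworth order of the sub-band filters.
FILTER_ORDER = 8


def _center(X: np.ndarray) -> np.ndarray:
    return X - X.mean(axis=1, keepdims=True)


def _inv_sqrt(C: np.ndarray, ridge: float) -> tuple[np.ndarray, bool]:
    p = C.shape[0]
    vals, vecs = spla.eigh(C)
    tol = max(vals.max(), 0.0) * p * np.finfo(float).eps
    deficient = bool(np.any(vals <= tol))  # judged before regularization
    vals = vals + ridge * (np.trace(C) / p)
    vals = np.maximum(vals, max(tol, np.finfo(float).tiny))
    return vecs @ np.diag(1.0 / np.sqrt(vals)) @ vecs.T, deficient


def cca(X: np.ndarray, Y: np.ndarray):
    """Canonical correlation analysis between row-variable matrices.

    Parameters
    ----------
    X, Y : arrays of shape (p, s) and (q, s)
        Two multichannel signals observed over the same ``s`` samples; rows
        are variables (channels) and are centered internally.

    Returns
    -------
    rho : (d,) canonical correlations, descending, d = min(p, q)
    w_x : (p, d) X-side weight vectors (columns)
    w_y : (q, d) Y-side weight vectors (columns)

    Solved by whitening both auto-covariances and taking the SVD of the
    whitened cross-covariance; a small ridge keeps rank-deficient inputs
    solvable (with a warning).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must be 2-D with a common sample axis")
    p, s = X.shape
    q = Y.shape[0]
    if s <= max(p, q):
        raise ValueError("need more samples than variables for CCA")
    Xc, Yc = _center(X), _center(Y)
    Cxx = Xc @ Xc.T / (s - 1)
    Cyy = Yc @ Yc.T / (s - 1)
    Cxy = Xc @ Yc.T / (s - 1)
    Kx, dx = _inv_sqrt(Cxx, CCA_RIDGE)
    Ky, dy = _inv_sqrt(Cyy, CCA_RIDGE)
    if dx or dy:
        warnings.warn("rank-deficient covariance in CCA; ridge-regularized solve", stacklevel=2)
    U, svals, Vt = spla.svd(Kx @ Cxy @ Ky.T, full_matrices=False)
    d = min(p, q)
    rho = np.clip(svals[:d], 0.0, 1.0)
    w_x = Kx.T @ U[:, :d]
    w_y = Ky.T @ Vt.T[:, :d]
    return rho, w_x, w_y


def build_template(trials) -> np.ndarray:
    """Element-wise arithmetic mean of same-shape trials of one class."""
    trials = [np.asarray(t, dtype=float) for t in trials]
    if not trials:
        raise ValueError("need at least one trial")
    if len({t.shape for t in trials}) > 1:
        raise ValueError("trial shapes differ")
    return np.mean(np.stack(trials), axis=0)


def build_spatial_filter(trials, template: np.ndarray) -> np.ndarray:
    """Class-specific spatial filter: first template-side CCA weight of
    ``cca(T_hat, X_hat)`` with all trials concatenated horizontally and the
    template replicated to match.

    The returned weight has unit Euclidean norm and a deterministic sign
    (its largest-magnitude coefficient is positive).
    """
    trials = [np.asarray(t, dtype=float) for t in trials]
    if len(trials) < 2:
        raise ValueError("need at least two trials")
    T_hat = np.concatenate(trials, axis=1)
    X_hat = np.tile(template, (1, len(trials)))
    _, _, w_xhat = cca(T_hat, X_hat)
    w = w_xhat[:, 0]
    w = w / np.linalg.norm(w)
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
    return w


def subband_filter(
    x: np.ndarray, band: tuple, sampling_rate: float, order: int = FILTER_ORDER
) -> np.ndarray:
    """Zero-phase band-pass (forward-reverse Butterworth) along the sample
    axis; output length equals input length.

    Reflection padding shrinks automatically for windows shorter than the
    default pad so that even the smallest classification windows pass
    through the same filter bank as the templates.
    """
    x = np.asarray(x, dtype=float)
    low, high = band
    nyq = sampling_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"invalid band {band} at sampling rate {sampling_rate}")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=sampling_rate, output="sos")
    n = x.shape[-1]
    default_pad = 3 * (2 * sos.shape[0] + 1)
    padlen = min(default_pad, n - 1)
    if padlen < 1:
        raise ValueError("signal too short to filter")
    return sps.sosfiltfilt(sos, x, axis=-1, padlen=padlen)


def subband_weights(M: int) -> np.ndarray:
    """Sub-band combination weights ``a_m``: ``a'_m = m**-1.25 + 0.25``
    normalized to sum to one; strictly decreasing over bands."""
    if M < 1:
        raise ValueError("M must be >= 1")
    m = np.arange(1, M + 1, dtype=float)
    a_prime = m ** -1.25 + 0.25
    return a_prime / a_prime.sum()


def subband_spec(M: int, high: float = 60.0, step: float = 8.0) -> list[tuple[float, float]]:
    """Cut-off frequencies of the M sub-bands: band m spans m*step to high Hz."""
    bands = [(step * m, high) for m in range(1, M + 1)]
    if bands[-1][0] >= high:
        raise ValueError("too many sub-bands for the upper cut-off")
    return bands


@dataclass
class TemplateBank:
    """Per-class, per-sub-band templates and spatial filters.

    ``templates[b][k]`` is the m x n_t class-k template in sub-band b;
    ``weights[b]`` stacks the K unit-norm spatial filters as a (K, m) array.
    ``a`` holds the sub-band combination weights (sums to 1).
    ``raw_templates[k]`` keeps the unfiltered class means so classification
    can band-filter a truncated reference with exactly the same in-window
    zero-phase filter as the data window (matched edge transients).
    """

    templates: list  # M x K list of (m, n_t) arrays
    weights: list  # M list of (K, m) arrays
    bands: list  # M (low, high) tuples
    a: np.ndarray
    sampling_rate: float
    raw_templates: list = None  # K list of (m, n_t) arrays
    paradigm: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def M(self) -> int:
        return len(self.templates)

    @property
    def K(self) -> int:
        return len(self.templates[0])

    @property
    def n_channels(self) -> int:
        return self.templates[0][0].shape[0]

    @property
    def n_t(self) -> int:
        return self.templates[0][0].shape[1]

    # -- persistence (JSON manifest + per-class/band TSV matrices) --------
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        manifest = {
            "K": self.K,
            "M": self.M,
            "bands": [list(b) for b in self.bands],
            "a": self.a.tolist(),
            "n_t": self.n_t,
            "n_channels": self.n_channels,
            "sampling_rate": self.sampling_rate,
            "paradigm": self.paradigm,
            "meta": self.meta,
        }
        with open(d / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        for b in range(self.M):
            np.savetxt(d / f"weights_band{b}.tsv", self.weights[b], delimiter="\t")
            for k in range(self.K):
                np.savetxt(
                    d / f"template_band{b}_class{k}.tsv",
                    self.templates[b][k],
                    delimiter="\t",
                )
        if self.raw_templates is not None:
            for k in range(self.K):
                np.savetxt(
                    d / f"template_raw_class{k}.tsv", self.raw_templates[k], delimiter="\t"
                )

    @classmethod
    def load(cls, directory) -> "TemplateBank":
        d = Path(directory)
        with open(d / "manifest.json") as fh:
            manifest = json.load(fh)
        M, K = manifest["M"], manifest["K"]
        templates, weights = [], []
        for b in range(M):
            weights.append(np.loadtxt(d / f"weights_band{b}.tsv", delimiter="\t", ndmin=2))
            templates.append(
                [
                    np.loadtxt(d / f"template_band{b}_class{k}.tsv", delimiter="\t", ndmin=2)
                    for k in range(K)
                ]
            )
        raw = None
        if (d / "template_raw_class0.tsv").exists():
            raw = [
                np.loadtxt(d / f"template_raw_class{k}.tsv", delimiter="\t", ndmin=2)
                for k in range(K)
            ]
        return cls(
            templates=templates,
            weights=weights,
            bands=[tuple(b) for b in manifest["bands"]],
            a=np.asarray(manifest["a"]),
            sampling_rate=manifest["sampling_rate"],
            raw_templates=raw,
            paradigm=manifest.get("paradigm", ""),
            meta=manifest.get("meta", {}),
        )


def train_bank(trainset, M: int = 1, high: float = 60.0) -> TemplateBank:
    """Build a :class:`TemplateBank` from a balanced training session.

    For every sub-band the trials are band-filtered first, then per class a
    template (trial mean) and a CCA spatial filter are constructed, so
    templates and online windows are filtered symmetrically.
    """
    if not trainset.is_balanced():
        raise ValueError("training set must contain every class once per block")
    bands = subband_spec(M, high=high)
    classes = trainset.classes
    raw_templates = [
        build_template(trainset.trials_of_class(int(k))) for k in classes
    ]
    templates, weights = [], []
    for band in bands:
        t_band, w_band = [], []
        filtered = [subband_filter(t, band, trainset.sampling_rate) for t in trainset.trials]
        for k in classes:
            cls_trials = [f for f, l in zip(filtered, trainset.labels) if l == k]
            X = build_template(cls_trials)
            w = build_spatial_filter(cls_trials, X)
            t_band.append(X)
            w_band.append(w)
        templates.append(t_band)
        weights.append(np.stack(w_band))
    return TemplateBank(
        templates=templates,
        weights=weights,
        bands=bands,
        a=subband_weights(M),
        sampling_rate=trainset.sampling_rate,
        raw_templates=raw_templates,
        paradigm=trainset.paradigm,
        meta={"classes": [int(k) for k in classes]},
    )
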