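"""Model/results interface for the dynamic-window VEP decoder.

:class:`DynamicWindowDecoder` is constructed from a labeled training
session (a :class:`~vepwin.synth.TrialSet`); :meth:`fit` trains the
CCA-template bank, runs the leave-one-block-out calibration and returns a
:class:`DynamicWindowResults` carrying the estimated parameters
(``n_y_min``, ``beta``), the accuracy/ITR curves, a ``summary()`` table and
convenience methods for online decoding and plotting.
"""

from __future__ import annotations

import numpy as np

from .calibration import CalibrationResult, itr, loo_curves, select_parameters, selection_time
from .decoder import DecoderConfig, run_online
from .spatial import TemplateBank, train_bank
from .synth import TrialSet

__all__ = ["DynamicWindowDecoder", "DynamicWindowResults"]

_DEFAULT_SUBBANDS = {"cvep": 1, "ssvep": 5}


class DynamicWindowDecoder:
    """Threshold-gated dynamic-window decoder fitted to a training session.

    Parameters
    ----------
    trainset : TrialSet
        Balanced training trials (every class once per block).
    n_subbands : int, optional
        Filter-bank size; defaults to 1 for c-VEP and 5 for SSVEP.
    grid_step : int
        Window-grid step in samples for the calibration curves.
    gaze_shift_s : float
        Stimulation pause after each output command, included in the
        selection time of the ITR.
    cv : {"block", "trial"}
        Leave-one-block-out (default) or leave-one-trial-out calibration.
    """

    def __init__(
        self,
        trainset: TrialSet,
        n_subbands: int | None = None,
        grid_step: int = 30,
        grid=None,
        gaze_shift_s: float = 1.0,
        cv: str = "block",
    ):
        if n_subbands is None:
            n_subbands = _DEFAULT_SUBBANDS.get(trainset.paradigm, 1)
        self.trainset = trainset
        self.n_subbands = int(n_subbands)
        self.grid_step = int(grid_step)
        self.grid = grid
        self.gaze_shift_s = float(gaze_shift_s)
        self.cv = cv

    @classmethod
    def from_simulation(
        cls, codeset, sim_config=None, n_b: int = 6, cycles_per_trial: int = 3, **kwargs
    ) -> "DynamicWindowDecoder":
        """Build the model directly from a simulated training session."""
        from .synth import simulate_training_session

        trainset = simulate_training_session(
            codeset, n_b=n_b, cycles_per_trial=cycles_per_trial, config=sim_config
        )
        return cls(trainset, **kwargs)

    def fit(self) -> "DynamicWindowResults":
        """Train the template bank on all blocks and calibrate
        (n_y_min, beta) by cross-validated ITR maximization."""
        bank = train_bank(self.trainset, self.n_subbands)
        curves = loo_curves(
            self.trainset,
            M=self.n_subbands,
            grid=self.grid,
            grid_step=self.grid_step,
            gaze_shift_s=self.gaze_shift_s,
            mode=self.cv,
        )
        n_y_min, beta = select_parameters(curves)
        return DynamicWindowResults(self, bank, curves, n_y_min, beta)


class DynamicWindowResults:
    """Fitted decoder: template bank, calibration curves and the selected
    runtime parameters."""

    def __init__(
        self,
        model: DynamicWindowDecoder,
        bank: TemplateBank,
        calibration: CalibrationResult,
        n_y_min: int,
        beta: float,
    ):
        self.model = model
        self.bank = bank
        self.calibration = calibration
        self.n_y_min = int(n_y_min)
        self.beta = float(beta)

    @property
    def cycle_samples(self) -> int:
        cs = self.model.trainset.codeset
        if cs is not None:
            return cs.cycle_samples(self.bank.sampling_rate)
        # fall back: training trials hold an integer number of cycles
        return self.model.trainset.n_samples // self.model.trainset.meta.get(
            "cycles_per_trial", 3
        )

    @property
    def max_itr(self) -> float:
        return float(np.max(self.calibration.itr_curve))

    def decoder_config(
        self, n_y_max: int | None = None, beta: float | None = None, **kwargs
    ) -> DecoderConfig:
        """Runtime configuration with the calibrated parameters; ``beta``
        may be overridden manually (e.g. lowered for responsiveness)."""
        n_c = self.cycle_samples
        if n_y_max is None:
            n_y_max = 2 * n_c
        return DecoderConfig(
            n_y_min=self.n_y_min,
            n_y_max=int(n_y_max),
            cycle_samples=n_c,
            beta=self.beta if beta is None else float(beta),
            gaze_shift_s=self.model.gaze_shift_s,
            **kwargs,
        )

    def run_online(self, stream, config: DecoderConfig | None = None):
        """Decode an online stream with the calibrated parameters."""
        if config is None:
            config = self.decoder_config(block_samples=getattr(stream, "n_a", 30))
        return run_online(stream, self.bank, config)

    def summary(self) -> str:
        c = self.calibration
        j = int(np.argmax(c.itr_curve))
        fs = c.sampling_rate
        lines = [
            "        Dynamic-window VEP decoder",
            "=" * 50,
            f"paradigm:            {self.model.trainset.paradigm}",
            f"trials / blocks:     {self.model.trainset.n_trials} / "
            f"{self.model.trainset.block_ids.size}",
            f"channels:            {self.model.trainset.n_channels}",
            f"sub-bands (M):       {self.bank.M}",
            f"window grid:         {c.window_grid[0]}..{c.window_grid[-1]} samples "
            f"(step {c.window_grid[1] - c.window_grid[0] if c.window_grid.size > 1 else 0})",
            "-" * 50,
            f"n_y_min (selected):  {self.n_y_min} samples = {self.n_y_min / fs:.2f} s",
            f"beta (selected):     {self.beta:.4f}",
            f"LOO accuracy there:  {c.accuracy_curve[j]:.3f}",
            f"max LOO ITR:         {c.itr_curve[j]:.2f} bits/min "
            f"(t = {selection_time(self.n_y_min, fs, c.gaze_shift_s):.2f} s/selection)",
            "=" * 50,
        ]
        return "\n".join(lines)

    def plot_calibration(self, ax=None):
        """Accuracy and ITR curves over the window grid with the selected
        minimum window marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.calibration
        t = c.window_grid / c.sampling_rate
        ax.plot(t, c.itr_curve, label="ITR [bits/min]")
        ax.set_xlabel("classification window [s]")
        ax.set_ylabel("ITR [bits/min]")
        ax2 = ax.twinx()
        ax2.plot(t, c.accuracy_curve, color="tab:green", label="accuracy")
        ax2.set_ylabel("accuracy")
        ax2.set_ylim(0, 1.05)
        ax.axvline(self.n_y_min / c.sampling_rate, color="tab:red", ls="--", label="n_y_min")
        ax.legend(loc="lower right")
        return ax
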