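"""End-to-end experiment orchestration shared by the CLI and tests.

Each step reads its inputs from the run directory, writes its artifact
there and updates ``manifest.json`` with the configuration hash and seed so
a run is bit-reproducible from its manifest.  Missing upstream artifacts
raise actionable errors naming the producing step.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np

from .calibration import CalibrationResult, calibrate, itr
from .config import RunConfig
from .decoder import DecoderConfig, run_online
from .io import (
    load_trialset_hdf5,
    load_trialset_tsv,
    save_trialset_hdf5,
    save_trialset_tsv,
    write_jsonl,
)
from .spatial import TemplateBank, train_bank
from .speller import Lexicon, load_fixture_lexicon, simulate_copy_spelling
from .stimcodes import CodeSet
from .synth import OnlineStream, simulate_training_session

__all__ = [
    "run_codes",
    "run_simulate",
    "run_train",
    "run_calibrate",
    "run_decode",
    "run_spell",
]


def _update_manifest(cfg: RunConfig, out: Path, step: str, artifact: str) -> None:
    path = out / "manifest.json"
    manifest = {"config_digest": cfg.digest(), "seed": cfg.seed, "steps": {}}
    if path.exists():
        with open(path) as fh:
            manifest = json.load(fh)
        manifest["config_digest"] = cfg.digest()
        manifest["seed"] = cfg.seed
    manifest.setdefault("steps", {})[step] = artifact
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def _require(path: Path, producer: str):
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path.name!r}; run the '{producer}' step first"
        )
    return path


def run_codes(cfg: RunConfig, out) -> Path:
    """Emit the stimulus code set as JSON."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "codes.json"
    cfg.codeset().to_json(path)
    _update_manifest(cfg, out, "codes", path.name)
    return path


def run_simulate(cfg: RunConfig, out, fmt: str = "tsv") -> Path:
    """Simulate and store a training session (text or HDF5 dialect)."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    ts = simulate_training_session(
        cfg.codeset(),
        n_b=cfg.n_blocks,
        cycles_per_trial=cfg.cycles_per_trial,
        config=cfg.sim_config(),
    )
    if fmt == "tsv":
        path = out / "trials"
        save_trialset_tsv(ts, path)
    elif fmt == "h5":
        path = out / "trials.h5"
        save_trialset_hdf5(ts, path)
    else:
        raise ValueError("fmt must be 'tsv' or 'h5'")
    _update_manifest(cfg, out, "simulate", path.name)
    return path


def _load_trials(out: Path):
    if (out / "trials").exists():
        return load_trialset_tsv(out / "trials")
    if (out / "trials.h5").exists():
        return load_trialset_hdf5(out / "trials.h5")
    raise FileNotFoundError("missing artifact 'trials'; run the 'simulate' step first")


def run_train(cfg: RunConfig, out) -> Path:
    """Train the template bank from the stored session."""
    out = Path(out)
    ts = _load_trials(out)
    bank = train_bank(ts, cfg.n_subbands)
    path = out / "bank"
    bank.save(path)
    _update_manifest(cfg, out, "train", path.name)
    return path


def run_calibrate(cfg: RunConfig, out) -> Path:
    """Leave-one-out calibration of (n_y_min, beta) from the stored session."""
    out = Path(out)
    ts = _load_trials(out)
    curves = calibrate(
        ts,
        M=cfg.n_subbands,
        grid_step=cfg.grid_step,
        gaze_shift_s=cfg.gaze_shift_s,
        mode=cfg.cv,
    )
    path = out / "calibration.json"
    curves.to_json(path)
    _update_manifest(cfg, out, "calibrate", path.name)
    return path


def _decoder_config(cfg: RunConfig, curves: CalibrationResult) -> DecoderConfig:
    n_c = cfg.cycle_samples()
    return DecoderConfig(
        n_y_min=int(curves.chosen_n_y_min),
        n_y_max=cfg.n_y_max_cycles * n_c,
        cycle_samples=n_c,
        block_samples=cfg.block_samples,
        beta=float(curves.chosen_beta),
        gaze_shift_s=cfg.gaze_shift_s,
    )


def run_decode(cfg: RunConfig, out, targets=None) -> Path:
    """Replay a synthetic online stream through the calibrated decoder and
    write the decision log (JSON lines)."""
    out = Path(out)
    bank = TemplateBank.load(_require(out / "bank", "train"))
    curves = CalibrationResult.from_json(_require(out / "calibration.json", "calibrate"))
    if targets is None:
        targets = list(range(cfg.K))
    stream = OnlineStream(
        cfg.codeset(),
        targets,
        config=replace(cfg.sim_config(), seed=(cfg.seed + 104729) & 0x7FFFFFFF),
        block_samples=cfg.block_samples,
        gaze_shift_s=cfg.gaze_shift_s,
    )
    decisions, log = run_online(stream, bank, _decoder_config(cfg, curves))
    path = out / "decisions.jsonl"
    write_jsonl(log, path)
    summary = {
        "intended": [int(t) for t in targets],
        "decoded": [d.C for d in decisions],
        "accuracy": (
            float(np.mean([d.C == t for d, t in zip(decisions, targets)]))
            if decisions
            else 0.0
        ),
        "n_decisions": len(decisions),
    }
    with open(out / "decode_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    _update_manifest(cfg, out, "decode", path.name)
    return path


def _load_lexicon(cfg: RunConfig) -> Lexicon:
    if cfg.lexicon is None:
        return load_fixture_lexicon()
    if cfg.lexicon == "empty":
        return Lexicon.empty()
    prefix = Path(cfg.lexicon)
    return Lexicon.from_tsv(
        prefix.with_suffix(".unigrams.tsv"), prefix.with_suffix(".bigrams.tsv")
    )


def decoder_executor(cfg: RunConfig, bank: TemplateBank, dconfig: DecoderConfig):
    """Command executor that drives the calibrated decoder on a fresh
    synthetic stream per selection; returns (executed_target, elapsed_s)."""
    fs = cfg.sampling_rate
    base = cfg.sim_config()

    def execute(intended: int, step: int):
        sim = replace(base, seed=(cfg.seed + 7919 * (step + 1)) & 0x7FFFFFFF)
        stream = OnlineStream(
            cfg.codeset(),
            [intended],
            config=sim,
            block_samples=cfg.block_samples,
            gaze_shift_s=cfg.gaze_shift_s,
        )
        decisions, _ = run_online(stream, bank, dconfig)
        b = stream.boundaries[0] if stream.boundaries else None
        if decisions:
            elapsed = b["stim_blocks"] * cfg.block_samples / fs + cfg.gaze_shift_s
            return decisions[0].C, elapsed
        stim_blocks = b["stim_blocks"] if b else stream.max_blocks
        return None, stim_blocks * cfg.block_samples / fs

    return execute


def run_spell(cfg: RunConfig, out, mode: str = "model") -> Path:
    """Copy-spelling simulation; writes the session log and a report with
    accuracy, ITR, OCM and command counts.

    ``mode='model'`` uses the uniform command-error model with the
    calibrated selection time; ``mode='decoder'`` drives every selection
    through the decoder on a synthetic EEG stream.
    """
    out = Path(out)
    curves = CalibrationResult.from_json(_require(out / "calibration.json", "calibrate"))
    lexicon = _load_lexicon(cfg)
    t_select = curves.chosen_n_y_min / cfg.sampling_rate + cfg.gaze_shift_s
    if mode == "model":
        session = simulate_copy_spelling(
            cfg.sentence,
            lexicon,
            command_error_rate=cfg.command_error_rate,
            selection_time_s=t_select,
            seed=cfg.seed,
        )
    elif mode == "decoder":
        bank = TemplateBank.load(_require(out / "bank", "train"))
        executor = decoder_executor(cfg, bank, _decoder_config(cfg, curves))
        session = simulate_copy_spelling(cfg.sentence, lexicon, executor=executor)
    else:
        raise ValueError("mode must be 'model' or 'decoder'")
    path = out / "session.jsonl"
    write_jsonl(session["log"], path)
    mean_t = session["elapsed_s"] / session["commands"] if session["commands"] else t_select
    report = {
        "sentence": session["sentence"],
        "commands": session["commands"],
        "accuracy": round(session["accuracy"], 6),
        "itr_bpm": round(itr(cfg.K, session["accuracy"], mean_t), 4),
        "ocm": round(session["ocm"], 4),
        "output_chars": session["output_chars"],
        "elapsed_s": round(session["elapsed_s"], 4),
        "mode": mode,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    _update_manifest(cfg, out, "spell", path.name)
    return path
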