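"""Run configuration: defaults, loading and cross-module validation.

A run configuration collects everything a full experiment needs (stimulus
parameters, simulator settings, decoder bounds, calibration and speller
options) in one structured-text file (JSON or YAML).  Loading fills in the
study defaults (600 Hz, 16 channels, 60 Hz refresh, 8 targets, 30-sample
blocks, 1 s gaze shift, M = 1 for c-VEP / 5 for SSVEP) and re-validates the
cross-module constraints: n_a must divide n_c, the sampling rate must be an
integer multiple of the refresh rate, and n_y_max must be a whole number of
cycles.  All validation failures are reported together.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field

import yaml

from .stimcodes import build_cvep_codes, build_ssvep_codes
from .synth import SimConfig

__all__ = ["RunConfig", "ConfigError", "load_config"]

_SUBBAND_DEFAULT = {"cvep": 1, "ssvep": 5}


class ConfigError(ValueError):
    """Aggregated configuration failures."""

    def __init__(self, failures):
        self.failures = list(failures)
        super().__init__("invalid configuration:\n- " + "\n- ".join(self.failures))


@dataclass
class RunConfig:
    """Validated run configuration with study defaults filled in."""

    paradigm: str
    seed: int = 0
    refresh_rate: float = 60.0
    K: int = 8
    sampling_rate: float = 600.0
    n_channels: int = 16
    snr_db: float = 0.0
    n_blocks: int = 6
    cycles_per_trial: int = 3
    block_samples: int = 30
    gaze_shift_s: float = 1.0
    n_subbands: int | None = None
    grid_step: int = 30
    n_y_max_cycles: int = 2
    cv: str = "block"
    sentence: str = "BCI"
    lexicon: str | None = None  # path to TSV pair prefix, or None for fixture
    command_error_rate: float = 0.0
    sim: dict = field(default_factory=dict)  # extra SimConfig overrides
    out_dir: str = "."
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.n_subbands is None and self.paradigm in _SUBBAND_DEFAULT:
            self.n_subbands = _SUBBAND_DEFAULT[self.paradigm]

    # -- derived objects ---------------------------------------------------
    def codeset(self):
        if self.paradigm == "cvep":
            return build_cvep_codes(K=self.K, refresh_rate=self.refresh_rate)
        return build_ssvep_codes(K=self.K, refresh_rate=self.refresh_rate)

    def cycle_samples(self) -> int:
        return self.codeset().cycle_samples(self.sampling_rate)

    def sim_config(self) -> SimConfig:
        kwargs = dict(
            n_channels=self.n_channels,
            sampling_rate=self.sampling_rate,
            snr_db=self.snr_db,
            seed=self.seed,
        )
        kwargs.update(self.sim)
        return SimConfig(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Stable hash of the configuration, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _validate(cfg: RunConfig) -> list[str]:
    failures = []
    if cfg.paradigm not in ("cvep", "ssvep"):
        failures.append(f"paradigm must be 'cvep' or 'ssvep', got {cfg.paradigm!r}")
        return failures
    spf = cfg.sampling_rate / cfg.refresh_rate
    if abs(spf - round(spf)) > 1e-9:
        failures.append(
            f"sampling_rate {cfg.sampling_rate} is not an integer multiple of "
            f"refresh_rate {cfg.refresh_rate}"
        )
        return failures
    n_c = cfg.cycle_samples()
    if cfg.block_samples <= 0 or n_c % cfg.block_samples != 0:
        failures.append(
            f"block_samples {cfg.block_samples} does not divide the cycle length {n_c}"
        )
    if cfg.n_subbands is not None and cfg.n_subbands < 1:
        failures.append("n_subbands must be >= 1")
    if cfg.n_subbands is not None and 8 * cfg.n_subbands >= 60:
        failures.append("too many sub-bands: lowest cut-off must stay below 60 Hz")
    if cfg.n_blocks < 2:
        failures.append("n_blocks must be >= 2 (leave-one-out needs >= 2 blocks)")
    if cfg.n_y_max_cycles < 1:
        failures.append("n_y_max_cycles must be >= 1")
    if cfg.K < 2:
        failures.append("K must be >= 2")
    if not 0.0 <= cfg.command_error_rate < 1.0:
        failures.append("command_error_rate must lie in [0, 1)")
    if cfg.cv not in ("block", "trial"):
        failures.append("cv must be 'block' or 'trial'")
    if not math.isfinite(cfg.snr_db):
        failures.append("snr_db must be finite")
    return failures


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a RunConfig from a JSON/YAML file plus optional
    dotted-path overrides; all constraint violations are raised together."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(["config file must contain a mapping"])
        data.update(loaded)
    if overrides:
        for key, value in overrides.items():
            node = data
            parts = key.split(".")
            for p in parts[:-1]:
                node = node.setdefault(p, {})
            node[parts[-1]] = value
    if "paradigm" not in data:
        raise ConfigError(["paradigm is required ('cvep' or 'ssvep')"])
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ConfigError([f"unknown config key {k!r}" for k in sorted(unknown)])
    cfg = RunConfig(**data)
    failures = _validate(cfg)
    if failures:
        raise ConfigError(failures)
    return cfg
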