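"""Run configuration.

Every tunable of the pipeline lives in one of two dataclasses so a run can
be serialized alongside its outputs and replayed exactly.  The defaults are
the values of the study protocol this package models: a 1,200 Hz eye
tracker, a 3-SD sliding-window blink criterion with 77/181-sample margins,
a 60% sentence-validity filter and a 15% participant filter, 28 blocks of
7 sentences with the published noise/response/retention timing, and the
modified HINT staircase steps (0.8 dB down / 3.2 dB up, doubled on the
first five trials).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "GeneratorConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


@dataclass
class PipelineConfig:
    """Tunables of the preprocessing/extraction/modelling pipeline."""

    # --- acquisition ---
    sample_rate_hz: float = 1200.0

    # --- blink detection ---
    window_samples: int = 1200        # 1 s sliding window
    sd_k: float = 3.0                 # threshold: mean - k*SD within window
    pre_margin: int = 77              # samples removed before each blink (64 ms)
    post_margin: int = 181            # samples removed after each blink (151 ms)

    # --- validity filters ---
    sentence_valid_min_pct: float = 60.0   # discard sentence if below
    participant_missing_max_pct: float = 15.0  # exclude participant if above

    # --- baseline extraction ---
    baseline_window_s: float = 1.0    # [sentence onset - 1 s, onset)

    # --- session timeline (seconds) ---
    n_blocks: int = 28
    sentences_per_block: int = 7
    noise_lead_first_s: float = 3.0   # noise before sentence 1 of a block
    noise_lead_rest_s: float = 1.0    # noise before sentences 2..7
    noise_trail_s: float = 1.0        # noise after each sentence offset
    sentence_duration_s: float = 1.8
    response_interval_s: float = 4.0  # silent repeat interval, sentences 1..6
    last_response_interval_s: float = 2.0  # shortened after sentence 7
    retention_interval_s: float = 4.0
    recall_window_s: float = 10.0
    break_s: float = 7.5              # between blocks (protocol: approx 5-10 s)

    # --- adaptive SNR procedures (dB) ---
    staircase_step_down_db: float = 0.8   # after a correct repetition
    staircase_step_up_db: float = 3.2     # after an incorrect repetition
    staircase_double_first_n: int = 5     # doubled step on trials 1..5
    staircase_n_trials: int = 20
    staircase_start_snr_db: float = 0.0   # target and noise both at 70 dB SPL
    staircase_result: str = "final"       # or "mean_last_k"
    staircase_mean_last_k: int = 6

    # --- mixed-model workflow ---
    alpha_random: float = 0.1         # LRT threshold, random-structure pruning
    alpha_fixed: float = 0.05         # Wald threshold, fixed-effect pruning
    standardize_predictors: bool = False  # center only by default
    singular_sd_rel_tol: float = 1e-6
    singular_corr_tol: float = 0.999

    # --- misc ---
    seed: int = 0
    # epoch used by the sentence validity rule: [onset - pre, offset + post)
    sentence_epoch_pre_s: float = 1.0
    sentence_epoch_post_s: float = 1.0

    def validate(self) -> None:
        positives = (
            "sample_rate_hz window_samples baseline_window_s n_blocks "
            "sentences_per_block noise_lead_first_s noise_lead_rest_s "
            "noise_trail_s sentence_duration_s response_interval_s "
            "last_response_interval_s retention_interval_s recall_window_s "
            "break_s"
        ).split()
        for name in positives:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.sentence_duration_s <= 0:
            raise ConfigError("sentence_duration_s must be positive")
        if self.pre_margin < 0 or self.post_margin < 0:
            raise ConfigError("margins must be non-negative")
        if not 0 <= self.sentence_valid_min_pct <= 100:
            raise ConfigError("sentence_valid_min_pct must be in [0, 100]")
        if not 0 <= self.participant_missing_max_pct <= 100:
            raise ConfigError("participant_missing_max_pct must be in [0, 100]")

    # -- serialization ------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def replace(self, **kwargs) -> "PipelineConfig":
        cfg = dataclasses.replace(self, **kwargs)
        cfg.validate()
        return cfg


@dataclass
class GeneratorConfig:
    """Conditions of the synthetic-session generator.

    Fixed-effect generating values (on the centered-predictor scale) default
    to the published coefficient table of the study the pipeline models:
    intercept 3.48 mm, Block slope -0.01 mm/block, RS slope 0.01 mm/%,
    SNR slope -0.09 mm/dB and RS x SNR interaction -0.01.  Covariate
    distributions follow the study sample: RS ~ N(41.72, 11.99) % clipped to
    [0, 100] and SNR ~ N(6.65, 3.08) dB.
    """

    n_participants: int = 21

    # fixed effects on centered predictors (mm)
    b0: float = 3.48
    b_block: float = -0.01
    b_rs: float = 0.01
    b_snr: float = -0.09
    b_rs_snr: float = -0.01
    # null by default; available for scenario studies
    b_block_rs: float = 0.0
    b_block_snr: float = 0.0
    b_block_rs_snr: float = 0.0

    # random effects / noise (mm)
    tau0: float = 0.3            # participant random-intercept SD
    tau_block: float = 0.003     # participant random Block-slope SD
    sigma_eps: float = 0.1       # block-level residual SD

    # covariate distributions
    rs_mean: float = 41.72
    rs_sd: float = 11.99
    snr_mean: float = 6.65
    snr_sd: float = 3.08
    age_mean: float = 58.0
    age_sd: float = 11.3
    pta_mean: float = 49.30
    pta_sd: float = 11.44

    # trace-level structure
    memory_ramp_mm: float = 0.02      # per sentence index within a block
    trace_noise_sd: float = 0.05      # Gaussian measurement-noise SD (mm)
    trace_noise_tau_s: float = 0.05   # noise autocorrelation time (0 = white)
    blink_rate_per_min: float = 15.0
    blink_duration_s: tuple[float, float] = (0.1, 0.4)

    # recall model (logit scale; centered RS)
    g0: float = 0.3277                # logit of the 58.10% grand mean
    g_rs: float = 0.03                # per centered RS point
    g_block: float = 0.0              # fixed Block effect (disengagement)
    tau_g_block: float = 0.02         # per-participant Block-slope SD (logit)

    # psychometric listener for staircase simulation
    srt_db: float = -3.0              # 50% point of the logistic
    slope_per_db: float = 0.5         # natural-logistic slope

    seed: int = 0

    def validate(self) -> None:
        for name in ("tau0", "tau_block", "sigma_eps", "rs_sd", "snr_sd",
                     "trace_noise_sd", "tau_g_block", "blink_rate_per_min"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        lo, hi = self.blink_duration_s
        if not 0 < lo <= hi:
            raise ConfigError("blink_duration_s must be an increasing pair > 0")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["blink_duration_s"] = list(self.blink_duration_s)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "blink_duration_s" in data:
            data["blink_duration_s"] = tuple(data["blink_duration_s"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def replace(self, **kwargs) -> "GeneratorConfig":
        cfg = dataclasses.replace(self, **kwargs)
        cfg.validate()
        return cfg

    @property
    def betas(self) -> dict[str, float]:
        return {
            "Intercept": self.b0,
            "Block": self.b_block,
            "RS": self.b_rs,
            "SNR": self.b_snr,
            "Block:RS": self.b_block_rs,
            "Block:SNR": self.b_block_snr,
            "RS:SNR": self.b_rs_snr,
            "Block:RS:SNR": self.b_block_rs_snr,
        }
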