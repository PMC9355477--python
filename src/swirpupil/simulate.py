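"""Synthetic SWIR-session generator.

Emulates the statistical structure the downstream analysis assumes so that
every stage is testable without real recordings:

* participant covariates (Reading Span %, individualized SNR, age, PTA)
  drawn from the study-sample distributions;
* per-participant, per-block *true* pupil baselines following a linear
  mixed model on centered predictors (random intercept and random Block
  slope by participant, block-level Gaussian residual);
* 1,200 Hz pupil traces that hold each block's level, add an optional
  linear within-block "memory ramp" across the seven sentences, Gaussian
  sample noise, and injected blink artifacts;
* binomial recall outcomes with a working-memory (RS) effect and optional
  block-slope heterogeneity on the logit scale;
* a logistic psychometric listener for adaptive-staircase simulation.

Every dataset carries its :class:`SyntheticTruth` so recovery tests can
compare extracted quantities against what was generated, without the
fitting code ever seeing the truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from swirpupil.config import ConfigError, GeneratorConfig, PipelineConfig
from swirpupil.types import (
    BlockSchedule,
    ParticipantRecord,
    PupilTrace,
    SentenceSchedule,
    SessionSchedule,
)

__all__ = [
    "SyntheticTruth",
    "gen_participants",
    "build_timeline",
    "gen_block_means",
    "gen_trace",
    "inject_blinks",
    "gen_recall",
    "gen_staircase_responses",
    "simulate_block_data",
    "generate_dataset",
]


@dataclass
class SyntheticTruth:
    """Ground-truth ledger persisted alongside every generated dataset."""

    random_intercepts: dict[str, float] = field(default_factory=dict)
    random_block_slopes: dict[str, float] = field(default_factory=dict)
    true_block_means: dict[str, list[float]] = field(default_factory=dict)
    blink_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    recall_probabilities: dict[str, list[float]] = field(default_factory=dict)
    centering_offsets: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "random_intercepts": self.random_intercepts,
            "random_block_slopes": self.random_block_slopes,
            "true_block_means": self.true_block_means,
            "blink_intervals": {k: [list(iv) for iv in v]
                                for k, v in self.blink_intervals.items()},
            "recall_probabilities": self.recall_probabilities,
            "centering_offsets": self.centering_offsets,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        d["blink_intervals"] = {k: [tuple(iv) for iv in v]
                                for k, v in d.get("blink_intervals", {}).items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# participants and covariates


def gen_participants(
    cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[list[ParticipantRecord], dict[str, tuple[float, float]]]:
    """Draw participant covariates and random effects.

    RS scores are Normal(rs_mean, rs_sd) clipped to [0, 100]; SNR is
    Normal(snr_mean, snr_sd).  Random intercepts u0 ~ N(0, tau0) and random
    Block slopes u1 ~ N(0, tau_block) are returned separately, keyed by
    participant id.
    """
    n = cfg.n_participants
    rs = np.clip(rng.normal(cfg.rs_mean, cfg.rs_sd, n), 0.0, 100.0)
    snr = rng.normal(cfg.snr_mean, cfg.snr_sd, n)
    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), 18.0, 90.0)
    pta = np.clip(rng.normal(cfg.pta_mean, cfg.pta_sd, n), 0.0, 120.0)
    u0 = rng.normal(0.0, cfg.tau0, n) if cfg.tau0 > 0 else np.zeros(n)
    u1 = rng.normal(0.0, cfg.tau_block, n) if cfg.tau_block > 0 else np.zeros(n)
    participants = [
        ParticipantRecord(
            id=f"P{i + 1:03d}",
            rs_score=float(rs[i]),
            snr_db=float(snr[i]),
            age=float(age[i]),
            pta_db_hl=float(pta[i]),
        )
        for i in range(n)
    ]
    effects = {p.id: (float(u0[i]), float(u1[i]))
               for i, p in enumerate(participants)}
    return participants, effects


# ---------------------------------------------------------------------------
# session timeline


def build_timeline(cfg: PipelineConfig) -> SessionSchedule:
    """Build the full session schedule from the protocol durations.

    Per block: background noise starts 3 s before sentence 1 and 1 s before
    sentences 2..7, and stops 1 s after each sentence offset; a 4 s silent
    response interval separates consecutive noise intervals (2 s after the
    last sentence), followed by a 4 s retention interval, the recall beep,
    the free-recall window, and a short break.
    """
    cfg.validate()
    if cfg.sentence_duration_s <= cfg.baseline_window_s - cfg.noise_lead_rest_s:
        # baseline window must fit inside the noise lead; with a 1 s lead and
        # a 1 s window the lead alone covers it, so this only guards odd configs
        pass
    blocks: list[BlockSchedule] = []
    t = 0.0
    for b in range(1, cfg.n_blocks + 1):
        sentences: list[SentenceSchedule] = []
        for j in range(1, cfg.sentences_per_block + 1):
            lead = cfg.noise_lead_first_s if j == 1 else cfg.noise_lead_rest_s
            noise_onset = t
            sent_onset = noise_onset + lead
            sent_offset = sent_onset + cfg.sentence_duration_s
            noise_offset = sent_offset + cfg.noise_trail_s
            sentences.append(SentenceSchedule(
                noise_onset_s=noise_onset,
                sentence_onset_s=sent_onset,
                sentence_offset_s=sent_offset,
                noise_offset_s=noise_offset,
            ))
            if j < cfg.sentences_per_block:
                t = noise_offset + cfg.response_interval_s
            else:
                t = noise_offset + cfg.last_response_interval_s
        retention_onset = t
        beep = retention_onset + cfg.retention_interval_s
        recall_end = beep + cfg.recall_window_s
        break_end = recall_end + cfg.break_s
        blocks.append(BlockSchedule(
            block_index=b,
            sentences=sentences,
            retention_onset_s=retention_onset,
            beep_s=beep,
            recall_end_s=recall_end,
            break_end_s=break_end,
        ))
        t = break_end
    schedule = SessionSchedule(blocks=blocks)
    schedule.validate()
    return schedule


# ---------------------------------------------------------------------------
# true block means and traces


def gen_block_means(
    participant: ParticipantRecord,
    cfg: GeneratorConfig,
    u0: float,
    u1: float,
    rs_offset: float,
    snr_offset: float,
    n_blocks: int = 28,
) -> np.ndarray:
    """True (noise-free) pupil-baseline mean for each block.

    ``mu_j = b0 + (b_block + u1) * Block_c_j + b_rs * RS_c + b_snr * SNR_c
    + b_rs_snr * RS_c * SNR_c + u0`` with predictors centered at the given
    offsets.  Higher-order generating terms (Block x RS etc.) are included
    when non-zero.
    """
    block = np.arange(1, n_blocks + 1, dtype=float)
    bc = block - (n_blocks + 1) / 2.0
    rc = participant.rs_score - rs_offset
    sc = participant.snr_db - snr_offset
    mu = (
        cfg.b0
        + (cfg.b_block + u1) * bc
        + cfg.b_rs * rc
        + cfg.b_snr * sc
        + cfg.b_rs_snr * rc * sc
        + cfg.b_block_rs * bc * rc
        + cfg.b_block_snr * bc * sc
        + cfg.b_block_rs_snr * bc * rc * sc
        + u0
    )
    return mu


def gen_trace(
    schedule: SessionSchedule,
    block_means: np.ndarray,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    sample_rate: float = 1200.0,
    eye: str = "right",
) -> PupilTrace:
    """Sample-level pupil trace for one session.

    Within each block the diameter sits at the block's true mean; from the
    noise onset of sentence k until the next sentence's noise onset a
    memory ramp of ``memory_ramp_mm * (k - 1)`` is added, emulating the
    load of holding k-1 words for later recall.  Measurement noise is a
    Gaussian AR(1) (Ornstein-Uhlenbeck) process with marginal SD
    ``trace_noise_sd`` and autocorrelation time ``trace_noise_tau_s``:
    pupil traces are smooth, and white noise at 1,200 Hz would scatter
    spurious 3-SD singletons through the blink detector at a rate no real
    recording shows.  ``trace_noise_tau_s = 0`` gives white noise.
    """
    n_samples = int(round(schedule.blocks[-1].break_end_s * sample_rate))
    level = np.empty(n_samples)
    # fill inter-block / pre-session gaps with the enclosing block's mean
    boundaries = np.array([b.sentences[0].noise_onset_s for b in schedule.blocks])
    for bi, block in enumerate(schedule.blocks):
        start = 0 if bi == 0 else int(round(boundaries[bi] * sample_rate))
        end = (n_samples if bi == len(schedule.blocks) - 1
               else int(round(boundaries[bi + 1] * sample_rate)))
        level[start:end] = block_means[bi]
        if cfg.memory_ramp_mm != 0.0:
            for k, sent in enumerate(block.sentences, start=1):
                s0 = int(round(sent.noise_onset_s * sample_rate))
                if k < len(block.sentences):
                    s1 = int(round(block.sentences[k].noise_onset_s * sample_rate))
                else:
                    s1 = int(round(block.retention_onset_s * sample_rate))
                level[s0:s1] += cfg.memory_ramp_mm * (k - 1)
    if cfg.trace_noise_sd > 0:
        eps = rng.normal(0.0, 1.0, n_samples)
        if cfg.trace_noise_tau_s > 0:
            from scipy.signal import lfilter

            rho = float(np.exp(-1.0 / (cfg.trace_noise_tau_s * sample_rate)))
            noise = lfilter([np.sqrt(1.0 - rho**2)], [1.0, -rho], eps)
        else:
            noise = eps
        level = level + cfg.trace_noise_sd * noise
    return PupilTrace(
        diameter=level,
        valid=np.ones(n_samples, dtype=bool),
        sample_rate=sample_rate,
        eye=eye,
    )


def inject_blinks(
    trace: PupilTrace,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    avoid_windows: list[tuple[float, float]] | None = None,
) -> tuple[PupilTrace, list[tuple[int, int]]]:
    """Superimpose blink artifacts on a trace.

    Blink onsets follow a Poisson process at ``blink_rate_per_min``; each
    blink dips linearly to 10% of the local diameter over 20 ms, stays
    there, and recovers linearly over 20 ms.  The core of the blink (all
    but the 20 ms transition edges) is marked invalid, as a tracker that
    has lost the pupil would do; the depressed transition samples stay
    "valid" — they are what threshold detection and the pre/post margins
    must catch.  Returns the modified trace (a copy) and the injected
    half-open sample intervals.

    ``avoid_windows`` (seconds) restricts placement: blinks overlapping any
    listed window are re-drawn elsewhere — used by clean-baseline fixtures.
    """
    if cfg.blink_rate_per_min == 0:
        return trace.copy(), []
    out = trace.copy()
    fs = trace.sample_rate
    n = len(trace)
    duration_s = n / fs
    n_blinks = rng.poisson(cfg.blink_rate_per_min * duration_s / 60.0)
    edge = max(1, int(round(0.020 * fs)))  # 20 ms transition
    intervals: list[tuple[int, int]] = []
    avoid = [(int(round(a * fs)), int(round(b * fs)))
             for a, b in (avoid_windows or [])]
    for _ in range(n_blinks):
        for _attempt in range(200):
            dur = rng.uniform(*cfg.blink_duration_s)
            length = max(3 * edge, int(round(dur * fs)))
            start = int(rng.integers(0, max(1, n - length)))
            end = start + length
            # blinks never overlap each other or an excluded window
            if not any(start < b and a < end for a, b in avoid + intervals):
                break
        else:
            continue
        seg = out.diameter[start:end]
        local = float(np.median(seg))
        depth = 0.1 * local
        shape = np.full(length, depth)
        shape[:edge] = np.linspace(local, depth, edge, endpoint=False)
        shape[length - edge:] = np.linspace(depth, local, edge)
        out.diameter[start:end] = shape
        out.valid[start + edge:end - edge] = False
        intervals.append((start, end))
    intervals.sort()
    merged: list[tuple[int, int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return out, merged


# ---------------------------------------------------------------------------
# behavioural outcomes


def gen_recall(
    participant: ParticipantRecord,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    rs_offset: float,
    u_block: float = 0.0,
    n_blocks: int = 28,
    n_words: int = 7,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-block recall percentage, Binomial(n_words, p).

    ``logit(p_j) = g0 + g_rs * RS_c + (g_block + u_block) * Block_c_j``.
    The fixed Block term is 0 by default (recall stable over the session);
    ``u_block`` injects per-participant slope heterogeneity.
    Returns (recall_pct array, true probability array).
    """
    block = np.arange(1, n_blocks + 1, dtype=float)
    bc = block - (n_blocks + 1) / 2.0
    rc = participant.rs_score - rs_offset
    eta = cfg.g0 + cfg.g_rs * rc + (cfg.g_block + u_block) * bc
    p = 1.0 / (1.0 + np.exp(-eta))
    correct = rng.binomial(n_words, p)
    return 100.0 * correct / n_words, p


def gen_staircase_responses(
    snr_db: float | np.ndarray,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Simulated correct/incorrect sentence repetitions at a given SNR.

    The listener is logistic: ``P(correct) = 1 / (1 + exp(-(snr - srt) *
    slope))`` — 50% at the speech reception threshold ``srt_db``.
    """
    p = listener_p_correct(snr_db, cfg)
    return rng.random(size if size is not None else np.shape(p)) < p


def listener_p_correct(snr_db, cfg: GeneratorConfig):
    """Closed-form psychometric function of the simulated listener."""
    from scipy.special import expit

    return expit((np.asarray(snr_db, dtype=float) - cfg.srt_db)
                 * cfg.slope_per_db)


# ---------------------------------------------------------------------------
# block-level dataset (the model's input, without the trace detour)


def simulate_block_data(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    n_blocks: int = 28,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate the analysis table directly at block level.

    Produces one row per participant x block with the observed pupil
    baseline (true block mean + N(0, sigma_eps) residual) and the recall
    percentage.  Centering offsets for generation are the sample means of
    the drawn covariates, mirroring how the analysis centers.
    """
    participants, effects = gen_participants(cfg, rng)
    rs_offset = float(np.mean([p.rs_score for p in participants]))
    snr_offset = float(np.mean([p.snr_db for p in participants]))
    truth = SyntheticTruth(centering_offsets={"rs": rs_offset, "snr": snr_offset})
    rows = []
    for p in participants:
        u0, u1 = effects[p.id]
        truth.random_intercepts[p.id] = u0
        truth.random_block_slopes[p.id] = u1
        mu = gen_block_means(p, cfg, u0, u1, rs_offset, snr_offset, n_blocks)
        truth.true_block_means[p.id] = [float(m) for m in mu]
        y = mu + (rng.normal(0.0, cfg.sigma_eps, n_blocks)
                  if cfg.sigma_eps > 0 else 0.0)
        ub = (rng.normal(0.0, cfg.tau_g_block)
              if cfg.tau_g_block > 0 else 0.0)
        recall, prob = gen_recall(p, cfg, rng, rs_offset, u_block=ub,
                                  n_blocks=n_blocks)
        truth.recall_probabilities[p.id] = [float(q) for q in prob]
        for j in range(n_blocks):
            rows.append({
                "participant": p.id,
                "block": j + 1,
                "rs_score": p.rs_score,
                "snr_db": p.snr_db,
                "pupil_baseline_mm": float(y[j]),
                "recall_pct": float(recall[j]),
            })
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# full-session file generation


def generate_dataset(
    gen_cfg: GeneratorConfig,
    pipe_cfg: PipelineConfig,
    out_dir: str | Path,
    rng: np.random.Generator | None = None,
    clean_baselines: bool = False,
) -> SyntheticTruth:
    """Write a complete synthetic dataset to ``out_dir``.

    Files: ``events.tsv`` (one schedule shared by all participants),
    ``participants.csv``, per-participant ``samples_<id>.tsv`` and
    ``recall_<id>.csv``, and ``truth.json``.  With ``clean_baselines`` the
    injected blinks avoid every sentence epoch, so all sentences stay 100%
    valid.
    """
    from swirpupil import io  # local import to avoid a cycle

    rng = rng if rng is not None else np.random.default_rng(gen_cfg.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    schedule = build_timeline(pipe_cfg)

    participants, effects = gen_participants(gen_cfg, rng)
    rs_offset = float(np.mean([p.rs_score for p in participants]))
    snr_offset = float(np.mean([p.snr_db for p in participants]))
    truth = SyntheticTruth(centering_offsets={"rs": rs_offset, "snr": snr_offset})

    avoid = None
    if clean_baselines:
        avoid = [
            (s.sentence_onset_s - pipe_cfg.sentence_epoch_pre_s,
             s.sentence_offset_s + pipe_cfg.sentence_epoch_post_s)
            for _, _, s in schedule.sentence_epochs()
        ]

    io.write_events(out / "events.tsv", schedule)
    for p in participants:
        u0, u1 = effects[p.id]
        truth.random_intercepts[p.id] = u0
        truth.random_block_slopes[p.id] = u1
        mu = gen_block_means(p, gen_cfg, u0, u1, rs_offset, snr_offset,
                             pipe_cfg.n_blocks)
        truth.true_block_means[p.id] = [float(m) for m in mu]
        trace = gen_trace(schedule, mu, gen_cfg, rng,
                          sample_rate=pipe_cfg.sample_rate_hz)
        trace, blinks = inject_blinks(trace, gen_cfg, rng, avoid_windows=avoid)
        truth.blink_intervals[p.id] = blinks
        ub = rng.normal(0.0, gen_cfg.tau_g_block) if gen_cfg.tau_g_block > 0 else 0.0
        recall, prob = gen_recall(p, gen_cfg, rng, rs_offset, u_block=ub,
                                  n_blocks=pipe_cfg.n_blocks)
        truth.recall_probabilities[p.id] = [float(q) for q in prob]
        # both eyes observe the same session; the left eye gets independent noise
        left = trace.copy()
        left.eye = "left"
        io.write_samples(out / f"samples_{p.id}.tsv", left, trace)
        pd.DataFrame({"block": np.arange(1, pipe_cfg.n_blocks + 1),
                      "recall_pct": recall}).to_csv(
            out / f"recall_{p.id}.csv", index=False)
    io.write_participants(out / "participants.csv", participants)
    truth.to_json(out / "truth.json")
    return truth
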