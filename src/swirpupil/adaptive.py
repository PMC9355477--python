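"""Adaptive SNR-setting procedures.

Two stages set the speech level for a session (the babble stays fixed at
70 dB SPL, so SNR moves with the target level):

1. A modified HINT staircase targeting ~80% sentence intelligibility:
   SNR drops 0.8 dB after a correct repetition and rises 3.2 dB after an
   incorrect one, with both steps doubled on the first five trials.  The
   asymmetric 1-up/1-down rule equilibrates where the expected step is
   zero, i.e. at p = 3.2 / (3.2 + 0.8) = 0.8.
2. A training-list adjustment over four 7-sentence lists: no change when
   6-7 last words were repeated correctly, +1 dB for 4-5, +2 dB for 0-3.

All step arithmetic is carried in integer tenths of a dB, so accumulated
SNRs are exact to 0.1 dB.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from swirpupil.config import GeneratorConfig, PipelineConfig

__all__ = [
    "StaircaseState",
    "hint_staircase",
    "swir_training_adjust",
    "simulate_snr_setting",
]


@dataclass
class StaircaseState:
    """History of one adaptive run."""

    snr_db: float
    history: list[tuple[float, bool, float]] = field(default_factory=list)
    # each entry: (snr at presentation, correct, step applied after it)

    @property
    def trial_index(self) -> int:
        return len(self.history) + 1


def _step_tenths(correct: bool, trial: int, cfg: PipelineConfig) -> int:
    down = round(cfg.staircase_step_down_db * 10)
    up = round(cfg.staircase_step_up_db * 10)
    step = -down if correct else up
    if trial <= cfg.staircase_double_first_n:
        step *= 2
    return step


def hint_staircase(
    responses: Sequence[bool] | Callable[[float, int], bool],
    cfg: PipelineConfig | None = None,
    n_trials: int | None = None,
) -> StaircaseState:
    """Run the modified HINT staircase.

    ``responses`` is either a sequence of correct/incorrect outcomes or a
    callable ``(snr_db, trial_index) -> bool`` (a simulated listener).
    The SNR is updated after every trial, including the first; the
    returned state's ``snr_db`` is the SNR after the final update.
    """
    cfg = cfg or PipelineConfig()
    if callable(responses):
        if n_trials is None:
            n_trials = cfg.staircase_n_trials
        get = responses
    else:
        seq = list(responses)
        if not seq:
            raise ValueError("response sequence must not be empty")
        if n_trials is None:
            n_trials = len(seq)
        get = lambda snr, t: seq[t - 1]  # noqa: E731
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    snr_tenths = round(cfg.staircase_start_snr_db * 10)
    state = StaircaseState(snr_db=snr_tenths / 10.0)
    for t in range(1, n_trials + 1):
        snr = snr_tenths / 10.0
        correct = bool(get(snr, t))
        step = _step_tenths(correct, t, cfg)
        snr_tenths += step
        state.history.append((snr, correct, step / 10.0))
    state.snr_db = snr_tenths / 10.0
    return state


def staircase_result_snr(state: StaircaseState, cfg: PipelineConfig) -> float:
    """SNR handed to the next stage: the post-final-update value by
    default, or the mean presented SNR over the last k trials."""
    if cfg.staircase_result == "mean_last_k":
        k = min(cfg.staircase_mean_last_k, len(state.history))
        return float(np.mean([h[0] for h in state.history[-k:]]))
    return state.snr_db


def swir_training_adjust(
    start_snr_db: float,
    per_list_correct_counts: Sequence[int],
) -> float:
    """Apply the four training-list adjustments sequentially.

    Per list of seven sentences: 6-7 last words correct -> no change,
    4-5 -> +1 dB, 0-3 -> +2 dB.
    """
    snr_tenths = round(start_snr_db * 10)
    for count in per_list_correct_counts:
        if not 0 <= count <= 7:
            raise ValueError(f"correct count must be in 0..7, got {count}")
        if count >= 6:
            delta = 0
        elif count >= 4:
            delta = 10
        else:
            delta = 20
        snr_tenths += delta
    return snr_tenths / 10.0


def simulate_snr_setting(
    gen_cfg: GeneratorConfig,
    pipe_cfg: PipelineConfig,
    rng: np.random.Generator,
) -> tuple[float, StaircaseState]:
    """Compose staircase and training adjustment for a simulated listener.

    Returns the SNR used for the remainder of the session and the
    staircase history.
    """
    from swirpupil.simulate import listener_p_correct

    def listener(snr_db: float, _trial: int) -> bool:
        return bool(rng.random() < listener_p_correct(snr_db, gen_cfg))

    state = hint_staircase(listener, pipe_cfg)
    snr = staircase_result_snr(state, pipe_cfg)
    counts = []
    for _ in range(4):
        p = listener_p_correct(snr, gen_cfg)
        counts.append(int(rng.binomial(7, p)))
        snr = swir_training_adjust(snr, [counts[-1]])
    return snr, state
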