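"""Baseline extraction, recall scoring and epoch grand-averaging.

The *sentence baseline* is the mean pupil diameter over the second before
a sentence starts (a half-open window, the onset sample excluded).  The
*pupil baseline* of a block is the mean of its retained sentence
baselines and is the unit of analysis for the arousal model.  Recall is
scored per block as the percentage of correctly recalled repeated words.
"""

from __future__ import annotations

import logging

import numpy as np

from swirpupil.config import PipelineConfig
from swirpupil.preprocess import ValidityLedger
from swirpupil.types import BlockRecord, PupilTrace, SessionSchedule

logger = logging.getLogger("swirpupil")

__all__ = [
    "sentence_baseline",
    "block_pupil_baseline",
    "recall_score",
    "epoch_grand_average",
    "extract_blocks",
]


def sentence_baseline(
    trace: PupilTrace,
    sentence_onset_s: float,
    window_s: float = 1.0,
) -> float | None:
    """Mean diameter over ``[onset - window_s, onset)``.

    Returns None when the window falls outside the trace (the sentence is
    then unusable).  Uses the interpolated diameter values.
    """
    i0, i1 = trace.window(sentence_onset_s - window_s, sentence_onset_s)
    if i0 < 0 or i1 > len(trace) or i1 <= i0:
        return None
    return float(trace.diameter[i0:i1].mean())


def block_pupil_baseline(sentence_baselines: list[float]) -> tuple[float, int]:
    """Mean over the used sentence baselines of one block.

    Returns ``(nan, 0)`` for an empty list; such blocks become missing
    rows rather than zeros, so they never enter the model.
    """
    vals = [v for v in sentence_baselines if v is not None and np.isfinite(v)]
    if not vals:
        return float("nan"), 0
    return float(np.mean(vals)), len(vals)


def recall_score(recalled_words: list[str], target_words: list[str]) -> float:
    """Percentage of target words present in the free-recall response.

    Matching is case-insensitive exact string equality against the word
    the participant repeated during the block (so a misperceived but
    consistently recalled word still counts); duplicates count once and
    recall order is ignored.
    """
    targets = {w.strip().lower() for w in target_words}
    recalled = {w.strip().lower() for w in recalled_words}
    if not target_words:
        return 0.0
    return 100.0 * len(targets & recalled) / len(target_words)


def epoch_grand_average(
    trace: PupilTrace,
    schedule: SessionSchedule,
    cfg: PipelineConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Grand-average pupil time course across sentence epochs.

    Epochs run from 1 s before each sentence onset to the next noise
    onset (or the retention onset for a block's last sentence), aligned
    at the sentence onset; ragged epochs are truncated to the shortest.
    Returns ``(t_s, mean, ci_lo, ci_hi)`` with a normal-approximation 95%
    confidence band across epochs.
    """
    fs = trace.sample_rate
    epochs = []
    for block in schedule.blocks:
        for j, s in enumerate(block.sentences):
            start = s.sentence_onset_s - cfg.sentence_epoch_pre_s
            if j + 1 < len(block.sentences):
                end = block.sentences[j + 1].noise_onset_s
            else:
                end = block.retention_onset_s
            i0, i1 = trace.window(start, end)
            if i0 < 0 or i1 > len(trace) or i1 <= i0:
                continue
            epochs.append(trace.diameter[i0:i1])
    if len(epochs) < 2:
        raise ValueError("need at least two sentence epochs to average")
    m = min(len(e) for e in epochs)
    arr = np.vstack([e[:m] for e in epochs])
    mean = arr.mean(axis=0)
    sem = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
    t = np.arange(m) / fs - cfg.sentence_epoch_pre_s
    return t, mean, mean - 1.96 * sem, mean + 1.96 * sem


def extract_blocks(
    trace: PupilTrace,
    schedule: SessionSchedule,
    ledger: ValidityLedger,
    cfg: PipelineConfig,
    participant_id: str,
    recall_pct: dict[int, float] | None = None,
) -> list[BlockRecord]:
    """Turn a cleaned trace into per-block records.

    Discarded sentences (per the ledger) are skipped; blocks with zero
    usable sentences are omitted entirely.  ``recall_pct`` maps block
    index to the behavioural score (NaN when absent).
    """
    records: list[BlockRecord] = []
    for block in schedule.blocks:
        vals: list[float | None] = []
        for j, s in enumerate(block.sentences, start=1):
            if ledger.is_discarded(block.block_index, j):
                continue
            vals.append(sentence_baseline(trace, s.sentence_onset_s,
                                          cfg.baseline_window_s))
        baseline, n_used = block_pupil_baseline([v for v in vals if v is not None])
        if n_used == 0:
            logger.info("participant %s block %d: no usable sentences; "
                        "block dropped", participant_id, block.block_index)
            continue
        rp = float("nan")
        if recall_pct is not None:
            rp = recall_pct.get(block.block_index, float("nan"))
        records.append(BlockRecord(
            participant=participant_id,
            block_index=block.block_index,
            pupil_baseline_mm=baseline,
            n_sentences_used=n_used,
            recall_pct=rp,
        ))
    return records
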