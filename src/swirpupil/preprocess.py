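"""Pupil-trace cleaning: eye selection, blink handling, validity filters.

Stage order::

    select_eye -> detect_blinks -> apply_margins -> mark invalid
               -> interpolate -> sentence_validity -> participant_filter

Blink detection uses a 1 s (1,200-sample) sliding window centered on each
sample: a sample is blink-flagged when its diameter falls more than
``sd_k`` (default 3) sample standard deviations below the window mean,
both computed over the window's valid samples.  Flagged runs are widened
by 77 samples before and 181 after, the widened intervals are marked
invalid and linearly interpolated.  Sentences with less than 60% valid
data (measured after margin widening, before interpolation) are
discarded, and participants with more than 15% of sentences discarded are
excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from swirpupil.config import PipelineConfig
from swirpupil.types import PupilTrace, SessionSchedule, UnusableTraceError

logger = logging.getLogger("swirpupil")

__all__ = [
    "ValidityLedger",
    "select_eye",
    "detect_blinks",
    "apply_margins",
    "interpolate",
    "sentence_validity",
    "participant_filter",
    "run_preprocess",
]

Interval = tuple[int, int]  # half-open sample interval [start, end)


@dataclass
class SentenceValidity:
    block_index: int
    sentence_index: int
    pct_valid: float
    discarded: bool


@dataclass
class ValidityLedger:
    """Two-level bookkeeping of the validity filters."""

    sentences: list[SentenceValidity] = field(default_factory=list)
    pct_sentences_missing: float = 0.0
    excluded: bool = False

    @property
    def n_discarded(self) -> int:
        return sum(s.discarded for s in self.sentences)

    def is_discarded(self, block_index: int, sentence_index: int) -> bool:
        for s in self.sentences:
            if s.block_index == block_index and s.sentence_index == sentence_index:
                return s.discarded
        return True  # unknown sentences are unusable


def select_eye(left: PupilTrace, right: PupilTrace) -> PupilTrace:
    """Pick the analysis eye: the right eye by default, the left only when
    it has strictly more valid samples."""
    if left.n_valid == 0 and right.n_valid == 0:
        raise UnusableTraceError("both eyes fully invalid")
    if left.n_valid > right.n_valid:
        return left
    return right


def detect_blinks(
    trace: PupilTrace,
    window_samples: int = 1200,
    k: float = 3.0,
) -> list[Interval]:
    """Flag below-threshold samples and merge them into runs.

    Sample ``i`` is flagged iff ``diameter[i] < mean_w(i) - k * sd_w(i)``
    where the mean and (sample) SD are taken over the valid samples of the
    centered window containing ``i``, clipped at the trace edges.  Windows
    with fewer than two valid samples yield no flags.  Detection is a
    single pass: window statistics use the trace's original validity mask.
    """
    n = len(trace)
    if n < 2:
        return []
    w = window_samples
    if w > n:
        logger.info("blink window (%d) longer than trace (%d); shrunk", w, n)
        w = n
    half = w // 2
    v = trace.valid.astype(float)
    # shift by the global valid mean before accumulating: keeps the
    # running second moment free of catastrophic cancellation
    shift = float(trace.diameter[trace.valid].mean()) if trace.valid.any() else 0.0
    d = trace.diameter - shift
    dv = np.where(trace.valid, d, 0.0)
    # prefix sums with a leading zero for O(1) window statistics
    c1 = np.concatenate(([0.0], np.cumsum(v)))
    s1 = np.concatenate(([0.0], np.cumsum(dv)))
    s2 = np.concatenate(([0.0], np.cumsum(dv * dv)))
    idx = np.arange(n)
    lo = np.clip(idx - half, 0, n)
    hi = np.clip(idx - half + w, 0, n)
    cnt = c1[hi] - c1[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = (s1[hi] - s1[lo]) / cnt
        var = (s2[hi] - s2[lo] - cnt * mean**2) / (cnt - 1)
    var = np.maximum(var, 0.0)
    sd = np.sqrt(var)
    ok = cnt >= 2
    # 1e-9 mm guard absorbs prefix-sum rounding on megasample traces;
    # far below any physiological signal, so the strict inequality of the
    # rule (a constant window flags nothing) is preserved
    guard = 1e-9 * max(1.0, abs(shift))
    flagged = np.zeros(n, dtype=bool)
    flagged[ok] = d[ok] < (mean[ok] - k * sd[ok] - guard)
    return _mask_to_runs(flagged)


def _mask_to_runs(mask: np.ndarray) -> list[Interval]:
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def apply_margins(
    runs: list[Interval],
    pre: int = 77,
    post: int = 181,
    n: int | None = None,
) -> list[Interval]:
    """Widen each run by ``pre`` samples before and ``post`` after, clip to
    ``[0, n)`` and merge overlaps.  Result is sorted and non-overlapping."""
    if n is None:
        raise ValueError("trace length n is required for clipping")
    widened = sorted(
        (max(0, s - pre), min(n, e + post)) for s, e in runs
    )
    merged: list[Interval] = []
    for s, e in widened:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def intervals_to_mask(intervals: list[Interval], n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return mask


def interpolate(trace: PupilTrace, intervals: list[Interval]) -> PupilTrace:
    """Replace samples inside ``intervals`` (and previously-invalid
    samples) by linear interpolation between the nearest valid neighbours.

    Leading/trailing gaps take the nearest valid value.  The returned
    trace's ``valid`` mask records the *pre-interpolation* state, so the
    sentence-validity rule can still see what was measured vs filled.
    """
    out = trace.copy()
    n = len(out)
    invalid = ~trace.valid | intervals_to_mask(intervals, n)
    good = ~invalid
    if not good.any():
        raise UnusableTraceError("no valid samples to interpolate from")
    if invalid.any():
        xi = np.flatnonzero(good)
        out.diameter[invalid] = np.interp(
            np.flatnonzero(invalid), xi, trace.diameter[xi]
        )
    out.valid = good
    return out


def sentence_validity(
    trace: PupilTrace,
    schedule: SessionSchedule,
    cfg: PipelineConfig,
) -> ValidityLedger:
    """Apply the sentence-level filter.

    Each sentence's epoch is ``[onset - sentence_epoch_pre_s,
    offset + sentence_epoch_post_s)``; the percentage of valid samples is
    computed from the pre-interpolation mask and the sentence is discarded
    when it is strictly below ``sentence_valid_min_pct``.
    """
    ledger = ValidityLedger()
    n = len(trace)
    for block_index, sentence_index, s in schedule.sentence_epochs():
        i0, i1 = trace.window(
            s.sentence_onset_s - cfg.sentence_epoch_pre_s,
            s.sentence_offset_s + cfg.sentence_epoch_post_s,
        )
        if i0 < 0 or i1 > n or i1 <= i0:
            logger.warning(
                "sentence %d/%d epoch [%d, %d) outside trace; discarded",
                block_index, sentence_index, i0, i1,
            )
            ledger.sentences.append(SentenceValidity(
                block_index, sentence_index, 0.0, True))
            continue
        pct = 100.0 * float(trace.valid[i0:i1].mean())
        ledger.sentences.append(SentenceValidity(
            block_index, sentence_index, pct,
            discarded=pct < cfg.sentence_valid_min_pct,
        ))
    return ledger


def participant_filter(ledger: ValidityLedger, cfg: PipelineConfig) -> ValidityLedger:
    """Apply the participant-level filter: excluded iff strictly more than
    ``participant_missing_max_pct`` of the sentences were discarded."""
    total = len(ledger.sentences)
    pct = 100.0 * ledger.n_discarded / total if total else 100.0
    ledger.pct_sentences_missing = pct
    ledger.excluded = pct > cfg.participant_missing_max_pct
    return ledger


def run_preprocess(
    left: PupilTrace,
    right: PupilTrace,
    schedule: SessionSchedule,
    cfg: PipelineConfig,
) -> tuple[PupilTrace, ValidityLedger]:
    """Run the full cleaning pipeline for one participant.

    Returns the cleaned (interpolated) trace of the selected eye, whose
    ``valid`` mask is the pre-interpolation validity, and the filled-in
    :class:`ValidityLedger`.
    """
    trace = select_eye(left, right)
    runs = detect_blinks(trace, cfg.window_samples, cfg.sd_k)
    intervals = apply_margins(runs, cfg.pre_margin, cfg.post_margin, len(trace))
    cleaned = interpolate(trace, intervals)
    ledger = sentence_validity(cleaned, schedule, cfg)
    ledger = participant_filter(ledger, cfg)
    return cleaned, ledger
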