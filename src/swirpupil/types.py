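"""Core data containers shared by every pipeline stage.

Conventions used throughout the package:

* timestamps are stored internally in microseconds, exposed in seconds;
* sample indices are 0-based;
* every sample window is half-open ``[start, end)``;
* pupil diameter is in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PupilTrace",
    "SentenceSchedule",
    "BlockSchedule",
    "SessionSchedule",
    "ParticipantRecord",
    "BlockRecord",
    "FormatError",
    "UnusableTraceError",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared layout."""


class UnusableTraceError(RuntimeError):
    """Raised when a participant's pupil data cannot be used at all
    (e.g. both eyes fully invalid, or no valid sample to interpolate from)."""


@dataclass
class PupilTrace:
    """One eye's pupil-diameter samples over a session.

    Parameters
    ----------
    diameter
        Pupil diameter in mm, one value per sample. Invalid samples may
        hold a sentinel (e.g. 0 or NaN); they are never used in statistics.
    valid
        Boolean mask aligned to ``diameter``; True where the tracker
        reported a usable sample.
    sample_rate
        Sampling frequency in Hz.
    t0_s
        Session time of sample 0, in seconds.
    eye
        ``"left"`` or ``"right"``.
    """

    diameter: np.ndarray
    valid: np.ndarray
    sample_rate: float = 1200.0
    t0_s: float = 0.0
    eye: str = "right"

    def __post_init__(self) -> None:
        self.diameter = np.asarray(self.diameter, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.diameter.shape != self.valid.shape:
            raise ValueError("diameter and valid must have equal length")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.eye not in ("left", "right"):
            raise ValueError(f"eye must be 'left' or 'right', got {self.eye!r}")

    def __len__(self) -> int:
        return self.diameter.shape[0]

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def index_at(self, t_s: float) -> int:
        """Sample index of session time ``t_s`` (rounded to nearest sample)."""
        return int(round((t_s - self.t0_s) * self.sample_rate))

    def window(self, start_s: float, end_s: float) -> tuple[int, int]:
        """Half-open sample window ``[i0, i1)`` for ``[start_s, end_s)``."""
        return self.index_at(start_s), self.index_at(end_s)

    def copy(self) -> "PupilTrace":
        return PupilTrace(
            diameter=self.diameter.copy(),
            valid=self.valid.copy(),
            sample_rate=self.sample_rate,
            t0_s=self.t0_s,
            eye=self.eye,
        )


@dataclass
class SentenceSchedule:
    """Timing of one sentence presentation, in session seconds.

    The background noise leads the sentence (3 s for the first sentence of
    a block, 1 s otherwise) and trails it by 1 s.
    """

    noise_onset_s: float
    sentence_onset_s: float
    sentence_offset_s: float
    noise_offset_s: float

    def validate(self) -> None:
        t = (
            self.noise_onset_s,
            self.sentence_onset_s,
            self.sentence_offset_s,
            self.noise_offset_s,
        )
        if not all(a < b for a, b in zip(t, t[1:])):
            raise FormatError(f"sentence times must be strictly increasing: {t}")


@dataclass
class BlockSchedule:
    """Structure of one test block: seven sentences, a retention interval,
    a beep cueing free recall, the recall window, then a short break."""

    block_index: int
    sentences: list[SentenceSchedule]
    retention_onset_s: float
    beep_s: float
    recall_end_s: float
    break_end_s: float

    def validate(self) -> None:
        for s in self.sentences:
            s.validate()
        times = [t for s in self.sentences
                 for t in (s.noise_onset_s, s.sentence_onset_s,
                           s.sentence_offset_s, s.noise_offset_s)]
        times += [self.retention_onset_s, self.beep_s,
                  self.recall_end_s, self.break_end_s]
        if not all(a < b for a, b in zip(times, times[1:])):
            raise FormatError(
                f"block {self.block_index}: times must be strictly increasing"
            )


@dataclass
class SessionSchedule:
    """Full session timing: a list of blocks (28 by default)."""

    blocks: list[BlockSchedule] = field(default_factory=list)

    def validate(self) -> None:
        prev_end = -np.inf
        for b in self.blocks:
            b.validate()
            if b.sentences[0].noise_onset_s < prev_end:
                raise FormatError("blocks must not overlap")
            prev_end = b.break_end_s

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_sentences(self) -> int:
        return sum(len(b.sentences) for b in self.blocks)

    def sentence_epochs(self) -> list[tuple[int, int, SentenceSchedule]]:
        """(block_index, sentence_index 1-based, schedule) for all sentences."""
        return [
            (b.block_index, j + 1, s)
            for b in self.blocks
            for j, s in enumerate(b.sentences)
        ]


@dataclass
class ParticipantRecord:
    """Participant-level covariates and inclusion status.

    rs_score is the Reading Span score in percent correct (working-memory
    capacity); snr_db the individualized signal-to-noise ratio of the
    session; pta_db_hl the pure-tone average (0.5/1/2/4 kHz).
    """

    id: str
    rs_score: float
    snr_db: float
    age: float = float("nan")
    pta_db_hl: float = float("nan")
    included: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.rs_score <= 100.0:
            raise ValueError(f"rs_score must be in [0, 100], got {self.rs_score}")


@dataclass
class BlockRecord:
    """Per-block derived outcomes: the pupil baseline (mean over the used
    sentence baselines, mm) and the recall performance (percent)."""

    participant: str
    block_index: int
    pupil_baseline_mm: float
    n_sentences_used: int
    recall_pct: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_sentences_used <= 7:
            raise ValueError("n_sentences_used must be in 0..7")
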