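"""Readers and writers for the pipeline's plain-text formats.

* ``samples.tsv`` — eye-tracker sample stream: ``time_us``,
  ``pupil_left_mm``, ``pupil_right_mm``, ``valid_left``, ``valid_right``.
* ``events.tsv`` — session schedule, one row per sentence with the
  block-level times repeated.
* ``participants.csv`` / ``blocks.csv`` — covariate and outcome tables.
* ``report.json`` — a fitted model's coefficients, confidence intervals,
  chi-square table, R2, VIF and elimination trail.

All tabular I/O goes through pandas; round trips are lossless for every
field the pipeline consumes.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from swirpupil.types import (
    BlockRecord,
    BlockSchedule,
    FormatError,
    ParticipantRecord,
    PupilTrace,
    SentenceSchedule,
    SessionSchedule,
)

logger = logging.getLogger("swirpupil")

__all__ = [
    "read_samples", "write_samples",
    "read_events", "write_events",
    "read_participants", "write_participants",
    "read_block_table", "write_block_table",
    "write_report",
]

SAMPLE_COLUMNS = ["time_us", "pupil_left_mm", "pupil_right_mm",
                  "valid_left", "valid_right"]
EVENT_COLUMNS = ["block", "sentence_index", "noise_onset_s", "sentence_onset_s",
                 "sentence_offset_s", "noise_offset_s", "retention_onset_s",
                 "beep_s", "recall_end_s", "break_end_s"]
BLOCK_COLUMNS = ["participant", "block", "pupil_baseline_mm",
                 "n_sentences_used", "recall_pct"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")


# ---------------------------------------------------------------------------
# sample streams


def read_samples(path: str | Path) -> tuple[PupilTrace, PupilTrace]:
    """Read a tab-separated sample stream into (left, right) traces.

    Timestamps must be strictly increasing; the sample rate is inferred
    from the median timestamp step.  Rows with unparseable fields are
    dropped, counted and logged.
    """
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, SAMPLE_COLUMNS, path)
    n_raw = len(df)
    df = df.apply(pd.to_numeric, errors="coerce").dropna()
    n_bad = n_raw - len(df)
    if n_bad:
        logger.warning("%s: dropped %d malformed rows", path, n_bad)
    if len(df) == 0:
        raise FormatError(f"{path}: no parseable sample rows")
    t = df["time_us"].to_numpy(dtype=np.int64)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise FormatError(f"{path}: timestamps must be strictly increasing")
    if len(t) > 1:
        # overall span, not per-step median: individual steps carry
        # integer-microsecond rounding (833/834 us at 1,200 Hz)
        rate = 1e6 * (len(t) - 1) / float(t[-1] - t[0])
    else:
        rate = 1200.0
    t0_s = float(t[0]) / 1e6
    left = PupilTrace(
        diameter=df["pupil_left_mm"].to_numpy(dtype=float),
        valid=df["valid_left"].to_numpy(dtype=float) != 0,
        sample_rate=rate, t0_s=t0_s, eye="left",
    )
    right = PupilTrace(
        diameter=df["pupil_right_mm"].to_numpy(dtype=float),
        valid=df["valid_right"].to_numpy(dtype=float) != 0,
        sample_rate=rate, t0_s=t0_s, eye="right",
    )
    return left, right


def write_samples(path: str | Path, left: PupilTrace, right: PupilTrace) -> None:
    if len(left) != len(right):
        raise ValueError("left and right traces must be aligned")
    n = len(left)
    t_us = (left.t0_s * 1e6 + np.arange(n) * 1e6 / left.sample_rate)
    pd.DataFrame({
        "time_us": np.round(t_us).astype(np.int64),
        "pupil_left_mm": left.diameter,
        "pupil_right_mm": right.diameter,
        "valid_left": left.valid.astype(int),
        "valid_right": right.valid.astype(int),
    }).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# event tables


def read_events(path: str | Path) -> SessionSchedule:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, EVENT_COLUMNS, path)
    blocks: list[BlockSchedule] = []
    for block_idx, grp in df.groupby("block", sort=True):
        grp = grp.sort_values("sentence_index")
        sentences = [
            SentenceSchedule(
                noise_onset_s=row.noise_onset_s,
                sentence_onset_s=row.sentence_onset_s,
                sentence_offset_s=row.sentence_offset_s,
                noise_offset_s=row.noise_offset_s,
            )
            for row in grp.itertuples()
        ]
        first = grp.iloc[0]
        blocks.append(BlockSchedule(
            block_index=int(block_idx),
            sentences=sentences,
            retention_onset_s=float(first.retention_onset_s),
            beep_s=float(first.beep_s),
            recall_end_s=float(first.recall_end_s),
            break_end_s=float(first.break_end_s),
        ))
    schedule = SessionSchedule(blocks=blocks)
    schedule.validate()
    return schedule


def write_events(path: str | Path, schedule: SessionSchedule) -> None:
    rows = []
    for b in schedule.blocks:
        for j, s in enumerate(b.sentences, start=1):
            rows.append({
                "block": b.block_index,
                "sentence_index": j,
                "noise_onset_s": s.noise_onset_s,
                "sentence_onset_s": s.sentence_onset_s,
                "sentence_offset_s": s.sentence_offset_s,
                "noise_offset_s": s.noise_offset_s,
                "retention_onset_s": b.retention_onset_s,
                "beep_s": b.beep_s,
                "recall_end_s": b.recall_end_s,
                "break_end_s": b.break_end_s,
            })
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# participant and block tables


def read_participants(path: str | Path) -> list[ParticipantRecord]:
    df = pd.read_csv(path)
    _require_columns(df, ["id", "rs_score", "snr_db"], path)
    records = []
    for row in df.itertuples():
        records.append(ParticipantRecord(
            id=str(row.id),
            rs_score=float(row.rs_score),
            snr_db=float(row.snr_db),
            age=float(getattr(row, "age", np.nan)),
            pta_db_hl=float(getattr(row, "pta_db_hl", np.nan)),
            included=bool(getattr(row, "included", True)),
        ))
    return records


def write_participants(path: str | Path, records: list[ParticipantRecord]) -> None:
    pd.DataFrame([{
        "id": r.id, "rs_score": r.rs_score, "snr_db": r.snr_db,
        "age": r.age, "pta_db_hl": r.pta_db_hl, "included": r.included,
    } for r in records]).to_csv(path, index=False)


def read_block_table(path: str | Path) -> list[BlockRecord]:
    df = pd.read_csv(path)
    _require_columns(df, BLOCK_COLUMNS, path)
    return [
        BlockRecord(
            participant=str(r.participant),
            block_index=int(r.block),
            pupil_baseline_mm=float(r.pupil_baseline_mm),
            n_sentences_used=int(r.n_sentences_used),
            recall_pct=float(r.recall_pct),
        )
        for r in df.itertuples()
    ]


def write_block_table(path: str | Path, records: list[BlockRecord]) -> None:
    pd.DataFrame([{
        "participant": r.participant,
        "block": r.block_index,
        "pupil_baseline_mm": r.pupil_baseline_mm,
        "n_sentences_used": r.n_sentences_used,
        "recall_pct": r.recall_pct,
    } for r in records], columns=BLOCK_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# model reports


def write_report(path: str | Path, report: dict) -> None:
    """Serialize a model report (see mixed_model.build_report) to JSON."""

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=1, default=_default))
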