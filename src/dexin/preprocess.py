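"""Baseline correction and per-trial peak-force extraction.

The resting baseline force on each finger at the start of each trial (mean
over the final 200 ms before the go-cue) is subtracted from the whole trace;
the per-channel peak is then the maximum signed force over the response
window (go-cue to trial end).  Flexion is positive, so peaks of uninstructed
fingers may be slightly negative when a finger relaxes instead of co-
contracting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CHANNELS, ForceTrial, SubjectRecord, channel_index

__all__ = [
    "BASELINE_WINDOW_S",
    "TARGET_ZONE_FRACTION",
    "PeakRecord",
    "PeakTable",
    "baseline_correct",
    "extract_peaks",
    "build_peak_table",
]

logger = logging.getLogger(__name__)

#: Baseline window: final 200 ms of the preparation phase.
BASELINE_WINDOW_S = 0.2
#: Target zone half-width as a fraction of the target force (target +/- 25%).
TARGET_ZONE_FRACTION = 0.25


@dataclass
class PeakRecord:
    """Baseline-corrected peak force on all 10 fingers for one trial."""

    subject_id: str
    block: int
    trial: int
    instructed_hand: str
    instructed_finger: str
    target_level: float
    baseline: np.ndarray  # (10,) resting force at trial start, N
    peak: np.ndarray      # (10,) baseline-corrected peak force, N
    in_target_zone: bool = False

    @property
    def instructed_peak(self) -> float:
        return float(self.peak[channel_index(self.instructed_hand,
                                             self.instructed_finger)])


@dataclass
class PeakTable:
    """All peak records of one subject, ordered by (block, trial)."""

    subject_id: str
    records: list[PeakRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def filter(self, *, hand: str | None = None, finger: str | None = None,
               blocks: set[int] | None = None) -> "PeakTable":
        """Subset by instructed hand/finger and/or block membership."""
        recs = [
            r for r in self.records
            if (hand is None or r.instructed_hand == hand)
            and (finger is None or r.instructed_finger == finger)
            and (blocks is None or r.block in blocks)
        ]
        return PeakTable(self.subject_id, recs)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "subject_id": r.subject_id, "block": r.block, "trial": r.trial,
                "instructed_hand": r.instructed_hand,
                "instructed_finger": r.instructed_finger,
                "target_level": r.target_level,
                "in_target_zone": r.in_target_zone,
            }
            row.update({f"peak_{c}": r.peak[i] for i, c in enumerate(CHANNELS)})
            row.update({f"baseline_{c}": r.baseline[i] for i, c in enumerate(CHANNELS)})
            rows.append(row)
        return pd.DataFrame(rows)


def _baseline(trial: ForceTrial) -> np.ndarray:
    n_window = int(round(BASELINE_WINDOW_S * trial.sample_rate))
    start = trial.go_cue - n_window
    if start < 0:
        logger.warning(
            "subject %s block %d trial %d: preparation shorter than the "
            "%g ms baseline window; truncating",
            trial.subject_id, trial.block, trial.trial, 1e3 * BASELINE_WINDOW_S,
        )
        start = 0
    if trial.go_cue == 0:
        return np.zeros(10)
    return np.asarray(trial.forces[start:trial.go_cue]).mean(axis=0)


def baseline_correct(trial: ForceTrial) -> np.ndarray:
    """Return the force matrix with each channel's resting baseline removed.

    The baseline is the per-channel mean over the last 200 ms before the
    go-cue (truncated, with a warning, if the preparation phase is shorter).
    """
    return np.asarray(trial.forces, dtype=float) - _baseline(trial)[None, :]


def extract_peaks(trial: ForceTrial) -> PeakRecord:
    """Baseline-corrected peak force per channel over the response window.

    The peak is the maximum *signed* force (flexion positive).  The target-
    zone flag records whether the instructed peak landed within +/-25% of
    the nominal target; trials outside the zone are flagged but never
    dropped here.
    """
    if trial.end <= trial.go_cue:
        raise ValueError(
            f"subject {trial.subject_id} block {trial.block} trial {trial.trial}: "
            "empty response window"
        )
    corrected = baseline_correct(trial)
    peaks = corrected[trial.go_cue:trial.end].max(axis=0)
    return PeakRecord(
        subject_id=trial.subject_id, block=trial.block, trial=trial.trial,
        instructed_hand=trial.instructed_hand,
        instructed_finger=trial.instructed_finger,
        target_level=trial.target_level,
        baseline=_baseline(trial), peak=peaks,
    )


def build_peak_table(subject: SubjectRecord,
                     target_forces: np.ndarray | None = None) -> PeakTable:
    """One :class:`PeakRecord` per trial, ordered by (block, trial).

    Target-zone flags are evaluated against ``target_level * MVC`` of the
    instructed finger (``subject.mvc`` unless ``target_forces`` overrides).
    """
    mvc = np.asarray(subject.mvc if target_forces is None else target_forces, float)
    records = []
    for trial in sorted(subject.trials, key=lambda t: (t.block, t.trial)):
        rec = extract_peaks(trial)
        target = trial.target_level * mvc[trial.instructed_channel]
        rec.in_target_zone = bool(
            abs(rec.instructed_peak - target) <= TARGET_ZONE_FRACTION * target
        )
        records.append(rec)
    return PeakTable(subject.subject_id, records)
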