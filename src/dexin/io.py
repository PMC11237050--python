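"""Cohort data model and on-disk formats.

A study cohort is a set of subjects (musicians, patient or control), each
with a per-finger maximum voluntary contraction (MVC), an optional map of
clinically symptomatic fingers, and a list of isometric force trials.  Each
trial records the forces on all 10 fingertips (both hands) sampled at
200 Hz while one instructed finger pressed to a fraction of its MVC.

On disk a cohort is a ``subjects.json`` manifest plus one tidy trace CSV
per subject (one row per sample, wide across the 10 force channels).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HANDS",
    "FINGERS",
    "CHANNELS",
    "FINGER_NAMES",
    "TARGET_LEVELS",
    "SAMPLE_RATE",
    "FORCE_RANGE",
    "ForceTrial",
    "SubjectRecord",
    "Cohort",
    "ValidationError",
    "CohortLoadError",
    "channel_index",
    "validate_trial",
    "read_cohort",
    "write_cohort",
]

HANDS = ("L", "R")
FINGERS = ("D1", "D2", "D3", "D4", "D5")
#: Channel order used for every 10-column force matrix in the package.
CHANNELS = tuple(f"{h}_{d}" for h in HANDS for d in FINGERS)
#: Anatomical names for the digit codes (D1 = thumb ... D5 = little finger).
FINGER_NAMES = {
    "D1": "thumb",
    "D2": "index",
    "D3": "middle",
    "D4": "ring",
    "D5": "little",
}
TARGET_LEVELS = (0.25, 0.50, 0.75)
SAMPLE_RATE = 200.0
#: Transducer dynamic range is 0-25 N; a small negative margin is allowed
#: for sensor noise around the resting baseline.
FORCE_RANGE = (-1.0, 25.0)


class ValidationError(ValueError):
    """A trial or subject violates a data-model invariant."""


class CohortLoadError(OSError):
    """A manifest or trace file could not be read."""


def channel_index(hand: str, finger: str) -> int:
    """Column index of a (hand, finger) channel in the 10-wide force matrix."""
    return HANDS.index(hand) * 5 + FINGERS.index(finger)


def parse_finger_code(code: str) -> tuple[str, str]:
    """Parse an ``"R-D3"``-style hand-finger code into ``("R", "D3")``."""
    hand, _, finger = code.partition("-")
    if hand not in HANDS or finger not in FINGERS:
        raise ValidationError(f"invalid hand-finger code {code!r}")
    return hand, finger


@dataclass
class ForceTrial:
    """One trial: a time x 10 matrix of fingertip forces plus design metadata.

    ``forces`` columns follow :data:`CHANNELS` (L-D1..L-D5, R-D1..R-D5).
    ``go_cue`` / ``end`` are 0-based sample indices bracketing the response
    window; samples before ``go_cue`` are the preparation phase.
    """

    subject_id: str
    block: int
    trial: int
    instructed_hand: str
    instructed_finger: str
    target_level: float
    forces: np.ndarray
    go_cue: int
    end: int
    sample_rate: float = SAMPLE_RATE

    @property
    def instructed_channel(self) -> int:
        return channel_index(self.instructed_hand, self.instructed_finger)

    @property
    def n_samples(self) -> int:
        return self.forces.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds from trial start."""
        return np.arange(self.n_samples) / self.sample_rate


@dataclass
class SubjectRecord:
    """A participant: group membership, MVCs, symptom map and all trials."""

    subject_id: str
    group: str  # "patient" | "control"
    handedness: str = "R"
    mvc: np.ndarray = field(default_factory=lambda: np.full(10, 20.0))
    symptom_map: frozenset[tuple[str, str]] = frozenset()
    severity: float | None = None
    duration_years: float | None = None
    age: float | None = None
    gender: str | None = None
    instrument: str | None = None
    trials: list[ForceTrial] = field(default_factory=list)

    def symptomatic_fingers(self, hand: str) -> set[str]:
        """Symptomatic digits of one hand, e.g. ``{"D3", "D4"}``."""
        return {f for h, f in self.symptom_map if h == hand}


@dataclass
class Cohort:
    """All subjects of one study run plus free-text provenance."""

    subjects: list[SubjectRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValidationError("subject_ids are not unique")

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)

    def by_group(self, group: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == group]

    @property
    def patients(self) -> list[SubjectRecord]:
        return self.by_group("patient")

    @property
    def controls(self) -> list[SubjectRecord]:
        return self.by_group("control")


# ---------------------------------------------------------------------------
# validation

def validate_trial(trial: ForceTrial) -> list[str]:
    """Check a trial against the data-model invariants.

    Returns a list of human-readable issues; an empty list means the trial
    is well formed.  Used by the loader and available for ad-hoc QC.
    """
    issues: list[str] = []
    if trial.sample_rate != SAMPLE_RATE:
        issues.append(f"sample_rate: expected {SAMPLE_RATE:g} Hz, got {trial.sample_rate:g}")
    if trial.instructed_hand not in HANDS:
        issues.append(f"instructed_hand: {trial.instructed_hand!r} not in {HANDS}")
    if trial.instructed_finger not in FINGERS:
        issues.append(f"instructed_finger: {trial.instructed_finger!r} not in {FINGERS}")
    if not any(np.isclose(trial.target_level, lv) for lv in TARGET_LEVELS):
        issues.append(f"target_level: {trial.target_level} not in {TARGET_LEVELS}")
    if trial.block < 1:
        issues.append(f"block: must be >= 1, got {trial.block}")
    if trial.trial < 1:
        issues.append(f"trial: must be >= 1, got {trial.trial}")
    f = np.asarray(trial.forces)
    if f.ndim != 2 or f.shape[1] != 10:
        issues.append(f"forces: expected (n, 10) matrix, got shape {f.shape}")
    else:
        lo, hi = FORCE_RANGE
        if f.size and (f.min() < lo or f.max() > hi):
            issues.append(
                f"forces: samples outside transducer range [{lo:g}, {hi:g}] N "
                f"(observed [{f.min():.3g}, {f.max():.3g}])"
            )
        if not (0 <= trial.go_cue < trial.end <= f.shape[0]):
            issues.append(
                f"phase_marks: need 0 <= go_cue < end <= n_samples, "
                f"got go_cue={trial.go_cue}, end={trial.end}, n={f.shape[0]}"
            )
    return issues


def validate_subject(subject: SubjectRecord) -> list[str]:
    issues: list[str] = []
    if subject.group not in ("patient", "control"):
        issues.append(f"group: {subject.group!r} not in ('patient', 'control')")
    if subject.group == "control" and subject.symptom_map:
        issues.append("symptom_map: controls must have an empty symptom map")
    mvc = np.asarray(subject.mvc, dtype=float)
    if mvc.shape != (10,):
        issues.append(f"mvc: expected 10 values, got shape {mvc.shape}")
    elif not np.all(mvc > 0):
        issues.append("mvc: all per-finger MVCs must be > 0")
    for t in subject.trials:
        for issue in validate_trial(t):
            issues.append(f"block {t.block} trial {t.trial}: {issue}")
    return issues


# ---------------------------------------------------------------------------
# on-disk format

_TRACE_COLUMNS = [
    "block", "trial", "instructed_hand", "instructed_finger",
    "target_level", "go_cue", "trial_end", "time_s", *CHANNELS,
]


def _subject_to_manifest(subject: SubjectRecord, trace_file: str) -> dict:
    return {
        "subject_id": subject.subject_id,
        "group": subject.group,
        "handedness": subject.handedness,
        "mvc": [float(v) for v in subject.mvc],
        "symptom_map": sorted(f"{h}-{d}" for h, d in subject.symptom_map),
        "severity": subject.severity,
        "duration_years": subject.duration_years,
        "age": subject.age,
        "gender": subject.gender,
        "instrument": subject.instrument,
        "trace_file": trace_file,
    }


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a cohort as ``subjects.json`` plus one trace CSV per subject.

    Row order within a CSV is (block, trial, sample); column order is fixed.
    Force values are written with full round-trip precision so that
    ``read_cohort(write_cohort(c))`` reproduces every sample bit-exactly.
    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"provenance": cohort.provenance, "subjects": []}
    for subject in cohort.subjects:
        trace_file = f"{subject.subject_id}_traces.csv"
        manifest["subjects"].append(_subject_to_manifest(subject, trace_file))
        frames = []
        for t in sorted(subject.trials, key=lambda t: (t.block, t.trial)):
            df = pd.DataFrame(np.asarray(t.forces, dtype=float), columns=list(CHANNELS))
            df.insert(0, "time_s", t.times)
            df.insert(0, "trial_end", t.end)
            df.insert(0, "go_cue", t.go_cue)
            df.insert(0, "target_level", t.target_level)
            df.insert(0, "instructed_finger", t.instructed_finger)
            df.insert(0, "instructed_hand", t.instructed_hand)
            df.insert(0, "trial", t.trial)
            df.insert(0, "block", t.block)
            frames.append(df)
        if frames:
            table = pd.concat(frames, ignore_index=True)
        else:
            table = pd.DataFrame(columns=_TRACE_COLUMNS)
        table.to_csv(out_dir / trace_file, index=False, float_format="%.17g")
    manifest_path = out_dir / "subjects.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def _trial_from_rows(subject_id: str, key, rows: pd.DataFrame) -> ForceTrial:
    block, trial = key
    rows = rows.sort_values("time_s")
    forces = rows[list(CHANNELS)].to_numpy(dtype=float)
    first = rows.iloc[0]
    t = ForceTrial(
        subject_id=subject_id,
        block=int(block),
        trial=int(trial),
        instructed_hand=str(first["instructed_hand"]),
        instructed_finger=str(first["instructed_finger"]),
        target_level=float(first["target_level"]),
        forces=forces,
        go_cue=int(first["go_cue"]),
        end=int(first["trial_end"]),
    )
    issues = validate_trial(t)
    if issues:
        raise ValidationError(
            f"subject {subject_id}, block {t.block}, trial {t.trial}: " + "; ".join(issues)
        )
    return t


def read_cohort(manifest_path: str | Path) -> Cohort:
    """Load a cohort from a ``subjects.json`` manifest.

    Trials are validated against the :class:`ForceTrial` invariants and
    sorted by (block, trial); partial designs load without error.  A missing
    trace file raises :class:`CohortLoadError` naming the file; an invariant
    violation raises :class:`ValidationError` naming subject/trial/field.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise CohortLoadError(f"manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    subjects = []
    for entry in manifest.get("subjects", []):
        sid = entry["subject_id"]
        trace_path = manifest_path.parent / entry["trace_file"]
        if not trace_path.exists():
            raise CohortLoadError(f"trace file not found for subject {sid}: {trace_path}")
        table = pd.read_csv(trace_path, float_precision="round_trip")
        trials = [
            _trial_from_rows(sid, key, rows)
            for key, rows in table.groupby(["block", "trial"], sort=True)
        ]
        trials.sort(key=lambda t: (t.block, t.trial))
        subject = SubjectRecord(
            subject_id=sid,
            group=entry["group"],
            handedness=entry.get("handedness", "R"),
            mvc=np.asarray(entry["mvc"], dtype=float),
            symptom_map=frozenset(parse_finger_code(c) for c in entry.get("symptom_map", [])),
            severity=entry.get("severity"),
            duration_years=entry.get("duration_years"),
            age=entry.get("age"),
            gender=entry.get("gender"),
            instrument=entry.get("instrument"),
            trials=trials,
        )
        issues = validate_subject(subject)
        if issues:
            raise ValidationError(f"subject {sid}: " + "; ".join(issues))
        subjects.append(subject)
    return Cohort(subjects=subjects, provenance=manifest.get("provenance", str(manifest_path)))
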