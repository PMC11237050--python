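"""Split-half reliability and cross-validated between-group pattern similarity.

Reliability: a subject's pattern is estimated separately from odd-numbered
and even-numbered blocks and the valid cells are correlated (Pearson)
across the two halves.  Group summaries average per-subject correlations on
the Fisher-Z scale and back-transform.

Similarity: each patient's pattern is correlated with the average control
pattern; each control's pattern is correlated with the average over the
*other* controls (leave-one-out, avoiding the positive bias of correlating
a pattern with an average that contains it).  Fisher-Z transformed
similarities are compared between groups with a pooled-variance two-sample
t-test: a null result means patients deviate from the normative pattern no
more than controls do, even if their overall coupling magnitude differs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import Cohort, SubjectRecord
from .metrics import SlopePattern, enslaving_pattern, mirroring_pattern
from .preprocess import PeakTable, build_peak_table

__all__ = [
    "ReliabilityResult",
    "SimilarityResult",
    "split_half_reliability",
    "group_reliability",
    "crossval_pattern_similarity",
]

logger = logging.getLogger(__name__)

#: Correlations are clamped to +/-(1 - 1e-6) before atanh so degenerate
#: perfect correlations keep a finite Fisher Z.
R_CLAMP = 1.0 - 1e-6


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    return np.arctanh(np.clip(r, -R_CLAMP, R_CLAMP))


def pooled_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pooled-variance two-sample t.  Degenerate zero-variance samples with
    equal means (e.g. every subject has the identical pattern) yield
    t = 0, p = 1 instead of NaN."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size and b.size and a.std() == 0 and b.std() == 0 \
            and np.isclose(a.mean(), b.mean()):
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def _estimate_pattern(peaks: PeakTable, kind: str, context: str) -> SlopePattern:
    if kind == "enslaving":
        return enslaving_pattern(peaks, context)
    if kind == "mirroring":
        return mirroring_pattern(peaks, context)
    raise ValueError(f"kind must be 'enslaving' or 'mirroring', got {kind!r}")


def subject_pattern(subject: SubjectRecord, kind: str, context: str,
                    blocks: set[int] | None = None) -> SlopePattern:
    """Estimate one subject's pattern, optionally from a subset of blocks.

    ``context`` is the instructed hand for enslaving, the active hand for
    mirroring.
    """
    peaks = build_peak_table(subject).filter(blocks=blocks)
    return _estimate_pattern(peaks, kind, context)


def split_half_reliability(subject: SubjectRecord, kind: str,
                           context: str) -> float:
    """Pearson correlation of pattern cells estimated from odd vs even blocks.

    Block parity is taken from the 1-based block index.  Cells invalid in
    either half are excluded pairwise; fewer than 3 common cells is an error.
    """
    blocks = {t.block for t in subject.trials}
    odd = {b for b in blocks if b % 2 == 1}
    even = blocks - odd
    if not odd or not even:
        raise ValueError(
            f"subject {subject.subject_id}: need at least one odd and one "
            "even block for a split-half estimate")
    p_odd = subject_pattern(subject, kind, context, blocks=odd)
    p_even = subject_pattern(subject, kind, context, blocks=even)
    common = p_odd.valid & p_even.valid
    if common.sum() < 3:
        raise ValueError(
            f"subject {subject.subject_id}: only {int(common.sum())} cells "
            "valid in both halves")
    r = np.corrcoef(p_odd.cells[common], p_even.cells[common])[0, 1]
    return float(r)


@dataclass
class ReliabilityResult:
    """Group split-half reliability with a 95% CI (Fisher-Z pooled)."""

    kind: str
    context: str
    subject_r: dict[str, float]
    mean_r: float
    ci_low: float
    ci_high: float


def group_reliability(subjects: list[SubjectRecord], kind: str,
                      context: str) -> ReliabilityResult:
    """Average split-half reliability across subjects.

    Per-subject correlations are Fisher-Z transformed, averaged, and the
    mean +/- 1.96 standard errors (of Z across subjects) is back-transformed
    to the r scale.
    """
    if len(subjects) < 2:
        raise ValueError("group reliability needs >= 2 subjects")
    subject_r = {s.subject_id: split_half_reliability(s, kind, context)
                 for s in subjects}
    z = np.array([fisher_z(r) for r in subject_r.values()])
    z_mean = z.mean()
    z_se = z.std(ddof=1) / np.sqrt(len(z))
    return ReliabilityResult(
        kind=kind, context=context, subject_r=subject_r,
        mean_r=float(np.tanh(z_mean)),
        ci_low=float(np.tanh(z_mean - 1.96 * z_se)),
        ci_high=float(np.tanh(z_mean + 1.96 * z_se)),
    )


@dataclass
class SimilarityResult:
    """Cross-validated pattern similarity, patients vs controls."""

    kind: str
    context: str
    subject_r: dict[str, float]   # per-subject similarity to control average
    subject_group: dict[str, str]
    mean_patient_r: float         # Fisher-Z mean of patient similarities, back-transformed
    mean_control_r: float
    t: float
    df: int
    p: float


def _pattern_similarities(patterns: dict[str, SlopePattern],
                          groups: dict[str, str]) -> dict[str, float]:
    controls = [sid for sid, g in groups.items() if g == "control"]
    valid_mask = None
    for p in patterns.values():
        valid_mask = p.valid if valid_mask is None else (valid_mask & p.valid)
    if valid_mask.sum() < 3:
        raise ValueError("fewer than 3 cells valid across all subjects")
    sims: dict[str, float] = {}
    control_stack = {sid: patterns[sid].cells[valid_mask] for sid in controls}
    for sid, pattern in patterns.items():
        own = pattern.cells[valid_mask]
        others = [v for cid, v in control_stack.items() if cid != sid]
        reference = np.mean(others, axis=0)
        if np.std(own) == 0 or np.std(reference) == 0:
            logger.warning("subject %s: zero-variance pattern, excluded from "
                           "similarity analysis", sid)
            continue
        sims[sid] = float(np.corrcoef(own, reference)[0, 1])
    return sims


def crossval_pattern_similarity(cohort: Cohort, kind: str,
                                context: str,
                                patterns: dict[str, SlopePattern] | None = None,
                                ) -> SimilarityResult:
    """Compare patients' and controls' similarity to the normative pattern.

    ``patterns`` may carry pre-computed per-subject patterns (keyed by
    subject id); otherwise they are estimated from the cohort's trials.
    """
    if len(cohort.controls) < 2 or len(cohort.patients) < 1:
        raise ValueError("similarity analysis needs >= 2 controls and >= 1 patient")
    groups = {s.subject_id: s.group for s in cohort}
    if patterns is None:
        patterns = {s.subject_id: subject_pattern(s, kind, context) for s in cohort}
    sims = _pattern_similarities(patterns, groups)
    z_pat = np.array([fisher_z(r) for sid, r in sims.items()
                      if groups[sid] == "patient"])
    z_con = np.array([fisher_z(r) for sid, r in sims.items()
                      if groups[sid] == "control"])
    if z_pat.size < 1 or z_con.size < 2:
        raise ValueError(
            "similarity t-test needs >= 1 patient and >= 2 control values "
            f"after exclusions (got {z_pat.size} and {z_con.size})")
    t, p = pooled_ttest(z_pat, z_con)
    return SimilarityResult(
        kind=kind, context=context, subject_r=sims,
        subject_group={sid: groups[sid] for sid in sims},
        mean_patient_r=float(np.tanh(z_pat.mean())),
        mean_control_r=float(np.tanh(z_con.mean())),
        t=float(t), df=len(z_pat) + len(z_con) - 2, p=float(p),
    )
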