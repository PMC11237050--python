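"""Group contrasts and symptomatic-finger analyses.

All tests run on per-subject summaries of the log-slope patterns:

* patients-vs-controls contrasts of mean enslaving/mirroring log-slopes
  (pooled-variance two-sample t);
* a one-way ANOVA over symptomatic/asymptomatic finger-pair categories in
  the patient group (eta-squared effect size, Tukey-Kramer post-hoc);
* paired tests for whether mirroring depends on the symptom status of the
  instructed finger (symptomatic hand active) or of the passive finger
  (asymptomatic hand active; a behavioural probe for mirror dystonia);
* demographic group summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import FINGERS, Cohort, SubjectRecord
from .metrics import SlopePattern
from .reliability import pooled_ttest

__all__ = [
    "PAIR_CATEGORIES",
    "TTestResult",
    "AnovaResult",
    "classify_finger_pairs",
    "group_mean_comparison",
    "symptomatic_pair_anova",
    "instructed_symptom_mirroring_test",
    "mirror_dystonia_test",
    "demographic_summary",
]

logger = logging.getLogger(__name__)

#: Finger-pair categories by (instructed status, uninstructed status).
PAIR_CATEGORIES = ("sym-sym", "sym-asy", "asy-sym", "asy-asy")


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    kind: str  # "two-sample pooled" | "paired"
    mean_a: float
    mean_b: float
    label_a: str = ""
    label_b: str = ""
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "t": self.t, "df": self.df, "p": self.p, "kind": self.kind,
            self.label_a or "mean_a": self.mean_a,
            self.label_b or "mean_b": self.mean_b,
        }


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    eta_squared: float
    group_means: dict[str, float]
    group_n: dict[str, int]
    tukey: list[tuple[str, str, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "F": self.F, "df_between": self.df_between,
            "df_within": self.df_within, "p": self.p,
            "eta_squared": self.eta_squared,
            "group_means": self.group_means, "group_n": self.group_n,
            "tukey": [{"pair": f"{a} vs {b}", "p_adj": p} for a, b, p in self.tukey],
        }


def classify_finger_pairs(symptom_map: frozenset[tuple[str, str]],
                          hand: str) -> np.ndarray:
    """Label each (instructed, uninstructed) cell of one hand's 5x5 pattern.

    Returns a 5x5 object array of category strings; the diagonal is None
    (a finger cannot be enslaved to itself).
    """
    sym = {f for h, f in symptom_map if h == hand}
    cats = np.full((5, 5), None, dtype=object)
    for i, fi in enumerate(FINGERS):
        for j, fj in enumerate(FINGERS):
            if i == j:
                continue
            a = "sym" if fi in sym else "asy"
            b = "sym" if fj in sym else "asy"
            cats[i, j] = f"{a}-{b}"
    return cats


def group_mean_comparison(cohort: Cohort,
                          subject_means: dict[str, float]) -> TTestResult:
    """Patients vs controls on a per-subject metric (mean log-slope).

    Pooled-variance two-sample t-test; df = n_patients + n_controls - 2.
    """
    pat = [subject_means[s.subject_id] for s in cohort.patients
           if s.subject_id in subject_means]
    con = [subject_means[s.subject_id] for s in cohort.controls
           if s.subject_id in subject_means]
    if len(pat) < 2 or len(con) < 2:
        raise ValueError("each group needs >= 2 subjects with a metric value")
    t, p = pooled_ttest(pat, con)
    return TTestResult(
        t=float(t), df=len(pat) + len(con) - 2, p=float(p),
        kind="two-sample pooled",
        mean_a=float(np.mean(pat)), mean_b=float(np.mean(con)),
        label_a="mean_patients", label_b="mean_controls",
    )


def symptomatic_pair_anova(patients: list[SubjectRecord],
                           patterns: dict[str, SlopePattern],
                           hand: str = "R") -> AnovaResult:
    """One-way ANOVA of enslaving across finger-pair symptom categories.

    The unit of analysis is each patient's mean log-slope within a category
    (sym-sym exists only for patients with >= 2 symptomatic fingers on the
    hand), so with 11 patients of whom 6 are multi-finger the design has
    11+11+11+6 = 39 observations and error df 35.  Post-hoc pairwise
    comparisons use Tukey-Kramer (handles the unequal category sizes); a
    Levene test on the category groups is logged for transparency.
    """
    obs_values: list[float] = []
    obs_cats: list[str] = []
    for s in patients:
        pattern = patterns[s.subject_id]
        cats = classify_finger_pairs(s.symptom_map, hand)
        for cat in PAIR_CATEGORIES:
            mask = (cats == cat) & pattern.valid
            if mask.any():
                obs_values.append(float(pattern.cells[mask].mean()))
                obs_cats.append(cat)
    values = np.asarray(obs_values)
    cats_arr = np.asarray(obs_cats)
    present = [c for c in PAIR_CATEGORIES if (cats_arr == c).any()]
    dropped = set(PAIR_CATEGORIES) - set(present)
    if dropped:
        logger.warning("categories with no observations dropped: %s", sorted(dropped))
    if len(present) < 2:
        raise ValueError("ANOVA needs at least 2 non-empty categories")
    groups = [values[cats_arr == c] for c in present]

    grand = values.mean()
    ss_total = float(((values - grand) ** 2).sum())
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    df_between = len(present) - 1
    df_within = len(values) - len(present)
    if ss_total > 0 and df_within > 0:
        F = (ss_between / df_between) / ((ss_total - ss_between) / df_within)
        p = float(stats.f.sf(F, df_between, df_within))
        eta_sq = ss_between / ss_total
    else:
        F, p, eta_sq = 0.0, 1.0, 0.0

    if values.std() > 0:
        _, levene_p = stats.levene(*groups)
        logger.info("Levene homogeneity-of-variance p = %.3f", levene_p)

    tukey: list[tuple[str, str, float]] = []
    if all(len(g) >= 2 for g in groups) and np.ptp(values) > 0:
        res = pairwise_tukeyhsd(values, cats_arr)
        pairs = list(combinations(res.groupsunique, 2))
        for (a, b), p_adj in zip(pairs, res.pvalues):
            tukey.append((str(a), str(b), float(p_adj)))

    return AnovaResult(
        F=float(F), df_between=df_between, df_within=df_within, p=p,
        eta_squared=float(eta_sq),
        group_means={c: float(values[cats_arr == c].mean()) for c in present},
        group_n={c: int((cats_arr == c).sum()) for c in present},
        tukey=tukey,
    )


def _paired_symptom_test(patients: list[SubjectRecord],
                         patterns: dict[str, SlopePattern],
                         status_hand: str, axis: str,
                         label: str) -> TTestResult:
    """Paired t-test of per-patient mean mirroring log-slope split by the
    symptom status of fingers on ``status_hand``.

    ``axis="instructed"`` splits by the instructed (row) finger,
    ``axis="passive"`` by the passive (column) finger.  Patients whose
    fingers on the status hand are all symptomatic or all asymptomatic are
    excluded with a warning.
    """
    sym_means, asy_means = [], []
    excluded = 0
    for s in patients:
        sym = s.symptomatic_fingers(status_hand)
        if not sym or len(sym) == len(FINGERS):
            logger.warning("patient %s: all-or-none symptomatic fingers on "
                           "hand %s; excluded from %s", s.subject_id,
                           status_hand, label)
            excluded += 1
            continue
        pattern = patterns[s.subject_id]
        finger_status = np.array([f in sym for f in FINGERS])
        if axis == "instructed":
            mask_sym = finger_status[:, None] & pattern.valid
            mask_asy = ~finger_status[:, None] & pattern.valid
        else:
            mask_sym = finger_status[None, :] & pattern.valid
            mask_asy = ~finger_status[None, :] & pattern.valid
        sym_means.append(float(pattern.cells[mask_sym].mean()))
        asy_means.append(float(pattern.cells[mask_asy].mean()))
    if len(sym_means) < 2:
        raise ValueError(f"{label}: fewer than 2 usable patients")
    diffs = np.asarray(sym_means) - np.asarray(asy_means)
    if np.all(diffs == 0):
        t, p = 0.0, 1.0  # exactly symmetric: no paired difference to test
    else:
        t, p = stats.ttest_rel(sym_means, asy_means)
    return TTestResult(
        t=float(t), df=len(sym_means) - 1, p=float(p), kind="paired",
        mean_a=float(np.mean(sym_means)), mean_b=float(np.mean(asy_means)),
        label_a="mean_symptomatic", label_b="mean_asymptomatic",
        n_excluded=excluded,
    )


def instructed_symptom_mirroring_test(patients: list[SubjectRecord],
                                      patterns: dict[str, SlopePattern],
                                      active_hand: str = "R") -> TTestResult:
    """Does mirroring depend on whether the instructed (symptomatic-hand)
    finger is itself symptomatic?  ``patterns`` are the active-hand
    mirroring patterns (rows = instructed fingers)."""
    return _paired_symptom_test(patients, patterns, status_hand=active_hand,
                                axis="instructed",
                                label="instructed-symptomatic mirroring test")


def mirror_dystonia_test(patients: list[SubjectRecord],
                         patterns: dict[str, SlopePattern],
                         passive_hand: str = "R") -> TTestResult:
    """Behavioural probe for mirror dystonia: during asymptomatic-hand
    presses, is mirroring larger on symptomatic than asymptomatic fingers
    of the passive (symptomatic) hand?  ``patterns`` are the mirroring
    patterns with the passive hand in the columns (e.g. L->R)."""
    return _paired_symptom_test(patients, patterns, status_hand=passive_hand,
                                axis="passive", label="mirror-dystonia test")


def demographic_summary(cohort: Cohort) -> dict:
    """Group means/SDs (n-1 denominator) of age, symptom duration and
    severity, plus an unpaired t-test for group age matching."""
    fields = ("age", "duration_years", "severity")
    table: dict[str, dict] = {}
    for group in ("patient", "control"):
        subjects = cohort.by_group(group)
        table[group] = {"n": len(subjects)}
        for name in fields:
            values = [getattr(s, name) for s in subjects
                      if getattr(s, name) is not None]
            if not values:
                table[group][name] = None
            elif len(values) == 1:
                table[group][name] = {"mean": float(values[0]), "sd": None, "n": 1}
            else:
                table[group][name] = {
                    "mean": float(np.mean(values)),
                    "sd": float(np.std(values, ddof=1)),
                    "n": len(values),
                }
    ages_p = [s.age for s in cohort.patients if s.age is not None]
    ages_c = [s.age for s in cohort.controls if s.age is not None]
    if len(ages_p) >= 2 and len(ages_c) >= 2:
        t, p = stats.ttest_ind(ages_p, ages_c, equal_var=True)
        table["age_comparison"] = {"t": float(t),
                                   "df": len(ages_p) + len(ages_c) - 2,
                                   "p": float(p)}
    else:
        table["age_comparison"] = None
        logger.info("age comparison skipped: insufficient age data")
    return table
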