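"""Symptomatic-finger classification, group contrasts, ANOVA, demographics."""

import numpy as np
import pytest
from scipy import stats

from dexin.clinical import (
    classify_finger_pairs,
    demographic_summary,
    group_mean_comparison,
    instructed_symptom_mirroring_test,
    mirror_dystonia_test,
    symptomatic_pair_anova,
)
from dexin.datasets import (
    REFERENCE_PATIENTS,
    reference_patient_table,
    reference_symptom_maps,
)
from dexin.io import FINGERS, Cohort, SubjectRecord
from dexin.metrics import SlopePattern


def enslaving_like(cells, kind="enslaving"):
    valid = ~np.eye(5, dtype=bool) if kind == "enslaving" else np.ones((5, 5), bool)
    full = np.array(cells, float)
    return SlopePattern(kind, "R", full, valid)


def reference_patients(rng=None, pattern_kind="enslaving", cell_sd=0.3):
    """Eleven trial-less patients with the reference symptom maps and random
    log-slope patterns."""
    rng = rng or np.random.default_rng(0)
    subjects, patterns = [], {}
    for k, symptoms in enumerate(reference_symptom_maps()):
        sid = f"pat{k:02d}"
        age, gender, instrument, _, duration, severity = REFERENCE_PATIENTS[k]
        subjects.append(SubjectRecord(
            subject_id=sid, group="patient", symptom_map=symptoms,
            age=age, gender=gender, instrument=instrument,
            duration_years=duration, severity=severity))
        patterns[sid] = enslaving_like(rng.normal(-3.5, 0.4, (5, 5)),
                                       kind=pattern_kind)
    return subjects, patterns


class TestClassifyFingerPairs:
    def test_reference_middle_ring_patient(self):
        """A patient with symptomatic right middle and ring fingers."""
        symptoms = frozenset({("R", "D3"), ("R", "D4")})
        cats = classify_finger_pairs(symptoms, "R")
        d = {f: i for i, f in enumerate(FINGERS)}
        assert cats[d["D3"], d["D4"]] == "sym-sym"
        assert cats[d["D2"], d["D3"]] == "asy-sym"
        assert cats[d["D3"], d["D2"]] == "sym-asy"
        assert cats[d["D1"], d["D2"]] == "asy-asy"
        assert cats[d["D3"], d["D3"]] is None
        # left hand of the same patient is entirely asymptomatic
        left = classify_finger_pairs(symptoms, "L")
        assert all(left[i, j] == "asy-asy" for i in range(5) for j in range(5)
                   if i != j)

    def test_empty_and_full_maps(self):
        empty = classify_finger_pairs(frozenset(), "R")
        assert {empty[i, j] for i in range(5) for j in range(5) if i != j} == {"asy-asy"}
        full = classify_finger_pairs(
            frozenset(("R", f) for f in FINGERS), "R")
        assert {full[i, j] for i in range(5) for j in range(5) if i != j} == {"sym-sym"}

    def test_transpose_antisymmetry(self):
        symptoms = frozenset({("R", "D1"), ("R", "D4")})
        cats = classify_finger_pairs(symptoms, "R")
        swap = {"sym-asy": "asy-sym", "asy-sym": "sym-asy",
                "sym-sym": "sym-sym", "asy-asy": "asy-asy"}
        for i in range(5):
            for j in range(5):
                if i != j:
                    assert cats[j, i] == swap[cats[i, j]]


class TestGroupComparison:
    def _cohort(self, n_pat, n_con):
        subjects = ([SubjectRecord(subject_id=f"p{i}", group="patient")
                     for i in range(n_pat)]
                    + [SubjectRecord(subject_id=f"c{i}", group="control")
                       for i in range(n_con)])
        return Cohort(subjects=subjects)

    def test_identical_groups(self):
        cohort = self._cohort(3, 3)
        means = {s.subject_id: -3.0 for s in cohort}
        res = group_mean_comparison(cohort, means)
        assert res.t == 0.0 and res.p == 1.0

    def test_df_for_11_vs_7(self, rng):
        cohort = self._cohort(11, 7)
        means = {s.subject_id: float(rng.normal(-3.3, 0.3)) for s in cohort}
        assert group_mean_comparison(cohort, means).df == 16

    def test_matches_textbook_formula(self, rng):
        cohort = self._cohort(3, 3)
        a = rng.normal(-3.0, 0.4, 3)
        b = rng.normal(-3.6, 0.4, 3)
        means = {f"p{i}": a[i] for i in range(3)} | {f"c{i}": b[i] for i in range(3)}
        res = group_mean_comparison(cohort, means)
        sp2 = (2 * a.var(ddof=1) + 2 * b.var(ddof=1)) / 4
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert res.t == pytest.approx(t_hand, abs=1e-10)
        assert res.p == pytest.approx(2 * stats.t.sf(abs(t_hand), 4), abs=1e-10)

    def test_small_group_raises(self):
        cohort = self._cohort(1, 3)
        means = {s.subject_id: -3.0 for s in cohort}
        with pytest.raises(ValueError):
            group_mean_comparison(cohort, means)


class TestSymptomaticAnova:
    def test_reference_maps_give_error_df_35(self):
        """11 reference patients contribute 11 + 11 + 11 + 6 category means
        (six have >= 2 symptomatic right-hand digits), so df = (3, 35)."""
        subjects, patterns = reference_patients()
        res = symptomatic_pair_anova(subjects, patterns, hand="R")
        assert res.df_between == 3
        assert res.df_within == 35
        assert res.group_n == {"sym-sym": 6, "sym-asy": 11,
                               "asy-sym": 11, "asy-asy": 11}
        assert 0 <= res.eta_squared <= 1
        assert len(res.tukey) == 6

    def test_all_equal_observations(self):
        subjects, patterns = reference_patients()
        flat = {sid: enslaving_like(np.full((5, 5), -3.5)) for sid in patterns}
        res = symptomatic_pair_anova(subjects, flat, hand="R")
        assert res.F == 0.0 and res.eta_squared == 0.0

    def test_matches_sums_of_squares_oracle(self, rng):
        """F and eta^2 agree with an explicit SS decomposition (and scipy)
        on a 4-group toy problem."""
        subjects, patterns = reference_patients(rng=rng)
        res = symptomatic_pair_anova(subjects, patterns, hand="R")
        # rebuild the observations exactly as the ANOVA defines them
        from dexin.clinical import PAIR_CATEGORIES, classify_finger_pairs
        obs = {c: [] for c in PAIR_CATEGORIES}
        for s in subjects:
            cats = classify_finger_pairs(s.symptom_map, "R")
            pat = patterns[s.subject_id]
            for c in PAIR_CATEGORIES:
                mask = (cats == c) & pat.valid
                if mask.any():
                    obs[c].append(pat.cells[mask].mean())
        groups = [np.array(v) for v in obs.values()]
        f_ref, p_ref = stats.f_oneway(*groups)
        assert res.F == pytest.approx(f_ref, abs=1e-10)
        assert res.p == pytest.approx(p_ref, abs=1e-10)
        allv = np.concatenate(groups)
        ss_total = ((allv - allv.mean()) ** 2).sum()
        ss_between = sum(len(g) * (g.mean() - allv.mean()) ** 2 for g in groups)
        assert res.eta_squared == pytest.approx(ss_between / ss_total, abs=1e-10)


class TestPairedSymptomTests:
    def test_df_10_for_11_patients(self, rng):
        subjects, patterns = reference_patients(rng=rng, pattern_kind="mirroring")
        res = instructed_symptom_mirroring_test(subjects, patterns, "R")
        assert res.df == 10
        assert res.kind == "paired"
        res2 = mirror_dystonia_test(subjects, patterns, "R")
        assert res2.df == 10

    def test_symmetric_pattern_gives_t0(self):
        subjects, _ = reference_patients()
        flat = {s.subject_id: enslaving_like(np.full((5, 5), -5.0), "mirroring")
                for s in subjects}
        res = instructed_symptom_mirroring_test(subjects, flat, "R")
        assert res.t == 0.0 and res.p == 1.0

    def test_matches_closed_form_paired_t(self, rng):
        subjects, patterns = reference_patients(rng=rng, pattern_kind="mirroring")
        res = instructed_symptom_mirroring_test(subjects, patterns, "R")
        # recompute the per-patient sym/asy means by hand
        diffs = []
        for s in subjects:
            sym = s.symptomatic_fingers("R")
            pat = patterns[s.subject_id]
            rows_sym = [i for i, f in enumerate(FINGERS) if f in sym]
            rows_asy = [i for i, f in enumerate(FINGERS) if f not in sym]
            diffs.append(pat.cells[rows_sym].mean() - pat.cells[rows_asy].mean())
        diffs = np.array(diffs)
        t_hand = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(len(diffs)))
        assert res.t == pytest.approx(t_hand, abs=1e-10)

    def test_all_or_none_patients_excluded(self, rng, caplog):
        subjects, patterns = reference_patients(rng=rng, pattern_kind="mirroring")
        subjects[0] = SubjectRecord(
            subject_id=subjects[0].subject_id, group="patient",
            symptom_map=frozenset(("R", f) for f in FINGERS))
        with caplog.at_level("WARNING"):
            res = instructed_symptom_mirroring_test(subjects, patterns, "R")
        assert res.df == 9
        assert res.n_excluded == 1


class TestDemographics:
    def _cohort(self, with_controls=True):
        subjects, _ = reference_patients()
        if with_controls:
            ages = [41, 29, 52, 60, 33, 45, 27]
            subjects += [SubjectRecord(subject_id=f"con{i}", group="control",
                                       age=a) for i, a in enumerate(ages)]
        return Cohort(subjects=subjects)

    def test_reference_patient_summaries(self):
        """Mean/SD of duration, severity and age recomputed from the
        reference rows."""
        table = demographic_summary(self._cohort())
        pat = table["patient"]
        assert pat["duration_years"]["mean"] == pytest.approx(7.82, abs=0.005)
        assert pat["duration_years"]["sd"] == pytest.approx(7.21, abs=0.005)
        assert pat["severity"]["mean"] == pytest.approx(2.55, abs=0.005)
        assert pat["severity"]["sd"] == pytest.approx(0.69, abs=0.005)
        assert pat["age"]["mean"] == pytest.approx(49.9, abs=0.05)
        assert pat["age"]["sd"] == pytest.approx(7.85, abs=0.005)

    def test_age_comparison_df(self):
        table = demographic_summary(self._cohort())
        assert table["age_comparison"]["df"] == 11 + 7 - 2

    def test_single_subject_group_sd_missing(self):
        subjects, _ = reference_patients()
        cohort = Cohort(subjects=subjects[:1]
                        + [SubjectRecord(subject_id="c", group="control", age=40),
                           SubjectRecord(subject_id="c2", group="control", age=44)])
        table = demographic_summary(cohort)
        assert table["patient"]["age"]["sd"] is None

    def test_reference_table_shape(self):
        table = reference_patient_table()
        assert len(table) == 11
        multi_right = sum(
            1 for m in reference_symptom_maps()
            if len([f for h, f in m if h == "R"]) >= 2)
        assert multi_right == 6
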