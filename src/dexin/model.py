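"""Model/results interface over the full individuation analysis.

:class:`FingerIndividuation` is constructed from a :class:`~dexin.io.Cohort`
(loaded from disk or simulated); its :meth:`~FingerIndividuation.fit`
estimates every subject's enslaving and mirroring patterns and returns an
:class:`IndividuationResults` that exposes the group statistics —
reliability, pattern similarity, group contrasts, symptomatic-finger tests —
plus a text ``summary()`` and tidy-table export.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical
from .io import Cohort, read_cohort
from .metrics import SlopePattern, mean_pattern_strength
from .preprocess import build_peak_table
from .reliability import (
    ReliabilityResult,
    SimilarityResult,
    crossval_pattern_similarity,
    group_reliability,
)
from .simulate import CohortConfig, CouplingModel, simulate_cohort

__all__ = ["FingerIndividuation", "IndividuationResults"]

#: All (kind, context) analysis slots; context is the instructed hand for
#: enslaving and the active hand for mirroring.
ANALYSES = (
    ("enslaving", "L"), ("enslaving", "R"),
    ("mirroring", "L"), ("mirroring", "R"),
)


class FingerIndividuation:
    """Finger-individuation model for a cohort of force-press sessions.

    Parameters
    ----------
    cohort : Cohort
        Subjects with their trials.
    kinds : sequence of {"enslaving", "mirroring"}
        Analyses to run (default both).
    """

    def __init__(self, cohort: Cohort, kinds=("enslaving", "mirroring")):
        self.cohort = cohort
        self.kinds = tuple(kinds)
        self.ground_truth: dict[str, CouplingModel] | None = None

    @classmethod
    def from_manifest(cls, manifest_path, **kwargs) -> "FingerIndividuation":
        """Build the model from an on-disk ``subjects.json`` manifest."""
        return cls(read_cohort(manifest_path), **kwargs)

    @classmethod
    def from_simulation(cls, config: CohortConfig, **kwargs) -> "FingerIndividuation":
        """Simulate a cohort and keep the ground-truth coupling attached."""
        cohort, truth = simulate_cohort(config)
        model = cls(cohort, **kwargs)
        model.ground_truth = truth
        return model

    def fit(self) -> "IndividuationResults":
        """Estimate all per-subject patterns and return the results object."""
        patterns: dict[str, dict[tuple[str, str], SlopePattern]] = {}
        from .metrics import enslaving_pattern, mirroring_pattern

        for subject in self.cohort:
            peaks = build_peak_table(subject)
            per = {}
            for kind, context in ANALYSES:
                if kind not in self.kinds:
                    continue
                if kind == "enslaving":
                    per[(kind, context)] = enslaving_pattern(peaks, context)
                else:
                    per[(kind, context)] = mirroring_pattern(peaks, context)
            patterns[subject.subject_id] = per
        return IndividuationResults(self, patterns)


class IndividuationResults:
    """Fitted patterns plus the derived group statistics."""

    def __init__(self, model: FingerIndividuation,
                 patterns: dict[str, dict[tuple[str, str], SlopePattern]]):
        self.model = model
        self.cohort = model.cohort
        self.patterns = patterns

    # -- accessors ---------------------------------------------------------

    def subject_patterns(self, kind: str, context: str) -> dict[str, SlopePattern]:
        return {sid: per[(kind, context)] for sid, per in self.patterns.items()
                if (kind, context) in per}

    def subject_means(self, kind: str, context: str) -> dict[str, float]:
        """Per-subject mean log-slope for one analysis slot."""
        return {sid: mean_pattern_strength(p)[0]
                for sid, p in self.subject_patterns(kind, context).items()}

    def group_geomeans(self, kind: str, context: str) -> dict[str, float]:
        """Back-transformed group mean log-slopes (N per N)."""
        means = self.subject_means(kind, context)
        out = {}
        for group in ("patient", "control"):
            vals = [means[s.subject_id] for s in self.cohort.by_group(group)
                    if s.subject_id in means]
            if vals:
                out[group] = float(np.exp(np.mean(vals)))
        return out

    def to_frame(self) -> pd.DataFrame:
        """All pattern cells as one tidy table."""
        frames = []
        for sid, per in self.patterns.items():
            group = next(s.group for s in self.cohort if s.subject_id == sid)
            for pattern in per.values():
                df = pattern.to_frame()
                df.insert(0, "subject_id", sid)
                df.insert(1, "group", group)
                frames.append(df)
        return pd.concat(frames, ignore_index=True)

    # -- group statistics --------------------------------------------------

    def group_comparison(self, kind: str, context: str) -> clinical.TTestResult:
        """Patients vs controls on mean log-slope (pooled two-sample t)."""
        return clinical.group_mean_comparison(
            self.cohort, self.subject_means(kind, context))

    def reliability(self, kind: str, context: str,
                    group: str | None = None) -> ReliabilityResult:
        """Split-half (odd/even blocks) reliability, optionally per group."""
        subjects = (self.cohort.by_group(group) if group
                    else list(self.cohort.subjects))
        return group_reliability(subjects, kind, context)

    def similarity(self, kind: str, context: str) -> SimilarityResult:
        """Cross-validated pattern similarity, patients vs controls."""
        return crossval_pattern_similarity(
            self.cohort, kind, context,
            patterns=self.subject_patterns(kind, context))

    def symptomatic_anova(self, hand: str = "R") -> clinical.AnovaResult:
        """Finger-pair symptom-category ANOVA on patient enslaving."""
        return clinical.symptomatic_pair_anova(
            self.cohort.patients, self.subject_patterns("enslaving", hand), hand)

    def instructed_symptom_mirroring(self, active_hand: str = "R") -> clinical.TTestResult:
        return clinical.instructed_symptom_mirroring_test(
            self.cohort.patients,
            self.subject_patterns("mirroring", active_hand), active_hand)

    def mirror_dystonia(self, active_hand: str = "L") -> clinical.TTestResult:
        passive = "R" if active_hand == "L" else "L"
        return clinical.mirror_dystonia_test(
            self.cohort.patients,
            self.subject_patterns("mirroring", active_hand), passive)

    def demographics(self) -> dict:
        return clinical.demographic_summary(self.cohort)

    # -- reporting ---------------------------------------------------------

    def summary_dict(self) -> dict:
        """All headline quantities as one JSON-serialisable dictionary."""
        out: dict = {"n_patients": len(self.cohort.patients),
                     "n_controls": len(self.cohort.controls)}
        have_groups = (len(self.cohort.patients) >= 2
                       and len(self.cohort.controls) >= 2)
        for kind, context in ANALYSES:
            if kind not in self.model.kinds:
                continue
            key = f"{kind}_{context}"
            entry: dict = {"group_geomean_slope": self.group_geomeans(kind, context)}
            if have_groups:
                entry["group_comparison"] = self.group_comparison(kind, context).to_dict()
                entry["similarity"] = {
                    k: v for k, v in vars(self.similarity(kind, context)).items()
                    if k in ("mean_patient_r", "mean_control_r", "t", "df", "p")
                }
                for grp in ("patient", "control"):
                    r = self.reliability(kind, context, group=grp)
                    entry[f"reliability_{grp}"] = {
                        "mean_r": r.mean_r, "ci": [r.ci_low, r.ci_high]}
            out[key] = entry
        if have_groups and "enslaving" in self.model.kinds:
            try:
                out["symptomatic_pair_anova_R"] = self.symptomatic_anova("R").to_dict()
            except ValueError:
                out["symptomatic_pair_anova_R"] = None
        if have_groups and "mirroring" in self.model.kinds:
            try:
                out["instructed_symptom_mirroring_R"] = \
                    self.instructed_symptom_mirroring("R").to_dict()
                out["mirror_dystonia_L_active"] = self.mirror_dystonia("L").to_dict()
            except (ValueError, KeyError):
                out["instructed_symptom_mirroring_R"] = None
                out["mirror_dystonia_L_active"] = None
        out["demographics"] = self.demographics()
        return out

    def summary(self) -> str:
        """Human-readable summary of the fitted analysis."""
        d = self.summary_dict()
        lines = [
            "Finger individuation analysis",
            "=" * 64,
            f"subjects: {d['n_patients']} patients, {d['n_controls']} controls",
        ]
        for kind, context in ANALYSES:
            key = f"{kind}_{context}"
            if key not in d:
                continue
            e = d[key]
            lines.append("")
            lines.append(f"{kind} ({'instructed' if kind == 'enslaving' else 'active'} hand {context})")
            lines.append("-" * 64)
            gm = e["group_geomean_slope"]
            gm_txt = ", ".join(f"{g}: {v:.4f} N/N" for g, v in gm.items())
            lines.append(f"  geometric-mean slope   {gm_txt}")
            if "group_comparison" in e:
                gc = e["group_comparison"]
                lines.append(
                    f"  patients vs controls   t({gc['df']}) = {gc['t']:.2f}, p = {gc['p']:.3f}")
                sim = e["similarity"]
                lines.append(
                    f"  pattern similarity     patient r = {sim['mean_patient_r']:.3f}, "
                    f"t({sim['df']}) = {sim['t']:.2f}, p = {sim['p']:.3f}")
                for grp in ("patient", "control"):
                    r = e[f"reliability_{grp}"]
                    lines.append(
                        f"  split-half r ({grp + ')':9s} {r['mean_r']:.3f} "
                        f"[{r['ci'][0]:.3f}, {r['ci'][1]:.3f}]")
        if d.get("symptomatic_pair_anova_R"):
            a = d["symptomatic_pair_anova_R"]
            lines.append("")
            lines.append(
                f"symptom-pair ANOVA (R)   F({a['df_between']},{a['df_within']}) = "
                f"{a['F']:.2f}, p = {a['p']:.3f}, eta^2 = {a['eta_squared']:.3f}")
        if d.get("instructed_symptom_mirroring_R"):
            t = d["instructed_symptom_mirroring_R"]
            lines.append(
                f"mirroring by instructed-finger status   t({t['df']}) = "
                f"{t['t']:.2f}, p = {t['p']:.3f}")
        if d.get("mirror_dystonia_L_active"):
            t = d["mirror_dystonia_L_active"]
            lines.append(
                f"mirror-dystonia probe (L active)        t({t['df']}) = "
                f"{t['t']:.2f}, p = {t['p']:.3f}")
        return "\n".join(lines)

    def save(self, out_dir, provenance: dict | None = None) -> None:
        """Write patterns.csv, reliability.csv, similarity.csv,
        stats_report.json and summary.json into ``out_dir``."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        prov = provenance or {}

        self.to_frame().to_csv(out_dir / "patterns.csv", index=False)

        rel_rows, sim_rows = [], []
        have_groups = (len(self.cohort.patients) >= 2
                       and len(self.cohort.controls) >= 2)
        for kind, context in ANALYSES:
            if kind not in self.model.kinds:
                continue
            if have_groups:
                for grp in ("patient", "control"):
                    r = self.reliability(kind, context, group=grp)
                    for sid, value in r.subject_r.items():
                        rel_rows.append({"kind": kind, "context": context,
                                         "group": grp, "subject_id": sid,
                                         "split_half_r": value})
                sim = self.similarity(kind, context)
                for sid, value in sim.subject_r.items():
                    sim_rows.append({"kind": kind, "context": context,
                                     "group": sim.subject_group[sid],
                                     "subject_id": sid, "similarity_r": value})
        pd.DataFrame(rel_rows).to_csv(out_dir / "reliability.csv", index=False)
        pd.DataFrame(sim_rows).to_csv(out_dir / "similarity.csv", index=False)

        summary = {"provenance": prov, **self.summary_dict()}
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
        (out_dir / "stats_report.json").write_text(json.dumps(
            {"provenance": prov, **{k: v for k, v in summary.items()
                                    if k != "provenance"}}, indent=1))
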