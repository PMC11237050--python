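"""Synthetic cohorts of isometric finger-press trials with known coupling.

No public dataset exists for the study design this package analyses, so the
simulator stands in for it: it generates 10-channel force trials in which
uninstructed fingers of the instructed hand produce *enslaved* forces and
fingers of the passive hand produce *mirrored* forces, both linear in the
instantaneous instructed force.  Because the generating coupling matrices
are returned alongside the cohort, every downstream estimator can be tested
by parameter recovery.

Generative model per trial
--------------------------
A trial is preparation (2-3 s at rest), a 0.3 s half-cosine ramp to the
achieved peak ``P = level * MVC * (1 + eps)`` with matching error
``eps ~ N(0, match_cv)``, a 2-3 s hold, and a 0.5 s release.  Uninstructed
channel *g* follows ``gain_g * f_instructed(t)`` where the gain is the
ground-truth enslaving/mirroring cell jittered per trial by a multiplicative
``1 + N(0, coupling_cv)`` term (trial-to-trial variability of motor
overflow).  Each channel additionally carries slow sensor/postural drift
with marginal sd ``sd_signal * |f| + sd_const`` plus a constant per-trial
baseline offset ``~ N(0, baseline_sd)``; all samples are clipped to the
transducer range.

Group structure: patients' enslaving/mirroring geometric means exceed
controls' by configurable gains, finger pairs couple more strongly the
closer they are anatomically (``distance_decay``), and finger pairs in
which both digits are clinically symptomatic receive an extra gain.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .datasets import reference_symptom_maps
from .io import (
    CHANNELS,
    FINGERS,
    FORCE_RANGE,
    HANDS,
    SAMPLE_RATE,
    TARGET_LEVELS,
    Cohort,
    ForceTrial,
    SubjectRecord,
    channel_index,
)

__all__ = [
    "CouplingModel",
    "CohortConfig",
    "make_coupling_model",
    "simulate_trial",
    "simulate_subject",
    "simulate_cohort",
]

RAMP_S = 0.3
RELEASE_S = 0.5
#: Knot spacing of the slow-drift noise process (seconds).  Drift is linear
#: between independent Gaussian knots, so a response window contains only a
#: handful of effective noise draws and max-based peak extraction stays
#: nearly unbiased.
DRIFT_KNOT_S = 1.0


@dataclass
class CouplingModel:
    """Ground-truth coupling and noise parameters for one simulated subject.

    ``E_L``/``E_R`` are 5x5 enslaving matrices (row = instructed finger,
    column = uninstructed finger of the same hand, N per N; diagonal fixed
    at 1 = the instructed finger's own gain).  ``M_RL`` maps right-hand
    presses onto the passive left hand; ``M_LR`` the reverse.
    """

    E_L: np.ndarray
    E_R: np.ndarray
    M_RL: np.ndarray
    M_LR: np.ndarray
    mvc: np.ndarray
    sd_signal: float = 0.02
    sd_const: float = 0.005
    match_cv: float = 0.12
    baseline_sd: float = 0.1
    coupling_cv: float = 0.3

    def enslaving(self, hand: str) -> np.ndarray:
        return self.E_L if hand == "L" else self.E_R

    def mirroring(self, active_hand: str) -> np.ndarray:
        return self.M_RL if active_hand == "R" else self.M_LR

    def gain_vector(self, hand: str, finger: str) -> np.ndarray:
        """Coupling of every channel to the instructed finger's force (10,)."""
        i = FINGERS.index(finger)
        gains = np.empty(10)
        for g_hand in HANDS:
            mat = self.enslaving(hand) if g_hand == hand else self.mirroring(hand)
            for j, g_finger in enumerate(FINGERS):
                gains[channel_index(g_hand, g_finger)] = mat[i, j]
        return gains

    def to_dict(self) -> dict:
        return {
            "E_L": self.E_L.tolist(), "E_R": self.E_R.tolist(),
            "M_RL": self.M_RL.tolist(), "M_LR": self.M_LR.tolist(),
            "mvc": self.mvc.tolist(), "sd_signal": self.sd_signal,
            "sd_const": self.sd_const, "match_cv": self.match_cv,
            "baseline_sd": self.baseline_sd, "coupling_cv": self.coupling_cv,
        }


@dataclass
class CohortConfig:
    """Study-design and calibration parameters for a simulated cohort.

    Defaults reproduce the study conditions: 11 patients vs 7 analysable
    controls, 10 blocks of 30 trials (3 levels x 10 fingers), control
    enslaving/mirroring geometric means of 0.028 / 0.006 N per N with
    patient gains raising them to 0.046 / 0.009, and between-subject spread
    sized so the group contrasts land at the observed t-statistic scale.
    """

    n_patients: int = 11
    n_controls: int = 7
    control_geomean_enslaving: float = 0.028
    patient_gain: float = 0.046 / 0.028
    control_geomean_mirroring: float = 0.006
    patient_mirror_gain: float = 0.009 / 0.006
    symsym_extra_gain: float = 1.5
    distance_decay: float = 0.6
    between_subject_cv: float = 0.3
    cell_cv: float = 0.2
    blocks: int = 10
    seed: int = 0
    # trial-level noise (copied into each subject's CouplingModel)
    sd_signal: float = 0.02
    sd_const: float = 0.005
    match_cv: float = 0.12
    baseline_sd: float = 0.1
    coupling_cv: float = 0.3

    def __post_init__(self) -> None:
        if self.n_patients < 0 or self.n_controls < 0:
            raise ValueError("subject counts must be >= 0")
        if self.blocks < 2:
            raise ValueError("blocks must be >= 2 (split-half needs both parities)")
        for name in ("control_geomean_enslaving", "patient_gain",
                     "control_geomean_mirroring", "patient_mirror_gain",
                     "symsym_extra_gain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def noise_free(self) -> "CohortConfig":
        """Copy with every stochastic trial-level term switched off."""
        return dataclasses.replace(
            self, sd_signal=0.0, sd_const=0.0, match_cv=0.0,
            baseline_sd=0.0, coupling_cv=0.0, between_subject_cv=0.0,
            cell_cv=0.0,
        )

    @classmethod
    def from_dict(cls, data: dict) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _log_structure(decay: float, cross_hand: bool) -> np.ndarray:
    """Log of the distance-decay structure, normalised to geometric mean 1.

    Within a hand the relevant distance is |i - j| over the 20 off-diagonal
    cells; across hands the homologous finger (distance 0) couples most.
    """
    i, j = np.meshgrid(np.arange(5), np.arange(5), indexing="ij")
    dist = np.abs(i - j).astype(float)
    logs = np.log(decay) * dist if decay > 0 else np.zeros((5, 5))
    valid = np.ones((5, 5), bool) if cross_hand else ~np.eye(5, dtype=bool)
    logs = logs - logs[valid].mean()
    logs[~valid] = 0.0
    return logs


def _draw_matrix(base: float, subject_log: float, struct_log: np.ndarray,
                 cell_cv: float, rng: np.random.Generator,
                 diagonal_one: bool) -> np.ndarray:
    cell = rng.normal(0.0, cell_cv, size=(5, 5)) if cell_cv > 0 else np.zeros((5, 5))
    mat = np.exp(np.log(base) + subject_log + struct_log + cell)
    mat = np.clip(mat, 0.0, 0.5)
    if diagonal_one:
        np.fill_diagonal(mat, 1.0)
    return mat


def make_coupling_model(config: CohortConfig, group: str,
                        symptom_map: frozenset[tuple[str, str]] | None,
                        rng: np.random.Generator) -> CouplingModel:
    """Draw one subject's ground-truth coupling matrices and MVCs.

    Off-diagonal enslaving cells are log-normal around the group geometric
    mean times the distance-decay structure; mirroring cells likewise around
    the group mirroring mean.  Cells whose two fingers are both symptomatic
    are multiplied by ``symsym_extra_gain``.
    """
    symptom_map = symptom_map or frozenset()
    if group == "control" and symptom_map:
        raise ValueError("controls cannot have a symptom map")

    base_e = config.control_geomean_enslaving
    base_m = config.control_geomean_mirroring
    if group == "patient":
        base_e *= config.patient_gain
        base_m *= config.patient_mirror_gain

    bs = config.between_subject_cv
    subj_e = rng.normal(0.0, bs) if bs > 0 else 0.0
    subj_m = rng.normal(0.0, bs) if bs > 0 else 0.0

    struct_e = _log_structure(config.distance_decay, cross_hand=False)
    struct_m = _log_structure(config.distance_decay, cross_hand=True)

    mats = {}
    for hand in HANDS:
        mats[f"E_{hand}"] = _draw_matrix(base_e, subj_e, struct_e,
                                         config.cell_cv, rng, diagonal_one=True)
    for active in ("R", "L"):
        passive = "L" if active == "R" else "R"
        key = f"M_{active}{passive}"
        mats[key] = _draw_matrix(base_m, subj_m, struct_m,
                                 config.cell_cv, rng, diagonal_one=False)

    if config.symsym_extra_gain != 1.0 and symptom_map:
        sym = {h: {f for hh, f in symptom_map if hh == h} for h in HANDS}
        for hand in HANDS:
            for i, fi in enumerate(FINGERS):
                for j, fj in enumerate(FINGERS):
                    if i != j and fi in sym[hand] and fj in sym[hand]:
                        mats[f"E_{hand}"][i, j] = min(
                            0.5, mats[f"E_{hand}"][i, j] * config.symsym_extra_gain)
        for active, passive in (("R", "L"), ("L", "R")):
            for i, fi in enumerate(FINGERS):
                for j, fj in enumerate(FINGERS):
                    if fi in sym[active] and fj in sym[passive]:
                        key = f"M_{active}{passive}"
                        mats[key][i, j] = min(0.5, mats[key][i, j] * config.symsym_extra_gain)

    # MVC ~ N(20, 2) truncated to [14, 24] N so 75% targets stay well inside
    # the 0-25 N transducer range.
    mvc = np.clip(rng.normal(20.0, 2.0, size=10), 14.0, 24.0)

    return CouplingModel(
        E_L=mats["E_L"], E_R=mats["E_R"], M_RL=mats["M_RL"], M_LR=mats["M_LR"],
        mvc=mvc, sd_signal=config.sd_signal, sd_const=config.sd_const,
        match_cv=config.match_cv, baseline_sd=config.baseline_sd,
        coupling_cv=config.coupling_cv,
    )


def _slow_drift(n: int, n_channels: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance slowly varying noise: linear interpolation of Gaussian
    knots spaced :data:`DRIFT_KNOT_S` seconds apart."""
    step = int(round(DRIFT_KNOT_S * SAMPLE_RATE))
    n_knots = n // step + 2
    knots = rng.standard_normal((n_knots, n_channels))
    x = np.arange(n) / step
    i0 = np.floor(x).astype(int)
    frac = (x - i0)[:, None]
    return knots[i0] * (1.0 - frac) + knots[i0 + 1] * frac


def simulate_trial(model: CouplingModel, instructed: tuple[str, str],
                   target_level: float, rng: np.random.Generator,
                   subject_id: str = "sim", block: int = 1,
                   trial: int = 1) -> ForceTrial:
    """Simulate one instructed finger press (see module docstring)."""
    if not any(np.isclose(target_level, lv) for lv in TARGET_LEVELS):
        raise ValueError(f"target_level must be one of {TARGET_LEVELS}")
    hand, finger = instructed
    ch = channel_index(hand, finger)

    n_prep = int(round(rng.uniform(2.0, 3.0) * SAMPLE_RATE))
    n_ramp = int(round(RAMP_S * SAMPLE_RATE))
    n_hold = int(round(rng.uniform(2.0, 3.0) * SAMPLE_RATE))
    n_rel = int(round(RELEASE_S * SAMPLE_RATE))
    n = n_prep + n_ramp + n_hold + n_rel

    eps = rng.normal(0.0, model.match_cv) if model.match_cv > 0 else 0.0
    peak = target_level * model.mvc[ch] * (1.0 + eps)

    clean = np.zeros(n)
    ramp_phase = 0.5 * (1.0 - np.cos(np.pi * np.arange(1, n_ramp + 1) / n_ramp))
    clean[n_prep:n_prep + n_ramp] = peak * ramp_phase
    clean[n_prep + n_ramp:n_prep + n_ramp + n_hold] = peak
    rel_phase = 0.5 * (1.0 + np.cos(np.pi * np.arange(1, n_rel + 1) / n_rel))
    clean[n_prep + n_ramp + n_hold:] = peak * rel_phase

    gains = model.gain_vector(hand, finger)
    if model.coupling_cv > 0:
        jitter = 1.0 + rng.normal(0.0, model.coupling_cv, size=10)
        gains = gains * np.clip(jitter, 0.05, None)
    gains[ch] = 1.0

    if model.sd_signal > 0 or model.sd_const > 0:
        drift = _slow_drift(n, 10, rng)
        env = model.sd_signal * np.abs(clean[:, None] * gains[None, :]) + model.sd_const
        noise = drift * env
    else:
        noise = np.zeros((n, 10))

    forces = np.empty((n, 10))
    forces[:, ch] = clean + noise[:, ch]
    for g in range(10):
        if g != ch:
            forces[:, g] = gains[g] * forces[:, ch] + noise[:, g]

    if model.baseline_sd > 0:
        forces += rng.normal(0.0, model.baseline_sd, size=10)[None, :]
    np.clip(forces, FORCE_RANGE[0], FORCE_RANGE[1], out=forces)

    return ForceTrial(
        subject_id=subject_id, block=block, trial=trial,
        instructed_hand=hand, instructed_finger=finger,
        target_level=target_level, forces=forces, go_cue=n_prep, end=n,
    )


def simulate_subject(model: CouplingModel, config: CohortConfig,
                     subject_id: str, group: str,
                     rng: np.random.Generator,
                     symptom_map: frozenset[tuple[str, str]] = frozenset(),
                     **meta) -> SubjectRecord:
    """Simulate a full session: ``config.blocks`` blocks of 30 trials.

    Within each block every (hand, finger, level) combination appears
    exactly once, in pseudo-random order.
    """
    combos = [(h, f, lv) for h in HANDS for f in FINGERS for lv in TARGET_LEVELS]
    trials = []
    for block in range(1, config.blocks + 1):
        order = rng.permutation(len(combos))
        for k, idx in enumerate(order, start=1):
            h, f, lv = combos[idx]
            trials.append(simulate_trial(model, (h, f), lv, rng,
                                         subject_id=subject_id, block=block, trial=k))
    return SubjectRecord(
        subject_id=subject_id, group=group, mvc=model.mvc.copy(),
        symptom_map=symptom_map, trials=trials, **meta,
    )


def sample_symptom_map(rng: np.random.Generator) -> frozenset[tuple[str, str]]:
    """Draw a patient symptom map from the reference clinical distribution
    (always at least one right-hand digit; 2/11 include a left-hand digit)."""
    maps = reference_symptom_maps()
    return maps[int(rng.integers(len(maps)))]


def simulate_cohort(config: CohortConfig) -> tuple[Cohort, dict[str, CouplingModel]]:
    """Simulate a full cohort; returns it with per-subject ground truth.

    Each subject gets a dedicated random stream spawned from the master
    seed, so a subject's data does not depend on cohort composition order.
    """
    master = np.random.SeedSequence(config.seed)
    n_total = config.n_patients + config.n_controls
    streams = master.spawn(n_total + 1)
    cohort_rng = np.random.default_rng(streams[0])

    subjects: list[SubjectRecord] = []
    truth: dict[str, CouplingModel] = {}
    k = 0
    for group, count in (("patient", config.n_patients), ("control", config.n_controls)):
        for i in range(count):
            sid = f"{group}{i + 1:02d}"
            rng = np.random.default_rng(streams[k + 1])
            k += 1
            symptoms = sample_symptom_map(cohort_rng) if group == "patient" else frozenset()
            model = make_coupling_model(config, group, symptoms, rng)
            subjects.append(simulate_subject(model, config, sid, group, rng,
                                             symptom_map=symptoms))
            truth[sid] = model
    provenance = f"simulated seed={config.seed} blocks={config.blocks}"
    return Cohort(subjects=subjects, provenance=provenance), truth
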