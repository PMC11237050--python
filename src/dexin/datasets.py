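"""Reference clinical descriptors for an 11-patient musician's-dystonia cohort.

The published demographic/clinical table of the dystonia cohort this package
analyses: age, instrument, symptomatic digits during performance, symptom
duration (years) and Tubiana-Chamagne severity (0 = unable to play ...
5 = returned to concert performance).  Every patient was symptomatic in the
right hand; two additionally had dystonia of the left thumb.

The table serves two purposes: the simulator samples patient symptom maps
from it, and the worked examples / clinical degrees-of-freedom checks are
recomputed from it (mean duration 7.82 y, mean severity 2.55, six patients
with more than one affected right-hand digit).
"""

from __future__ import annotations

import pandas as pd

from .io import parse_finger_code

__all__ = ["REFERENCE_PATIENTS", "reference_patient_table", "reference_symptom_maps"]

#: One row per patient: (age, gender, instrument, symptomatic digit codes,
#: duration of symptoms in years, Tubiana-Chamagne severity).
REFERENCE_PATIENTS = (
    (39, "M", "piano", ("R-D1",), 2, 3),
    (49, "M", "piano", ("R-D1", "L-D1"), 5, 2),
    (56, "M", "guitar", ("R-D2",), 9, 2),
    (49, "M", "piano", ("R-D3", "R-D4", "L-D1"), 7, 3),
    (68, "M", "piano", ("R-D4", "R-D5"), 26, 2),
    (51, "M", "guitar", ("R-D1", "R-D2"), 6, 2),
    (51, "F", "guitar", ("R-D2", "R-D3", "R-D4"), 3, 2),
    (39, "M", "guitar", ("R-D3",), 2, 3),
    (47, "M", "piano", ("R-D4", "R-D5"), 4, 4),
    (51, "M", "guitar", ("R-D3", "R-D4"), 6, 3),
    (49, "M", "guitar", ("R-D1",), 16, 2),
)


def reference_patient_table() -> pd.DataFrame:
    """The reference cohort as a DataFrame (one row per patient)."""
    return pd.DataFrame(
        REFERENCE_PATIENTS,
        columns=["age", "gender", "instrument", "symptomatic_digits",
                 "duration_years", "severity"],
    )


def reference_symptom_maps() -> list[frozenset[tuple[str, str]]]:
    """Symptom maps as frozensets of (hand, finger) pairs, one per patient."""
    return [
        frozenset(parse_finger_code(c) for c in codes)
        for (_, _, _, codes, _, _) in REFERENCE_PATIENTS
    ]
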