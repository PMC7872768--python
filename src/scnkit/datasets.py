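"""Bundled example cohort: 24 complete thoracic spinal-cord-injury patients.

A small real-world clinical table used in the worked examples and the
reproduction script: per-patient age, sex, injury aetiology, injury-to-scan
interval (months), neurological injury level, impairment grade (AIS, all
grade A = complete injury), ASIA motor (0-100) and sensory (0-224) scores,
visual-analog pain score (VAS, 0-10) and WHO ICF functioning score. The
matched healthy control arm (n = 26) is summarised by its sex composition,
which is all the pipeline's demographic statistics need from it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["sci_cohort", "control_gender_counts", "gender_contingency"]

_ROWS = [
    # age, sex, etiology, duration_months, level, ais, motor, sensory, vas, icf
    (41, "M", "Fall injury", 6, "T8", "A", 50, 125, 5, 120),
    (46, "F", "Crushing injury", 9, "T7", "A", 50, 123, 5, 138),
    (40, "M", "Fall injury", 9, "T10", "A", 53, 141, 6, 112),
    (52, "M", "Vehicle accident", 5, "T10", "A", 50, 140, 7, 121),
    (19, "M", "Crushing injury", 10, "T11", "A", 56, 82, 6, 121),
    (43, "M", "Crushing injury", 3, "T12", "A", 50, 156, 3, 78),
    (23, "M", "Fall injury", 6, "T10", "A", 52, 136, 4, 100),
    (28, "M", "Fall injury", 9, "T11", "A", 53, 148, 5, 105),
    (53, "M", "Fall injury", 1, "T11", "A", 50, 146, 4, 100),
    (23, "M", "Crushing injury", 10, "T9", "A", 50, 132, 6, 125),
    (32, "M", "Fall injury", 3, "T10", "A", 52, 141, 0, 120),
    (43, "M", "Fall injury", 6, "T11", "A", 54, 148, 2, 107),
    (33, "M", "Fall injury", 3, "T11", "A", 52, 148, 10, 124),
    (39, "M", "Fall injury", 4, "T3", "A", 50, 86, 3, 140),
    (29, "M", "Fall injury", 6, "T11", "A", 52, 149, 3, 142),
    (61, "F", "Fall injury", 1, "T7", "A", 42, 112, 2, 145),
    (44, "M", "Vehicle accident", 2, "T3", "A", 50, 88, 2, 129),
    (49, "M", "Fall injury", 7, "T11", "A", 50, 148, 6, 76),
    (33, "M", "Vehicle accident", 2, "T11", "A", 60, 78, 3, 126),
    (50, "M", "Fall injury", 11, "T10", "A", 60, 143, 8, 136),
    (34, "M", "Fall injury", 3, "T9", "A", 50, 132, 3, 125),
    (43, "M", "Vehicle accident", 10, "T6", "A", 42, 108, 3, 122),
    (46, "M", "Fall injury", 4, "T10", "A", 52, 136, 0, 124),
    (20, "M", "Fall injury", 4, "T6", "A", 40, 100, 0, 129),
]

#: Sex composition of the healthy control arm: 24 male, 2 female (n = 26).
CONTROL_MALE = 24
CONTROL_FEMALE = 2


def sci_cohort() -> pd.DataFrame:
    """Return the patient table as a DataFrame, one row per patient.

    Columns: ``subject_id, group, age, gender`` (M/F), ``etiology,
    duration, level, ais, motor, sensory, vas, icf``. ``duration`` is the
    injury-to-enrolment interval in months.
    """
    df = pd.DataFrame(
        _ROWS,
        columns=["age", "gender", "etiology", "duration", "level",
                 "ais", "motor", "sensory", "vas", "icf"],
    )
    df.insert(0, "group", "SCI")
    df.insert(0, "subject_id", [f"sci-{i + 1:02d}" for i in range(len(df))])
    return df


def control_gender_counts() -> tuple[int, int]:
    """(male, female) counts of the healthy control arm."""
    return CONTROL_MALE, CONTROL_FEMALE


def gender_contingency() -> np.ndarray:
    """2x2 sex-by-group contingency table [[patients M, F], [controls M, F]]."""
    df = sci_cohort()
    pm = int((df["gender"] == "M").sum())
    return np.array([[pm, len(df) - pm], [CONTROL_MALE, CONTROL_FEMALE]])
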