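"""Benchmark tables from the published validation of the moxonidine HILIC method.

These small in-paper tables are shipped so that the validation classifiers
can be exercised against real reported numbers (and so the summary recovery
statistics can be recomputed from them).
"""

from __future__ import annotations

import pandas as pd

from .validation import RecoveryRecord

# accuracy / precision of the validated method: mean recovery and RSD per
# compound and spike level (nominal concentrations in µg/mL)
_RECOVERY_ROWS = [
    ("moxonidine", "80%", 80.0, 99.04, 1.85),
    ("moxonidine", "100%", 100.0, 101.15, 0.45),
    ("moxonidine", "120%", 120.0, 101.54, 0.32),
    ("impurity_a", "LOQ", 0.04, 95.89, 3.79),
    ("impurity_a", "100%", 0.5, 101.22, 0.35),
    ("impurity_a", "120%", 0.6, 100.51, 0.88),
    ("impurity_b", "LOQ", 0.04, 97.65, 2.92),
    ("impurity_b", "100%", 0.5, 101.28, 0.27),
    ("impurity_b", "120%", 0.6, 99.19, 0.85),
    ("impurity_c", "LOQ", 0.08, 95.95, 2.02),
    ("impurity_c", "100%", 1.0, 114.08, 0.27),
    ("impurity_c", "120%", 1.2, 93.82, 1.48),
    ("impurity_d", "LOQ", 0.08, 93.66, 2.09),
    ("impurity_d", "100%", 1.0, 100.83, 0.83),
    ("impurity_d", "120%", 1.2, 97.77, 0.39),
]

# calibration-curve statistics of the validated method: concentration range
# (µg/mL), regression line, correlation coefficient, intercept t statistic
# and the tabulated two-sided critical value at p = 0.05
_CALIBRATION_ROWS = [
    ("moxonidine", 25.0, 150.0, 29142.47, 94.864, 0.9992, 1.1968, 2.365),
    ("impurity_a", 0.04, 0.6, 24.45681, -0.09526, 0.9991, 0.0607, 2.262),
    ("impurity_b", 0.04, 0.6, 27.659, 0.1724, 0.9976, 0.5319, 2.262),
    ("impurity_c", 0.08, 1.2, 18.18141, 0.1283, 0.9982, 0.4016, 2.262),
    ("impurity_d", 0.08, 1.2, 11.82117, 0.1404, 0.9976, 0.5762, 2.262),
]


def reference_recovery_table() -> pd.DataFrame:
    """Published accuracy/precision rows (15 records: 5 compounds × 3 levels)."""
    return pd.DataFrame(
        _RECOVERY_ROWS,
        columns=["compound", "level", "nominal_ug_ml", "recovery_pct", "rsd_pct"],
    )


def reference_recovery_records() -> list[RecoveryRecord]:
    """The same rows as :class:`RecoveryRecord` objects, ready for assessment."""
    records = []
    for compound, level, nominal, recovery, rsd in _RECOVERY_ROWS:
        role = "API" if compound == "moxonidine" else "impurity"
        records.append(RecoveryRecord(
            compound=compound, level=level, nominal_ug_ml=nominal,
            found_ug_ml=nominal * recovery / 100.0,
            recovery_pct=recovery, rsd_pct=rsd, role=role,
        ))
    return records


def reference_calibration_table() -> pd.DataFrame:
    """Published calibration statistics (slope, intercept, r, intercept t)."""
    return pd.DataFrame(
        _CALIBRATION_ROWS,
        columns=["compound", "range_low_ug_ml", "range_high_ug_ml",
                 "slope", "intercept", "r", "t", "t_tab"],
    )
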