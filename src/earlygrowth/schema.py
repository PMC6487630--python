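"""Column dictionary for the wide per-child cohort table and the long
infant observation table.

Wide table: one row per child, fixed visit schedule (second/third-trimester
ultrasound, birth, ~6/12/24-month infant visits, ~10-year childhood visit).
Long table: one row per infant weight/length measurement, used by the
trajectory models.
"""
from __future__ import annotations

#: Categorical columns and their admissible string levels.
CATEGORICAL_LEVELS = {
    "sex": ("boy", "girl"),
    "education": ("lower", "higher"),
    "smoking": ("no", "yes"),
    "folic_acid": ("no", "yes"),
    "ethnicity": ("european", "non_european"),
    "breastfeeding": ("never", "ever"),
}

#: Numeric wide columns with plausibility bounds (checked on the median).
NUMERIC_BOUNDS = {
    "maternal_age": (14, 55),
    "prepregnancy_bmi": (13, 60),
    "parity": (0, 15),
    "ga_20w_wk": (14, 28),
    "hc_20w_cm": (8, 30),
    "ac_20w_cm": (6, 30),
    "fl_20w_cm": (0.8, 6),
    "ga_30w_wk": (25, 36),
    "hc_30w_cm": (20, 36),
    "ac_30w_cm": (18, 36),
    "fl_30w_cm": (3.5, 8),
    "birth_ga_wk": (22, 44),
    "birth_weight_g": (300, 6500),
    "age_6mo_mo": (3, 10),
    "weight_6mo_kg": (3, 14),
    "length_6mo_cm": (55, 80),
    "age_12mo_mo": (9, 16),
    "weight_12mo_kg": (5, 17),
    "length_12mo_cm": (60, 90),
    "age_24mo_mo": (18, 32),
    "weight_24mo_kg": (7, 25),
    "length_24mo_cm": (70, 105),
    "child_age_yr": (6, 14),
    "height_cm": (100, 180),
    "weight_kg": (15, 90),
    "fat_mass_kg": (1, 50),
    "fat_free_mass_kg": (10, 60),
    "visceral_fat_vol_ml": (30, 3000),
    "pericardial_fat_vol_ml": (1, 100),
    "liver_fat_pct_s1": (0, 100),
    "liver_fat_pct_s2": (0, 100),
    "liver_fat_pct_s3": (0, 100),
    "liver_fat_pct_s4": (0, 100),
}

WIDE_COLUMNS = ["child_id"] + list(CATEGORICAL_LEVELS)[:1] + [
    "maternal_age",
    "prepregnancy_bmi",
    "parity",
] + list(CATEGORICAL_LEVELS)[1:] + [c for c in NUMERIC_BOUNDS if c not in ("maternal_age", "prepregnancy_bmi", "parity")]

#: Columns that must exist for the pipeline to run at all.
MANDATORY_COLUMNS = [
    "child_id",
    "sex",
    "ga_20w_wk",
    "hc_20w_cm",
    "ac_20w_cm",
    "fl_20w_cm",
    "birth_ga_wk",
    "birth_weight_g",
]

OBS_COLUMNS = ["child_id", "sex", "age_mo", "weight_kg", "length_cm"]
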