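"""Default distribution settings for the synthetic CKD cohort.

Every number used by the generator lives here. The defaults are plausibility
choices for a moderately aged chronic-kidney-disease cohort; they are NOT
estimates taken from any real study data. They are chosen so that the
downstream analyses see the structure they assume: near-total uniqueness on
the quasi-identifier combination, a BMI column consistent with height and
weight, and diabetes-linked shifts in albuminuria, eGFR and blood pressure.
"""

from __future__ import annotations

# --- cohort shape -----------------------------------------------------------
N_RECORDS = 5217
N_COLUMNS = 70
DEFAULT_SEED = 42

# --- quasi-identifiers ------------------------------------------------------
# age in whole years, truncated normal
AGE_MEAN = 60.0
AGE_SD = 12.0
AGE_RANGE = (18, 74)

# gender: dichotomous, recorded as strings
GENDER_LEVELS = ("female", "male")
MALE_P = 0.60

# height (cm, integer resolution), conditional on gender
HEIGHT_BY_GENDER = {"male": (178.0, 7.0), "female": (165.0, 7.0)}
HEIGHT_RANGE = (140, 210)

# weight (kg, integer resolution) is generated through a latent BMI so that
# the anthropometric triple is interdependent by construction
LATENT_BMI_MEAN = 29.0
LATENT_BMI_SD = 5.0
LATENT_BMI_RANGE = (16.0, 60.0)
WEIGHT_RANGE = (35, 160)
BMI_RANGE = (15.0, 70.0)  # recorded BMI must stay inside this domain

RENAL_BIOPSY_LEVELS = ("no", "yes")
RENAL_BIOPSY_P = 0.25

# --- analysis variables -----------------------------------------------------
DIABETES_LEVELS = ("no", "yes")
DIABETES_P = 0.35

EGFR_MEAN = 49.0
EGFR_SD = 18.0
EGFR_DIABETES_SHIFT = -4.0
EGFR_RANGE = (5, 120)  # mL/min, integer resolution
EGFR_MISSING_RATE = 0.01

UACR_LEVELS = ("<30", "30-300", ">300")  # mg/g
UACR_PROBS = {"no": (0.45, 0.35, 0.20), "yes": (0.25, 0.35, 0.40)}
UACR_MISSING_RATE = 0.05

SBP_MEAN = 139.0
SBP_SD = 18.0
SBP_DIABETES_SHIFT = 6.0
SBP_RANGE = (80, 220)  # mm Hg, integer resolution
SBP_MISSING_RATE = 0.02

MEDICATION_LEVELS = ("no", "yes")
MEDICATION_PROBS = {
    "ace_inhibitor": 0.45,
    "arb": 0.25,
    "statin": 0.50,
    "diuretic": 0.40,
}
MEDICATION_STATIN_DIABETES_SHIFT = 0.15
MEDICATION_MISSING_RATE = 0.0

CKD_CAUSE_LEVELS = (
    "diabetic_nephropathy",
    "vascular",
    "glomerulonephritis",
    "interstitial",
    "other",
)
CKD_CAUSE_PROBS = {
    "no": (0.02, 0.25, 0.35, 0.13, 0.25),
    "yes": (0.45, 0.20, 0.12, 0.08, 0.15),
}
CKD_CAUSE_MISSING_RATE = 0.10

# --- filler variables -------------------------------------------------------
# Inert independent noise columns padding the table to N_COLUMNS; they carry
# no clinical meaning and exist only so the column count of the emulated
# extract is reproducible.
FILLER_BINARY_P = 0.5
FILLER_CONTINUOUS_MEAN = 0.0
FILLER_CONTINUOUS_SD = 1.0
FILLER_MISSING_RATE = 0.02
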