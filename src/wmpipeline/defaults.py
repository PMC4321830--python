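"""Default calibration tables for the synthetic cohort and phantoms.

The biomarker population parameters, cohort composition and risk-factor
incidence rates are the published summary statistics the generator is
calibrated against.  Structural contrast values and CSF parametric values are
synthetic plumbing chosen so the segmentation problem is well posed.
"""

from __future__ import annotations

BIOMARKERS = ("FA", "MD", "MTR", "T1")

#: per-Fazekas-score cohort sizes (total 676)
GROUP_SIZES: dict[int, int] = {0: 9, 1: 100, 2: 311, 3: 143, 4: 72, 5: 28, 6: 13}

#: per-score male counts, used to derive gender fractions
MALE_COUNTS: dict[int, int] = {0: 6, 1: 57, 2: 161, 3: 86, 4: 32, 5: 13, 6: 3}

#: age range in years for the uniform age model
AGE_RANGE_YEARS = (71.0, 74.2)
DAYS_PER_YEAR = 365.25

#: population (mean, SD) per biomarker per tissue; MD in 1e-9 m^2/s, MTR in %, T1 in s
BIOMARKER_TABLE: dict[str, dict[str, tuple[float, float]]] = {
    "FA": {"nawm": (0.338, 0.024), "wmh": (0.299, 0.042)},
    "MD": {"nawm": (0.692, 0.034), "wmh": (0.833, 0.061)},
    "MTR": {"nawm": (56.80, 0.99), "wmh": (54.37, 1.51)},
    "T1": {"nawm": (1.002, 0.092), "wmh": (1.086, 0.117)},
}

#: between-tissue subject-level correlation for paired draws (generator
#: parameter; pooled-SD effect sizes are independent of it)
DEFAULT_RHO = 0.6

#: NAWM (mean, SD) per biomarker for each total Fazekas score group
PER_SCORE_NAWM: dict[int, dict[str, tuple[float, float]]] = {
    0: {"FA": (0.336, 0.037), "MD": (0.675, 0.042), "MTR": (56.9, 1.0), "T1": (1.02, 0.12)},
    1: {"FA": (0.343, 0.020), "MD": (0.681, 0.031), "MTR": (56.7, 1.1), "T1": (1.00, 0.10)},
    2: {"FA": (0.342, 0.023), "MD": (0.688, 0.033), "MTR": (56.8, 0.9), "T1": (0.99, 0.09)},
    3: {"FA": (0.335, 0.022), "MD": (0.698, 0.035), "MTR": (57.0, 0.9), "T1": (1.00, 0.09)},
    4: {"FA": (0.328, 0.023), "MD": (0.709, 0.034), "MTR": (56.5, 1.0), "T1": (1.01, 0.09)},
    5: {"FA": (0.314, 0.026), "MD": (0.712, 0.028), "MTR": (56.8, 1.0), "T1": (1.07, 0.07)},
    6: {"FA": (0.299, 0.025), "MD": (0.720, 0.029), "MTR": (56.5, 1.1), "T1": (1.09, 0.11)},
}

#: self-reported vascular risk factor incidence, percent, by gender
VRF_INCIDENCE: dict[str, tuple[float, float]] = {
    # factor: (male %, female %)
    "current_smoker": (7.8, 8.5),
    "ex_smoker": (50.8, 38.7),
    "hypertension": (50.8, 46.9),
    "diabetes": (13.1, 6.6),
    "hypercholesterolemia": (42.5, 40.9),
    "cardiovascular_disease": (33.2, 19.8),
    "stroke": (18.2, 15.6),
}

VRF_FACTORS = tuple(VRF_INCIDENCE)

#: fixed parametric values assigned to CSF voxels (plausible fluid values)
CSF_PARAMETRIC = {"FA": 0.1, "MD": 3.0, "MTR": 5.0, "T1": 4.0}

#: structural contrast (mean, SD) in arbitrary scanner units per tissue.
#: Chosen so T1W+T2W separates NAWM (bright red) and CSF (bright green), and
#: FLAIR makes WMH the brightest green class in the T2*W+FLAIR fusion.
CONTRAST_TABLE: dict[str, dict[str, tuple[float, float]]] = {
    "T1W": {"csf": (50.0, 6.0), "nawm": (200.0, 8.0), "wmh": (150.0, 8.0), "stroke": (120.0, 8.0)},
    "T2W": {"csf": (230.0, 8.0), "nawm": (90.0, 8.0), "wmh": (160.0, 8.0), "stroke": (180.0, 8.0)},
    "FLAIR": {"csf": (40.0, 6.0), "nawm": (120.0, 8.0), "wmh": (220.0, 8.0), "stroke": (180.0, 8.0)},
    "T2SW": {"csf": (180.0, 8.0), "nawm": (110.0, 8.0), "wmh": (135.0, 8.0), "stroke": (90.0, 8.0)},
}

STRUCTURAL_MODALITIES = ("T1W", "T2W", "FLAIR", "T2SW")

#: penumbra defaults (synthetic; qualitatively reproduce the decaying
#: distance trends, not estimated from any measurement)
PENUMBRA_AMPLITUDE = 0.3
PENUMBRA_DECAY_MM = 4.0

DEFAULT_QUANTIZE_LEVELS = 16
SHELL_STEP_MM = 2.0
SHELL_MAX_MM = 10.0


def total_cohort_size(group_sizes: dict[int, int] | None = None) -> int:
    sizes = GROUP_SIZES if group_sizes is None else group_sizes
    return int(sum(sizes.values()))
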