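"""Published reference values from the seven-park Shanghai field study.

The original field campaign (68 plots of 30 m x 30 m across seven urban
parks, observed October--November 2024) released its fitted models and
descriptive tables but not its raw data.  This module packages those
printed values so that (a) the synthetic-data generator can be calibrated
to realistic study conditions and (b) the fitted prediction equations can
be applied to new parks without re-running the field work.

Landscape fractions are stored on the [0, 1] scale; the source tables
print them as percentages.
"""

from __future__ import annotations

FEATURES: tuple[str, ...] = (
    "sky",
    "water",
    "tree",
    "shrub",
    "grass",
    "building",
    "pavement",
    "rough_ground",
    "resting_facility",
    "service_facility",
    "shading_facility",
)

OUTCOMES: tuple[str, ...] = ("OBI", "EBI", "LBI", "SBI")

#: Number of 30x30 m measurement plots per park in the original design.
PARK_PLOT_COUNTS: dict[str, int] = {
    "UP-1": 5,   # Jiangpu
    "UP-2": 5,   # Quyang
    "UP-3": 5,   # Fuxing
    "UP-4": 10,  # Jinqiao
    "UP-5": 12,  # Zhabei
    "UP-6": 15,  # Zhongshan
    "UP-7": 16,  # Daning
}

#: Photo protocol of the field campaign: >= 9 shooting points per plot,
#: 4 compass directions each.
PHOTO_POINTS_PER_PLOT = 9
PHOTO_DIRECTIONS = 4

#: Overall landscape-composition means and SDs across the 68 plots
#: (fractions of image pixels), used as generator defaults.
LANDSCAPE_MEANS: dict[str, float] = {
    "sky": 0.1476,
    "water": 0.0207,
    "tree": 0.3626,
    "shrub": 0.0605,
    "grass": 0.0459,
    "building": 0.0288,
    "pavement": 0.1289,
    "rough_ground": 0.0548,
    "resting_facility": 0.0014,
    "service_facility": 0.0005,
    "shading_facility": 0.0431,
}

LANDSCAPE_SDS: dict[str, float] = {
    "sky": 0.09,
    "water": 0.03,
    "tree": 0.11,
    "shrub": 0.04,
    "grass": 0.06,
    "building": 0.02,
    "pavement": 0.07,
    "rough_ground": 0.04,
    "resting_facility": 0.002,
    "service_facility": 0.001,
    "shading_facility": 0.05,
}

#: Per-park and overall intensity summaries (MET.persons) as published.
#: Each entry: outcome -> (mean, sd).
INTENSITY_SUMMARY: dict[str, dict[str, tuple[float, float]]] = {
    "Overall": {"OBI": (463.98, 253.36), "EBI": (192.91, 187.37),
                "LBI": (128.47, 84.11), "SBI": (145.55, 170.37)},
    "UP-1": {"OBI": (523.30, 253.17), "EBI": (148.30, 151.38),
             "LBI": (182.30, 45.51), "SBI": (192.70, 91.36)},
    "UP-2": {"OBI": (487.34, 175.55), "EBI": (189.80, 134.28),
             "LBI": (119.94, 95.01), "SBI": (177.60, 85.15)},
    "UP-3": {"OBI": (460.58, 315.84), "EBI": (92.02, 58.66),
             "LBI": (177.60, 88.52), "SBI": (190.96, 241.85)},
    "UP-4": {"OBI": (470.86, 208.80), "EBI": (228.14, 193.84),
             "LBI": (172.47, 124.12), "SBI": (70.25, 49.77)},
    "UP-5": {"OBI": (482.25, 222.33), "EBI": (263.03, 184.42),
             "LBI": (137.83, 65.18), "SBI": (81.39, 60.95)},
    "UP-6": {"OBI": (465.49, 311.46), "EBI": (252.38, 239.99),
             "LBI": (80.27, 49.04), "SBI": (132.84, 191.09)},
    "UP-7": {"OBI": (419.79, 279.50), "EBI": (108.98, 154.47),
             "LBI": (109.62, 78.02), "SBI": (213.70, 240.07)},
}

#: Published per-subcategory participant counts (the study's most frequent
#: activities) out of OBSERVED_TOTAL_PARTICIPANTS visitors.
OBSERVED_TOTAL_PARTICIPANTS = 11_987
OBSERVED_ACTIVITY_COUNTS: dict[int, int] = {
    202: 2_857,  # resting (sitting)
    208: 788,    # card games
    205: 721,    # walking
    305: 879,    # parent-child activities
    302: 781,    # group conversations
    306: 724,    # camping
    112: 995,    # social dancing
    104: 510,    # aerobics
    101: 368,    # stretching
}

#: Age-group, gender and day-type shares of all observed visitors.
DEMOGRAPHIC_SHARES: dict[str, dict[str, float]] = {
    "age_group": {"older_adult": 0.69, "adult": 0.22,
                  "child": 0.08, "adolescent": 0.01},
    "gender": {"female": 0.52, "male": 0.48},
    "day_type": {"weekend": 0.56, "weekday": 0.44},
}

#: Observer reliability reported for the dual-coded parks.
REFERENCE_ICC = 0.979
REFERENCE_AGREEMENT_PCT = 93.1

# ---------------------------------------------------------------------------
# Fitted regression models.
#
# REDUCED_MODEL_TERMS are the published prediction equations (significant
# terms only); FULL_MODEL_TERMS are the complete fitted term sets with
# their standard errors as printed.  Diagnostics (R2, adjusted R2, overall
# F-test p) describe the full fits.
# ---------------------------------------------------------------------------

REDUCED_MODEL_TERMS: dict[str, dict[str, float]] = {
    "OBI": {"const": 281.63, "sky": 857.13, "pavement": 1040.91,
            "rough_ground": -1736.40},
    "EBI": {"const": -167.14, "tree": 762.37, "pavement": 1462.50,
            "rough_ground": -1553.52, "resting_facility": -27547.01},
    "LBI": {"const": 119.00, "shrub": 585.04},
    "SBI": {"const": -106.58, "sky": 1261.75},
}

FULL_MODEL_TERMS: dict[str, dict[str, tuple[float, float]]] = {
    # outcome -> term -> (estimate, std. error)
    "OBI": {
        "const": (281.63, 130.46),
        "sky": (857.13, 331.32),
        "water": (812.55, 973.18),
        "pavement": (1040.91, 505.92),
        "rough_ground": (-1736.40, 873.98),
    },
    "EBI": {
        "const": (-167.14, 124.97),
        "water": (539.54, 711.73),
        "tree": (762.37, 206.27),
        "grass": (147.14, 402.78),
        "pavement": (1462.50, 400.58),
        "rough_ground": (-1553.52, 606.02),
        "resting_facility": (-27547.01, 12413.63),
    },
    "LBI": {
        "const": (119.00, 23.15),
        "shrub": (585.04, 237.29),
        "rough_ground": (-473.24, 261.63),
    },
    "SBI": {
        "const": (-106.58, 210.36),
        "sky": (1261.75, 389.71),
        "tree": (118.39, 333.11),
        "shrub": (-540.11, 452.20),
        "building": (1447.28, 1163.77),
        "rough_ground": (152.50, 539.41),
        "service_facility": (10657.09, 36168.39),
    },
}

MODEL_DIAGNOSTICS: dict[str, dict[str, float]] = {
    "OBI": {"r2": 0.297, "adj_r2": 0.252, "f_pvalue": 0.000157},
    "EBI": {"r2": 0.463, "adj_r2": 0.410, "f_pvalue": 6.86e-07},
    "LBI": {"r2": 0.134, "adj_r2": 0.108, "f_pvalue": 0.00918},
    "SBI": {"r2": 0.433, "adj_r2": 0.377, "f_pvalue": 3.24e-06},
}
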