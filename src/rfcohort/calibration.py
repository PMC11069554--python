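"""Printed group statistics of the five-week exposure study.

Each cell is the published ``(mean, dispersion)`` for one endpoint, one age
group (juvenile / adult / presenile male Wistar rats, n = 10 per arm) and
one arm (exposed to the 5G NR antenna vs sham-housed control).  Dispersions
are treated as per-animal standard deviations throughout (the published
"standard error" label is not numerically plausible at n = 10; see
docs/methods.md).

Timepoints: body weight at baseline plus weeks 1-5; rectal and hind-limb
skin temperature at baseline plus weeks 1-4; organ masses at necropsy as a
percentage of terminal body weight; water-maze testing on days 1, 2, 3, 4
and 7 with four 60 s trials per day.
"""

from __future__ import annotations

AGE_GROUPS = ("juvenile", "adult", "presenile")
ARMS = ("exposed", "control")

WEIGHT_TIMEPOINTS = ("baseline", "week1", "week2", "week3", "week4", "week5")
TEMP_TIMEPOINTS = ("baseline", "week1", "week2", "week3", "week4")
ORGANS = ("brain", "heart", "liver", "left_testicle", "right_testicle")
MWM_DAYS = (1, 2, 3, 4, 7)
TRIALS_PER_DAY = 4
N_ANIMALS = 10

# Body weight [g], (mean, sd) at the six timepoints.
BODY_WEIGHT_G = {
    ("juvenile", "control"): [(227.4, 15.8), (273.8, 21.2), (298.7, 23.9),
                              (316.5, 27.6), (328.2, 27.9), (338.3, 28.2)],
    ("juvenile", "exposed"): [(232.7, 20.6), (280.1, 22.2), (299.7, 18.7),
                              (313.3, 24.0), (327.0, 25.6), (344.3, 27.0)],
    ("adult", "control"): [(260.2, 18.9), (298.2, 22.2), (317.4, 26.5),
                           (335.7, 26.7), (348.3, 25.9), (346.4, 27.8)],
    ("adult", "exposed"): [(273.3, 20.7), (314.5, 30.0), (331.1, 30.6),
                           (347.3, 33.9), (355.4, 31.5), (368.3, 33.5)],
    ("presenile", "control"): [(495.1, 55.1), (495.0, 62.1), (497.3, 61.4),
                               (498.1, 64.2), (513.2, 54.1), (519.2, 84.2)],
    ("presenile", "exposed"): [(488.0, 43.9), (488.5, 48.0), (490.5, 45.8),
                               (493.9, 49.3), (509.9, 54.5), (493.4, 51.4)],
}

# Organ weight coefficients [% of terminal body weight], (mean, sd) per organ.
ORGAN_COEFF_PCT = {
    ("juvenile", "control"): {"brain": (0.53, 0.03), "heart": (0.26, 0.01),
                              "liver": (4.81, 0.42), "left_testicle": (0.54, 0.06),
                              "right_testicle": (0.48, 0.07)},
    ("juvenile", "exposed"): {"brain": (0.54, 0.05), "heart": (0.29, 0.08),
                              "liver": (4.22, 0.74), "left_testicle": (0.59, 0.08),
                              "right_testicle": (0.58, 0.09)},
    ("adult", "control"): {"brain": (0.51, 0.04), "heart": (0.22, 0.05),
                           "liver": (4.54, 0.18), "left_testicle": (0.50, 0.06),
                           "right_testicle": (0.50, 0.07)},
    ("adult", "exposed"): {"brain": (0.52, 0.12), "heart": (0.23, 0.02),
                           "liver": (4.73, 0.34), "left_testicle": (0.55, 0.05),
                           "right_testicle": (0.56, 0.04)},
    ("presenile", "control"): {"brain": (0.35, 0.06), "heart": (0.24, 0.02),
                               "liver": (3.33, 0.64), "left_testicle": (0.43, 0.05),
                               "right_testicle": (0.43, 0.05)},
    ("presenile", "exposed"): {"brain": (0.38, 0.02), "heart": (0.25, 0.02),
                               "liver": (3.42, 0.57), "left_testicle": (0.44, 0.02),
                               "right_testicle": (0.45, 0.01)},
}

# Rectal temperature [deg C], (mean, sd) at the five timepoints.
RECTAL_C = {
    ("juvenile", "control"): [(37.6, 0.6), (37.5, 0.3), (37.5, 0.4),
                              (37.9, 0.3), (37.7, 0.2)],
    ("juvenile", "exposed"): [(37.4, 0.6), (37.6, 0.5), (37.3, 0.3),
                              (37.6, 0.3), (37.4, 0.4)],
    ("adult", "control"): [(37.5, 0.4), (37.7, 0.4), (37.4, 0.5),
                           (37.8, 0.3), (37.5, 0.3)],
    ("adult", "exposed"): [(37.7, 0.3), (37.8, 0.4), (37.3, 0.5),
                           (37.4, 0.6), (37.8, 0.3)],
    ("presenile", "control"): [(36.8, 0.7), (36.4, 0.4), (36.3, 0.5),
                               (36.8, 0.6), (37.3, 0.4)],
    ("presenile", "exposed"): [(36.4, 0.8), (37.0, 0.6), (36.0, 0.7),
                               (37.1, 0.6), (37.5, 0.5)],
}

# Hind-limb skin surface temperature [deg C], (mean, sd).
SKIN_C = {
    ("juvenile", "control"): [(35.8, 0.4), (35.3, 0.6), (36.3, 0.2),
                              (36.1, 0.1), (36.2, 0.2)],
    ("juvenile", "exposed"): [(35.8, 0.6), (35.8, 0.5), (36.3, 0.3),
                              (36.1, 0.1), (36.3, 0.1)],
    ("adult", "control"): [(36.1, 0.2), (36.1, 0.2), (36.0, 0.3),
                           (36.0, 0.3), (36.1, 0.1)],
    ("adult", "exposed"): [(36.0, 0.2), (36.1, 0.5), (36.1, 0.2),
                           (36.0, 0.2), (36.2, 0.2)],
    ("presenile", "control"): [(36.3, 0.2), (36.2, 0.4), (36.2, 0.1),
                               (36.0, 0.3), (36.1, 0.1)],
    ("presenile", "exposed"): [(35.7, 0.9), (36.2, 0.1), (36.1, 0.2),
                               (36.1, 0.2), (36.2, 0.2)],
}

# Water maze: successful-swim latency [s], (mean, sd) per testing day.
MWM_LATENCY_S = {
    ("juvenile", "control"): {1: (28.9, 15.4), 2: (21.1, 8.0), 3: (15.8, 3.3),
                              4: (19.5, 9.5), 7: (21.5, 7.0)},
    ("juvenile", "exposed"): {1: (27.3, 8.3), 2: (21.7, 7.2), 3: (19.2, 4.4),
                              4: (18.3, 5.9), 7: (21.3, 8.2)},
    ("adult", "control"): {1: (22.2, 8.2), 2: (23.9, 10.4), 3: (17.7, 7.7),
                           4: (15.9, 6.1), 7: (17.0, 9.5)},
    ("adult", "exposed"): {1: (25.8, 9.6), 2: (22.7, 8.6), 3: (17.5, 6.1),
                           4: (14.8, 5.5), 7: (13.2, 4.9)},
    ("presenile", "control"): {1: (37.7, 9.5), 2: (22.4, 6.0), 3: (21.8, 6.3),
                               4: (16.4, 7.5), 7: (16.9, 7.1)},
    ("presenile", "exposed"): {1: (30.4, 9.1), 2: (23.1, 5.2), 3: (21.1, 11.1),
                               4: (16.9, 5.3), 7: (15.6, 3.7)},
}

# Water maze: percentage of successful swims per testing day.
MWM_SUCCESS_PCT = {
    ("juvenile", "control"): {1: 55.5, 2: 63.9, 3: 81.2, 4: 83.3, 7: 90.6},
    ("juvenile", "exposed"): {1: 63.6, 2: 86.4, 3: 93.2, 4: 97.7, 7: 90.0},
    ("adult", "control"): {1: 65.0, 2: 92.5, 3: 92.5, 4: 100.0, 7: 100.0},
    ("adult", "exposed"): {1: 65.9, 2: 90.0, 3: 93.2, 4: 97.7, 7: 95.4},
    ("presenile", "control"): {1: 59.1, 2: 81.8, 3: 95.4, 4: 95.4, 7: 95.4},
    ("presenile", "exposed"): {1: 66.7, 2: 85.4, 3: 91.7, 4: 95.8, 7: 100.0},
}

# Stylized probability that a FAILED trial is scored as passive swimming
# (drifting until rescue).  Concentrated on day 1 and decaying, matching the
# published qualitative pattern; not a reverse-engineered roster.
PASSIVE_PROB_BY_DAY = {1: 0.50, 2: 0.35, 3: 0.25, 4: 0.15, 7: 0.10}

# Cage numbering of the housing plan: exposed arms in odd-numbered cages
# under the antenna, controls in even-numbered cages in the sham room.
# Presenile animals were housed 5 per cage in two cages per arm.
CAGE_IDS = {
    ("juvenile", "exposed"): (1,), ("juvenile", "control"): (2,),
    ("adult", "exposed"): (3,), ("adult", "control"): (4,),
    ("presenile", "exposed"): (1, 3), ("presenile", "control"): (2, 4),
}

# Exposure geometry: antenna input power / gain / carrier, the two cage
# placements, and the cohort physique entering the SAR scaling.  The cage
# extent along the beam axis is the 375 mm cage dimension; mean lengths are
# working assumptions (not published) and are flagged as such in reports.
ANTENNA = {"power_input_w": 0.0891, "gain_db": 7.0, "frequency_ghz": 2.4}

EXPOSURE_SCENARIOS = {
    # presenile cages at 12 cm; mass = mean of the two baseline group means
    "exposure_1": {"r_near_m": 0.12, "cage_extent_m": 0.375,
                   "mean_mass_kg": 0.49155, "mean_length_m": 0.25,
                   "s_avg_published_wm2": 0.605,
                   "age_groups": ("presenile",)},
    # juvenile + adult cages at 20 cm; pooled baseline mass, shorter animals
    "exposure_2": {"r_near_m": 0.20, "cage_extent_m": 0.375,
                   "mean_mass_kg": 0.2484, "mean_length_m": 0.19,
                   "s_avg_published_wm2": 0.31,
                   "age_groups": ("juvenile", "adult")},
}

ASSUMED_MEAN_LENGTHS = True  # mean_length_m values above are assumptions
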