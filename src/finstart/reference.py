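"""Published summary statistics for amberjack fast-start tank experiments.

These constants describe the study conditions the synthetic generator
emulates and serve as worked-example inputs: five tagged Japanese amberjacks
(Seriola quinqueradiata), 41 escape and 41 feeding events, 500 Hz 9-axis
logger, 1-s analysis segments.  Per-class locomotor variables are given as
(mean, SEM) with n = 41 per class; class SDs are reconstructed as
``SEM * sqrt(41)``.

All acceleration values are m s^-2, angular velocities deg s^-1.
"""

from __future__ import annotations

import math

N_PER_CLASS = 41

#: Per-fish escape / feeding event counts (fish A-E).
FISH_EVENT_COUNTS: dict[str, tuple[int, int]] = {
    "A": (11, 10),
    "B": (8, 11),
    "C": (11, 20),
    "D": (4, 0),
    "E": (7, 0),
}

#: Windowed (1 s) SD of acceleration magnitude, (mean, SEM), n = 82 windows.
FS_SD_MA = (11.77, 0.53)
RM_SD_MA = (2.47, 0.12)
#: Windowed (1 s) SD of angular-velocity magnitude, (mean, SEM).
FS_SD_MG = (229.22, 9.30)
RM_SD_MG = (64.27, 3.97)
N_SD_WINDOWS = 82

#: Detection thresholds learned by a depth-1 decision tree.
MA_THRESHOLD = 5.16      # m s^-2
MG_THRESHOLD = 129.32    # deg s^-1
#: Detection performance at those thresholds.
MA_DETECTION = {"precision": 0.98, "recall": 0.96}
MG_DETECTION = {"precision": 0.78, "recall": 0.92}

# ---------------------------------------------------------------------------
# Axis-specific variables, (escape_mean, escape_sem, feeding_mean, feeding_sem)
# ---------------------------------------------------------------------------

#: Dynamic acceleration (all-combined) + angular velocity (shared with
#: gyro-only: fusion does not touch the gyro channel).
AXIS_COMBINED: dict[str, tuple[float, float, float, float]] = {
    "MaxAx": (89.05, 4.37, 49.04, 3.32),
    "MaxAy": (46.99, 3.30, 32.10, 2.04),
    "MaxAz": (65.87, 3.33, 39.58, 2.34),
    "RangeAx": (133.21, 6.01, 81.02, 5.05),
    "RangeAy": (69.43, 4.30, 53.28, 3.51),
    "RangeAz": (112.56, 5.61, 70.27, 4.31),
    "MeanAx": (0.05, 0.11, 0.00, 0.15),
    "MeanAy": (0.61, 0.07, 0.58, 0.10),
    "MeanAz": (0.32, 0.05, 0.36, 0.08),
    "SDAx": (8.58, 0.46, 7.09, 0.51),
    "SDAy": (5.26, 0.31, 4.82, 0.30),
    "SDAz": (7.56, 0.36, 6.41, 0.44),
    "RMSAx": (8.60, 0.46, 7.16, 0.51),
    "RMSAy": (5.31, 0.31, 4.87, 0.31),
    "RMSAz": (7.57, 0.36, 6.44, 0.44),
    "MaxGx": (477.60, 32.84, 340.53, 17.98),
    "MaxGy": (1298.94, 70.61, 962.76, 71.63),
    "MaxGz": (814.68, 29.19, 530.88, 25.47),
    "RangeGx": (652.46, 38.29, 534.58, 26.98),
    "RangeGy": (2367.95, 137.93, 1701.25, 132.55),
    "RangeGz": (1145.68, 57.64, 841.51, 40.84),
    "MeanGx": (6.54, 2.50, 5.17, 3.66),
    "MeanGy": (0.44, 1.22, 4.69, 2.39),
    "MeanGz": (23.12, 6.92, 14.47, 10.59),
    "SDGx": (63.75, 3.81, 65.29, 3.11),
    "SDGy": (192.06, 12.20, 182.76, 16.18),
    "SDGz": (138.78, 5.86, 139.67, 6.55),
    "RMSGx": (65.80, 3.89, 68.89, 3.43),
    "RMSGy": (192.16, 12.18, 183.44, 16.15),
    "RMSGz": (146.91, 6.18, 154.53, 7.29),
}

#: Raw acceleration (acc-only: gravity retained).
AXIS_ACC_ONLY: dict[str, tuple[float, float, float, float]] = {
    "MaxAx": (87.82, 4.39, 50.40, 3.30),
    "MaxAy": (46.65, 3.26, 33.33, 2.13),
    "MaxAz": (65.98, 3.11, 44.21, 2.24),
    "RangeAx": (135.41, 6.11, 83.16, 5.09),
    "RangeAy": (69.98, 4.26, 53.38, 3.54),
    "RangeAz": (114.17, 5.66, 70.43, 4.32),
    "MeanAx": (-2.16, 0.31, -0.92, 0.38),
    "MeanAy": (-0.08, 0.11, 0.75, 0.24),
    "MeanAz": (-8.72, 0.07, -8.45, 0.11),
    "SDAx": (8.89, 0.46, 7.48, 0.53),
    "SDAy": (5.41, 0.30, 5.16, 0.31),
    "SDAz": (7.71, 0.36, 6.46, 0.44),
    "RMSAx": (9.41, 0.43, 8.02, 0.49),
    "RMSAy": (5.45, 0.30, 5.43, 0.31),
    "RMSAz": (11.77, 0.25, 10.88, 0.28),
}

# ---------------------------------------------------------------------------
# Inter-axial variables
# ---------------------------------------------------------------------------

INTER_COMBINED: dict[str, tuple[float, float, float, float]] = {
    "DiffMaxAxAy": (42.06, 4.19, 16.94, 2.71),
    "DiffMaxAyAz": (-18.88, 2.86, -7.48, 2.32),
    "DiffMaxAxAz": (23.18, 3.80, 9.46, 2.52),
    "DiffRangeAxAy": (63.77, 4.64, 27.74, 3.74),
    "DiffRangeAyAz": (-43.13, 4.55, -16.98, 3.94),
    "DiffRangeAxAz": (20.64, 4.50, 10.75, 3.72),
    "DiffMeanAxAy": (-0.57, 0.13, -0.58, 0.19),
    "DiffMeanAyAz": (0.29, 0.08, 0.22, 0.11),
    "DiffMeanAxAz": (-0.28, 0.11, -0.36, 0.18),
    "DiffSDAxAy": (3.32, 0.23, 2.27, 0.27),
    "DiffSDAyAz": (-2.30, 0.23, -1.59, 0.26),
    "DiffSDAxAz": (1.02, 0.27, 0.68, 0.29),
    "DiffRMSAxAy": (3.29, 0.23, 2.29, 0.26),
    "DiffRMSAyAz": (-2.26, 0.23, -1.57, 0.26),
    "DiffRMSAxAz": (1.03, 0.27, 0.72, 0.29),
    "DiffMaxGxGy": (-821.34, 60.99, -622.23, 66.56),
    "DiffMaxGyGz": (484.26, 66.7, 431.88, 67.71),
    "DiffMaxGxGz": (-337.08, 34.88, -190.35, 23.54),
    "DiffRangeGxGy": (-1715.49, 120.19, -1166.67, 120.46),
    "DiffRangeGyGz": (1222.27, 116.58, 859.74, 125.18),
    "DiffRangeGxGz": (-493.22, 44.59, -306.93, 34.39),
    "DiffMeanGxGy": (6.10, 2.44, 0.48, 5.15),
    "DiffMeanGyGz": (-22.67, 6.66, -9.78, 11.87),
    "DiffMeanGxGz": (-16.57, 5.38, -9.30, 8.71),
    "DiffSDGxGy": (-128.31, 11.74, -117.47, 15.65),
    "DiffSDGyGz": (53.28, 10.25, 43.06, 14.88),
    "DiffSDGxGz": (-75.03, 5.17, -74.41, 5.15),
    "DiffRMSGxGy": (-126.36, 11.93, -114.54, 15.78),
    "DiffRMSGyGz": (45.26, 10.39, 28.91, 15.28),
    "DiffRMSGxGz": (-81.11, 5.43, -85.64, 5.75),
}

INTER_ACC_ONLY: dict[str, tuple[float, float, float, float]] = {
    "DiffMaxAxAy": (41.17, 4.13, 17.07, 2.67),
    "DiffMaxAyAz": (-19.33, 2.78, -10.88, 2.42),
    "DiffMaxAxAz": (21.84, 3.90, 6.19, 2.54),
    "DiffRangeAxAy": (65.43, 4.70, 29.78, 3.8),
    "DiffRangeAyAz": (-44.19, 4.69, -17.05, 3.96),
    "DiffRangeAxAz": (21.24, 4.58, 12.73, 3.71),
    "DiffMeanAxAy": (-2.08, 0.31, -1.67, 0.43),
    "DiffMeanAyAz": (8.64, 0.12, 9.20, 0.22),
    "DiffMeanAxAz": (6.56, 0.33, 7.52, 0.43),
    "DiffSDAxAy": (3.48, 0.24, 2.32, 0.28),
    "DiffSDAyAz": (-2.30, 0.23, -1.29, 0.25),
    "DiffSDAxAz": (1.18, 0.28, 1.03, 0.31),
    "DiffRMSAxAy": (3.95, 0.22, 2.60, 0.26),
    "DiffRMSAyAz": (-6.32, 0.21, -5.45, 0.21),
    "DiffRMSAxAz": (-2.37, 0.31, -2.85, 0.34),
}

# ---------------------------------------------------------------------------
# Published classification rates (10-fold CV, n = 41 per class).
# Keys: (metric_set, variant); per class: precision, recall, F.
# ---------------------------------------------------------------------------

CLASSIFICATION_RATES: dict[tuple[str, str], dict] = {
    ("axis", "acc-only"): {
        "accuracy": 0.78,
        "escape": {"precision": 0.76, "recall": 0.83, "f_measure": 0.79},
        "feeding": {"precision": 0.81, "recall": 0.73, "f_measure": 0.77},
        "variables": ["MaxAx", "MeanAy"],
    },
    ("axis", "gyro-only"): {
        "accuracy": 0.62,
        "escape": {"precision": 0.63, "recall": 0.61, "f_measure": 0.62},
        "feeding": {"precision": 0.62, "recall": 0.63, "f_measure": 0.63},
        "variables": ["MaxGz"],
    },
    ("axis", "all-combined"): {
        "accuracy": 0.84,
        "escape": {"precision": 0.83, "recall": 0.85, "f_measure": 0.84},
        "feeding": {"precision": 0.85, "recall": 0.83, "f_measure": 0.84},
        "variables": ["MaxAx"],
    },
    ("interaxial", "acc-only"): {
        "accuracy": 0.80,
        "escape": {"precision": 0.82, "recall": 0.78, "f_measure": 0.80},
        "feeding": {"precision": 0.79, "recall": 0.83, "f_measure": 0.81},
        "variables": ["DiffRangeAxAy", "DiffMeanAyAz"],
    },
    ("interaxial", "gyro-only"): {
        "accuracy": 0.66,
        "escape": {"precision": 0.88, "recall": 0.37, "f_measure": 0.52},
        "feeding": {"precision": 0.60, "recall": 0.95, "f_measure": 0.74},
        "variables": ["DiffMaxGxGz"],
    },
    ("interaxial", "all-combined"): {
        "accuracy": 0.84,
        "escape": {"precision": 0.89, "recall": 0.78, "f_measure": 0.83},
        "feeding": {"precision": 0.80, "recall": 0.90, "f_measure": 0.85},
        "variables": ["DiffRangeAxAy", "DiffMaxGxGz"],
    },
}


def class_sd(sem: float, n: int = N_PER_CLASS) -> float:
    """Reconstruct a class SD from a printed SEM: ``SD = SEM * sqrt(n)``."""
    return sem * math.sqrt(n)


def summary_table(metric_set: str, variant: str) -> dict[str, tuple[float, float, float, float]]:
    """(escape_mean, escape_sem, feeding_mean, feeding_sem) per variable."""
    if metric_set == "axis":
        return AXIS_ACC_ONLY if variant == "acc-only" else {
            k: v for k, v in AXIS_COMBINED.items()
            if variant != "gyro-only" or k[-2] == "G"
        }
    if metric_set == "interaxial":
        return INTER_ACC_ONLY if variant == "acc-only" else {
            k: v for k, v in INTER_COMBINED.items()
            if variant != "gyro-only" or "G" in k[4:]
        }
    raise ValueError("metric_set must be axis|interaxial")


__all__ = [
    "N_PER_CLASS", "FISH_EVENT_COUNTS", "FS_SD_MA", "RM_SD_MA", "FS_SD_MG",
    "RM_SD_MG", "N_SD_WINDOWS", "MA_THRESHOLD", "MG_THRESHOLD",
    "MA_DETECTION", "MG_DETECTION", "AXIS_COMBINED", "AXIS_ACC_ONLY",
    "INTER_COMBINED", "INTER_ACC_ONLY", "CLASSIFICATION_RATES",
    "class_sd", "summary_table",
]
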