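"""Published reference values used as worked-example fixtures.

A published reliability study of lower-limb dynamometry in 30 healthy young
adults reported, per muscle group, test–retest ICC(2,1) values for all 14
RFD algorithm variants on a fixed 1000 Hz dynamometer, together with SEM and
MDC percentages for peak-force and RFD reliability comparisons.  Those
printed coefficient grids are packaged here so that the column-summary and
MDC arithmetic of :mod:`rfdkit.agreement` can be exercised against known
published numbers without any external download.

These are coefficients, not raw participant measurements; the raw trial
data behind them is not redistributed here.
"""

from __future__ import annotations

import pandas as pd

from .model import MUSCLE_CODES
from .strength import RfdMethodSpec

__all__ = [
    "reference_icc_table",
    "reference_intra_rater_sem_mdc",
    "reference_inter_rater_sem_mdc",
    "REFERENCE_METHOD_LABELS",
]

#: column order of the published method-comparison grid
REFERENCE_METHOD_LABELS = [
    RfdMethodSpec("time_to_peak").label,
    *[RfdMethodSpec("percent_window", lo_pct=lo, hi_pct=hi).label
      for lo, hi in ((5, 95), (10, 90), (15, 85), (20, 80), (25, 75), (30, 70), (35, 65), (40, 60))],
    *[RfdMethodSpec("moving_window", window_ms=w).label for w in (10, 20, 50, 100, 200)],
]

# per-muscle test-retest ICC(2,1) of each RFD variant on the fixed
# dynamometer; rows follow MUSCLE_CODES, columns REFERENCE_METHOD_LABELS
_ICC_GRID = [
    # ttp   5-95  10-90 15-85 20-80 25-75 30-70 35-65 40-60  w10   w20   w50   w100  w200
    [-0.93, 0.24, 0.49, 0.71, 0.70, 0.65, 0.63, 0.63, 0.62, 0.64, 0.65, 0.62, 0.72, 0.77],  # ADF
    [0.67, 0.95, 0.96, 0.97, 0.95, 0.87, 0.85, 0.88, 0.88, 0.96, 0.96, 0.96, 0.95, 0.95],   # APF
    [-0.47, -0.22, 0.45, 0.59, 0.77, 0.82, 0.81, 0.79, 0.83, 0.83, 0.83, 0.86, 0.90, 0.88], # HAB
    [0.46, 0.47, 0.62, 0.56, 0.59, 0.75, 0.74, 0.77, 0.77, 0.78, 0.79, 0.80, 0.88, 0.92],   # HAD
    [0.40, 0.41, 0.17, 0.26, 0.54, 0.57, 0.84, 0.79, 0.85, 0.91, 0.91, 0.91, 0.91, 0.87],   # HE
    [0.70, 0.77, 0.92, 0.94, 0.95, 0.95, 0.94, 0.94, 0.94, 0.95, 0.95, 0.95, 0.95, 0.94],   # HF
    [0.75, 0.82, 0.83, 0.91, 0.91, 0.92, 0.91, 0.90, 0.90, 0.97, 0.97, 0.97, 0.97, 0.98],   # KE
    [0.39, 0.77, 0.84, 0.78, 0.73, 0.70, 0.66, 0.66, 0.67, 0.93, 0.93, 0.92, 0.89, 0.93],   # KF
]

# published per-column medians and below-0.75 counts (for cross-checks)
REFERENCE_MEDIANS = [0.43, 0.62, 0.73, 0.75, 0.75, 0.79, 0.83, 0.79, 0.84,
                     0.92, 0.92, 0.92, 0.91, 0.93]
REFERENCE_N_BELOW = [7, 4, 4, 4, 4, 3, 3, 2, 2, 1, 1, 1, 1, 0]

# intra-rater peak-force reliability: SEM% and MDC% per muscle for each
# rater x device cell plus the fixed dynamometer (MDC/SEM ratio 1.96*sqrt(2))
_INTRA_COLUMNS = ["A_Lafayette", "A_Hoggan", "B_Lafayette", "B_Hoggan", "KinCom"]
_INTRA_SEM = [
    [8.62, 6.20, 7.39, 8.13, 17.45],   # ADF
    [8.53, 6.06, 7.70, 10.81, 5.72],   # APF
    [9.59, 7.30, 6.43, 6.53, 6.17],    # HAB
    [6.82, 5.74, 6.09, 6.68, 4.48],    # HAD
    [6.77, 5.22, 6.76, 5.34, 7.03],    # HE
    [6.15, 5.43, 5.83, 8.17, 6.45],    # HF
    [7.73, 8.54, 8.72, 8.98, 5.67],    # KE
    [6.93, 8.59, 8.07, 5.29, 6.67],    # KF
]
_INTRA_MDC = [
    [23.89, 17.19, 20.47, 22.52, 48.36],
    [23.64, 16.81, 21.35, 29.97, 15.86],
    [26.59, 20.23, 17.82, 18.11, 17.10],
    [18.89, 15.91, 16.87, 18.51, 12.42],
    [18.76, 14.48, 18.74, 14.79, 19.49],
    [17.05, 15.05, 16.16, 22.65, 17.89],
    [21.42, 23.67, 24.16, 24.88, 15.72],
    [19.21, 23.81, 22.36, 14.66, 18.48],
]

# inter-rater reliability: SEM% and MDC% per muscle for peak force and RFD on
# each hand-held device (MDC/SEM ratio 1.96)
_INTER_COLUMNS = ["PF_Lafayette", "PF_Hoggan", "RFD_Lafayette", "RFD_Hoggan"]
_INTER_SEM = [
    [11.30, 11.54, 16.05, 13.41],  # ADF
    [9.33, 11.18, 10.25, 11.74],   # APF
    [6.92, 6.51, 9.24, 14.27],     # HAB
    [4.54, 7.72, 12.59, 14.00],    # HAD
    [7.29, 5.34, 10.15, 13.36],    # HE
    [6.39, 6.71, 10.76, 9.80],     # HF
    [9.30, 8.76, 13.84, 19.58],    # KE
    [12.53, 7.40, 18.46, 14.71],   # KF
]
_INTER_MDC = [
    [22.15, 22.63, 31.46, 26.28],
    [18.29, 21.91, 20.08, 23.01],
    [13.56, 12.75, 18.10, 27.97],
    [8.90, 15.12, 24.68, 27.44],
    [14.29, 10.46, 19.90, 26.18],
    [12.53, 13.15, 21.08, 19.21],
    [18.23, 17.18, 27.12, 38.37],
    [24.56, 14.51, 36.18, 28.83],
]

# one fully worked intra-rater cell (ankle dorsiflexors, rater A, stable
# 40 Hz device): session-1 mean (kg), session-1 SD (kg), printed ICC
WORKED_EXAMPLE_CELL = {"mean1": 19.19, "sd1": 4.92, "icc": 0.89,
                       "sem_pct": 8.62, "mdc_pct": 23.89}


def reference_icc_table() -> pd.DataFrame:
    """Published per-muscle ICC grid (8 muscles x 14 RFD variants)."""
    return pd.DataFrame(_ICC_GRID, index=list(MUSCLE_CODES), columns=REFERENCE_METHOD_LABELS)


def _tidy(sem_grid, mdc_grid, columns, variant) -> pd.DataFrame:
    rows = []
    for muscle, sems, mdcs in zip(MUSCLE_CODES, sem_grid, mdc_grid):
        for col, s, m in zip(columns, sems, mdcs):
            rows.append(
                {"muscle": muscle, "cell": col, "sem_pct": s, "mdc_pct": m,
                 "mdc_variant": variant}
            )
    return pd.DataFrame(rows)


def reference_intra_rater_sem_mdc() -> pd.DataFrame:
    """Published intra-rater peak-force SEM%/MDC% pairs (sqrt2 MDC variant)."""
    return _tidy(_INTRA_SEM, _INTRA_MDC, _INTRA_COLUMNS, "sqrt2")


def reference_inter_rater_sem_mdc() -> pd.DataFrame:
    """Published inter-rater SEM%/MDC% pairs (plain 1.96 MDC variant)."""
    return _tidy(_INTER_SEM, _INTER_MDC, _INTER_COLUMNS, "plain")
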