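"""Published per-condition summary statistics for MCF-7 cells.

These printed population-level values anchor the synthetic generators (class
mixes per drug condition, Bax-positive fractions, TMRM collapse timing) and
serve as inputs to arithmetic cross-checks.  They are summary statistics, not
raw data; the underlying images were never released.
"""

from __future__ import annotations

#: Mean percentage (networked, fragmented, swollen) of the RF degree-of-belonging
#: scores per cell, by condition (6 h treatment).
CONDITION_NFS_PERCENT: dict[str, tuple[float, float, float]] = {
    "FM": (52.24, 35.65, 12.11),
    "BSS": (43.56, 45.70, 10.73),
    "ceramide": (23.54, 53.18, 23.28),
    "CCCP": (3.72, 13.07, 83.19),
    "TNFa": (39.79, 44.42, 15.79),
    "TRAIL": (49.26, 41.18, 9.56),
    "oligomycin": (13.20, 38.26, 48.53),
    "thapsigargin": (48.64, 43.22, 8.14),
    "camptothecin": (37.39, 38.31, 24.30),
}

#: Percentage of cells scored positive for GFP-Bax clustering, by condition.
BAX_POSITIVE_PERCENT: dict[str, float] = {
    "BSS": 5.0,
    "CCCP": 28.0,
    "TNFa": 42.0,
    "TRAIL": 10.0,
    "oligomycin": 8.0,
    "camptothecin": 64.0,
}

#: TMRM signal dissipation half-time under full medium (negative control), seconds.
FM_T_HALF_DECAY_S = 232.0

#: Intercellular standard deviation (%) extremes of morphology-class scores.
INTERCELLULAR_SD_PERCENT = {"camptothecin": 25.0, "CCCP": 15.0}

#: Reference RMSEs of the retained direction models (arbitrary units):
#: Bax->Fragmented, Bax->MAX, Bax->t1/2_decay, Fragmented->Y_spread,
#: Swollen->Y_spread.  Documented for comparison only; the condition-level
#: membrane-potential means needed to re-fit them were never published.
REFERENCE_DIRECTION_RMSE = {
    ("Bax", "F"): 13.83,
    ("Bax", "MAX"): 8.46,
    ("Bax", "t1_2_decay"): 8.49,
    ("F", "Y_spread"): 6.69,
    ("S", "Y_spread"): 6.56,
}

#: Classifier benchmarks: overall 10x10-fold CV accuracy on cropped training
#: cells, and accuracy of in-situ classification within full images.
CV_ACCURACY = 0.92
IN_SITU_ACCURACY = 0.90
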