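"""Reference summary tables from a published ten-breed cattle SNP-chip scan.

The original genotypes behind these summaries are not public; what is
reproducible from print is the arithmetic on the published tables. This
module ships those tables as plain data so that row means, group means,
thresholds and between-series correlations can be recomputed from scratch:

* the pairwise Weir-Cockerham F_ST matrix of the ten breeds,
* the per-breed signature counts (comparison-specific grid, Total, Final),
  mean SNPs per signature, and LD-based Ne at 5 and 50 generations ago,
* the worked example of a calibration threshold (the two calibration-breed
  chromosome maxima whose mean defines significance).

Breed codes: GLW Galloway, BBB Blanc-Bleu Belge, RH Red Holstein,
BBV Braunvieh, OBV Original Braunvieh, MWF Murnau-Werdenfelser,
FGV Franken Gelbvieh, DFV German Fleckvieh; ABB (Anatolian Black) and
IMB (Illyrian Mountain Busa) are the artificially unselected calibration
breeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BREEDS = ["GLW", "BBB", "RH", "BBV", "OBV", "MWF", "FGV", "DFV", "ABB", "IMB"]
CALIBRATION_BREEDS = ["ABB", "IMB"]
SELECTED_BREEDS = ["GLW", "BBB", "RH", "BBV", "OBV", "MWF", "FGV", "DFV"]
#: single-purpose, most intensively selected breeds (dairy- or beef-only)
SINGLE_PURPOSE_BREEDS = ["GLW", "BBB", "RH", "BBV"]

#: worked calibration-threshold example: chromosome-wide maxima of the two
#: calibration case breeds against one control breed; the significance
#: threshold is their arithmetic mean.
THRESHOLD_EXAMPLE = {"max_imb": 2.658523, "max_abb": 3.056731}

_FST = [
    # GLW     BBB     RH      BBV     OBV     MWF     FGV     DFV     ABB     IMB
    [np.nan, 0.1274, 0.1244, 0.1576, 0.1301, 0.1345, 0.1217, 0.1313, 0.1317, 0.0959],
    [0.1274, np.nan, 0.0792, 0.1316, 0.1040, 0.1086, 0.0931, 0.1062, 0.1009, 0.0708],
    [0.1244, 0.0792, np.nan, 0.1264, 0.0997, 0.1046, 0.0914, 0.1026, 0.0938, 0.0673],
    [0.1576, 0.1316, 0.1264, np.nan, 0.0807, 0.1058, 0.0994, 0.1026, 0.1128, 0.0852],
    [0.1301, 0.1040, 0.0997, 0.0807, np.nan, 0.0761, 0.0698, 0.0722, 0.0845, 0.0554],
    [0.1345, 0.1086, 0.1046, 0.1058, 0.0761, np.nan, 0.0749, 0.0779, 0.0915, 0.0617],
    [0.1217, 0.0931, 0.0914, 0.0994, 0.0698, 0.0749, np.nan, 0.0530, 0.0819, 0.0522],
    [0.1313, 0.1062, 0.1026, 0.1026, 0.0722, 0.0779, 0.0530, np.nan, 0.0894, 0.0604],
    [0.1317, 0.1009, 0.0938, 0.1128, 0.0845, 0.0915, 0.0819, 0.0894, np.nan, 0.0369],
    [0.0959, 0.0708, 0.0673, 0.0852, 0.0554, 0.0617, 0.0522, 0.0604, 0.0369, np.nan],
]

#: comparison-specific signature counts: rows = control breed, columns = case
_COMPARISON_GRID = {
    "GLW": [np.nan, 51, 62, 77, 60, 69, 45, 53, 26, 11],
    "BBB": [71, np.nan, 50, 37, 46, 45, 42, 50, 18, 22],
    "RH":  [63, 76, np.nan, 82, 44, 90, 58, 70, 16, 33],
    "BBV": [139, 117, 130, np.nan, 62, 217, 118, 115, 23, 14],
    "OBV": [86, 78, 64, 118, np.nan, 76, 63, 82, 25, 19],
    "MWF": [32, 60, 42, 39, 32, np.nan, 47, 64, 18, 18],
    "FGV": [65, 66, 52, 95, 49, 75, np.nan, 73, 20, 19],
    "DFV": [65, 80, 72, 100, 45, 79, 67, np.nan, 19, 18],
}

_SUMMARY_ROWS = {
    "total":    [199, 232, 217, 201, 175, 414, 290, 269, 123, 129],
    "final":    [128, 144, 131, 140, 100, 229, 153, 151, 43, 32],
    "snps_per_signature": [11.64, 7.38, 10.00, 14.11, 8.79, 5.48, 5.37, 7.19,
                           3.02, 2.59],
    "ne5":      [110.74, 68.36, 111.48, 84.45, 92.31, 52.64, 109.95, 126.53,
                 183.70, 149.76],
    "ne50":     [282.55, 322.29, 388.91, 254.77, 425.88, 283.17, 463.48, 548.95,
                 1680.69, 1054.34],
    "ne5_ne50_ratio": [0.39, 0.21, 0.29, 0.33, 0.22, 0.19, 0.24, 0.23, 0.11, 0.14],
}


def fst_reference() -> pd.DataFrame:
    """Published pairwise F_ST matrix (10 breeds), nan on the diagonal."""
    return pd.DataFrame(_FST, index=BREEDS, columns=BREEDS)


def summary_reference() -> pd.DataFrame:
    """Published per-breed scan summary: rows total / final /
    snps_per_signature / ne5 / ne50 / ne5_ne50_ratio, columns = breeds."""
    return pd.DataFrame(_SUMMARY_ROWS, index=BREEDS).T


def comparison_grid_reference() -> pd.DataFrame:
    """Published comparison-specific signature counts (control x case)."""
    return pd.DataFrame(_COMPARISON_GRID, index=BREEDS).T
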