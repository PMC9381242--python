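"""Published benchmark numbers from the original clinical evaluation.

The framework variants were evaluated on a clinical cohort (50 end-stage
renal disease patients, ten-fold cross-validation on the cognition scores)
whose raw data are not publicly available. The fold-level accuracies and
the feature-weight row printed in that evaluation are embedded here as
reference inputs, so that aggregation logic and selection thresholds can be
exercised against the published figures.

Metric triples are (RMSE, MAE, MAPE); MAPE is a fraction, not a percent.
"""

from __future__ import annotations

import numpy as np

__all__ = ["REFERENCE_FOLD_METRICS", "REFERENCE_AVERAGES",
           "REFERENCE_FEATURE_WEIGHTS"]

#: per-fold (RMSE, MAE, MAPE) of each framework variant, folds 1..10
REFERENCE_FOLD_METRICS: dict[str, list[tuple[float, float, float]]] = {
    "GPSV": [
        (3.5064, 2.3835, 0.1364),
        (3.4820, 3.0951, 0.1454),
        (3.2648, 2.8499, 0.1267),
        (3.6154, 3.1792, 0.1542),
        (2.5508, 2.2965, 0.1109),
        (2.2724, 1.7919, 0.0790),
        (4.1150, 3.6825, 0.1788),
        (2.8204, 2.6590, 0.1277),
        (5.7247, 4.0523, 0.1999),
        (3.0707, 2.7852, 0.1334),
    ],
    "GPLSV": [
        (5.2634, 4.1970, 0.2149),
        (4.6628, 3.1899, 0.1305),
        (3.4819, 2.8121, 0.1491),
        (3.1611, 2.7837, 0.1385),
        (2.1046, 1.8884, 0.0898),
        (2.1620, 2.1246, 0.0994),
        (3.3545, 3.0199, 0.1524),
        (3.9891, 3.7250, 0.1800),
        (2.2805, 1.7733, 0.0812),
        (2.8879, 2.4838, 0.1214),
    ],
    "GPWLSV": [
        (4.2408, 3.4782, 0.1695),
        (3.3293, 2.8178, 0.1240),
        (3.0657, 2.4178, 0.1188),
        (3.3027, 2.9839, 0.1466),
        (1.3125, 1.1388, 0.0529),
        (1.9272, 1.4114, 0.0618),
        (2.9412, 2.7196, 0.1311),
        (2.7899, 2.6865, 0.1284),
        (2.6758, 2.3282, 0.1092),
        (3.0313, 2.8014, 0.1335),
    ],
    "GPLWLSV": [
        (3.9132, 3.1026, 0.1561),
        (3.2506, 2.8334, 0.1258),
        (2.7307, 2.4334, 0.1075),
        (2.9976, 2.3738, 0.1216),
        (1.2192, 1.1111, 0.0530),
        (0.7180, 0.6497, 0.0313),
        (2.5167, 2.1156, 0.1036),
        (2.0709, 1.9636, 0.0914),
        (2.1757, 1.9467, 0.0916),
        (2.4163, 2.0302, 0.1007),
    ],
}

#: published "Average" rows (RMSE, MAE, MAPE) for each variant
REFERENCE_AVERAGES: dict[str, tuple[float, float, float]] = {
    "GPSV": (3.4423, 2.8775, 0.1392),
    "GPLSV": (3.3348, 2.7998, 0.1357),
    "GPWLSV": (2.8616, 2.4784, 0.1176),
    "GPLWLSV": (2.4009, 2.0560, 0.0983),
}

#: published feature weights (fractions) in the order
#: (gamma, lambda, sigma, Cp, Lp, Eglobal, Elocal)
REFERENCE_FEATURE_WEIGHTS = np.array(
    [0.0003, 0.0007, 0.0017, 0.0028, 0.0325, 0.3089, 0.6531])
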