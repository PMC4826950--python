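"""Published benchmark results for LXRE and its baselines.

These are the evaluation tables reported in the literature for the LXRE
algorithm and its two ablations on PropBank subsets of 50/100/200 sentences
and on a balanced 1000-sentence AIMed sample, plus the two competitor
systems quoted for AIMed.  They serve as fixed reference data for validating
the metric arithmetic in :mod:`lxre.metrics`: every F-measure cell must be
recoverable from its Precision/Recall columns, and every relative-improvement
cell from the accuracy columns.

All index values are percentages as printed (two-decimal display rounding).
Row keys: (algorithm, kernel variant) for the PropBank tables; algorithm
name for AIMed.  Column order mirrors the published layout
(Y, N, Total, Precision, Recall, F-measure, Accuracy).
"""

from __future__ import annotations

__all__ = [
    "PROPBANK_RESULTS",
    "IMPROVEMENT_GRID",
    "AIMED_RESULTS",
]

# (algorithm, variant) -> corpus size -> row
# row = (Y, N, total, precision, recall, f_measure, accuracy)
PROPBANK_RESULTS: dict[tuple[str, str], dict[int, tuple]] = {
    ("LXRE", "ST"): {
        50: (39, 11, 50, 75.00, 84.0, 79.25, 78.0),
        100: (79, 21, 100, 82.05, 69.57, 75.30, 79.0),
        200: (144, 56, 200, 76.83, 63.00, 69.23, 72.0),
    },
    ("LXRE", "SST"): {
        50: (39, 11, 50, 81.82, 72.0, 76.60, 78.0),
        100: (77, 23, 100, 87.10, 58.70, 70.13, 77.0),
        200: (142, 58, 200, 80.00, 56.00, 65.88, 71.0),
    },
    ("N-LXRE", "ST"): {
        50: (37, 13, 50, 68.75, 88.0, 77.19, 74.0),
        100: (74, 26, 100, 83.33, 54.35, 65.79, 74.0),
        200: (139, 61, 200, 80.00, 52.00, 63.03, 69.5),
    },
    ("N-LXRE", "SST"): {
        50: (38, 12, 50, 76.00, 76.0, 76.00, 76.0),
        100: (73, 27, 100, 82.76, 52.10, 63.94, 73.0),
        200: (135, 65, 200, 79.66, 47.00, 59.12, 67.5),
    },
    ("N-RE", "ST"): {
        50: (37, 13, 50, 68.75, 88.0, 77.19, 74.0),
        100: (78, 22, 100, 77.27, 73.91, 75.55, 78.0),
        200: (140, 60, 200, 72.22, 65.00, 68.42, 70.0),
    },
    ("N-RE", "SST"): {
        50: (37, 13, 50, 87.50, 56.0, 68.29, 74.0),
        100: (75, 25, 100, 88.89, 52.17, 65.75, 75.0),
        200: (130, 70, 200, 81.25, 39.00, 52.70, 65.0),
    },
}

# variant -> corpus size -> (best, worst): published relative improvement of
# the LXRE accuracy over the best / worst of {N-LXRE, N-RE}, in %.
IMPROVEMENT_GRID: dict[str, dict[int, tuple[float, float]]] = {
    "ST": {50: (5.41, 5.41), 100: (1.28, 6.76), 200: (2.86, 3.60)},
    "SST": {50: (2.63, 5.41), 100: (2.67, 5.48), 200: (5.19, 9.23)},
}

# algorithm -> (precision, recall, f_measure) on the AIMed sample, in %.
AIMED_RESULTS: dict[str, tuple[float, float, float]] = {
    "LXRE": (55.91, 42.60, 48.36),
    "Yakushiji": (33.70, 33.10, 33.40),
    "Mitsumori": (54.20, 42.60, 47.70),
}
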