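"""Worked-example rank tables for the statistical machinery.

Two published 5-classifier × 9-sampler Friedman rank tables from benchmark
comparisons on the ADL and Opportunity activity-recognition datasets, bundled
as ready-made inputs: feeding them to :func:`harsample.stats.friedman_test`
reproduces the reported χ² statistics (21.8133 and 24.2133, df = 8) and
rank-sum rows exactly. Ranks run 1 (lowest weighted F1) to 9 (highest) within
each classifier row.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["METHOD_COLUMNS", "CLASSIFIER_ROWS", "ADL_RANKS", "OPPORTUNITY_RANKS"]

METHOD_COLUMNS = (
    "CBSO",
    "NDBM",
    "CBM",
    "DBM",
    "MSMOTE",
    "ProWSyn",
    "Random_SMOTE",
    "SMOTE_TomekLinks",
    "SMOTE",
)

CLASSIFIER_ROWS = ("KNN", "LR", "MLP", "RF", "SVM")

ADL_RANKS = pd.DataFrame(
    [
        [1, 7, 9, 4, 5, 8, 2, 6, 3],
        [1, 8, 3, 9, 2, 5, 6, 7, 4],
        [3, 8, 9, 7, 1, 5, 2, 4, 6],
        [1, 6, 9, 4, 7, 8, 3, 5, 2],
        [1, 8, 7, 9, 2, 3, 6, 4, 5],
    ],
    index=list(CLASSIFIER_ROWS),
    columns=list(METHOD_COLUMNS),
    dtype=float,
)

OPPORTUNITY_RANKS = pd.DataFrame(
    [
        [5, 6, 9, 7, 1, 4, 8, 3, 2],
        [5, 9, 7, 8, 1, 2, 6, 4, 3],
        [5, 7, 9, 8, 1, 3, 2, 4, 6],
        [4, 5, 8, 3, 1, 9, 7, 6, 2],
        [2, 7, 8, 9, 1, 4, 3, 5, 6],
    ],
    index=list(CLASSIFIER_ROWS),
    columns=list(METHOD_COLUMNS),
    dtype=float,
)
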