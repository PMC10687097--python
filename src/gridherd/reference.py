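"""Published reference values for the Kazakhstan small-ruminant case study.

``published_selection_table`` reproduces the printed 12-model selection
experiment (2015 small-ruminant density; four buffer radii x three
train:test splits, cross-validation and independent-test RMSE/R^2/MAE).
It is shipped so the model-selection rule can be replayed against the
published metrics without access to the original census or rasters.
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # buffer_km, train_fraction, cv_rmse, cv_r2, cv_mae, test_rmse, test_r2, test_mae
    (0, 0.7, 70.00, 0.49, 17.29, 84.17, 0.48, 20.93),
    (0, 0.8, 65.30, 0.59, 16.74, 87.21, 0.29, 19.29),
    (0, 0.9, 68.96, 0.63, 17.08, 50.29, 0.21, 14.00),
    (2, 0.7, 52.22, 0.51, 13.40, 62.96, 0.70, 12.35),
    (2, 0.8, 61.09, 0.51, 14.46, 22.98, 0.59, 8.65),
    (2, 0.9, 57.13, 0.54, 13.13, 20.33, 0.68, 8.38),
    (5, 0.7, 49.55, 0.60, 11.26, 30.20, 0.33, 7.09),
    (5, 0.8, 45.63, 0.62, 9.90, 35.77, 0.25, 7.90),
    (5, 0.9, 44.07, 0.60, 9.30, 35.67, 0.38, 7.22),
    (10, 0.7, 21.11, 0.62, 5.84, 11.13, 0.79, 4.74),
    (10, 0.8, 19.45, 0.67, 5.40, 12.68, 0.73, 4.94),
    (10, 0.9, 17.53, 0.76, 4.87, 11.75, 0.82, 4.74),
]

_COLUMNS = [
    "buffer_km", "train_fraction",
    "cv_rmse", "cv_r2", "cv_mae",
    "test_rmse", "test_r2", "test_mae",
]


def published_selection_table() -> pd.DataFrame:
    """The printed 12-model buffer x split metric table as a DataFrame."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)
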