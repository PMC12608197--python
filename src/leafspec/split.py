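"""SPXY calibration/prediction partitioning and per-set summary statistics.

SPXY is a Kennard-Stone-style deterministic farthest-point selection on the
joint distance d(i,j) = dx(i,j)/max(dx) + dy(i,j)/max(dy), where dx is the
Euclidean distance between spectra and dy the absolute response difference.
The calibration set therefore spans both the spectral and the response space;
there is no randomness anywhere.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .tables import DatasetSplit, ResponseVector, SpectraTable

__all__ = ["spxy_split", "dataset_summary", "calibration_size"]


def calibration_size(n: int, ratio: float) -> int:
    """floor(n * ratio / (ratio + 1)); 735 at 3:1 gives 551."""
    return int(np.floor(n * ratio / (ratio + 1.0)))


def joint_distance_matrix(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """The SPXY metric: max-normalized X and y distances summed."""
    dx = squareform(pdist(X, metric="euclidean"))
    dy = np.abs(y[:, None] - y[None, :])
    max_dx, max_dy = dx.max(), dy.max()
    if max_dy == 0:
        raise ValueError("constant response: SPXY joint distance undefined")
    if max_dx == 0:
        raise ValueError("identical spectra everywhere: SPXY undefined")
    return dx / max_dx + dy / max_dy


def spxy_split(
    table: SpectraTable | np.ndarray,
    response: ResponseVector | np.ndarray,
    ratio: float = 3.0,
) -> DatasetSplit:
    """Deterministic SPXY partition at calibration:prediction = ratio:1.

    Selection starts from the pair with the largest joint distance and
    repeatedly adds the sample farthest (max-min) from the selected set;
    ties break to the lowest index.  Selected samples form the calibration
    set, the remainder the prediction set.
    """
    X = table.values if isinstance(table, SpectraTable) else np.asarray(table, dtype=float)
    y = response.values if isinstance(response, ResponseVector) else np.asarray(response, dtype=float).ravel()
    n = X.shape[0]
    if n < 4:
        raise ValueError("SPXY needs at least 4 samples")
    if y.size != n:
        raise ValueError("response length does not match spectra table")
    d = joint_distance_matrix(X, y)
    n_cal = calibration_size(n, ratio)
    if not 1 <= n_cal < n:
        raise ValueError(f"ratio {ratio} leaves no prediction samples for n={n}")

    # argmax over the upper triangle; np.argmax returns the first (lowest
    # flat index) maximum, i.e. lowest (i, then j) on ties.
    iu = np.triu_indices(n, k=1)
    k = int(np.argmax(d[iu]))
    first, second = int(iu[0][k]), int(iu[1][k])
    selected = [first, second]
    in_set = np.zeros(n, dtype=bool)
    in_set[[first, second]] = True
    min_dist = np.minimum(d[first], d[second])
    while len(selected) < n_cal:
        min_dist[in_set] = -1.0
        nxt = int(np.argmax(min_dist))  # first max = lowest index on ties
        selected.append(nxt)
        in_set[nxt] = True
        min_dist = np.minimum(min_dist, d[nxt])
    calibration = np.sort(np.array(selected))
    prediction = np.flatnonzero(~in_set)
    return DatasetSplit(calibration=calibration, prediction=prediction, ratio=ratio)


def dataset_summary(response: ResponseVector, split: DatasetSplit) -> pd.DataFrame:
    """Per-set (n, max, min, mean, sample SD) of the reference values."""
    y = response.values
    rows = []
    if split.calibration.size == 0:
        raise ValueError("calibration set is empty")
    for label, idx in (("calibration", split.calibration), ("prediction", split.prediction)):
        if idx.size == 0:  # degenerate all-calibration split: skip the row
            continue
        vals = y[idx]
        rows.append(
            {
                "set": label,
                "n": int(idx.size),
                "max": float(vals.max()),
                "min": float(vals.min()),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if idx.size > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
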