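"""Tabular containers: per-sample mean spectra, reference values, splits."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .grid import WavelengthGrid

__all__ = ["SpectraTable", "ResponseVector", "DatasetSplit"]


@dataclass
class SpectraTable:
    """n x p matrix of per-sample mean reflectance spectra.

    ``values`` rows are samples, columns follow ``grid``.  ``meta`` optionally
    carries per-sample metadata (growth stage, treatment, leaf position).
    """

    values: np.ndarray
    grid: WavelengthGrid
    meta: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("spectra table must be 2-D (samples x channels)")
        if self.values.shape[1] != len(self.grid):
            raise ValueError(
                f"channel count {self.values.shape[1]} does not match grid "
                f"length {len(self.grid)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectra table contains non-finite values")
        if self.meta is not None and len(self.meta) != self.n_samples:
            raise ValueError("metadata length does not match sample count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def select_channels(self, indices: np.ndarray) -> "SpectraTable":
        indices = np.asarray(indices, dtype=int)
        return SpectraTable(self.values[:, indices], self.grid.subset(indices), self.meta)

    def to_frame(self) -> pd.DataFrame:
        """Wide CSV-ready frame, one column per wavelength (nm)."""
        cols = [f"{w:.3f}" for w in self.grid.centers]
        frame = pd.DataFrame(self.values, columns=cols)
        if self.meta is not None:
            frame = pd.concat([self.meta.reset_index(drop=True), frame], axis=1)
        return frame


@dataclass
class ResponseVector:
    """Reference analyte values paired with a :class:`SpectraTable`.

    Units are '%' for nitrogen (dry-mass percentage) and 'mg/g' for
    chlorophyll.
    """

    values: np.ndarray
    analyte: str = "nitrogen"
    units: str = "%"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0 or not np.all(np.isfinite(self.values)):
            raise ValueError("response vector must be non-empty and finite")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class DatasetSplit:
    """Disjoint calibration/prediction row indices covering all samples."""

    calibration: np.ndarray
    prediction: np.ndarray
    ratio: float = 3.0

    def __post_init__(self) -> None:
        self.calibration = np.asarray(self.calibration, dtype=int)
        self.prediction = np.asarray(self.prediction, dtype=int)
        cal, pred = set(self.calibration.tolist()), set(self.prediction.tolist())
        if cal & pred:
            raise ValueError("calibration and prediction sets overlap")
        n = len(cal) + len(pred)
        if cal | pred != set(range(n)):
            raise ValueError("split must cover all sample indices exactly once")

    @property
    def n_samples(self) -> int:
        return self.calibration.size + self.prediction.size

    def to_frame(self) -> pd.DataFrame:
        rows = [(int(i), "calibration") for i in self.calibration]
        rows += [(int(i), "prediction") for i in self.prediction]
        return pd.DataFrame(sorted(rows), columns=["sample", "set"])
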