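"""Wavelength grids for VNIR hyperspectral line-scan data.

The instrument model is a push-broom VNIR imager covering 380-1000 nm at a
uniform sampling interval of 0.727 nm (856 bands).  Quantitative modeling is
restricted to the stable 430-900 nm window, which by convention holds 646
channels (see :func:`crop window helpers <leafspec.cube.crop_window>`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WavelengthGrid",
    "vnir_grid",
    "modeling_window_grid",
    "VNIR_START_NM",
    "VNIR_STEP_NM",
    "VNIR_N_BANDS",
    "MODELING_WINDOW_NM",
    "MODELING_WINDOW_CHANNELS",
]

VNIR_START_NM = 380.0
VNIR_STEP_NM = 0.727
VNIR_N_BANDS = 856

#: Stable modeling window (nm) and its conventional channel count.
MODELING_WINDOW_NM = (430.0, 900.0)
MODELING_WINDOW_CHANNELS = 646

_UNIFORMITY_TOL = 1e-6


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band centers (nm) with uniform spacing.

    Parameters
    ----------
    centers
        Strictly increasing band-center wavelengths in nm.  Spacing must be
        uniform to within 1e-6 nm.
    """

    centers: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        if centers.ndim != 1 or centers.size == 0:
            raise ValueError("grid requires a non-empty 1-D array of centers")
        if centers.size > 1:
            diffs = np.diff(centers)
            if np.any(diffs <= 0):
                raise ValueError("band centers must be strictly increasing")
            if np.ptp(diffs) > _UNIFORMITY_TOL:
                raise ValueError("band spacing must be uniform within 1e-6 nm")
        object.__setattr__(self, "centers", centers)

    def __len__(self) -> int:
        return int(self.centers.size)

    @property
    def sampling_interval(self) -> float:
        """Band spacing in nm (0.0 for a single-channel grid)."""
        if len(self) < 2:
            return 0.0
        return float(self.centers[1] - self.centers[0])

    def window_indices(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Indices of channels with ``lo_nm <= center <= hi_nm``."""
        return np.flatnonzero((self.centers >= lo_nm) & (self.centers <= hi_nm))

    def subset(self, indices: np.ndarray) -> "WavelengthGrid":
        return WavelengthGrid(self.centers[np.asarray(indices)])

    def nearest_index(self, nm: float) -> int:
        return int(np.argmin(np.abs(self.centers - nm)))


def vnir_grid() -> WavelengthGrid:
    """The full 856-band VNIR grid, 380 + 0.727*k nm for k = 0..855."""
    k = np.arange(VNIR_N_BANDS)
    return WavelengthGrid(VNIR_START_NM + VNIR_STEP_NM * k)


def modeling_window_grid() -> WavelengthGrid:
    """The 646-channel 430-900 nm modeling window of the full VNIR grid.

    The inclusive crop of the nominal grid yields 647 channels; the
    definitional count of the modeling window is 646, obtained by dropping the
    topmost channel (centers 430.163-899.078 nm).  All percentage bookkeeping
    of selected wavelengths is relative to these 646 channels.
    """
    full = vnir_grid()
    idx = full.window_indices(*MODELING_WINDOW_NM)[:MODELING_WINDOW_CHANNELS]
    return full.subset(idx)
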