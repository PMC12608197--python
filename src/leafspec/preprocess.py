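"""Row-wise spectral preprocessing: Savitzky-Golay, SNV, detrending.

Every step operates on one spectrum at a time (no cross-sample statistics),
so permuting samples commutes with the pipeline.  The default pipeline order
is S-G smoothing, then SNV, then detrending.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .tables import SpectraTable

__all__ = [
    "PreprocessSpec",
    "savgol_smooth",
    "snv",
    "detrend",
    "apply_pipeline",
    "apply_to_matrix",
    "default_pipeline",
]


def savgol_smooth(spectrum: np.ndarray, order: int = 1, window: int = 5) -> np.ndarray:
    """Savitzky-Golay smoothing: local least-squares polynomial refit.

    Each point is replaced by the center value of a polynomial of the given
    order fitted to its window; edge points are taken from the polynomial
    fitted to the terminal window (``mode='interp'``).
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if window % 2 == 0:
        raise ValueError("window length must be odd")
    if window <= order:
        raise ValueError("window length must exceed polynomial order")
    if spectrum.shape[-1] < window:
        raise ValueError("spectrum shorter than smoothing window")
    return savgol_filter(spectrum, window, order, axis=-1, mode="interp")


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum (x - mean) / sd with n-1 sd.

    Removes multiplicative scatter (glossiness, surface geometry) from each
    spectrum independently; the output has mean 0 and sample SD 1.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    sd = spectrum.std(axis=-1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("SNV undefined for a constant spectrum (zero SD)")
    return (spectrum - spectrum.mean(axis=-1, keepdims=True)) / sd


def detrend(spectrum: np.ndarray, order: int = 2, x: np.ndarray | None = None) -> np.ndarray:
    """Subtract the global least-squares polynomial baseline of given order.

    Removes baseline drift from diffuse reflection.  ``x`` defaults to the
    channel index; any affine reparameterization of the axis gives the same
    residual.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    p = spectrum.shape[-1]
    if p <= order:
        raise ValueError("spectrum length must exceed polynomial order")
    if x is None:
        x = np.arange(p, dtype=float)
    # orthonormal polynomial basis -> stable projection for any order
    basis = np.polynomial.polynomial.polyvander(
        (x - x.mean()) / max(np.ptp(x), 1.0), order
    )
    q, _ = np.linalg.qr(basis)
    flat = np.atleast_2d(spectrum)
    baseline = (flat @ q) @ q.T
    out = flat - baseline
    return out.reshape(spectrum.shape)


_STEP_FUNCS = {"sg": savgol_smooth, "snv": snv, "detrend": detrend}


@dataclass
class PreprocessSpec:
    """Ordered preprocessing steps, each (name, params).

    Default: S-G smoothing with polynomial order 1 / window 5, SNV, then
    order-2 polynomial detrending.
    """

    steps: list[tuple[str, dict]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, params in self.steps:
            if name not in _STEP_FUNCS:
                raise ValueError(f"unknown preprocessing step {name!r}")
            if name in ("sg",):
                window = params.get("window", 5)
                order = params.get("order", 1)
                if window % 2 == 0 or window <= order:
                    raise ValueError("S-G window must be odd and > order")

    def to_dict(self) -> list:
        return [[name, dict(params)] for name, params in self.steps]

    @classmethod
    def from_dict(cls, data: list) -> "PreprocessSpec":
        return cls([(name, dict(params)) for name, params in data])


def default_pipeline() -> PreprocessSpec:
    return PreprocessSpec(
        [("sg", {"order": 1, "window": 5}), ("snv", {}), ("detrend", {"order": 2})]
    )


def apply_to_matrix(matrix: np.ndarray, spec: PreprocessSpec) -> np.ndarray:
    """Apply the pipeline row-wise to an n x p matrix."""
    out = np.asarray(matrix, dtype=float)
    for name, params in spec.steps:
        out = _STEP_FUNCS[name](out, **params)
    return out


def apply_pipeline(table: SpectraTable, spec: PreprocessSpec) -> SpectraTable:
    """Apply the pipeline to every row of a spectra table; grid unchanged."""
    return SpectraTable(apply_to_matrix(table.values, spec), table.grid, table.meta)
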