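"""Pixel-wise trait inversion, enhanced Lee speckle filtering, pseudocolor maps.

A fitted PLSR model is applied to every leaf pixel of a calibrated cube:
the pixel spectrum is preprocessed exactly like the tabular calibration
spectra, the model's channel subset is weighted by the regression
coefficients and summed, giving a per-pixel analyte estimate.  The resulting
concentration map is despeckled with the enhanced Lee filter and rendered as
a blue-to-red pseudocolor image over a fixed display range (nitrogen
0-7.64 %, chlorophyll 0-3.70 mg/g by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib.colors import LinearSegmentedColormap

from .cube import HyperCube, LeafMask
from .plsr import PLSRModel, predict
from .preprocess import PreprocessSpec, apply_to_matrix

__all__ = [
    "ConcentrationMap",
    "predict_pixelwise",
    "lee_enhanced",
    "render_pseudocolor",
    "save_pseudocolor_png",
    "DISPLAY_RANGES",
]

#: Default pseudocolor display ranges per analyte (units: % and mg/g).
DISPLAY_RANGES = {"nitrogen": (0.0, 7.64), "chlorophyll": (0.0, 3.70)}

#: Blue -> red through cyan/green/yellow/orange; endpoints are pure blue/red.
PSEUDOCOLOR_CMAP = LinearSegmentedColormap.from_list(
    "leafspec", ["#0000ff", "#00ffff", "#00ff00", "#ffff00", "#ff8000", "#ff0000"]
)


@dataclass
class ConcentrationMap:
    """Per-pixel analyte estimate with mask and display range.

    Background pixels carry NaN as sentinel.  ``display_range`` bounds the
    pseudocolor scale only; stored values are not clipped.
    """

    values: np.ndarray
    mask: LeafMask
    display_range: tuple[float, float]
    units: str = "%"
    analyte: str = "nitrogen"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.mask.values.shape:
            raise ValueError("map and mask shapes differ")


def predict_pixelwise(
    cube: HyperCube,
    mask: LeafMask,
    model: PLSRModel,
    prep: PreprocessSpec,
    analyte: str = "nitrogen",
    units: str = "%",
    display_range: tuple[float, float] | None = None,
) -> ConcentrationMap:
    """Invert a tabular PLSR model over every masked pixel of a cube.

    The cube must be calibrated and cropped to the modeling window the model
    was trained on; preprocessing is applied to the full-window pixel
    spectrum before the model's channel subset is extracted, exactly
    mirroring the tabular workflow.
    """
    if not cube.calibrated:
        raise ValueError("pixel-wise inversion requires a calibrated cube")
    if mask.values.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match cube")
    n_bands = cube.shape[2]
    if model.channels.size and model.channels.max() >= n_bands:
        missing = model.channels[model.channels >= n_bands]
        nm = (
            ", ".join(f"{w:.1f} nm" for w in model.wavelengths_nm[model.channels >= n_bands])
            if model.wavelengths_nm is not None
            else f"channel indices {missing.tolist()}"
        )
        raise ValueError(f"cube lacks model channels: {nm}")
    out = np.full(cube.shape[:2], np.nan)
    if mask.n_pixels:
        spectra = cube.values[mask.values]  # m x B
        spectra = apply_to_matrix(spectra, prep)
        out[mask.values] = predict(model, spectra[:, model.channels])
    if display_range is None:
        display_range = DISPLAY_RANGES.get(analyte, (0.0, 1.0))
    return ConcentrationMap(out, mask, display_range, units=units, analyte=analyte)


def _window_stats(values: np.ndarray, size: int) -> tuple[np.ndarray, np.ndarray]:
    """NaN-aware sliding-window mean and sample SD (background excluded)."""
    h, w = values.shape
    r = size // 2
    padded = np.pad(values, r, constant_values=np.nan)
    stack = np.empty((size * size, h, w))
    k = 0
    for dy in range(size):
        for dx in range(size):
            stack[k] = padded[dy : dy + h, dx : dx + w]
            k += 1
    count = np.sum(~np.isnan(stack), axis=0)
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    sd = np.where(count > 1, sd, 0.0)
    return mean, sd


def lee_enhanced(
    cmap: ConcentrationMap,
    size: int = 3,
    damping: float = 1.0,
    homog: float = 0.52,
    heterog: float = 1.73,
) -> ConcentrationMap:
    """Enhanced Lee speckle filter on the concentration values.

    The local coefficient of variation C = sd/|mean| over the size x size
    window (background pixels excluded) classifies each pixel: C <= homog ->
    replaced by the local mean; homog < C < heterog -> damped blend
    mean + w*(x - mean) with w = exp(-damping*(C - homog)/(heterog - C));
    C >= heterog -> preserved (point targets / edges).
    """
    if size < 3 or size % 2 == 0:
        raise ValueError("filter size must be odd and >= 3")
    if not (0 <= homog < heterog):
        raise ValueError("need 0 <= homog < heterog")
    values = cmap.values
    mean, sd = _window_stats(values, size)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(np.abs(mean) > 0, sd / np.abs(mean), np.where(sd > 0, np.inf, 0.0))
        weight = np.exp(-damping * (c - homog) / np.maximum(heterog - c, 1e-300))
    out = np.where(c <= homog, mean, np.where(c >= heterog, values, mean + weight * (values - mean)))
    out = np.where(cmap.mask.values, out, np.nan)
    return ConcentrationMap(out, cmap.mask, cmap.display_range, cmap.units, cmap.analyte)


def render_pseudocolor(
    cmap: ConcentrationMap,
    background_rgb: tuple[int, int, int] = (180, 180, 180),
) -> np.ndarray:
    """Render H x W x 3 uint8 pseudocolor pixels over the display range.

    Values at the low end map to pure blue, at the high end to pure red,
    with light-blue/green/yellow/orange transitional hues; values outside the
    range are clipped for display only.  Background renders neutral gray.
    """
    lo, hi = cmap.display_range
    if lo >= hi:
        raise ValueError("display range low bound must be below high bound")
    norm = np.clip((cmap.values - lo) / (hi - lo), 0.0, 1.0)
    norm = np.where(np.isnan(norm), 0.0, norm)
    rgb = (PSEUDOCOLOR_CMAP(norm)[..., :3] * 255).round().astype(np.uint8)
    bg = ~cmap.mask.values | np.isnan(cmap.values)
    rgb[bg] = np.array(background_rgb, dtype=np.uint8)
    return rgb


def save_pseudocolor_png(cmap: ConcentrationMap, path: str | Path, dpi: int = 150) -> Path:
    """Save the pseudocolor map with an annotated colorbar."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rgb = render_pseudocolor(cmap)
    lo, hi = cmap.display_range
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.imshow(rgb)
    ax.set_axis_off()
    sm = plt.cm.ScalarMappable(
        cmap=PSEUDOCOLOR_CMAP, norm=plt.Normalize(vmin=lo, vmax=hi)
    )
    fig.colorbar(sm, ax=ax, label=f"{cmap.analyte} ({cmap.units})")
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    return Path(path)
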