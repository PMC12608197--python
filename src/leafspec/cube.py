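"""Hyperspectral cubes: ENVI I/O, radiometric calibration, masking, ROI means.

Cubes are stored H x W x B (row, column, band).  On disk the ENVI convention
is used: a plain-text ``.hdr`` and a raw binary file, BIL interleave, float32,
band-center wavelengths recorded in the header.  Pixel coordinates are
0-based, row-major, origin at the top-left.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
from skimage import measure

from .grid import (
    MODELING_WINDOW_CHANNELS,
    MODELING_WINDOW_NM,
    WavelengthGrid,
)
from .tables import SpectraTable

__all__ = [
    "HyperCube",
    "LeafMask",
    "read_envi",
    "write_envi",
    "radiometric_correct",
    "crop_window",
    "crop_modeling_window",
    "segment_leaf",
    "roi_mean_spectrum",
]


@dataclass
class HyperCube:
    """H x W x B reflectance (or raw-count) cube on a wavelength grid."""

    values: np.ndarray
    grid: WavelengthGrid
    calibrated: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("cube must be 3-D (rows x cols x bands)")
        if self.values.shape[2] != len(self.grid):
            raise ValueError(
                f"band count {self.values.shape[2]} does not match grid "
                f"length {len(self.grid)}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class LeafMask:
    """Boolean H x W region-of-interest membership."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def n_pixels(self) -> int:
        return int(self.values.sum())


# ---------------------------------------------------------------------------
# ENVI I/O
# ---------------------------------------------------------------------------

def write_envi(cube: HyperCube, header_path: Union[str, Path]) -> Path:
    """Write an ENVI header + BIL float32 binary next to it.

    The data file drops the ``.hdr`` suffix (``leaf.hdr`` -> ``leaf.dat``).
    Returns the data-file path.
    """
    header_path = Path(header_path)
    data_path = header_path.with_suffix(".dat")
    h, w, b = cube.shape
    wavelengths = ", ".join(f"{x:.6f}" for x in cube.grid.centers)
    header = (
        "ENVI\n"
        "description = {leafspec hyperspectral cube}\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bil\n"
        "byte order = 0\n"
        f"calibrated = {int(cube.calibrated)}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wavelengths}}}\n"
    )
    header_path.write_text(header)
    # BIL: line-major, band within line: (lines, bands, samples)
    bil = np.ascontiguousarray(cube.values.transpose(0, 2, 1), dtype="<f4")
    bil.tofile(data_path)
    return data_path


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    key, buf, in_braces = None, [], False
    for line in text.splitlines():
        if in_braces:
            buf.append(line)
            if "}" in line:
                fields[key] = " ".join(buf)
                in_braces, key, buf = False, None, []
            continue
        if "=" not in line:
            continue
        k, v = line.split("=", 1)
        k, v = k.strip().lower(), v.strip()
        if v.startswith("{") and "}" not in v:
            key, buf, in_braces = k, [v], True
        else:
            fields[k] = v
    return fields


def read_envi(header_path: Union[str, Path]) -> HyperCube:
    """Read an ENVI cube written by :func:`write_envi` (BIL, float32)."""
    header_path = Path(header_path)
    fields = _parse_envi_header(header_path.read_text())
    h = int(fields["lines"])
    w = int(fields["samples"])
    b = int(fields["bands"])
    if fields.get("interleave", "bil").lower() != "bil":
        raise ValueError("only BIL interleave is supported")
    if int(fields.get("data type", 4)) != 4:
        raise ValueError("only float32 (ENVI data type 4) is supported")
    wl_text = fields["wavelength"].strip().strip("{}")
    centers = np.array([float(x) for x in wl_text.split(",") if x.strip()])
    if centers.size != b:
        raise ValueError("wavelength list length does not match band count")
    data = np.fromfile(header_path.with_suffix(".dat"), dtype="<f4")
    values = data.reshape(h, b, w).transpose(0, 2, 1).astype(np.float64)
    calibrated = bool(int(fields.get("calibrated", 0)))
    return HyperCube(values, WavelengthGrid(centers), calibrated=calibrated)


# ---------------------------------------------------------------------------
# Radiometric calibration
# ---------------------------------------------------------------------------

def radiometric_correct(raw: HyperCube, white: HyperCube, dark: HyperCube) -> HyperCube:
    """Convert raw counts to reflectance: R = (R0 - Rb) / (Rw - Rb).

    ``white`` is a reference acquisition of a near-perfect diffuse reflector,
    ``dark`` a lens-occluded dark-current frame.  All three cubes must share
    shape and grid, and the white-dark difference must be nonzero everywhere.
    """
    for name, ref in (("white", white), ("dark", dark)):
        if ref.shape != raw.shape:
            raise ValueError(f"{name} reference shape {ref.shape} != raw {raw.shape}")
        if not np.allclose(ref.grid.centers, raw.grid.centers):
            raise ValueError(f"{name} reference grid does not match raw grid")
    denom = white.values - dark.values
    zero = denom == 0
    if np.any(zero):
        r, c, b = (int(i[0]) for i in np.nonzero(zero))
        raise ValueError(
            "white - dark is zero at pixel "
            f"(row={r}, col={c}), band {b} ({raw.grid.centers[b]:.3f} nm)"
        )
    out = (raw.values - dark.values) / denom
    return HyperCube(out, raw.grid, calibrated=True)


def average_reference_frame(ref: HyperCube) -> HyperCube:
    """Replace every pixel of a reference cube by the spatial mean spectrum.

    Per-column (line-averaged) white/dark references are expanded to full
    frames this way before calibration.
    """
    mean = ref.values.mean(axis=(0, 1))
    values = np.broadcast_to(mean, ref.shape).copy()
    return HyperCube(values, ref.grid, calibrated=ref.calibrated)


# ---------------------------------------------------------------------------
# Spectral window cropping
# ---------------------------------------------------------------------------

def crop_window(
    data: Union[HyperCube, SpectraTable],
    lo_nm: float,
    hi_nm: float,
    n_channels: int | None = None,
):
    """Restrict a cube or spectra table to channels with lo <= center <= hi.

    When ``n_channels`` is given and the inclusive crop retains more channels,
    the topmost channels are dropped to honor a definitional channel budget
    (the 430-900 nm modeling window counts 646 channels by convention although
    the inclusive crop of the nominal grid yields 647).
    """
    idx = data.grid.window_indices(lo_nm, hi_nm)
    if idx.size == 0:
        raise ValueError(f"window [{lo_nm}, {hi_nm}] nm contains no channels")
    if n_channels is not None:
        idx = idx[:n_channels]
    if isinstance(data, HyperCube):
        return HyperCube(data.values[:, :, idx], data.grid.subset(idx), data.calibrated)
    return data.select_channels(idx)


def crop_modeling_window(data: Union[HyperCube, SpectraTable]):
    """Apply the canonical 430-900 nm / 646-channel modeling window."""
    lo, hi = MODELING_WINDOW_NM
    return crop_window(data, lo, hi, n_channels=MODELING_WINDOW_CHANNELS)


# ---------------------------------------------------------------------------
# Leaf segmentation and ROI spectra
# ---------------------------------------------------------------------------

def segment_leaf(
    cube: HyperCube,
    threshold: float = 0.1,
    nir_window: tuple[float, float] = (760.0, 800.0),
) -> LeafMask:
    """Threshold the mean NIR reflectance and keep the largest component.

    Leaf tissue is strongly reflective on the NIR plateau while the imaging
    background is dark, so the mean 760-800 nm reflectance separates the two.
    An all-background result produces an empty mask with a warning.
    """
    if not cube.calibrated:
        raise ValueError("segment_leaf requires a calibrated (reflectance) cube")
    nir_idx = cube.grid.window_indices(*nir_window)
    if nir_idx.size == 0:  # window outside grid: fall back to all bands
        nir_idx = np.arange(len(cube.grid))
    score = cube.values[:, :, nir_idx].mean(axis=2)
    raw = score > threshold
    if not raw.any():
        warnings.warn("leaf segmentation found no foreground pixels", stacklevel=2)
        return LeafMask(raw)
    labels = measure.label(raw, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return LeafMask(labels == int(np.argmax(counts)))


def roi_mean_spectrum(cube: HyperCube, mask: LeafMask) -> np.ndarray:
    """Per-band arithmetic mean over masked pixels."""
    if mask.values.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match cube")
    if mask.n_pixels == 0:
        raise ValueError("cannot average over an empty mask")
    return cube.values[mask.values].mean(axis=0)
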