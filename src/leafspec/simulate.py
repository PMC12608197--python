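"""Synthetic leaf spectra and cubes with known analyte-wavelength structure.

The generator emulates the data regime of a greenhouse nitrogen-stress
trial imaged with a benchtop VNIR line scanner: per-sample mean reflectance
spectra on the 646-channel 430-900 nm modeling grid, with analyte-driven
Gaussian absorption features planted at diagnostic wavelengths (defaults
479 nm and 689 nm, the blue and red chlorophyll absorption bands shared by
nitrogen and chlorophyll), plus sensor noise.  Reflectance is
``baseline - sum_j effect_j * response * G(center_j, width_j) + noise``,
clipped to [0, 1]; responses are uniform over the analyte range.  The noise
has two components: i.i.d. per-channel detector noise (``noise_sd``) and a
smooth per-sample baseline drift (``drift_sd``, correlation length
``drift_length_nm``) emulating the illumination/scattering drift that the
detrending preprocessing step targets in real acquisitions.

Because the planted channels are known, every downstream stage (selection,
modeling, pixel-wise inversion) can be tested for recovery against ground
truth without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cube import HyperCube, LeafMask
from .grid import WavelengthGrid, modeling_window_grid
from .mapping import ConcentrationMap
from .tables import ResponseVector, SpectraTable

__all__ = [
    "SimulationConfig",
    "SamplingDesign",
    "EllipseSpec",
    "VeinSpec",
    "tomato_trial_design",
    "two_block_config",
    "enumerate_design",
    "simulate_spectra",
    "simulate_cube",
    "NITROGEN_RANGE",
    "CHLOROPHYLL_RANGE",
]

#: Observed analyte ranges in the emulated trial (min, max).
NITROGEN_RANGE = (0.7374, 7.6357)  # % dry mass
CHLOROPHYLL_RANGE = (0.2614, 3.7026)  # mg/g


@dataclass
class SimulationConfig:
    """Parameters of the spectra generator.

    ``planted_bands`` lists (center nm, width nm, effect size) triples; the
    effect size is the reflectance depression per unit response at the band
    center.  Defaults place bands at the shared blue/red diagnostic
    wavelengths with 15 nm widths, a 0.55 baseline, and low sensor noise
    (SD 0.005 reflectance), giving a high-SNR regime in which planted
    channels dominate channel-response correlation.
    """

    seed: int = 0
    n_samples: int = 245
    planted_bands: Sequence[tuple[float, float, float]] = (
        (479.0, 15.0, 0.030),
        (689.0, 15.0, 0.030),
    )
    baseline_level: float = 0.55
    noise_sd: float = 0.005
    drift_sd: float = 0.003
    drift_length_nm: float = 30.0
    response_noise_sd: float | None = None
    response_range: tuple[float, float] = NITROGEN_RANGE
    grid: WavelengthGrid = field(default_factory=modeling_window_grid)
    analyte: str = "nitrogen"
    units: str = "%"

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if self.noise_sd < 0 or self.drift_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        lo, hi = self.response_range
        if not lo < hi:
            raise ValueError("response_range min must be below max")
        if self.response_noise_sd is None:
            # reference-assay error: 5% of the analyte range by default
            self.response_noise_sd = 0.05 * (hi - lo)
        if self.response_noise_sd < 0:
            raise ValueError("response_noise_sd must be >= 0")
        gmin, gmax = self.grid.centers[0], self.grid.centers[-1]
        for center, width, _ in self.planted_bands:
            if not gmin <= center <= gmax:
                raise ValueError(f"planted band center {center} nm outside grid")
            if width <= 0:
                raise ValueError("planted band width must be positive")

    def planted_channels(self, within_nm: float = 1.0) -> np.ndarray:
        """Channel indices within ``within_nm`` of any planted band center."""
        hits = [
            np.flatnonzero(np.abs(self.grid.centers - c) <= within_nm)
            for c, _, _ in self.planted_bands
        ]
        return np.unique(np.concatenate(hits)) if hits else np.array([], dtype=int)

    def planted_block_channels(self, n_sigma: float = 1.0) -> np.ndarray:
        """Channel indices within n_sigma band widths of any planted center."""
        hits = [
            np.flatnonzero(np.abs(self.grid.centers - c) <= n_sigma * w)
            for c, w, _ in self.planted_bands
        ]
        return np.unique(np.concatenate(hits)) if hits else np.array([], dtype=int)


def two_block_config(seed: int = 0, n_samples: int = 200) -> SimulationConfig:
    """Recovery-study conditions: signal confined to two narrow 10-channel blocks.

    Bands at 479 and 689 nm with 3.6 nm widths (so the signal is essentially
    confined to ~10 channels around each center), effect 0.05 per unit
    response, detector noise SD 0.02 and baseline drift SD 0.01 -- a
    high-SNR regime (peak signal swing ~0.35 reflectance) in which a
    selector should retain the planted blocks and discard channels far from
    them.  Reference values are exact here: the recovery conditions isolate
    spectral noise from reference-assay error.
    """
    return SimulationConfig(
        seed=seed,
        n_samples=n_samples,
        planted_bands=((479.0, 3.6, 0.05), (689.0, 3.6, 0.05)),
        noise_sd=0.02,
        drift_sd=0.01,
        response_noise_sd=0.0,
    )


def _band_profile(cfg: SimulationConfig) -> np.ndarray:
    """Per-channel absorption profile per unit response (sum over bands)."""
    lam = cfg.grid.centers
    profile = np.zeros_like(lam)
    for center, width, effect in cfg.planted_bands:
        profile += effect * np.exp(-((lam - center) ** 2) / (2.0 * width**2))
    return profile


def _drift_noise(
    cfg: SimulationConfig, shape: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """Smooth per-sample baseline drift: unit-SD filtered noise * drift_sd."""
    from scipy.ndimage import gaussian_filter1d

    if cfg.drift_sd == 0:
        return np.zeros(shape)
    step = cfg.grid.sampling_interval or 1.0
    sigma = max(cfg.drift_length_nm / step, 1.0)
    rough = rng.normal(0.0, 1.0, shape)
    smooth = gaussian_filter1d(rough, sigma, axis=-1, mode="reflect")
    sd = smooth.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return smooth / sd * cfg.drift_sd


def simulate_spectra(cfg: SimulationConfig) -> tuple[SpectraTable, ResponseVector]:
    """Draw responses and spectra; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.response_range
    responses = rng.uniform(lo, hi, cfg.n_samples)
    profile = _band_profile(cfg)
    clean = cfg.baseline_level - responses[:, None] * profile[None, :]
    noise = rng.normal(0.0, cfg.noise_sd, clean.shape) if cfg.noise_sd > 0 else 0.0
    noise = noise + _drift_noise(cfg, clean.shape, rng)
    values = np.clip(clean + noise, 0.0, 1.0)
    meta = pd.DataFrame({"sample": np.arange(cfg.n_samples)})
    table = SpectraTable(values, cfg.grid, meta)
    # the reported reference values carry wet-chemistry assay error
    observed = responses + (
        rng.normal(0.0, cfg.response_noise_sd, cfg.n_samples)
        if cfg.response_noise_sd > 0
        else 0.0
    )
    observed = np.maximum(observed, 0.0)  # assays report non-negative content
    return table, ResponseVector(observed, analyte=cfg.analyte, units=cfg.units)


# ---------------------------------------------------------------------------
# Sampling design bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class SamplingDesign:
    """Stratified sampling plan: per-treatment sample counts repeated per stage."""

    treatments: list[tuple[str, int]]
    stages: list[str]
    leaves_per_sample: int = 6

    def __post_init__(self) -> None:
        if not self.treatments or not self.stages:
            raise ValueError("design needs at least one treatment and one stage")
        for name, count in self.treatments:
            if count < 1:
                raise ValueError(f"treatment {name!r} has non-positive count")
        if self.leaves_per_sample < 1:
            raise ValueError("leaves_per_sample must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.stages) * sum(c for _, c in self.treatments)

    @property
    def n_leaves(self) -> int:
        return self.n_samples * self.leaves_per_sample


def tomato_trial_design() -> SamplingDesign:
    """The emulated trial: 25 samples for each of 9 nitrogen treatments plus
    20 for the highest, per each of 3 growth stages (245 x 3 = 735 samples,
    6 leaves each = 4410 leaves)."""
    treatments = [(f"N{20 * (i + 1)}", 25) for i in range(9)] + [("N200", 20)]
    return SamplingDesign(treatments, ["seedling", "flowering", "fruiting"], 6)


def enumerate_design(design: SamplingDesign) -> pd.DataFrame:
    """One row per sample: (stage, treatment, sample id within treatment)."""
    rows = []
    for stage in design.stages:
        for name, count in design.treatments:
            for i in range(count):
                rows.append((stage, name, i))
    return pd.DataFrame(rows, columns=["stage", "treatment", "sample"])


# ---------------------------------------------------------------------------
# Synthetic cubes
# ---------------------------------------------------------------------------


@dataclass
class EllipseSpec:
    """Leaf footprint: axis-aligned ellipse (row/col center, semi-axes)."""

    center_row: float
    center_col: float
    semi_row: float
    semi_col: float


@dataclass
class VeinSpec:
    """Vein/base depressions of the concentration field.

    The main vein runs along the long axis; ``n_secondary`` straight side
    veins branch off it.  Vein and leaf-base pixels carry ``depth``-fraction
    lower concentrations, emulating the lower analyte content of vascular
    tissue and the leaf base.
    """

    main_width: int = 1
    n_secondary: int = 4
    depth: float = 0.35
    base_fraction: float = 0.15


def _ellipse_mask(shape: tuple[int, int], ellipse: EllipseSpec) -> np.ndarray:
    h, w = shape
    if (
        ellipse.center_row - ellipse.semi_row < -0.5
        or ellipse.center_row + ellipse.semi_row > h - 0.5
        or ellipse.center_col - ellipse.semi_col < -0.5
        or ellipse.center_col + ellipse.semi_col > w - 0.5
    ):
        raise ValueError("leaf ellipse does not fit inside the frame")
    rr, cc = np.mgrid[0:h, 0:w]
    if ellipse.semi_row <= 0 or ellipse.semi_col <= 0:
        return np.zeros(shape, dtype=bool)
    return (
        ((rr - ellipse.center_row) / ellipse.semi_row) ** 2
        + ((cc - ellipse.center_col) / ellipse.semi_col) ** 2
    ) <= 1.0


def _concentration_field(
    mask: np.ndarray,
    ellipse: EllipseSpec,
    veins: VeinSpec,
    response_range: tuple[float, float],
    constant: Optional[float],
) -> np.ndarray:
    """Smooth tip-to-base gradient with vein/base depressions, NaN outside."""
    h, w = mask.shape
    rr, cc = np.mgrid[0:h, 0:w]
    lo, hi = response_range
    field = np.full(mask.shape, np.nan)
    if not mask.any():
        return field
    if constant is not None:
        field[mask] = constant
        return field
    # gradient along the long (column) axis: tip (high col) richer than base
    t = (cc - (ellipse.center_col - ellipse.semi_col)) / (2 * ellipse.semi_col)
    base = lo + (hi - lo) * (0.35 + 0.55 * np.clip(t, 0, 1))
    depress = np.zeros(mask.shape)
    # main vein along the row center line
    vein = np.abs(rr - ellipse.center_row) <= veins.main_width / 2
    # secondary veins: straight diagonals branching from the main vein
    for k in range(veins.n_secondary):
        cx = ellipse.center_col + (k - (veins.n_secondary - 1) / 2) * (
            ellipse.semi_col / max(veins.n_secondary, 1)
        )
        diag_up = np.abs((rr - ellipse.center_row) - (cc - cx)) <= 0.5
        diag_dn = np.abs((rr - ellipse.center_row) + (cc - cx)) <= 0.5
        vein |= diag_up | diag_dn
    depress[vein] = veins.depth
    base_zone = t < veins.base_fraction
    depress[base_zone] = np.maximum(depress[base_zone], veins.depth)
    field[mask] = (base * (1.0 - depress))[mask]
    return np.clip(field, lo, hi, out=field)


BACKGROUND_REFLECTANCE = 0.02  # flat dark background signature


def simulate_cube(
    cfg: SimulationConfig,
    shape: tuple[int, int] = (48, 64),
    ellipse: Optional[EllipseSpec] = None,
    veins: Optional[VeinSpec] = None,
    constant_concentration: Optional[float] = None,
) -> tuple[HyperCube, ConcentrationMap]:
    """Synthetic calibrated cube of a single leaf plus its true analyte field.

    Inside-leaf pixels carry spectra from the same band model as
    :func:`simulate_spectra`, driven by a smooth spatial concentration field
    (tip-to-base gradient with lower values on veins and at the leaf base);
    background pixels carry a flat 0.02 reflectance signature.  The returned
    true field enables recovery tests of the pixel-wise inversion.
    """
    h, w = shape
    if h < 8 or w < 8:
        raise ValueError("cube frame must be at least 8 x 8")
    if ellipse is None:
        ellipse = EllipseSpec(h / 2, w / 2, 0.38 * h, 0.42 * w)
    if veins is None:
        veins = VeinSpec()
    mask = _ellipse_mask(shape, ellipse)
    field = _concentration_field(
        mask, ellipse, veins, cfg.response_range, constant_concentration
    )
    rng = np.random.default_rng(cfg.seed)
    b = len(cfg.grid)
    values = np.full((h, w, b), BACKGROUND_REFLECTANCE)
    if mask.any():
        profile = _band_profile(cfg)
        conc = field[mask]
        spectra = cfg.baseline_level - conc[:, None] * profile[None, :]
        if cfg.noise_sd > 0:
            spectra = spectra + rng.normal(0.0, cfg.noise_sd, spectra.shape)
        if cfg.drift_sd > 0:
            spectra = spectra + _drift_noise(cfg, spectra.shape, rng)
        values[mask] = np.clip(spectra, 0.0, 1.0)
    cube = HyperCube(values, cfg.grid, calibrated=True)
    lo, hi = cfg.response_range
    truth = ConcentrationMap(
        field, LeafMask(mask), (0.0, hi), units=cfg.units, analyte=cfg.analyte
    )
    return cube, truth
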