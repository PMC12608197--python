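"""End-to-end coarse-fine-optimal cascades and the strategy comparison table.

Twelve strategies = {iRF, iVISSA} x {CARS, BOSS, VCPA} x {IRIV, GA}.  Every
selection stage sees only the calibration rows; prediction rows are touched
solely by the final metric evaluation.  A PLSR model (latent-variable count
re-selected by 10-fold CV) is fitted at every stage boundary so that the
comparison table reports NV / R / RMSE / RPD per stage, with the best
strategy flagged by maximal prediction R (ties: minimal prediction RMSE).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .coarse import irf_select, ivissa_select
from .fine import boss_select, cars_select, vcpa_select
from .grid import MODELING_WINDOW_CHANNELS
from .optimal import ga_select, iriv_select
from .plsr import (
    MAX_COMPONENTS,
    MetricsReport,
    PLSRModel,
    cv_select_components,
    evaluate,
    fit_plsr,
)
from .selection import SelectionResult
from .tables import DatasetSplit, ResponseVector, SpectraTable

__all__ = [
    "CascadeConfig",
    "CascadeResult",
    "StageModel",
    "STRATEGIES",
    "run_strategy",
    "run_all",
    "comparison_table",
    "wavelength_report",
    "window_percent",
]


def window_percent(count: int, window_size: int = MODELING_WINDOW_CHANNELS) -> float:
    """Percentage-of-window bookkeeping, rounded to 2 decimals (28 -> 4.33)."""
    return round(100.0 * count / window_size, 2)

COARSE_ALGOS = {"iRF": irf_select, "iVISSA": ivissa_select}
FINE_ALGOS = {"CARS": cars_select, "BOSS": boss_select, "VCPA": vcpa_select}
OPTIMAL_ALGOS = {"IRIV": iriv_select, "GA": ga_select}

#: The 12 strategy triples, e.g. ("iRF", "CARS", "IRIV").
STRATEGIES: list[tuple[str, str, str]] = [
    (c, f, o) for c, f, o in product(COARSE_ALGOS, FINE_ALGOS, OPTIMAL_ALGOS)
]


@dataclass
class CascadeConfig:
    """Per-algorithm keyword overrides plus global CV settings.

    Defaults follow the reference configuration (1000 iRF iterations, 1000
    iVISSA/BOSS/VCPA sub-models, 100 CARS runs, a 200-evaluation GA budget);
    reduced budgets for desk-scale runs are passed through the per-algorithm
    dicts.
    """

    irf: dict = field(default_factory=dict)
    ivissa: dict = field(default_factory=dict)
    cars: dict = field(default_factory=dict)
    boss: dict = field(default_factory=dict)
    vcpa: dict = field(default_factory=dict)
    iriv: dict = field(default_factory=dict)
    ga: dict = field(default_factory=dict)
    max_components: int = MAX_COMPONENTS
    cv_folds: int = 10

    def params_for(self, algo: str) -> dict:
        base = {
            "max_components": self.max_components,
            "cv_folds": self.cv_folds,
        }
        base.update(getattr(self, algo.lower()))
        return base

    @classmethod
    def reduced(cls, scale: float = 0.1) -> "CascadeConfig":
        """Desk-scale budgets: same algorithms, fewer sampled sub-models."""
        return cls(
            irf={"n_iterations": max(20, int(1000 * scale))},
            ivissa={"n_submodels": max(30, int(1000 * scale)), "max_rounds": 6},
            cars={"n_mc": max(20, int(100 * scale * 5))},
            boss={"n_bootstrap": max(30, int(1000 * scale)), "max_rounds": 5},
            vcpa={
                "n_bms": max(30, int(1000 * scale)),
                "n_edf_iters": max(5, int(50 * scale)),
                "final_pool": 40,
                "max_subset_eval": 20,
            },
            iriv={"n_models": max(40, int(500 * scale)), "max_rounds": 5},
            ga={"n_evaluations": 200},
            cv_folds=5,
        )


@dataclass
class StageModel:
    """Fitted model + metrics at one stage boundary."""

    stage: str
    selection: SelectionResult | None
    model: PLSRModel
    calibration: MetricsReport
    prediction: MetricsReport

    @property
    def n_variables(self) -> int:
        return int(self.model.channels.size)


@dataclass
class CascadeResult:
    """One strategy's chained selections and per-stage models."""

    strategy: tuple[str, str, str]
    stages: list[StageModel]
    seed: int

    @property
    def name(self) -> str:
        return "–".join(self.strategy)  # e.g. iRF-CARS-IRIV

    @property
    def final(self) -> StageModel:
        return self.stages[-1]

    def selection_chain(self) -> list[SelectionResult]:
        return [s.selection for s in self.stages if s.selection is not None]


def _fit_stage(
    stage: str,
    selection: SelectionResult | None,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_pred: np.ndarray,
    y_pred: np.ndarray,
    config: CascadeConfig,
    seed: int,
    wavelengths: np.ndarray,
) -> StageModel:
    channels = (
        selection.channels if selection is not None else np.arange(X_cal.shape[1])
    )
    Xc, Xp = X_cal[:, channels], X_pred[:, channels]
    k, _ = cv_select_components(
        Xc, y_cal, max_components=config.max_components, folds=config.cv_folds, seed=seed
    )
    model = fit_plsr(Xc, y_cal, k, channels=channels, wavelengths_nm=wavelengths[channels])
    cal = evaluate(model, Xc, y_cal, "calibration")
    pred = evaluate(model, Xp, y_pred, "prediction")
    return StageModel(stage, selection, model, cal, pred)


def run_strategy(
    table: SpectraTable,
    response: ResponseVector,
    split: DatasetSplit,
    strategy: tuple[str, str, str],
    config: CascadeConfig | None = None,
    seed: int = 0,
    _coarse_cache: dict | None = None,
    _fine_cache: dict | None = None,
) -> CascadeResult:
    """Run one coarse-fine-optimal strategy end to end.

    All selections are fitted on calibration rows only.  Models are refit at
    the full-spectrum, coarse, fine, and optimal boundaries.
    """
    coarse_name, fine_name, opt_name = strategy
    if coarse_name not in COARSE_ALGOS:
        raise ValueError(f"unknown coarse algorithm {coarse_name!r}")
    if fine_name not in FINE_ALGOS:
        raise ValueError(f"unknown fine algorithm {fine_name!r}")
    if opt_name not in OPTIMAL_ALGOS:
        raise ValueError(f"unknown optimal algorithm {opt_name!r}")
    if config is None:
        config = CascadeConfig()

    X, y = table.values, response.values
    X_cal, y_cal = X[split.calibration], y[split.calibration]
    X_pred, y_pred = X[split.prediction], y[split.prediction]
    wavelengths = table.grid.centers

    # stage seeds derived from one run seed, stable per algorithm
    stage_seed = {name: seed + i for i, name in enumerate(["coarse", "fine", "optimal"])}

    def cached(cache, key, builder):
        if cache is None:
            return builder()
        if key not in cache:
            cache[key] = builder()
        return cache[key]

    coarse = cached(
        _coarse_cache,
        coarse_name,
        lambda: COARSE_ALGOS[coarse_name](
            X_cal, y_cal, seed=stage_seed["coarse"], **config.params_for(coarse_name)
        ),
    )
    fine = cached(
        _fine_cache,
        (coarse_name, fine_name),
        lambda: FINE_ALGOS[fine_name](
            X_cal[:, coarse.channels],
            y_cal,
            seed=stage_seed["fine"],
            parent=coarse,
            **config.params_for(fine_name),
        ),
    )
    opt_fn = OPTIMAL_ALGOS[opt_name]
    opt_out = opt_fn(
        X_cal[:, fine.channels],
        y_cal,
        seed=stage_seed["optimal"],
        parent=fine,
        **config.params_for(opt_name),
    )
    optimal = opt_out[0] if isinstance(opt_out, tuple) else opt_out

    stages = [
        _fit_stage("full", None, X_cal, y_cal, X_pred, y_pred, config, seed, wavelengths),
        _fit_stage("coarse", coarse, X_cal, y_cal, X_pred, y_pred, config, seed, wavelengths),
        _fit_stage("fine", fine, X_cal, y_cal, X_pred, y_pred, config, seed, wavelengths),
        _fit_stage("optimal", optimal, X_cal, y_cal, X_pred, y_pred, config, seed, wavelengths),
    ]
    return CascadeResult(strategy=strategy, stages=stages, seed=seed)


def run_all(
    table: SpectraTable,
    response: ResponseVector,
    split: DatasetSplit,
    config: CascadeConfig | None = None,
    seed: int = 0,
) -> tuple[list[CascadeResult], pd.DataFrame]:
    """Run all 12 strategies (coarse and fine stages shared via caching)."""
    coarse_cache: dict = {}
    fine_cache: dict = {}
    results = [
        run_strategy(
            table,
            response,
            split,
            strategy,
            config=config,
            seed=seed,
            _coarse_cache=coarse_cache,
            _fine_cache=fine_cache,
        )
        for strategy in STRATEGIES
    ]
    return results, comparison_table(results, window_size=table.n_channels)


def comparison_table(
    results: list[CascadeResult], window_size: int = MODELING_WINDOW_CHANNELS
) -> pd.DataFrame:
    """Per-strategy, per-stage metrics in the Coarse/Fine/Optimization layout.

    The best row is the optimal-stage row with maximal prediction R, ties
    broken by minimal prediction RMSE.
    """
    rows = []
    for res in results:
        for stage in res.stages:
            rows.append(
                {
                    "coarse": res.strategy[0],
                    "fine": res.strategy[1] if stage.stage in ("fine", "optimal") else "-",
                    "optimization": res.strategy[2] if stage.stage == "optimal" else "-",
                    "stage": stage.stage,
                    "NV": stage.n_variables,
                    "NV_percent": round(100.0 * stage.n_variables / window_size, 2),
                    "R_C": stage.calibration.r,
                    "RMSE_C": stage.calibration.rmse,
                    "RPD_C": stage.calibration.rpd,
                    "R_P": stage.prediction.r,
                    "RMSE_P": stage.prediction.rmse,
                    "RPD_P": stage.prediction.rpd,
                    "strategy": res.name,
                }
            )
    frame = pd.DataFrame(rows).drop_duplicates(
        subset=["coarse", "fine", "optimization", "stage"], ignore_index=True
    )
    is_opt = frame["stage"] == "optimal"
    frame["best"] = False
    if is_opt.any():
        opt = frame[is_opt].sort_values(
            ["R_P", "RMSE_P"], ascending=[False, True], kind="stable"
        )
        frame.loc[opt.index[0], "best"] = True
    return frame


def wavelength_report(
    result: CascadeResult, window_size: int = MODELING_WINDOW_CHANNELS
) -> tuple[list[int], float]:
    """Selected wavelengths as rounded-nm labels plus percent of the window.

    nm labels are printed as nearest integers while channel indices stay
    exact internally; percent = count / window size, rounded to 2 decimals.
    """
    final = result.final
    wl = final.model.wavelengths_nm
    labels = [int(round(w)) for w in (wl if wl is not None else [])]
    percent = round(100.0 * len(labels) / window_size, 2)
    return labels, percent
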