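"""Stage-2 model-population fine selection on X1: CARS, BOSS, VCPA.

All three selectors sample many variable subsets, score each sub-model by
its cross-validated RMSE, and return the minimum-RMSE_CV subset.  Channel
indices returned are relative to the modeling window (subsets of the coarse
parent's channels).
"""

from __future__ import annotations

import numpy as np

from .plsr import MAX_COMPONENTS, fit_plsr, subset_rmsecv
from .selection import PopulationTrace, SelectionResult

__all__ = [
    "cars_select",
    "boss_select",
    "vcpa_select",
    "cars_edf_schedule",
    "vcpa_pool_schedule",
]


def cars_edf_schedule(p: int, n_runs: int) -> np.ndarray:
    """Exponentially decreasing retained-count schedule for CARS.

    r_i = a*exp(-k*i) calibrated so the first run keeps all ``p`` channels
    and the last keeps 2: k = ln(p/2)/(N-1), a = e^k.
    """
    if p < 2:
        raise ValueError("need at least 2 channels")
    if n_runs < 1:
        raise ValueError("need at least 1 run")
    if n_runs == 1 or p == 2:
        return np.full(n_runs, p if n_runs == 1 else 2, dtype=int)[:n_runs]
    k = np.log(p / 2.0) / (n_runs - 1)
    i = np.arange(1, n_runs + 1)
    ratios = np.exp(k) * np.exp(-k * i)
    counts = np.clip(np.round(ratios * p).astype(int), 2, p)
    counts[0], counts[-1] = p, 2
    return counts


def _wavelengths_of(parent: SelectionResult | None, p: int) -> np.ndarray:
    if parent is not None:
        return parent.channels
    return np.arange(p)


def cars_select(
    X1: np.ndarray,
    y: np.ndarray,
    n_mc: int = 100,
    max_components: int = MAX_COMPONENTS,
    row_fraction: float = 0.8,
    cv_folds: int = 10,
    cv_seed: int = 0,
    seed: int = 0,
    parent: SelectionResult | None = None,
) -> SelectionResult:
    """Competitive adaptive reweighted sampling.

    Per Monte Carlo run: fit PLSR on a random ``row_fraction`` row subset,
    rank the surviving channels by |regression coefficient|, enforce the
    exponentially decreasing retained count, then resample survivors with
    probability proportional to |coefficient| (adaptive reweighted
    sampling).  Each run's subset is scored by RMSE_CV on the full
    calibration rows; the minimum-RMSE_CV run wins.
    """
    X1 = np.asarray(X1, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X1.shape
    if p < 2:
        raise ValueError("CARS needs at least 2 channels")
    rng = np.random.default_rng(seed)
    schedule = cars_edf_schedule(p, n_mc)
    survivors = np.arange(p)
    subsets, rmse_trace, size_trace = [], [], []
    n_rows = max(2, int(round(row_fraction * n)))

    for i in range(n_mc):
        rows = rng.choice(n, size=n_rows, replace=False)
        k = int(min(max_components, survivors.size, n_rows - 1))
        model = fit_plsr(X1[np.ix_(rows, survivors)], y[rows], k)
        weights = np.abs(model.coef)
        n_keep = min(schedule[i], survivors.size)
        top = np.argsort(-weights, kind="stable")[:n_keep]
        kept, kept_w = survivors[top], weights[top]
        # adaptive reweighted sampling among the enforced survivors
        if kept_w.sum() > 0:
            prob = kept_w / kept_w.sum()
            drawn = rng.choice(kept, size=n_keep, replace=True, p=prob)
            new = np.unique(drawn)
        else:
            new = kept
        if new.size < 2:
            new = np.sort(kept[np.argsort(-kept_w, kind="stable")[:2]])
        survivors = np.sort(new)
        r, _ = subset_rmsecv(
            X1, y, survivors, max_components=max_components, folds=cv_folds, seed=cv_seed
        )
        subsets.append(survivors.copy())
        rmse_trace.append(r)
        size_trace.append(survivors.size)

    best = int(np.argmin(rmse_trace))
    window_channels = _wavelengths_of(parent, p)
    return SelectionResult(
        channels=window_channels[subsets[best]],
        stage="fine",
        algorithm="CARS",
        seed=seed,
        trace=PopulationTrace(np.array(size_trace), np.array(rmse_trace)),
        parent=parent,
        best_rmsecv=float(rmse_trace[best]),
        extras={"best_run": best + 1},
    )


def boss_select(
    X1: np.ndarray,
    y: np.ndarray,
    n_bootstrap: int = 1000,
    keep_fraction: float = 0.10,
    max_rounds: int = 10,
    max_components: int = MAX_COMPONENTS,
    cv_folds: int = 10,
    cv_seed: int = 0,
    seed: int = 0,
    parent: SelectionResult | None = None,
) -> SelectionResult:
    """Bootstrapping soft shrinkage.

    Rounds of weighted bootstrap channel sampling: each sub-model draws p
    channels with replacement with probability given by the current weights
    (the unique draws form the sub-model), the best ``keep_fraction`` of
    sub-models by RMSE_CV contribute their normalized |coefficient| mass to
    the next weight vector (soft shrinkage: weights decay rather than being
    hard-zeroed).  Rounds stop when the weight support stops shrinking; the
    overall minimum-RMSE_CV sub-model is returned.
    """
    X1 = np.asarray(X1, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X1.shape
    if p < 2:
        raise ValueError("BOSS needs at least 2 channels")
    rng = np.random.default_rng(seed)
    w = np.full(p, 1.0 / p)
    best_rmse, best_subset = np.inf, None
    rmse_trace, size_trace = [], []
    prev_support = p

    for _ in range(max_rounds):
        new_w = np.zeros(p)
        round_rmse = np.empty(n_bootstrap)
        round_subsets = []
        for j in range(n_bootstrap):
            draws = rng.choice(p, size=p, replace=True, p=w)
            idx = np.unique(draws)
            if idx.size < 2:
                idx = np.union1d(idx, rng.choice(p, size=2, replace=False, p=w))
            round_subsets.append(idx)
            round_rmse[j], _ = subset_rmsecv(
                X1, y, idx, max_components=max_components, folds=cv_folds, seed=cv_seed
            )
        order = np.argsort(round_rmse, kind="stable")
        n_keep = max(1, int(round(keep_fraction * n_bootstrap)))
        for j in order[:n_keep]:
            idx = round_subsets[j]
            k = int(min(max_components, idx.size, n - 1))
            model = fit_plsr(X1[:, idx], y, k)
            mass = np.abs(model.coef)
            if mass.sum() > 0:
                new_w[idx] += mass / mass.sum()
        j_best = int(order[0])
        rmse_trace.append(float(round_rmse[j_best]))
        size_trace.append(int(round_subsets[j_best].size))
        if round_rmse[j_best] < best_rmse:
            best_rmse, best_subset = float(round_rmse[j_best]), round_subsets[j_best]
        if new_w.sum() == 0:
            break
        w = new_w / new_w.sum()  # weights sum to 1 each round
        support = int((w > 0).sum())
        if support >= prev_support:
            break
        prev_support = support

    window_channels = _wavelengths_of(parent, p)
    return SelectionResult(
        channels=window_channels[best_subset],
        stage="fine",
        algorithm="BOSS",
        seed=seed,
        trace=PopulationTrace(np.array(size_trace), np.array(rmse_trace), weights=w),
        parent=parent,
        best_rmsecv=best_rmse,
        extras={"weights": w},
    )


def vcpa_pool_schedule(p: int, n_iters: int, final_pool: int) -> np.ndarray:
    """Monotone non-increasing geometric pool-size schedule p -> final_pool."""
    if n_iters < 1:
        return np.array([], dtype=int)
    target = min(final_pool, p)
    i = np.arange(1, n_iters + 1)
    sizes = np.round(p * (target / p) ** (i / n_iters)).astype(int)
    sizes = np.minimum.accumulate(np.clip(sizes, 2, p))
    sizes[-1] = max(target, 2)
    return np.maximum(sizes, 2)


def vcpa_select(
    X1: np.ndarray,
    y: np.ndarray,
    n_bms: int = 1000,
    n_edf_iters: int = 50,
    keep_fraction: float = 0.10,
    final_pool: int = 100,
    inclusion_ratio: float = 0.1,
    max_subset_eval: int = 30,
    max_components: int = MAX_COMPONENTS,
    cv_folds: int = 10,
    cv_seed: int = 0,
    seed: int = 0,
    parent: SelectionResult | None = None,
) -> SelectionResult:
    """Variable combination population analysis.

    An exponentially decreasing pool schedule shrinks the candidate pool
    from p1 to ``final_pool`` over ``n_edf_iters`` iterations.  Each
    iteration draws ``n_bms`` random binary variable combinations at a fixed
    inclusion ratio, scores them by RMSE_CV, and keeps the channels most
    frequent in the best ``keep_fraction`` of combinations.  The surviving
    pool is then searched over nested prefixes of the frequency ranking
    (sizes 2..``max_subset_eval``) with a greedy drop refinement; the
    minimum-RMSE_CV subset wins.  ``n_edf_iters=0`` returns the initial
    pool unchanged.
    """
    X1 = np.asarray(X1, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X1.shape
    if p < 2:
        raise ValueError("VCPA needs at least 2 channels")
    rng = np.random.default_rng(seed)
    pool = np.arange(p)
    window_channels = _wavelengths_of(parent, p)
    rmse_trace, size_trace = [], []

    if n_edf_iters == 0:
        r, _ = subset_rmsecv(
            X1, y, pool, max_components=max_components, folds=cv_folds, seed=cv_seed
        )
        return SelectionResult(
            channels=window_channels[pool],
            stage="fine",
            algorithm="VCPA",
            seed=seed,
            trace=PopulationTrace(np.array([p]), np.array([r])),
            parent=parent,
            best_rmsecv=r,
            extras={},
        )

    schedule = vcpa_pool_schedule(p, n_edf_iters, final_pool)
    freq = np.ones(pool.size)
    for target in schedule:
        m = pool.size
        n_inc = max(2, int(round(inclusion_ratio * m)))
        n_inc = min(n_inc, m)
        combos = np.zeros((n_bms, m), dtype=bool)
        for j in range(n_bms):
            combos[j, rng.choice(m, size=n_inc, replace=False)] = True
        rmse = np.empty(n_bms)
        for j in range(n_bms):
            idx = pool[combos[j]]
            rmse[j], _ = subset_rmsecv(
                X1, y, idx, max_components=max_components, folds=cv_folds, seed=cv_seed
            )
        order = np.argsort(rmse, kind="stable")
        n_keep = max(1, int(round(keep_fraction * n_bms)))
        freq = combos[order[:n_keep]].mean(axis=0)
        rmse_trace.append(float(rmse[order[0]]))
        size_trace.append(int(pool.size))
        if target < pool.size:
            # stable ranking: frequency desc, index asc on ties
            rank = np.lexsort((np.arange(m), -freq))
            keep_local = np.sort(rank[:target])
            pool = pool[keep_local]
            freq = freq[keep_local]

    # final search: nested prefixes of the frequency ranking + greedy drops
    rank = np.lexsort((np.arange(pool.size), -freq))
    ranked = pool[rank]
    best_rmse, best_subset = np.inf, ranked[: min(2, ranked.size)]
    for size in range(2, min(ranked.size, max_subset_eval) + 1):
        idx = np.sort(ranked[:size])
        r, _ = subset_rmsecv(
            X1, y, idx, max_components=max_components, folds=cv_folds, seed=cv_seed
        )
        if r < best_rmse:
            best_rmse, best_subset = r, idx
    improved = True
    while improved and best_subset.size > 2:
        improved = False
        for drop in best_subset:
            idx = best_subset[best_subset != drop]
            r, _ = subset_rmsecv(
                X1, y, idx, max_components=max_components, folds=cv_folds, seed=cv_seed
            )
            if r < best_rmse:
                best_rmse, best_subset, improved = r, idx, True
                break

    return SelectionResult(
        channels=window_channels[best_subset],
        stage="fine",
        algorithm="VCPA",
        seed=seed,
        trace=PopulationTrace(np.array(size_trace), np.array(rmse_trace)),
        parent=parent,
        best_rmsecv=float(best_rmse),
        extras={"pool": window_channels[pool], "frequency": freq},
    )
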