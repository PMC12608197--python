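"""Stage-1 coarse wavelength selection: interval-level screening of X -> X1.

Two interval selectors operate on the full modeling window:

* ``irf_select`` -- interval random frog: a reversible-jump search over sets
  of contiguous fixed-width windows.  Each iteration proposes adding,
  removing or shifting one interval and accepts by RMSE_CV improvement with
  an annealed tolerance; per-channel selection frequency over the visited
  states (after a burn-in) yields the coarse subset.

* ``ivissa_select`` -- interval variable iterative space shrinkage: sparse
  weighted binary sub-model sampling under a fixed expected channel budget.
  Each round, channels enriched in the best fraction of sub-models gain
  weight multiplicatively while the budget forces uninformative channels to
  shed weight; weights are smoothed across immediate neighbors so that
  selections grow as contiguous intervals.  Iteration stops when weights
  converge (max |dw| < 0.01) or at a round cap; channels with final weight
  above 0.5 are selected.
"""

from __future__ import annotations

import numpy as np

from .plsr import MAX_COMPONENTS, subset_rmsecv
from .selection import PopulationTrace, SelectionResult

__all__ = ["irf_select", "ivissa_select"]


def _interval_channels(starts: np.ndarray, width: int, p: int) -> np.ndarray:
    return np.unique(
        np.concatenate([np.arange(s, min(s + width, p)) for s in starts])
    )


def irf_select(
    X: np.ndarray,
    y: np.ndarray,
    n_iterations: int = 1000,
    window_width: int = 10,
    n_subintervals: int = 20,
    max_components: int = MAX_COMPONENTS,
    freq_threshold: float = 0.5,
    accept_tol: float = 0.005,
    size_penalty: float = 0.6,
    burn_in: float = 0.3,
    cv_folds: int = 10,
    cv_seed: int = 0,
    seed: int = 0,
) -> SelectionResult:
    """Interval random frog coarse selection.

    The search state is a set of contiguous ``window_width``-channel
    intervals, initialized as ``n_subintervals`` equidistant windows.  Each
    iteration proposes adding, removing or shifting one interval; proposals
    are scored by RMSE_CV times a mild parsimony factor
    ``1 + size_penalty * n_channels / p`` (so intervals that contribute
    nothing are shed rather than drifting), and accepted when the score is
    within an annealed tolerance of the current state's (the tolerance
    decays linearly to zero, so late iterations accept only improvements).
    Channels present in at least ``freq_threshold`` of the post-burn-in
    states form the coarse subset (threshold 0 returns every channel).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p < window_width:
        raise ValueError("fewer channels than the interval width")
    rng = np.random.default_rng(seed)

    starts = np.unique(
        np.round(np.linspace(0, p - window_width, n_subintervals)).astype(int)
    )
    state = set(starts.tolist())
    cur_channels = _interval_channels(np.array(sorted(state)), window_width, p)

    def scored(channels: np.ndarray) -> tuple[float, float]:
        rmse, _ = subset_rmsecv(
            X, y, channels, max_components=max_components, folds=cv_folds, seed=cv_seed
        )
        return rmse, rmse * (1.0 + size_penalty * channels.size / p)

    cur_rmse, cur_score = scored(cur_channels)
    counts = np.zeros(p)
    n_counted = 0
    first_counted = int(np.floor(burn_in * n_iterations))
    if n_iterations == 0 or first_counted == 0:
        counts[cur_channels] += 1.0
        n_counted += 1
    trace_sizes, trace_rmse = [cur_channels.size], [cur_rmse]

    all_starts = np.arange(0, p - window_width + 1)
    for it in range(n_iterations):
        proposal = set(state)
        move = rng.integers(3)
        if move == 0 and len(proposal) < len(all_starts):  # add
            candidates = np.setdiff1d(all_starts, np.array(sorted(proposal)))
            proposal.add(int(rng.choice(candidates)))
        elif move == 1 and len(proposal) > 1:  # remove
            proposal.discard(int(rng.choice(np.array(sorted(proposal)))))
        else:  # shift one interval
            old = int(rng.choice(np.array(sorted(proposal))))
            step = int(rng.integers(1, window_width + 1))
            shift = step if rng.random() < 0.5 else -step
            new = int(np.clip(old + shift, 0, p - window_width))
            proposal.discard(old)
            proposal.add(new)
        cand_channels = _interval_channels(np.array(sorted(proposal)), window_width, p)
        cand_rmse, cand_score = scored(cand_channels)
        tol = accept_tol * (1.0 - (it + 1) / n_iterations)  # annealed tolerance
        if cand_score <= cur_score * (1.0 + tol):
            state, cur_channels = proposal, cand_channels
            cur_rmse, cur_score = cand_rmse, cand_score
        if it >= first_counted:
            counts[cur_channels] += 1.0
            n_counted += 1
        trace_sizes.append(cur_channels.size)
        trace_rmse.append(cur_rmse)

    freq = counts / max(n_counted, 1)
    selected = np.flatnonzero(freq >= freq_threshold)
    if selected.size < 2:
        selected = np.sort(np.argsort(freq, kind="stable")[-2:])
    best_rmse, _ = subset_rmsecv(
        X, y, selected, max_components=max_components, folds=cv_folds, seed=cv_seed
    )
    return SelectionResult(
        channels=selected,
        stage="coarse",
        algorithm="iRF",
        seed=seed,
        trace=PopulationTrace(np.array(trace_sizes), np.array(trace_rmse), weights=freq),
        best_rmsecv=best_rmse,
        extras={"frequency": freq},
    )


def _smooth_neighbors(values: np.ndarray) -> np.ndarray:
    """[0.25, 0.5, 0.25] smoothing with edge padding (interval coherence)."""
    kernel = np.array([0.25, 0.5, 0.25])
    return np.convolve(np.pad(values, 1, mode="edge"), kernel, mode="valid")


def ivissa_select(
    X: np.ndarray,
    y: np.ndarray,
    n_submodels: int = 1000,
    w0: float = 0.5,
    interval_width: int = 10,
    max_components: int = MAX_COMPONENTS,
    best_fraction: float = 0.10,
    submodel_fraction: float = 0.10,
    shrinkage_power: float = 1.5,
    tol: float = 0.01,
    max_rounds: int = 15,
    smooth: bool = True,
    shrink: bool = True,
    cv_folds: int = 10,
    cv_seed: int = 0,
    seed: int = 0,
) -> SelectionResult:
    """Interval-wise iterative space shrinkage with weighted sub-model sampling.

    The channel axis is partitioned into contiguous ``interval_width``
    intervals, each starting at weight ``w0``.  Per round, ``n_submodels``
    sub-models are unions of intervals sampled with probabilities rescaled
    to an expected ``submodel_fraction`` of all intervals (sparse
    sub-models are what make enrichment informative).  Each interval's
    enrichment -- its frequency among the best ``best_fraction`` of
    sub-models relative to its overall sampling frequency -- multiplies its
    weight (raised to ``shrinkage_power``); the fixed total-weight budget
    then shrinks unenriched intervals.  Adjacent-interval smoothing grows
    contiguous selections.  Iteration stops when weights converge
    (max |dw| < ``tol``).  Channels of intervals with final weight above
    0.5 are selected.  ``shrink=False`` freezes the weights (w0 = 1 then
    keeps the full channel set).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    rng = np.random.default_rng(seed)
    starts = np.arange(0, p, interval_width)
    n_int = starts.size
    members = [np.arange(s, min(s + interval_width, p)) for s in starts]
    w = np.full(n_int, float(w0))
    budget = max(2.0, submodel_fraction * n_int)
    trace_sizes, trace_rmse = [], []

    for _ in range(max_rounds if shrink else 1):
        q = np.clip(w * (budget / max(w.sum(), 1e-12)), 0.0, 1.0)
        masks = rng.random((n_submodels, n_int)) < q
        for row in np.flatnonzero(masks.sum(axis=1) < 1):
            masks[row, rng.integers(n_int)] = True
        rmse = np.empty(n_submodels)
        for j in range(n_submodels):
            idx = np.concatenate([members[i] for i in np.flatnonzero(masks[j])])
            rmse[j], _ = subset_rmsecv(
                X, y, idx, max_components=max_components, folds=cv_folds, seed=cv_seed
            )
        order = np.argsort(rmse, kind="stable")
        n_best = max(1, int(round(best_fraction * n_submodels)))
        best_rows = order[:n_best]
        freq_best = masks[best_rows].mean(axis=0)
        freq_all = masks.mean(axis=0)
        trace_sizes.append(
            int(masks[best_rows].sum(axis=1).mean().round()) * interval_width
        )
        trace_rmse.append(float(rmse[best_rows].mean()))
        if not shrink:
            break
        eps = 1.0 / n_submodels
        lift = (freq_best + eps) / (freq_all + eps)
        # relative competition: intervals enriched above the (weight-averaged)
        # mean lift grow toward 1, the rest shrink toward 0; the sampling
        # budget only sets sub-model sparsity, not the selection size
        ref = float(np.average(lift, weights=np.maximum(w, 1e-9)))
        score = w * (lift / max(ref, 1e-9)) ** shrinkage_power
        if smooth:
            score = _smooth_neighbors(score)
        w_new = np.clip(score, 0.0, 1.0)
        delta = float(np.max(np.abs(w_new - w)))
        w = w_new
        if delta < tol:
            break

    chosen = np.flatnonzero(w > 0.5)
    if chosen.size == 0:
        chosen = np.argsort(w, kind="stable")[-1:]
    selected = np.unique(np.concatenate([members[i] for i in chosen]))
    if selected.size < 2:
        selected = np.sort(np.argsort(w, kind="stable")[-2:])
    channel_weights = np.empty(p)
    for i in range(n_int):
        channel_weights[members[i]] = w[i]
    best_rmse, _ = subset_rmsecv(
        X, y, selected, max_components=max_components, folds=cv_folds, seed=cv_seed
    )
    return SelectionResult(
        channels=selected,
        stage="coarse",
        algorithm="iVISSA",
        seed=seed,
        trace=PopulationTrace(
            np.array(trace_sizes), np.array(trace_rmse), weights=channel_weights
        ),
        best_rmsecv=best_rmse,
        extras={"weights": channel_weights, "interval_weights": w},
    )
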