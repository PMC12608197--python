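"""Stage-3 optimal refinement on X2: IRIV backward elimination and a GA.

IRIV draws random binary sub-model populations and, for every channel,
compares the RMSE_CV distributions of sub-models that include versus exclude
it: DMEAN = mean(RMSE_CV | included) - mean(RMSE_CV | excluded), so
informative channels have DMEAN < 0, and a Mann-Whitney U test grades the
difference.  Uninformative and interfering channels are dropped round by
round; a final backward pass removes weak channels whose removal lowers
RMSE_CV.

The GA evolves binary chromosomes capped at 30 set bits with tournament
selection, single-point crossover, bit-flip mutation and elitism, under a
fixed budget of subset evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .plsr import MAX_COMPONENTS, subset_rmsecv
from .selection import PopulationTrace, SelectionResult

__all__ = ["IrivAssessment", "iriv_select", "ga_select"]

#: class labels, determined by sign(DMEAN) and the Mann-Whitney p-value
_CLASSES = {
    (True, True): "strong",         # DMEAN < 0, p < alpha
    (True, False): "weak",          # DMEAN < 0, p >= alpha
    (False, False): "uninformative",  # DMEAN >= 0, p >= alpha
    (False, True): "interfering",   # DMEAN >= 0, p < alpha
}


@dataclass
class IrivAssessment:
    """Per-round channel assessment: DMEAN, Mann-Whitney p, class label."""

    table: pd.DataFrame  # columns: channel, dmean, p_value, label

    def informative_channels(self) -> np.ndarray:
        keep = self.table["label"].isin(["strong", "weak"])
        return self.table.loc[keep, "channel"].to_numpy()


def _assess_round(
    X: np.ndarray,
    y: np.ndarray,
    channels: np.ndarray,
    n_models: int,
    inclusion_p: float,
    max_components: int,
    cv_folds: int,
    alpha: float,
    rng: np.random.Generator,
    cv_seed: int,
) -> IrivAssessment:
    m = channels.size
    masks = rng.random((n_models, m)) < inclusion_p
    for row in np.flatnonzero(masks.sum(axis=1) < 2):
        masks[row, rng.choice(m, size=2, replace=False)] = True
    rmse = np.empty(n_models)
    for j in range(n_models):
        idx = channels[masks[j]]
        rmse[j], _ = subset_rmsecv(
            X, y, idx, max_components=max_components, folds=cv_folds, seed=cv_seed
        )
    rows = []
    for i, ch in enumerate(channels):
        incl, excl = rmse[masks[:, i]], rmse[~masks[:, i]]
        if incl.size == 0 or excl.size == 0:
            dmean, p_val = 0.0, 1.0
        else:
            dmean = float(incl.mean() - excl.mean())
            if np.ptp(rmse) == 0:
                p_val = 1.0
            else:
                p_val = float(mannwhitneyu(incl, excl, alternative="two-sided").pvalue)
        label = _CLASSES[(dmean < 0, p_val < alpha)]
        rows.append({"channel": int(ch), "dmean": dmean, "p_value": p_val, "label": label})
    return IrivAssessment(pd.DataFrame(rows))


def iriv_select(
    X2: np.ndarray,
    y: np.ndarray,
    n_models: int = 500,
    inclusion_p: float = 0.5,
    max_components: int = MAX_COMPONENTS,
    max_rounds: int = 10,
    alpha: float = 0.05,
    cv_folds: int = 10,
    cv_seed: int = 0,
    seed: int = 0,
    parent: SelectionResult | None = None,
) -> tuple[SelectionResult, list[IrivAssessment]]:
    """Iteratively retaining informative variables.

    Drops uninformative and interfering channels round by round until only
    strong/weak informative channels remain, then backward-eliminates weak
    channels one at a time whenever removal lowers RMSE_CV.  Returns the
    selection plus the per-round assessments.
    """
    X2 = np.asarray(X2, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X2.shape
    if p < 2:
        raise ValueError("IRIV needs at least 2 channels")
    rng = np.random.default_rng(seed)
    local = np.arange(p)
    rounds: list[IrivAssessment] = []
    for _ in range(max_rounds):
        if local.size <= 2:
            break  # a pair is the smallest assessable model: keep it
        assessment = _assess_round(
            X2, y, local, n_models, inclusion_p, max_components, cv_folds, alpha, rng, cv_seed
        )
        rounds.append(assessment)
        kept = assessment.informative_channels()
        if kept.size == local.size:
            break
        if kept.size < 2:
            # keep the two most informative (lowest DMEAN) to stay modelable
            order = assessment.table.sort_values(
                ["dmean", "channel"], kind="stable"
            )["channel"].to_numpy()
            kept = np.sort(order[:2])
        local = np.sort(kept)

    # backward elimination of weak channels, least informative first
    last = rounds[-1].table.set_index("channel") if rounds else None
    best_rmse, _ = subset_rmsecv(
        X2, y, local, max_components=max_components, folds=cv_folds, seed=cv_seed
    )
    if last is not None:
        weak = [int(c) for c in local if last.loc[int(c), "label"] == "weak"]
        weak.sort(key=lambda c: -last.loc[c, "dmean"])  # least informative first
        for ch in weak:
            if local.size <= 2:
                break
            trial = local[local != ch]
            r, _ = subset_rmsecv(
                X2, y, trial, max_components=max_components, folds=cv_folds, seed=cv_seed
            )
            if r < best_rmse:
                best_rmse, local = r, trial

    window_channels = parent.channels if parent is not None else np.arange(p)
    result = SelectionResult(
        channels=window_channels[local],
        stage="optimal",
        algorithm="IRIV",
        seed=seed,
        parent=parent,
        best_rmsecv=float(best_rmse),
        extras={"n_rounds": len(rounds)},
    )
    return result, rounds


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------


def _repair(bits: np.ndarray, max_vars: int, rng: np.random.Generator) -> np.ndarray:
    """Enforce 1 <= set bits <= max_vars by random clearing / setting."""
    on = np.flatnonzero(bits)
    if on.size > max_vars:
        off = rng.choice(on, size=on.size - max_vars, replace=False)
        bits = bits.copy()
        bits[off] = False
    elif on.size == 0:
        bits = bits.copy()
        bits[rng.integers(bits.size)] = True
    return bits


def ga_select(
    X2: np.ndarray,
    y: np.ndarray,
    n_chromosomes: int = 30,
    max_vars_per_chromosome: int = 30,
    p_crossover: float = 0.5,
    p_mutation: float = 0.01,
    n_evaluations: int = 200,
    max_components: int = MAX_COMPONENTS,
    cv_folds: int = 10,
    cv_seed: int = 0,
    seed: int = 0,
    parent: SelectionResult | None = None,
) -> SelectionResult:
    """Genetic-algorithm subset search under an evaluation budget.

    Fitness is -RMSE_CV; chromosomes are binary channel masks repaired to at
    most ``max_vars_per_chromosome`` set bits.  Tournament selection (size
    2), single-point crossover, per-bit mutation, and elitism (the best
    chromosome always survives).  Evolution stops once ``n_evaluations``
    subsets have been scored; the best-ever chromosome is returned.
    """
    X2 = np.asarray(X2, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X2.shape
    if p < 2:
        raise ValueError("GA needs at least 2 channels")
    rng = np.random.default_rng(seed)
    evals = 0

    def fitness(bits: np.ndarray) -> float:
        nonlocal evals
        idx = np.flatnonzero(bits)
        r, _ = subset_rmsecv(
            X2, y, idx, max_components=max_components, folds=cv_folds, seed=cv_seed
        )
        evals += 1
        return -r

    init_p = min(0.5, max_vars_per_chromosome / p)
    pop = [
        _repair(rng.random(p) < init_p, max_vars_per_chromosome, rng)
        for _ in range(n_chromosomes)
    ]
    fits = []
    for bits in pop:
        if evals >= n_evaluations:
            fits.append(-np.inf)
        else:
            fits.append(fitness(bits))
    best_i = int(np.argmax(fits))
    best_bits, best_fit = pop[best_i].copy(), fits[best_i]
    history = [best_fit]

    while evals < n_evaluations:
        children = []
        while len(children) < n_chromosomes - 1:
            cand = rng.integers(n_chromosomes, size=4)
            p1 = pop[cand[0]] if fits[cand[0]] >= fits[cand[1]] else pop[cand[1]]
            p2 = pop[cand[2]] if fits[cand[2]] >= fits[cand[3]] else pop[cand[3]]
            c1, c2 = p1.copy(), p2.copy()
            if rng.random() < p_crossover and p > 1:
                cut = int(rng.integers(1, p))
                c1 = np.concatenate([p1[:cut], p2[cut:]])
                c2 = np.concatenate([p2[:cut], p1[cut:]])
            for c in (c1, c2):
                flip = rng.random(p) < p_mutation
                c ^= flip
                children.append(_repair(c, max_vars_per_chromosome, rng))
        children = children[: n_chromosomes - 1]
        child_fits = []
        for bits in children:
            if evals >= n_evaluations:
                child_fits.append(-np.inf)
            else:
                child_fits.append(fitness(bits))
        # elitism: best-ever chromosome always survives
        pop = [best_bits.copy()] + children
        fits = [best_fit] + child_fits
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_bits, best_fit = pop[gen_best].copy(), fits[gen_best]
        history.append(best_fit)
        if all(f == -np.inf for f in child_fits):
            break

    window_channels = parent.channels if parent is not None else np.arange(p)
    selected = np.flatnonzero(best_bits)
    return SelectionResult(
        channels=window_channels[selected],
        stage="optimal",
        algorithm="GA",
        seed=seed,
        trace=PopulationTrace(
            np.full(len(history), selected.size), -np.array(history)
        ),
        parent=parent,
        best_rmsecv=float(-best_fit),
        extras={"n_evaluations": evals, "best_fitness_history": np.array(history)},
    )
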