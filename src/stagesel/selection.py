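"""Stage-3 procedures: FOX wrapper feature selection and FOX-optimized
weighted-average (soft-voting) ensembling of two base models.

Both searches minimize ``1 - cross-validated accuracy``; the CV cost is
seeded identically to the rest of the framework so the cost surface is
deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fox import OptimizerRun, SearchSpace, fox_minimize
from .pipeline import FeatureTable, MetricTriplet, cross_val_proba, metrics_from_predictions

__all__ = [
    "FeatureMask",
    "EnsembleWeights",
    "position_to_mask",
    "fox_feature_select",
    "fox_ensemble",
    "combine_probabilities",
]

#: positions >= this value keep the feature (>= so exactly 0.5 keeps)
MASK_THRESHOLD = 0.5


@dataclass(frozen=True)
class FeatureMask:
    """Binary keep-mask over the current feature columns."""

    kept: np.ndarray
    threshold: float = MASK_THRESHOLD

    def __post_init__(self) -> None:
        kept = np.asarray(self.kept, dtype=bool)
        object.__setattr__(self, "kept", kept)
        if not kept.any():
            raise ValueError("a feature mask must keep at least one feature")

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())


@dataclass(frozen=True)
class EnsembleWeights:
    """Two nonnegative soft-voting weights summing to one."""

    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if w.shape != (2,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("ensemble weights must be 2 nonnegative reals summing to 1")


def position_to_mask(position: np.ndarray, threshold: float = MASK_THRESHOLD) -> np.ndarray:
    """Binarize a continuous agent position at the threshold."""
    return np.asarray(position, dtype=float) >= threshold


def _normalize_pair(position: np.ndarray) -> np.ndarray:
    total = float(position.sum())
    if total <= 0:
        return np.array([0.5, 0.5])
    return position / total


def combine_probabilities(
    proba_a: np.ndarray, proba_b: np.ndarray, weights: EnsembleWeights
) -> np.ndarray:
    """Weighted average of two positive-class probability vectors."""
    return weights.w[0] * np.asarray(proba_a) + weights.w[1] * np.asarray(proba_b)


def fox_feature_select(
    table: FeatureTable,
    classifier: str = "rf",
    k: int = 5,
    seed: int = 0,
    n_agents: int = 10,
    n_iters: int = 20,
    classifier_params: dict | None = None,
) -> tuple[FeatureMask, MetricTriplet, OptimizerRun]:
    """Wrapper feature selection with accuracy as the (minimized) cost.

    Each agent position lives in [0, 1]^n_features and is binarized at
    0.5; the cost of a mask is ``1 - pooled CV accuracy`` of the
    classifier on the masked table, and an empty mask is penalized with
    cost 1. The all-features baseline is injected into the initial
    population, so the selected mask can never do worse than using every
    feature on the search objective. Costs are memoized per mask since
    converged populations revisit the same subsets.
    """
    n = table.n_features
    cache: dict[bytes, float] = {}

    def cost(position: np.ndarray) -> float:
        mask = position_to_mask(position)
        if not mask.any():
            return 1.0
        key = np.packbits(mask).tobytes()
        if key not in cache:
            proba, _ = cross_val_proba(
                table.select(mask),
                classifier=classifier,
                k=k,
                seed=seed,
                classifier_params=classifier_params,
            )
            cache[key] = 1.0 - metrics_from_predictions(table.y, proba).accuracy
        return cache[key]

    run = fox_minimize(
        cost,
        SearchSpace.cube(n, 0.0, 1.0),
        n_agents=n_agents,
        n_iters=n_iters,
        seed=seed,
        x0=[np.ones(n)],
    )
    mask = FeatureMask(position_to_mask(run.best_position))
    proba, _ = cross_val_proba(
        table.select(mask.kept),
        classifier=classifier,
        k=k,
        seed=seed,
        classifier_params=classifier_params,
    )
    return mask, metrics_from_predictions(table.y, proba), run


def fox_ensemble(
    proba_a: np.ndarray,
    proba_b: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    n_agents: int = 10,
    n_iters: int = 30,
) -> tuple[EnsembleWeights, MetricTriplet, OptimizerRun]:
    """Optimize the two soft-voting weights over [0, 1]^2 (normalized to
    sum 1); cost is ``1 - accuracy`` at decision threshold 0.5."""
    proba_a = np.asarray(proba_a, dtype=float)
    proba_b = np.asarray(proba_b, dtype=float)
    y = np.asarray(y, dtype=int)
    if proba_a.shape != proba_b.shape or proba_a.shape != y.shape:
        raise ValueError("probability vectors and labels must have equal length")

    def cost(position: np.ndarray) -> float:
        w = _normalize_pair(position)
        combined = w[0] * proba_a + w[1] * proba_b
        return 1.0 - float(((combined >= 0.5).astype(int) == y).mean())

    run = fox_minimize(
        cost,
        SearchSpace.cube(2, 0.0, 1.0),
        n_agents=n_agents,
        n_iters=n_iters,
        seed=seed,
        x0=[np.array([1.0, 0.0]), np.array([0.0, 1.0]), np.array([0.5, 0.5])],
    )
    weights = EnsembleWeights(_normalize_pair(run.best_position))
    combined = combine_probabilities(proba_a, proba_b, weights)
    return weights, metrics_from_predictions(y, combined), run
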