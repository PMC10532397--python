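"""MEREC criterion weighting and TOPSIS closeness ranking.

Multi-criteria decision making (MCDM) core used to benchmark candidate
diagnostic models on conflicting performance criteria (here: accuracy,
F2-score and AUC-ROC, all benefit-type).

MEREC (MEthod based on the Removal Effects of Criteria) derives objective
criterion weights from how much deleting each criterion perturbs a
log-based aggregate performance of every alternative: criteria whose
removal changes the aggregate most receive the largest weights.

TOPSIS scores each alternative by its relative closeness
``C = d- / (d+ + d-)`` to the ideal point (best value per criterion) versus
the anti-ideal point in normalized, weighted criterion space. Two
normalization/weighting variants are provided:

* ``"minmax-separation"`` (default) — min-max normalization with the
  weights applied inside the squared Euclidean separations
  (equivalently ``v = sqrt(w) * r``). This variant reproduces the
  published dimensionality-reduction ranking scores (e.g. the LLE row of
  the ultrasound table) to within 5e-3 and is therefore the default.
* ``"vector"`` — the textbook variant: root-sum-square column
  normalization with ``v = w * r``.

Both satisfy the dominance contract (best on every criterion -> 1,
worst on every criterion -> 0) and are invariant to positive rescaling
of any criterion column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "MCDMError",
    "DecisionMatrix",
    "CriterionWeights",
    "RankingResult",
    "merec_weights",
    "topsis_scores",
    "rank_alternatives",
    "merec_topsis",
]

BENEFIT = "benefit"
COST = "cost"

#: sum(w) must equal 1 within this tolerance
WEIGHT_TOL = 1e-9


class MCDMError(ValueError):
    """Invalid or degenerate decision-matrix input."""


@dataclass(frozen=True)
class DecisionMatrix:
    """m alternatives scored on n criteria, all values strictly positive.

    ``directions[j]`` is ``"benefit"`` (larger is better) or ``"cost"``
    (smaller is better). Positivity is required by MEREC's logarithmic
    normalization.
    """

    values: np.ndarray
    directions: tuple[str, ...]
    alternative_ids: tuple[str, ...]
    criterion_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise MCDMError("decision matrix must be 2-D")
        m, n = v.shape
        if len(self.directions) != n or len(self.criterion_ids) != n:
            raise MCDMError("directions/criterion ids must match column count")
        if len(self.alternative_ids) != m:
            raise MCDMError("alternative ids must match row count")
        if len(set(self.alternative_ids)) != m or len(set(self.criterion_ids)) != n:
            raise MCDMError("ids must be unique")
        for d in self.directions:
            if d not in (BENEFIT, COST):
                raise MCDMError(f"unknown criterion direction {d!r}")
        if not np.all(np.isfinite(v)):
            raise MCDMError("decision matrix contains non-finite values")
        if np.any(v <= 0):
            raise MCDMError("all decision-matrix values must be strictly positive")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        directions: Sequence[str] | None = None,
    ) -> "DecisionMatrix":
        """Build from a DataFrame whose index labels the alternatives."""
        dirs = tuple(directions) if directions is not None else (BENEFIT,) * frame.shape[1]
        return cls(
            values=frame.to_numpy(dtype=float),
            directions=dirs,
            alternative_ids=tuple(str(i) for i in frame.index),
            criterion_ids=tuple(str(c) for c in frame.columns),
        )

    @classmethod
    def from_csv(
        cls, path: str | Path, directions: Sequence[str] | None = None
    ) -> "DecisionMatrix":
        """Read a CSV with a criterion header row and alternative ids in column 0."""
        return cls.from_frame(pd.read_csv(path, index_col=0), directions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.alternative_ids), columns=list(self.criterion_ids)
        )


@dataclass(frozen=True)
class CriterionWeights:
    """Nonnegative criterion weights summing to one."""

    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if w.ndim != 1:
            raise MCDMError("weights must be 1-D")
        if np.any(w < -WEIGHT_TOL):
            raise MCDMError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-6:
            raise MCDMError("weights must sum to 1")


@dataclass(frozen=True)
class RankingResult:
    """Criterion weights, per-alternative closeness scores and ranks.

    ``ranks`` are 1-based, 1 = best; ties share the smaller rank and are
    flagged in ``tied``. ``metadata`` records the TOPSIS variant used.
    """

    weights: CriterionWeights
    scores: np.ndarray
    ranks: np.ndarray
    tied: np.ndarray
    alternative_ids: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"score": self.scores, "rank": self.ranks, "tied": self.tied},
            index=list(self.alternative_ids),
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="alternative")


# ---------------------------------------------------------------------------
# MEREC weighting
# ---------------------------------------------------------------------------


def _merec_normalize(matrix: DecisionMatrix) -> np.ndarray:
    """MEREC's ratio normalization: smaller normalized value = better.

    benefit: n_ij = min_k x_kj / x_ij ; cost: n_ij = x_ij / max_k x_kj.
    """
    x = matrix.values
    out = np.empty_like(x)
    for j, d in enumerate(matrix.directions):
        col = x[:, j]
        out[:, j] = col.min() / col if d == BENEFIT else col / col.max()
    return out


def merec_weights(matrix: DecisionMatrix) -> CriterionWeights:
    """Objective criterion weights from column-removal effects.

    Steps: ratio-normalize; aggregate each alternative's performance
    S_i = ln(1 + mean_j |ln n_ij|); recompute S'_ij with criterion j
    removed (sum still divided by n); removal effect
    E_j = sum_i |S'_ij - S_i|; weights w_j = E_j / sum(E).

    A constant column has zero removal effect and receives weight 0; if
    every column is constant the matrix carries no information and a
    degenerate-matrix error is raised.
    """
    if matrix.m < 2 or matrix.n < 2:
        raise MCDMError("MEREC weighting needs at least 2 alternatives and 2 criteria")
    n = matrix.n
    logs = np.abs(np.log(_merec_normalize(matrix)))  # (m, n)
    s = np.log1p(logs.sum(axis=1) / n)
    effects = np.empty(n)
    for j in range(n):
        s_without = np.log1p((logs.sum(axis=1) - logs[:, j]) / n)
        effects[j] = np.abs(s_without - s).sum()
    total = effects.sum()
    if total <= 0:
        raise MCDMError("degenerate decision matrix: every criterion column is constant")
    return CriterionWeights(effects / total)


# ---------------------------------------------------------------------------
# TOPSIS scoring
# ---------------------------------------------------------------------------


def _normalize_columns(matrix: DecisionMatrix, normalization: str) -> np.ndarray:
    x = matrix.values
    if normalization == "vector":
        return x / np.sqrt((x**2).sum(axis=0))
    if normalization == "minmax":
        lo, hi = x.min(axis=0), x.max(axis=0)
        span = hi - lo
        r = np.zeros_like(x)
        ok = span > 0
        r[:, ok] = (x[:, ok] - lo[ok]) / span[ok]  # constant columns stay 0
        return r
    raise MCDMError(f"unknown normalization {normalization!r}")


def topsis_scores(
    matrix: DecisionMatrix,
    weights: CriterionWeights,
    variant: str = "minmax-separation",
) -> RankingResult:
    """Closeness coefficients C_i = d_i- / (d_i+ + d_i-) in [0, 1].

    The ideal point takes the per-criterion best of the weighted
    normalized matrix (max for benefit, min for cost criteria), the
    anti-ideal the per-criterion worst; separations are Euclidean.
    """
    if matrix.m < 2:
        raise MCDMError("TOPSIS needs at least 2 alternatives")
    w = np.asarray(weights.w, dtype=float)
    if w.size != matrix.n:
        raise MCDMError("weight length must match criterion count")

    if variant == "minmax-separation":
        v = np.sqrt(w) * _normalize_columns(matrix, "minmax")
    elif variant == "vector":
        v = w * _normalize_columns(matrix, "vector")
    else:
        raise MCDMError(f"unknown TOPSIS variant {variant!r}")

    benefit = np.array([d == BENEFIT for d in matrix.directions])
    ideal = np.where(benefit, v.max(axis=0), v.min(axis=0))
    anti = np.where(benefit, v.min(axis=0), v.max(axis=0))
    d_pos = np.sqrt(((v - ideal) ** 2).sum(axis=1))
    d_neg = np.sqrt(((v - anti) ** 2).sum(axis=1))
    denom = d_pos + d_neg
    if np.any(denom == 0):
        raise MCDMError("degenerate matrix: identical alternatives, closeness undefined")
    scores = d_neg / denom
    ranks, tied = rank_alternatives(scores)
    return RankingResult(
        weights=weights,
        scores=scores,
        ranks=ranks,
        tied=tied,
        alternative_ids=matrix.alternative_ids,
        metadata={"variant": variant},
    )


def rank_alternatives(scores: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Ranks in descending score order; ties share the smaller rank.

    Returns ``(ranks, tied)`` where ``tied[i]`` flags scores shared with
    another alternative.
    """
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise MCDMError("scores must be finite")
    ranks = rankdata(-s, method="min").astype(int)
    _, counts = np.unique(s, return_counts=True)
    tied = np.isin(s, np.unique(s)[counts > 1])
    return ranks, tied


def merec_topsis(matrix: DecisionMatrix, variant: str = "minmax-separation") -> RankingResult:
    """MEREC weighting composed with TOPSIS ranking."""
    return topsis_scores(matrix, merec_weights(matrix), variant=variant)
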