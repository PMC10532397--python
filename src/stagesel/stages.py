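"""Three-stage model-selection protocol with MEREC-TOPSIS ranking.

Stage 1 crosses feature extractors with classifiers (one PCA spec fixed),
stage 2 crosses the winning extractor/classifier with the six
dimensionality-reduction methods and forwards the top two candidates,
stage 3 compares FOX feature selection on each forwarded table against a
FOX-weighted soft-voting ensemble of both. After every stage the
candidates' (accuracy, F2, AUC-ROC) triplets form an all-benefit decision
matrix ranked by MEREC-TOPSIS.

"Fixture mode" builds a stage report directly from a table of published
metric triplets instead of running any learning; it is the execution path
used to check the ranking chain against printed results.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .mcdm import DecisionMatrix, RankingResult, merec_topsis
from .pipeline import FeatureTable, MetricTriplet, cross_val_proba, evaluate_cv, metrics_from_predictions
from .selection import fox_ensemble, fox_feature_select

__all__ = [
    "StageReport",
    "rank_candidates",
    "run_stage1",
    "run_stage2",
    "run_stage3",
    "top_candidates",
    "fixture_names",
    "load_fixture",
    "fixture_report",
]

CRITERIA = ("accuracy", "f2_score", "auc_roc")

_FIXTURES = ("table1", "table2", "table4", "table5", "table7", "table8")


@dataclass(frozen=True)
class StageReport:
    """Candidates with their metric triplets plus the attached ranking."""

    candidates: tuple[tuple[str, MetricTriplet], ...]
    ranking: RankingResult
    stage: int

    def to_frame(self) -> pd.DataFrame:
        rows = {name: m.as_criteria() for name, m in self.candidates}
        frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(CRITERIA))
        frame["topsis_score"] = self.ranking.scores
        frame["rank"] = self.ranking.ranks
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="model")

    def best(self) -> str:
        return top_candidates(self, 1)[0]


def rank_candidates(
    candidates: list[tuple[str, MetricTriplet]], stage: int
) -> StageReport:
    """MEREC-TOPSIS ranking of metric triplets in criteria order
    (accuracy, F2, AUC-ROC), all benefit-type."""
    names = [name for name, _ in candidates]
    values = np.array([m.as_criteria() for _, m in candidates])
    matrix = DecisionMatrix(
        values=values,
        directions=("benefit",) * 3,
        alternative_ids=tuple(names),
        criterion_ids=CRITERIA,
    )
    return StageReport(
        candidates=tuple(candidates), ranking=merec_topsis(matrix), stage=stage
    )


def top_candidates(report: StageReport, k: int = 2) -> list[str]:
    """The k best candidate names; ties broken by candidate order."""
    order = np.lexsort((np.arange(len(report.candidates)), report.ranking.ranks))
    return [report.candidates[i][0] for i in order[:k]]


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------


def run_stage1(
    table_per_extractor: dict[str, FeatureTable],
    classifiers: tuple[str, ...] = ("lr", "nb", "svc", "knn", "rf"),
    reducer: tuple[str, int] | None = None,
    k: int = 5,
    seed: int = 0,
    classifier_params: dict | None = None,
) -> StageReport:
    """One candidate per (extractor table, classifier) pair."""
    if not table_per_extractor:
        raise ValueError("at least one extractor table is required")
    candidates = []
    for extractor, table in table_per_extractor.items():
        for clf in classifiers:
            try:
                metrics = evaluate_cv(
                    table, classifier=clf, reducer=reducer, k=k, seed=seed,
                    classifier_params=(classifier_params or {}).get(clf),
                )
            except Exception as exc:  # surface the failing pair
                raise RuntimeError(f"evaluation failed for ({extractor}, {clf})") from exc
            candidates.append((f"{extractor}+{clf}", metrics))
    return rank_candidates(candidates, stage=1)


def run_stage2(
    table: FeatureTable,
    classifier: str = "rf",
    reducers: tuple[tuple[str, int], ...] = (),
    k: int = 5,
    seed: int = 0,
    classifier_params: dict | None = None,
) -> StageReport:
    """One candidate per dimensionality-reduction spec on the winning
    extractor table/classifier; the caller forwards the top two."""
    if not reducers:
        raise ValueError("at least one reducer spec is required")
    candidates = []
    for method, n_comp in reducers:
        metrics = evaluate_cv(
            table, classifier=classifier, reducer=(method, n_comp), k=k, seed=seed,
            classifier_params=classifier_params,
        )
        candidates.append((method, metrics))
    return rank_candidates(candidates, stage=2)


def run_stage3(
    top2_tables: dict[str, FeatureTable],
    classifier: str = "rf",
    k: int = 5,
    seed: int = 0,
    n_agents: int = 10,
    n_iters: int = 20,
    classifier_params: dict | None = None,
) -> StageReport:
    """Exactly three candidates: feature selection on the best table, the
    weighted-average ensemble of both tables, feature selection on the
    runner-up table (the Model21/22/23 pattern)."""
    if len(top2_tables) != 2:
        raise ValueError("stage 3 expects exactly the two forwarded tables")
    (name_a, table_a), (name_b, table_b) = top2_tables.items()
    if not np.array_equal(table_a.y, table_b.y):
        raise ValueError("the two forwarded tables must describe the same samples")

    _, metrics_fs_a, _ = fox_feature_select(
        table_a, classifier=classifier, k=k, seed=seed,
        n_agents=n_agents, n_iters=n_iters, classifier_params=classifier_params,
    )
    proba_a, _ = cross_val_proba(
        table_a, classifier=classifier, k=k, seed=seed, classifier_params=classifier_params
    )
    proba_b, _ = cross_val_proba(
        table_b, classifier=classifier, k=k, seed=seed, classifier_params=classifier_params
    )
    _, metrics_ens, _ = fox_ensemble(
        proba_a, proba_b, table_a.y, seed=seed, n_agents=n_agents, n_iters=n_iters
    )
    _, metrics_fs_b, _ = fox_feature_select(
        table_b, classifier=classifier, k=k, seed=seed,
        n_agents=n_agents, n_iters=n_iters, classifier_params=classifier_params,
    )
    candidates = [
        (f"{name_a}+fox-fs+{classifier}", metrics_fs_a),
        (f"{name_a}+{name_b} ensemble+{classifier}", metrics_ens),
        (f"{name_b}+fox-fs+{classifier}", metrics_fs_b),
    ]
    return rank_candidates(candidates, stage=3)


# ---------------------------------------------------------------------------
# Fixture mode
# ---------------------------------------------------------------------------


def fixture_names() -> tuple[str, ...]:
    return _FIXTURES


def load_fixture(name: str) -> pd.DataFrame:
    """Packaged transcription of a published metric table.

    Columns: model, label, accuracy, f2_score, auc_roc and the published
    topsis_score/rank columns, stored exactly as printed.
    """
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; expected one of {_FIXTURES}")
    with resources.files("stagesel.fixtures").joinpath(f"{name}.csv").open() as fh:
        return pd.read_csv(fh, index_col="model")


def fixture_report(name: str) -> StageReport:
    """Stage report with metric triplets injected from a fixture table;
    the ranking is recomputed from the triplets, never copied."""
    frame = load_fixture(name)
    stage = {"table1": 1, "table2": 1, "table4": 2, "table5": 2, "table7": 3, "table8": 3}[name]
    candidates = [
        (str(model), MetricTriplet(row.accuracy, row.f2_score, row.auc_roc))
        for model, row in frame.iterrows()
    ]
    return rank_candidates(candidates, stage=stage)
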