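"""MEREC weighting and TOPSIS ranking against brute-force transcriptions,
dominance/invariance properties and the published decision tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stagesel import (
    MCDMError,
    merec_topsis,
    merec_weights,
    rank_alternatives,
    topsis_scores,
)
from stagesel.mcdm import CriterionWeights
from stagesel.stages import load_fixture, fixture_report

from conftest import make_matrix, random_decision_values


# ---------------------------------------------------------------------------
# Independent step-by-step oracles (literal formula transcriptions)
# ---------------------------------------------------------------------------


def merec_oracle(x, directions):
    m, n = x.shape
    nrm = np.empty_like(x)
    for j in range(n):
        for i in range(m):
            nrm[i, j] = (
                x[:, j].min() / x[i, j] if directions[j] == "benefit" else x[i, j] / x[:, j].max()
            )
    s = np.array([np.log(1 + sum(abs(np.log(nrm[i, j])) for j in range(n)) / n) for i in range(m)])
    e = np.zeros(n)
    for j in range(n):
        for i in range(m):
            s_ij = np.log(1 + sum(abs(np.log(nrm[i, k])) for k in range(n) if k != j) / n)
            e[j] += abs(s_ij - s[i])
    return e / e.sum()


def topsis_oracle(x, w, directions, variant):
    m, n = x.shape
    if variant == "vector":
        r = np.array([[x[i, j] / np.sqrt((x[:, j] ** 2).sum()) for j in range(n)] for i in range(m)])
        v = w * r
    else:  # minmax normalization, weights inside the separations
        r = np.array(
            [
                [
                    (x[i, j] - x[:, j].min()) / (x[:, j].max() - x[:, j].min())
                    if x[:, j].max() > x[:, j].min()
                    else 0.0
                    for j in range(n)
                ]
                for i in range(m)
            ]
        )
        v = np.sqrt(w) * r
    ideal = np.array([v[:, j].max() if directions[j] == "benefit" else v[:, j].min() for j in range(n)])
    anti = np.array([v[:, j].min() if directions[j] == "benefit" else v[:, j].max() for j in range(n)])
    dp = np.sqrt(((v - ideal) ** 2).sum(axis=1))
    dm = np.sqrt(((v - anti) ** 2).sum(axis=1))
    return dm / (dp + dm)


@pytest.mark.parametrize("variant", ["minmax-separation", "vector"])
def test_oracle_equivalence_on_random_matrices(variant):
    """Weights and scores agree to 1e-9 with literal formula transcriptions
    over 200 random positive matrices, both criterion directions mixed in."""
    rng = np.random.default_rng(42)
    for trial in range(200):
        x = random_decision_values(rng)
        dirs = tuple(rng.choice(["benefit", "cost"], size=x.shape[1]))
        matrix = make_matrix(x, dirs)
        try:
            w = merec_weights(matrix)
        except MCDMError:
            continue  # degenerate draw
        np.testing.assert_allclose(w.w, merec_oracle(x, dirs), atol=1e-9)
        result = topsis_scores(matrix, w, variant=variant)
        np.testing.assert_allclose(
            result.scores, topsis_oracle(x, w.w, dirs, variant), atol=1e-9
        )


def test_merec_weights_match_published_stage1_tables():
    for name, expected in [
        ("table1", (0.31123, 0.4062, 0.2826)),
        ("table2", (0.3694, 0.2601, 0.3704)),
    ]:
        matrix = make_matrix(load_fixture(name)[["accuracy", "f2_score", "auc_roc"]].to_numpy())
        np.testing.assert_allclose(merec_weights(matrix).w, expected, atol=1e-3)


def test_merec_weights_match_published_stage2_tables():
    for name, expected in [
        ("table4", (0.2963, 0.5711, 0.1326)),
        ("table5", (0.2868, 0.2786, 0.4346)),
    ]:
        matrix = make_matrix(load_fixture(name)[["accuracy", "f2_score", "auc_roc"]].to_numpy())
        np.testing.assert_allclose(merec_weights(matrix).w, expected, atol=1e-3)


def test_merec_duplicate_columns_share_weight_equally():
    w = merec_weights(make_matrix([[1, 1], [2, 2], [4, 4]]))
    np.testing.assert_allclose(w.w, [0.5, 0.5], atol=1e-12)


def test_merec_constant_column_gets_zero_weight():
    w = merec_weights(make_matrix([[1.0, 3.0, 2.0], [2.0, 3.0, 1.5], [4.0, 3.0, 0.7]]))
    assert w.w[1] == pytest.approx(0.0, abs=1e-12)
    assert w.w.sum() == pytest.approx(1.0, abs=1e-9)


def test_merec_errors_on_degenerate_input():
    with pytest.raises(MCDMError):
        merec_weights(make_matrix([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]]))  # all constant
    with pytest.raises(MCDMError):
        make_matrix([[1.0, -2.0], [3.0, 4.0]])  # nonpositive value
    with pytest.raises(MCDMError):
        merec_weights(make_matrix([[1.0, 2.0]]))  # single alternative


def test_topsis_dominant_and_dominated_rows_hit_bounds():
    rng = np.random.default_rng(3)
    for _ in range(20):
        x = random_decision_values(rng, m=6, n=3)
        x = np.vstack([x, x.max(axis=0) + 1.0, np.full(3, 1e-3)])
        res = merec_topsis(make_matrix(x))
        assert res.scores[-2] == pytest.approx(1.0, abs=1e-12)
        assert res.scores[-1] == pytest.approx(0.0, abs=1e-12)
        assert res.ranks[-2] == 1
        assert np.all((res.scores >= 0) & (res.scores <= 1))


@pytest.mark.parametrize("variant", ["minmax-separation", "vector"])
def test_topsis_scores_invariant_to_column_rescaling(variant):
    rng = np.random.default_rng(8)
    x = random_decision_values(rng, m=7, n=4)
    matrix = make_matrix(x)
    w = merec_weights(matrix)
    base = topsis_scores(matrix, w, variant=variant)
    scaled = x.copy()
    scaled[:, 2] *= 37.5
    res = topsis_scores(make_matrix(scaled), w, variant=variant)
    np.testing.assert_allclose(res.scores, base.scores, atol=1e-12)
    np.testing.assert_array_equal(res.ranks, base.ranks)


def test_topsis_identical_alternatives_is_degenerate():
    with pytest.raises(MCDMError):
        topsis_scores(
            make_matrix([[1.0, 2.0], [1.0, 2.0]]), CriterionWeights(np.array([0.5, 0.5]))
        )


def test_rank_alternatives_ordering_and_ties():
    ranks, tied = rank_alternatives([0.9, 0.1, 0.5])
    assert ranks.tolist() == [1, 3, 2] and not tied.any()
    ranks, tied = rank_alternatives([0.4, 0.4, 0.4])
    assert ranks.tolist() == [1, 1, 1] and tied.all()
    with pytest.raises(MCDMError):
        rank_alternatives([0.1, float("nan")])


def test_rank_of_published_score_columns_reproduces_published_ranks():
    """Each printed rank column is the descending-order ranking of its own
    printed score column, for all six tables."""
    for name in ("table1", "table2", "table4", "table5", "table7", "table8"):
        frame = load_fixture(name)
        ranks, _ = rank_alternatives(frame["topsis_score"].to_numpy())
        np.testing.assert_array_equal(ranks, frame["rank"].to_numpy())


def test_merec_topsis_hand_example_dominant_row_wins():
    res = merec_topsis(make_matrix([[1.0, 2.0], [2.0, 4.0]]))
    np.testing.assert_allclose(res.weights.w, [0.5, 0.5], atol=1e-12)
    assert res.ranks.tolist() == [2, 1]


def test_merec_topsis_stage3_tables_rank1_not_always_best_on_f2():
    """Table 5's winner (PCA row) is not the best alternative on F2, yet
    ranks first; Table 7's winner dominates all criteria."""
    rep5 = fixture_report("table5")
    frame5 = rep5.to_frame()
    assert frame5.loc["Model10", "rank"] == 1
    assert frame5["f2_score"].idxmax() != "Model10"
    rep7 = fixture_report("table7")
    assert rep7.to_frame().loc["Model21", "topsis_score"] == pytest.approx(1.0, abs=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.integers(2, 8),
    st.integers(2, 5),
    st.integers(0, 10_000),
)
def test_weights_and_scores_contracts_hold_for_arbitrary_matrices(m, n, seed):
    rng = np.random.default_rng(seed)
    matrix = make_matrix(rng.uniform(0.5, 5.0, size=(m, n)))
    try:
        res = merec_topsis(matrix)
    except MCDMError:
        return  # degenerate draws are rejected, not mis-scored
    assert res.weights.w.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(res.weights.w >= 0)
    assert np.all((res.scores >= -1e-12) & (res.scores <= 1 + 1e-12))
    assert sorted(res.ranks[~res.tied]) == sorted(set(res.ranks[~res.tied]))
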