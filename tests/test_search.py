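import itertools
import math

import numpy as np
import pandas as pd
import pytest

from efoscreen import (
    ConsensusModel,
    EFORanker,
    ScoreTable,
    SearchConfig,
    SyntheticConfig,
    apply_model,
    enumerate_subsets,
    fit_all_subsets,
    generate,
    optimize_coefficients,
    standardize,
)
from efoscreen.metrics import quality, rank_molecules

from conftest import random_table


def grid_best_direction(table, subset, cluster_size, step_deg=1.0):
    """Brute-force Q maximization over the unit circle (k=2 only)."""
    X = table.score_matrix(subset)
    Z, _, _ = standardize(X)
    ids, labels = table.molecule_ids, table.labels
    best_q, best_w = -np.inf, None
    for deg in np.arange(0.0, 360.0, step_deg):
        w = np.array([math.cos(math.radians(deg)), math.sin(math.radians(deg))])
        r = rank_molecules(ids, Z @ w)
        q = quality(r, labels, min(cluster_size, table.n)).q
        if q > best_q:
            best_q, best_w = q, w
    return best_w, best_q


def test_standardize_basic_and_heldout():
    Z, m, s = standardize(np.array([[1.0], [2.0], [3.0]]))
    assert m[0] == 2.0 and s[0] == pytest.approx(np.sqrt(2 / 3))
    np.testing.assert_allclose(Z[:, 0], (np.array([1, 2, 3]) - 2.0) / s[0])
    held = (np.array([5.0]) - m) / s
    assert held[0] == pytest.approx((5.0 - 2.0) / s[0])


def test_standardize_zero_variance_errors():
    with pytest.raises(ValueError, match="zero-variance"):
        standardize(np.ones((5, 1)))


def test_enumerate_subset_counts():
    cols = [f"c{i:02d}" for i in range(11)]
    assert len(enumerate_subsets(cols, 2)) == 55
    assert len(enumerate_subsets(cols, 3)) == 165
    assert len(enumerate_subsets(cols[:10], 2)) == 45
    assert enumerate_subsets(["b", "a"], 1) == [("a",), ("b",)]
    with pytest.raises(ValueError):
        enumerate_subsets(["a"], 2)


@pytest.mark.parametrize("seed", range(8))
def test_k1_optimizer_is_exact_orientation_exhaustion(seed):
    """For a single score the optimizer must return the better of +/-."""
    t = random_table(seed, n=120, n_scores=1)
    cfg = SearchConfig(cluster_size=12, seed=seed)
    m = optimize_coefficients(t, ("s0",), cfg)
    Z, _, _ = standardize(t.score_matrix(["s0"]))
    qs = {}
    for sign in (+1.0, -1.0):
        r = rank_molecules(t.molecule_ids, sign * Z[:, 0])
        qs[sign] = quality(r, t.labels, 12).q
    assert m.train_quality.q == pytest.approx(max(qs.values()))
    assert m.coefficients[0] == (1.0 if qs[1.0] >= qs[-1.0] else -1.0)


def test_k1_negated_orientation_recovered():
    # actives have the most positive "energy": good molecules rank last by +col
    n, a = 200, 10
    labels = np.zeros(n, dtype=int)
    labels[:a] = 1
    energy = np.where(labels == 1, 5.0, 0.0) + np.random.default_rng(0).normal(0, 0.1, n)
    t = ScoreTable(
        molecule_ids=np.array([f"m{i:03d}" for i in range(n)], dtype=object),
        labels=labels,
        scores=pd.DataFrame({"e": -energy}),  # lower = better for actives
    )
    m = optimize_coefficients(t, ("e",), SearchConfig(cluster_size=a, seed=1))
    assert m.coefficients[0] == -1.0
    assert m.train_quality.cluster_actives == a


def test_perfect_planted_separator_reaches_ceiling():
    """Zero column noise, huge latent shift: all actives on top, Q maximal."""
    cfg = SyntheticConfig(
        n_molecules=300, n_active=12, n_scores=2, effect_size=8.0,
        loadings=(-0.6, -0.8), noise_sds=(0.0, 0.0), seed=3,
    )
    table, _ = generate(cfg)
    m = optimize_coefficients(table, ("score_01", "score_02"),
                              SearchConfig(cluster_size=12, seed=0))
    assert m.train_quality.cluster_actives == 12
    assert m.train_quality.q == pytest.approx(12 + 1 - 6.5 / 300)


def test_planted_direction_matches_grid_oracle():
    cfg = SyntheticConfig(
        n_molecules=500, n_active=20, n_scores=2, effect_size=2.5,
        loadings=(-0.6, -0.8), noise_sds=(0.3, 0.3), seed=7,
    )
    table, _ = generate(cfg)
    config = SearchConfig(cluster_size=25, seed=2)
    m = optimize_coefficients(table, ("score_01", "score_02"), config)
    w_grid, q_grid = grid_best_direction(table, ("score_01", "score_02"), 25)
    assert m.train_quality.q >= q_grid - 1e-12  # optimizer at least as good as 1° grid
    assert abs(float(m.coefficients @ w_grid)) >= 0.95


def test_quality_scale_invariance_of_direction():
    t = random_table(11, n=100, n_scores=2)
    Z, _, _ = standardize(t.score_matrix(["s0", "s1"]))
    w = np.array([0.3, -0.9])
    for c in (0.1, 1.0, 17.0):
        r1 = rank_molecules(t.molecule_ids, Z @ w)
        r2 = rank_molecules(t.molecule_ids, Z @ (c * w))
        assert quality(r1, t.labels, 10).q == quality(r2, t.labels, 10).q


def test_monotone_capacity_with_warm_start(planted_table):
    table, _ = planted_table
    cfg = SearchConfig(cluster_size=40, seed=4)
    models = fit_all_subsets(table, table.score_names, 3, cfg)
    best = {
        k: max(m.train_quality.q for s, m in models.items() if len(s) == k)
        for k in (1, 2, 3)
    }
    assert best[1] <= best[2] <= best[3]


def test_determinism_same_seed_bit_identical(planted_table):
    table, _ = planted_table
    cfg = SearchConfig(cluster_size=40, seed=9)
    m1 = optimize_coefficients(table, ("score_01", "score_02"), cfg)
    m2 = optimize_coefficients(table, ("score_01", "score_02"), cfg)
    assert m1.to_record() == m2.to_record()
    assert (m1.coefficients == m2.coefficients).all()


def test_apply_model_reproduces_train_quality(planted_table):
    table, _ = planted_table
    cfg = SearchConfig(cluster_size=40, seed=0)
    m = optimize_coefficients(table, ("score_01", "score_03"), cfg)
    _, _, _, qv = apply_model(m, table, cluster_size=40)
    assert qv.q == m.train_quality.q


def test_apply_model_single_column_reproduces_column_ranking(planted_table):
    table, _ = planted_table
    m = optimize_coefficients(table, ("score_01",), SearchConfig(cluster_size=40, seed=0))
    combined, _, _, _ = apply_model(m, table)
    col = table.scores["score_01"].to_numpy()
    r1 = rank_molecules(table.molecule_ids, combined)
    r2 = rank_molecules(table.molecule_ids, float(m.coefficients[0]) * col)
    assert list(r1.ids) == list(r2.ids)


def test_apply_model_missing_column_errors(planted_table):
    table, _ = planted_table
    m = optimize_coefficients(table, ("score_01",), SearchConfig(seed=0))
    small = ScoreTable(
        molecule_ids=table.molecule_ids,
        labels=table.labels,
        scores=table.scores[["score_02"]].copy(),
    )
    with pytest.raises(Exception, match="score_01"):
        apply_model(m, small)


def test_model_canonical_form_validation():
    with pytest.raises(ValueError, match="unit L2"):
        ConsensusModel(
            subset=("a", "b"),
            coefficients=np.array([1.0, 1.0]),
            means=np.zeros(2),
            sds=np.ones(2),
            train_quality=None,
        )


class TestEFORanker:
    def test_sklearn_contract(self, planted_table):
        from sklearn.base import clone

        table, _ = planted_table
        est = EFORanker(k=1, cluster_size=40, random_state=0)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        est.fit(table.scores, table.labels)
        assert len(est.subset_) == 1
        assert est.coef_.shape == (1,)
        s = est.decision_function(table.scores)
        assert s.shape == (table.n,)
        assert 0.5 < est.score(table.scores, table.labels) <= 1.0

    def test_selects_planted_subset(self, planted_table):
        table, truth = planted_table
        est = EFORanker(k=2, cluster_size=40, random_state=0)
        est.fit(table.scores, table.labels)
        assert set(est.subset_) == {"score_01", "score_02"}

    def test_ndarray_input(self, planted_table):
        table, _ = planted_table
        X = table.scores.to_numpy()
        est = EFORanker(k=1, cluster_size=40, random_state=0).fit(X, table.labels)
        assert est.subset_[0].startswith("x")
        assert est.decision_function(X).shape == (len(X),)

    def test_k_out_of_range(self, planted_table):
        table, _ = planted_table
        with pytest.raises(ValueError):
            EFORanker(k=5).fit(table.scores, table.labels)
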