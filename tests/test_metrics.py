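import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from efoscreen.metrics import (
    enrichment_factor,
    enrichment_profile,
    quality,
    rank_asymmetry,
    rank_molecules,
    roc_auc,
)

from conftest import random_table


# -- independent oracles ------------------------------------------------------

def brute_force_ef(ids, scores, labels, fraction):
    """Count actives in the top ceil(f*N) rows of an independently sorted list."""
    rows = sorted(zip(scores, ids, labels), key=lambda r: (-r[0], r[1]))
    n = len(rows)
    s_f = math.ceil(fraction * n)
    a_f = sum(lab for _, _, lab in rows[:s_f])
    a = sum(labels)
    return (a_f / s_f) / (a / n), s_f, a_f


def brute_force_auc(scores, labels):
    """Exhaustive pairwise comparison: wins + half-ties over A*(N-A) pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


# -- ranking -----------------------------------------------------------------

def test_rank_order_and_ties():
    r = rank_molecules(["a", "b", "c"], [3.0, 1.0, 2.0])
    assert list(r.ids) == ["a", "c", "b"]
    r = rank_molecules(["c", "a", "b"], [1.0, 1.0, 1.0])
    assert list(r.ids) == ["a", "b", "c"]  # lexicographic on full tie
    assert r.tie_groups == [["a", "b", "c"]]


def test_rank_rejects_non_finite():
    with pytest.raises(ValueError, match="non-finite"):
        rank_molecules(["a", "b"], [1.0, np.nan])


@pytest.mark.parametrize("seed", range(10))
def test_rank_matches_stable_sort_oracle(seed):
    rng = np.random.default_rng(seed)
    ids = [f"m{i:03d}" for i in range(50)]
    scores = rng.choice([0.0, 1.0, 2.5, -1.0], size=50)  # force ties
    r = rank_molecules(ids, scores)
    expect = [i for _, i in sorted(zip(scores, ids), key=lambda t: (-t[0], t[1]))]
    assert list(r.ids) == expect


# -- enrichment factor -------------------------------------------------------

def test_ef_perfect_ranking():
    labels = np.zeros(1000, dtype=int)
    labels[:10] = 1
    scores = -np.arange(1000, dtype=float)  # rank = row order
    ids = [f"m{i:04d}" for i in range(1000)]
    r = rank_molecules(ids, scores)
    ef, s, a = enrichment_factor(r, labels, 0.01)
    assert (s, a, ef) == (10, 10, 100.0)


def test_ef_uniform_spread():
    labels = np.zeros(1000, dtype=int)
    labels[np.arange(99, 1000, 100)] = 1  # ranks 100, 200, ..., 1000
    scores = -np.arange(1000, dtype=float)
    ids = [f"m{i:04d}" for i in range(1000)]
    ef, s, a = enrichment_factor(rank_molecules(ids, scores), labels, 0.10)
    assert (s, a) == (100, 1)
    assert ef == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(20))
@pytest.mark.parametrize("fraction", [0.01, 0.05, 0.2, 1.0])
def test_ef_matches_brute_force(seed, fraction):
    t = random_table(seed, n=int(np.random.default_rng(seed).integers(10, 200)))
    scores = t.scores["s0"].to_numpy()
    r = rank_molecules(t.molecule_ids, scores)
    ef, s, a = enrichment_factor(r, t.labels, fraction)
    ef0, s0, a0 = brute_force_ef(list(t.molecule_ids), scores, list(t.labels), fraction)
    assert (ef, s, a) == (ef0, s0, a0)


def test_ef_invariant_under_monotone_transform():
    t = random_table(3, n=100)
    s = t.scores["s0"].to_numpy()
    r1 = rank_molecules(t.molecule_ids, s)
    r2 = rank_molecules(t.molecule_ids, np.exp(2.0 * s) + 5)
    for f in (0.01, 0.05, 0.2):
        assert enrichment_factor(r1, t.labels, f) == enrichment_factor(r2, t.labels, f)


def test_random_ranking_ef_expectation_is_one():
    """E[EF_f] = 1 over random permutations, within 3 standard errors."""
    rng = np.random.default_rng(99)
    n, a, f = 120, 12, 0.10
    labels = np.zeros(n, dtype=int)
    labels[:a] = 1
    ids = [f"m{i:03d}" for i in range(n)]
    efs = []
    for _ in range(1000):
        r = rank_molecules(ids, rng.standard_normal(n))
        efs.append(enrichment_factor(r, labels, f)[0])
    efs = np.asarray(efs)
    se = efs.std(ddof=1) / np.sqrt(len(efs))
    assert abs(efs.mean() - 1.0) < 3 * se


def test_profile_actives_nondecreasing_in_fraction():
    for seed in range(10):
        t = random_table(seed, n=150)
        r = rank_molecules(t.molecule_ids, t.scores["s0"].to_numpy())
        p = enrichment_profile(r, t.labels)
        found = [p.actives_found[f] for f in p.fractions]
        assert found == sorted(found)
        assert all(0 <= p.actives_found[f] <= min(p.selected[f], p.n_active)
                   for f in p.fractions)


# -- AUC ---------------------------------------------------------------------

def test_auc_perfect_and_tied():
    labels = [1, 1, 0, 0]
    assert roc_auc([4.0, 3.0, 2.0, 1.0], labels) == 1.0
    assert roc_auc([1.0, 1.0, 1.0, 1.0], labels) == 0.5


def test_auc_eight_row_example_matches_pair_loop():
    scores = [5.0, 3.0, 3.0, 2.0, 4.0, 1.0, 3.0, 0.0]
    labels = [1, 1, 0, 0, 0, 1, 0, 0]
    assert roc_auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels))


@pytest.mark.parametrize("seed", range(20))
def test_auc_matches_pairwise_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 100))
    labels = np.zeros(n, dtype=int)
    labels[: int(rng.integers(1, n))] = 1
    scores = np.round(rng.standard_normal(n), 1)  # some ties
    assert roc_auc(scores, labels) == pytest.approx(
        brute_force_auc(list(scores), list(labels)), abs=1e-12
    )


def test_auc_reflection_without_ties():
    rng = np.random.default_rng(5)
    scores = rng.permutation(40).astype(float)
    labels = (rng.random(40) < 0.3).astype(int)
    labels[0] = 1
    labels[1] = 0
    assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)


def test_auc_single_class_errors():
    with pytest.raises(ValueError):
        roc_auc([1.0, 2.0], [1, 1])


# -- asymmetry and quality ---------------------------------------------------

def test_asymmetry_symmetric_actives_zero_skew():
    n = 101
    labels = np.zeros(n, dtype=int)
    labels[[10, 50, 90]] = 1  # ranks symmetric about the middle
    scores = -np.arange(n, dtype=float)
    ids = [f"m{i:03d}" for i in range(n)]
    d = rank_asymmetry(rank_molecules(ids, scores), labels)
    assert d["skewness"] == pytest.approx(0.0, abs=1e-12)


def test_asymmetry_top_block_closed_form():
    n, a = 200, 8
    labels = np.zeros(n, dtype=int)
    labels[:a] = 1
    scores = -np.arange(n, dtype=float)
    ids = [f"m{i:03d}" for i in range(n)]
    d = rank_asymmetry(rank_molecules(ids, scores), labels)
    assert d["mean_normalized_rank"] == pytest.approx((a + 1) / (2 * n))


@pytest.mark.parametrize("seed", range(5))
def test_asymmetry_matches_textbook_formulas(seed):
    t = random_table(seed, n=100, n_active=9)
    r = rank_molecules(t.molecule_ids, t.scores["s0"].to_numpy())
    d = rank_asymmetry(r, t.labels)
    ranked = np.asarray(t.labels)[r.order]
    ranks = np.flatnonzero(ranked) + 1.0
    assert d["mean_normalized_rank"] == pytest.approx(ranks.mean() / 100)
    m = ranks.mean()
    s = ranks.std(ddof=1)
    n = len(ranks)
    g1 = ((ranks - m) ** 3).mean() / (((ranks - m) ** 2).mean()) ** 1.5
    adj = math.sqrt(n * (n - 1)) / (n - 2) * g1
    assert d["skewness"] == pytest.approx(adj)


def test_quality_closed_forms():
    n, a, c = 1000, 10, 100
    ids = [f"m{i:04d}" for i in range(n)]
    scores = -np.arange(n, dtype=float)
    top = np.zeros(n, dtype=int)
    top[:a] = 1
    qv = quality(rank_molecules(ids, scores), top, c)
    assert qv.q == pytest.approx(10 + (1 - 5.5 / 1000))
    bottom = np.zeros(n, dtype=int)
    bottom[-a:] = 1
    qv = quality(rank_molecules(ids, scores), bottom, c)
    assert qv.cluster_actives == 0
    assert qv.q == pytest.approx(1 - 995.5 / 1000)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_quality_matches_direct_recomputation(seed):
    t = random_table(seed % 1000, n=80, n_active=7)
    r = rank_molecules(t.molecule_ids, t.scores["s0"].to_numpy())
    qv = quality(r, t.labels, 10)
    ranked = np.asarray(t.labels)[r.order]
    ranks = np.flatnonzero(ranked) + 1
    assert qv.cluster_actives == int((ranks <= 10).sum())
    assert qv.q == pytest.approx(qv.cluster_actives + 1 - ranks.mean() / 80)
    # Q strictly increases with cluster count: fractional part in [0, 1)
    assert 0.0 <= qv.asymmetry < 1.0
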