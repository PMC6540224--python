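"""Exhaustive subset enumeration and coefficient optimization.

The consensus model is a linear combination of 1-3 standardized docking
scores.  For each score subset the unit-norm coefficient vector is fitted by
maximizing the cluster-based quality Q (see :mod:`efoscreen.metrics`): Q is
piecewise constant in the coefficients (it depends only on the induced
ranking), so the local refinement is a derivative-free accept-if-better
Gaussian pattern search on the unit sphere, restarted from several random
directions to escape local optima.

Optimizer settings follow the calibrated defaults of the method: cluster
size 100, 12 random-sampling starts per model, at most 5000 iterations per
start, convergence when the step size satisfies sigma * sqrt(k) < 0.001.

For k = 1 the unit sphere has two points, so the optimizer is exact: it
returns the better of the + and - orientations.

A warm start is added for k >= 2: the best (k-1)-score model over any
sub-subset, padded with a zero coefficient, seeds one extra refinement.
Accept-if-better refinement never decreases Q, so the best training Q is
non-decreasing in k by construction.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import _kernels
from .metrics import (
    QualityValue,
    enrichment_profile,
    quality,
    rank_molecules,
    roc_auc,
)
from .score_table import ScoreTable

__all__ = [
    "SearchConfig",
    "ConsensusModel",
    "EFORanker",
    "standardize",
    "enumerate_subsets",
    "optimize_coefficients",
    "fit_all_subsets",
    "apply_model",
]


@dataclass(frozen=True)
class SearchConfig:
    """Optimizer settings.

    cluster_size : top-of-ranking window the quality function counts actives
    in (molecules, default 100).
    n_starts : random unit-vector starts per subset (default 12).
    max_iter : iteration cap per start (default 5000).
    rms_tol : step-size convergence tolerance; a start stops when
    sigma * sqrt(k) < rms_tol (default 1e-3).
    sigma0 : initial Gaussian step size on the unit sphere (default 0.5).
    halve_after : consecutive rejections before sigma is halved (default 100).
    warm_start : seed each k-subset with its best (k-1)-sub-model (default True).
    seed : master seed; all per-subset randomness derives from it.
    """

    cluster_size: int = 100
    n_starts: int = 12
    max_iter: int = 5000
    rms_tol: float = 1e-3
    sigma0: float = 0.5
    halve_after: int = 100
    warm_start: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.cluster_size, self.n_starts, self.max_iter) < 1:
            raise ValueError("cluster_size, n_starts and max_iter must be positive")
        if self.rms_tol <= 0 or self.sigma0 <= 0:
            raise ValueError("rms_tol and sigma0 must be positive")


@dataclass
class ConsensusModel:
    """A fitted linear consensus of ``k`` docking scores.

    ``coefficients`` has unit L2 norm; its signs are meaningful (they orient
    each score so that higher combined score = more likely active).
    ``means``/``sds`` are the per-column standardization parameters estimated
    on the fitting rows and re-applied verbatim to new data.
    """

    subset: tuple[str, ...]
    coefficients: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    train_quality: QualityValue
    k: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.k = len(self.subset)
        if self.coefficients.shape != (self.k,):
            raise ValueError("one coefficient per subset column required")
        nrm = np.linalg.norm(self.coefficients)
        if not np.isclose(nrm, 1.0, atol=1e-9):
            raise ValueError(f"coefficients must have unit L2 norm (got {nrm})")
        if (self.sds <= 0).any():
            raise ValueError("standardization sds must be positive")

    def combine(self, table: ScoreTable) -> np.ndarray:
        """Combined score on a table using the stored standardization."""
        X = table.score_matrix(self.subset)
        return (X - self.means) / self.sds @ self.coefficients

    def to_record(self) -> dict:
        return {
            "subset": list(self.subset),
            "coefficients": [float(c) for c in self.coefficients],
            "means": [float(m) for m in self.means],
            "sds": [float(s) for s in self.sds],
            "train_quality": {
                "cluster_actives": self.train_quality.cluster_actives,
                "asymmetry": self.train_quality.asymmetry,
                "q": self.train_quality.q,
            },
            "k": self.k,
            "seed": self.seed,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "ConsensusModel":
        return cls(
            subset=tuple(rec["subset"]),
            coefficients=np.asarray(rec["coefficients"], dtype=float),
            means=np.asarray(rec["means"], dtype=float),
            sds=np.asarray(rec["sds"], dtype=float),
            train_quality=QualityValue(
                cluster_actives=rec["train_quality"]["cluster_actives"],
                asymmetry=rec["train_quality"]["asymmetry"],
                q=rec["train_quality"]["q"],
            ),
            seed=rec.get("seed", 0),
        )


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """z = (x - mean) / sd per column; returns (Z, means, sds).

    Population (ddof=0) standard deviation; a zero-variance column is an
    error because its z-scores are undefined.
    """
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    if (sds == 0).any():
        raise ValueError(
            f"zero-variance column at index {int(np.flatnonzero(sds == 0)[0])}"
        )
    return (X - means) / sds, means, sds


def enumerate_subsets(columns: Sequence[str], k: int) -> list[tuple[str, ...]]:
    """All C(n, k) subsets in deterministic lexicographic order."""
    cols = list(columns)
    if not 1 <= k <= len(cols):
        raise ValueError(f"k={k} out of range for {len(cols)} columns")
    return [tuple(s) for s in itertools.combinations(sorted(cols), k)]


def _subset_seed(master_seed: int, subset: tuple[str, ...]) -> int:
    """Deterministic per-subset seed, independent of enumeration order."""
    crc = zlib.crc32(("|".join(subset)).encode())
    return int(np.random.SeedSequence([master_seed, crc]).generate_state(1)[0] % (2**31))


def _optimize_direction(
    Za: np.ndarray,
    Zd: np.ndarray,
    k: int,
    config: SearchConfig,
    seed: int,
    warm: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Best unit coefficient vector for pre-standardized active/decoy blocks."""
    C = min(config.cluster_size, Za.shape[0] + Zd.shape[0])
    if k == 1:
        one = np.ones(1)
        q_pos = _kernels.quality_value(Za[:, 0], Zd[:, 0], C)[2]
        q_neg = _kernels.quality_value(-Za[:, 0], -Zd[:, 0], C)[2]
        return (one, q_pos) if q_pos >= q_neg else (-one, q_neg)

    rng = np.random.default_rng(seed)
    starts: list[np.ndarray] = []
    if warm is not None:
        starts.append(np.asarray(warm, dtype=float))
    for _ in range(config.n_starts):
        g = rng.standard_normal(k)
        while not np.linalg.norm(g) > 0:  # pragma: no cover - measure zero
            g = rng.standard_normal(k)
        starts.append(g / np.linalg.norm(g))
    kernel_seeds = rng.integers(0, 2**31 - 1, size=len(starts))

    best_w: np.ndarray | None = None
    best_q = -np.inf
    for w0, ks in zip(starts, kernel_seeds):
        w, q, _ = _kernels.pattern_search(
            Za, Zd, C, np.ascontiguousarray(w0),
            config.sigma0, config.max_iter, config.rms_tol,
            config.halve_after, int(ks),
        )
        if q > best_q:
            best_q = q
            best_w = w
    assert best_w is not None
    return best_w / np.linalg.norm(best_w), float(best_q)


def _exact_quality(
    table: ScoreTable, combined: np.ndarray, cluster_size: int
) -> QualityValue:
    ranking = rank_molecules(table.molecule_ids, combined)
    return quality(ranking, table.labels, min(cluster_size, table.n))


def optimize_coefficients(
    table: ScoreTable,
    subset: Sequence[str],
    config: SearchConfig | None = None,
    warm_start: ConsensusModel | None = None,
) -> ConsensusModel:
    """Fit the unit coefficient vector maximizing Q for one score subset.

    ``warm_start`` may be a fitted model on a sub-subset of ``subset``; its
    coefficients are padded with zeros at the missing columns and refined
    alongside the random starts, which guarantees the result is at least as
    good as the smaller model on the same fitting rows.
    """
    config = config or SearchConfig()
    subset = tuple(subset)
    X = table.score_matrix(subset)
    Z, means, sds = standardize(X)
    act = table.labels == 1
    Za = np.ascontiguousarray(Z[act])
    Zd = np.ascontiguousarray(Z[~act])
    if Za.shape[0] == 0:
        raise ValueError("cannot optimize without actives")

    warm_vec = None
    if warm_start is not None and config.warm_start and len(subset) >= 2:
        if not set(warm_start.subset) <= set(subset):
            raise ValueError("warm start subset must be contained in the target subset")
        warm_vec = np.zeros(len(subset))
        for name, c in zip(warm_start.subset, warm_start.coefficients):
            warm_vec[subset.index(name)] = c

    seed = _subset_seed(config.seed, subset)
    w, _ = _optimize_direction(Za, Zd, len(subset), config, seed, warm=warm_vec)
    combined = Z @ w
    tq = _exact_quality(table, combined, config.cluster_size)
    return ConsensusModel(
        subset=subset, coefficients=w, means=means, sds=sds,
        train_quality=tq, seed=seed,
    )


def fit_all_subsets(
    table: ScoreTable,
    columns: Sequence[str],
    k_max: int,
    config: SearchConfig | None = None,
) -> dict[tuple[str, ...], ConsensusModel]:
    """Fit every subset of size 1..k_max over ``columns``, with warm starts.

    Models are fitted in order of increasing size so each k-subset can be
    seeded with the best of its (k-1)-sub-models.  Returns a dict keyed by
    subset tuple (columns in sorted order).
    """
    config = config or SearchConfig()
    models: dict[tuple[str, ...], ConsensusModel] = {}
    for k in range(1, k_max + 1):
        for subset in enumerate_subsets(columns, k):
            warm = None
            if k >= 2 and config.warm_start:
                subs = [
                    models[s]
                    for s in itertools.combinations(subset, k - 1)
                    if s in models
                ]
                if subs:
                    warm = max(subs, key=lambda m: m.train_quality.q)
            models[subset] = optimize_coefficients(table, subset, config, warm_start=warm)
    return models


def apply_model(model: ConsensusModel, table: ScoreTable, cluster_size: int = 100):
    """Apply a fitted model to a table: combined scores, EF profile, AUC, Q.

    Returns ``(combined, profile, auc, quality_value)``; standardization uses
    the model's stored fitting-set parameters, never the new table's.
    """
    combined = model.combine(table)
    ranking = rank_molecules(table.molecule_ids, combined)
    profile = enrichment_profile(ranking, table.labels)
    auc = roc_auc(combined, table.labels)
    qv = quality(ranking, table.labels, min(cluster_size, table.n))
    return combined, profile, auc, qv


class EFORanker(BaseEstimator):
    """Enrichment-factor-optimized linear consensus of docking scores.

    Exhaustively enumerates all subsets of ``k`` score columns, fits each
    subset's unit-norm coefficient vector by derivative-free maximization of
    the cluster quality Q on the training data, and keeps the best subset.
    ``decision_function`` returns the combined score (higher = more likely
    active).

    Parameters mirror :class:`SearchConfig`; ``random_state`` seeds every
    random start, making ``fit`` fully deterministic.

    Attributes
    ----------
    subset_ : tuple of str — selected score columns.
    coef_ : ndarray of shape (k,) — unit-norm coefficients.
    model_ : ConsensusModel — full fitted model (standardization included).
    models_ : dict — every fitted subset's model, keyed by subset tuple.
    quality_ : float — training Q of the selected model.

    Examples
    --------
    >>> from efoscreen.synthetic import SyntheticConfig, generate
    >>> table, truth = generate(SyntheticConfig(seed=7))
    >>> ranker = EFORanker(k=2, random_state=0).fit(table.scores, table.labels)
    >>> len(ranker.subset_)
    2
    """

    def __init__(
        self,
        k: int = 2,
        cluster_size: int = 100,
        n_starts: int = 12,
        max_iter: int = 5000,
        rms_tol: float = 1e-3,
        sigma0: float = 0.5,
        halve_after: int = 100,
        warm_start_from_lower: bool = True,
        random_state: int | None = None,
    ):
        self.k = k
        self.cluster_size = cluster_size
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.rms_tol = rms_tol
        self.sigma0 = sigma0
        self.halve_after = halve_after
        self.warm_start_from_lower = warm_start_from_lower
        self.random_state = random_state

    def _config(self) -> SearchConfig:
        return SearchConfig(
            cluster_size=self.cluster_size,
            n_starts=self.n_starts,
            max_iter=self.max_iter,
            rms_tol=self.rms_tol,
            sigma0=self.sigma0,
            halve_after=self.halve_after,
            warm_start=self.warm_start_from_lower,
            seed=0 if self.random_state is None else int(self.random_state),
        )

    def _to_table(self, X, y) -> ScoreTable:
        if isinstance(X, pd.DataFrame):
            scores = X.reset_index(drop=True).astype(float)
        else:
            X = np.asarray(X, dtype=float)
            scores = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
        ids = np.array([f"row{i:07d}" for i in range(len(scores))], dtype=object)
        return ScoreTable(molecule_ids=ids, labels=np.asarray(y, dtype=int), scores=scores)

    def fit(self, X, y):
        if not 1 <= self.k <= 3:
            raise ValueError("k must be 1, 2 or 3")
        table = self._to_table(X, y)
        if self.k > len(table.score_names):
            raise ValueError(
                f"k={self.k} exceeds the {len(table.score_names)} available score columns"
            )
        cfg = self._config()
        self.models_ = fit_all_subsets(table, table.score_names, self.k, cfg)
        k_models = {s: m for s, m in self.models_.items() if len(s) == self.k}
        best = min(
            k_models.items(), key=lambda kv: (-kv[1].train_quality.q, kv[0])
        )[1]
        self.model_ = best
        self.subset_ = best.subset
        self.coef_ = best.coefficients
        self.quality_ = best.train_quality.q
        self.n_features_in_ = table.scores.shape[1]
        self.feature_names_in_ = np.asarray(table.score_names, dtype=object)
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.subset_ if c not in X.columns]
            if missing:
                raise ValueError(f"missing score columns: {missing}")
            M = X[list(self.subset_)].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            idx = [int(name[1:]) for name in self.subset_]
            M = X[:, idx]
        return (M - self.model_.means) / self.model_.sds @ self.coef_

    def predict(self, X) -> np.ndarray:
        """Label the top ``cluster_size`` ranked molecules as 1, the rest 0."""
        check_is_fitted(self, "model_")
        s = self.decision_function(X)
        order = np.argsort(-s, kind="stable")
        out = np.zeros(len(s), dtype=int)
        out[order[: min(self.cluster_size, len(s))]] = 1
        return out

    def score(self, X, y) -> float:
        """ROC AUC of the combined score on (X, y)."""
        return roc_auc(self.decision_function(X), y)
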