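"""Score-column prefilters applied before subset enumeration.

Two filters, run in this order:

1. :class:`VifFilter` — greedy elimination of interrelated (multicollinear)
   score columns: while any column's variance inflation factor exceeds the
   threshold (default 5), the worst offender is dropped and VIFs are
   recomputed.  Ties are broken by dropping the column with the lower
   single-score EF at the top 5% (then lexicographic name), so that of two
   redundant scores the more enriching one survives.
2. :class:`EffectivenessFilter` — drops individually ineffective scores:
   a column is kept only if ranking by it (in its better orientation, + or -)
   yields EF at the top 5% of at least 2.0.

Both are scikit-learn transformers (``fit`` / ``transform`` / ``get_support``)
and also exposed as plain functions over :class:`~efoscreen.score_table.ScoreTable`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .score_table import ScoreTable

__all__ = [
    "VIF_SENTINEL",
    "VifReport",
    "EffectivenessReport",
    "VifFilter",
    "EffectivenessFilter",
    "compute_vif",
    "vif_filter",
    "effectiveness_filter",
    "single_score_ef",
]

#: VIF reported for perfectly collinear (singular-regression) columns.
VIF_SENTINEL = 1.0e6


@dataclass
class VifReport:
    vif: dict[str, float]                       # VIFs of the initial column set
    removal_sequence: list[tuple[str, float]]   # (column, VIF at removal)
    surviving: list[str]


@dataclass
class EffectivenessReport:
    best_ef: dict[str, float]                   # max EF over both orientations
    kept: dict[str, bool]
    fraction: float
    min_ef: float


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return np.ascontiguousarray(X.to_numpy(dtype=float)), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D score matrix")
    return X, [f"x{i}" for i in range(X.shape[1])]


class _neg_name(str):
    """Reverses lexicographic comparison, for use inside a min() key tuple."""

    def __lt__(self, other) -> bool:  # type: ignore[override]
        return str(self) > str(other)


def _vif_values(Z: np.ndarray) -> np.ndarray:
    """VIF_i = 1/(1 - R_i^2) from OLS of standardized column i on the rest."""
    n, p = Z.shape
    out = np.empty(p)
    for i in range(p):
        others = np.delete(Z, i, axis=1)
        coef, _, _, _ = np.linalg.lstsq(others, Z[:, i], rcond=None)
        resid = Z[:, i] - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(Z[:, i] @ Z[:, i])
        r2 = 1.0 - ss_res / ss_tot
        if r2 >= 1.0 - 1.0 / VIF_SENTINEL:
            out[i] = VIF_SENTINEL
        else:
            out[i] = min(1.0 / (1.0 - r2), VIF_SENTINEL)
    return out


def _standardize_cols(X: np.ndarray, names: list[str]) -> np.ndarray:
    sd = X.std(axis=0, ddof=0)
    const = sd == 0
    if const.any():
        raise ValueError(f"constant score column: {names[int(np.flatnonzero(const)[0])]!r}")
    return (X - X.mean(axis=0)) / sd


def _top_fraction_ef(scores: np.ndarray, labels: np.ndarray, fraction: float) -> float:
    """EF of one oriented score vector; ties broken by row order (stable sort)."""
    n = len(scores)
    n_active = int(labels.sum())
    s_f = math.ceil(fraction * n)
    order = np.argsort(-scores, kind="stable")
    a_f = int(labels[order[:s_f]].sum())
    return (a_f / s_f) / (n_active / n)


def single_score_ef(X, y, fraction: float = 0.05) -> np.ndarray:
    """Best single-column EF at ``fraction``, maximized over both orientations.

    Energy-like scores (lower = better) score well through the negated
    orientation; a column carries no signal when both orientations give
    EF near 1.
    """
    X, _ = _as_matrix(X)
    y = np.asarray(y, dtype=int)
    out = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        out[j] = max(
            _top_fraction_ef(X[:, j], y, fraction),
            _top_fraction_ef(-X[:, j], y, fraction),
        )
    return out


class VifFilter(BaseEstimator, TransformerMixin):
    """Greedy variance-inflation-factor filter for redundant score columns.

    Parameters
    ----------
    threshold : float, default=5.0
        Columns are eliminated until every remaining VIF is <= threshold.
    ef_fraction : float, default=0.05
        Ranking fraction of the single-score EF used for tie-breaking.

    Attributes
    ----------
    support_ : bool array of shape (n_features,)
        True for surviving columns.
    report_ : VifReport
        Initial VIFs, ordered removal sequence, and survivors.
    """

    def __init__(self, threshold: float = 5.0, ef_fraction: float = 0.05):
        self.threshold = threshold
        self.ef_fraction = ef_fraction

    def fit(self, X, y):
        X, names = _as_matrix(X)
        if X.shape[1] < 2:
            raise ValueError("VIF needs at least 2 score columns")
        y = np.asarray(y, dtype=int)
        single_efs = single_score_ef(X, y, self.ef_fraction)
        Z = _standardize_cols(X, names)

        active = list(range(X.shape[1]))
        initial_vif = dict(zip(names, _vif_values(Z)))
        removals: list[tuple[str, float]] = []
        while len(active) >= 2:
            vifs = _vif_values(Z[:, active])
            worst = vifs.max()
            if worst <= self.threshold:
                break
            tied = [active[i] for i in range(len(active)) if vifs[i] == worst]
            # among equally collinear columns, sacrifice the least enriching;
            # on a full tie keep the earlier-named (primary) column
            drop = min(tied, key=lambda j: (single_efs[j], _neg_name(names[j])))
            pos = active.index(drop)
            removals.append((names[drop], float(vifs[pos])))
            active.remove(drop)

        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[active] = True
        self.report_ = VifReport(
            vif={k: float(v) for k, v in initial_vif.items()},
            removal_sequence=removals,
            surviving=[names[j] for j in active],
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_


class EffectivenessFilter(BaseEstimator, TransformerMixin):
    """Drop columns whose best single-orientation EF at top 5% is below 2.0.

    Attributes
    ----------
    support_ : bool array, True for kept columns.
    report_ : EffectivenessReport
    """

    def __init__(self, min_ef: float = 2.0, fraction: float = 0.05):
        self.min_ef = min_ef
        self.fraction = fraction

    def fit(self, X, y):
        X, names = _as_matrix(X)
        y = np.asarray(y, dtype=int)
        best = single_score_ef(X, y, self.fraction)
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.support_ = best >= self.min_ef
        self.report_ = EffectivenessReport(
            best_ef=dict(zip(names, best.astype(float))),
            kept={n: bool(k) for n, k in zip(names, self.support_)},
            fraction=self.fraction,
            min_ef=self.min_ef,
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_


# -- thin functional wrappers over ScoreTable --------------------------------

def compute_vif(table: ScoreTable, columns=None) -> VifReport:
    """VIF of each score column regressed on the others (no filtering)."""
    cols = list(columns) if columns is not None else table.score_names
    X = table.score_matrix(cols)
    Z = _standardize_cols(X, cols)
    return VifReport(
        vif=dict(zip(cols, (float(v) for v in _vif_values(Z)))),
        removal_sequence=[],
        surviving=cols,
    )


def vif_filter(table: ScoreTable, columns=None, threshold: float = 5.0):
    """Greedy VIF elimination; returns ``(surviving_columns, VifReport)``."""
    cols = list(columns) if columns is not None else table.score_names
    f = VifFilter(threshold=threshold).fit(table.scores[cols], table.labels)
    return f.report_.surviving, f.report_


def effectiveness_filter(
    table: ScoreTable, columns=None, min_ef: float = 2.0, fraction: float = 0.05
):
    """Single-score EF filter; returns ``(surviving_columns, EffectivenessReport)``."""
    cols = list(columns) if columns is not None else table.score_names
    f = EffectivenessFilter(min_ef=min_ef, fraction=fraction).fit(
        table.scores[cols], table.labels
    )
    surviving = [c for c, keep in zip(cols, f.support_) if keep]
    return surviving, f.report_
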