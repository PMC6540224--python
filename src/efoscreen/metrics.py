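"""Ranking-based early-recognition metrics.

Enrichment factors at fixed ranking fractions, ROC AUC, active-rank asymmetry
diagnostics, and the cluster-based quality function Q that the coefficient
optimizer maximizes.

Orientation convention: a *higher* combined score is better.  Energy-like
scores (more negative = better binding) are handled upstream by the sign of
the combination coefficient, never by per-column flags.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "DEFAULT_FRACTIONS",
    "Ranking",
    "EnrichmentProfile",
    "QualityValue",
    "rank_molecules",
    "enrichment_factor",
    "enrichment_profile",
    "roc_auc",
    "rank_asymmetry",
    "quality",
]

logger = logging.getLogger(__name__)

#: Ranking fractions reported in enrichment profiles (EF 1% ... EF 20%).
DEFAULT_FRACTIONS = (0.01, 0.02, 0.05, 0.10, 0.20)


@dataclass
class Ranking:
    """A deterministic ordering of molecules, rank 1 = best.

    ``order`` holds row indices into the originating table; ``ids`` the
    molecule identifiers in ranked order.  Ties in the combined score are
    broken by lexicographic molecule id so that a fixed table and model always
    produce the same ranking; tie groups are recorded for diagnostics.
    """

    order: np.ndarray
    ids: np.ndarray
    scores: np.ndarray
    tie_groups: list[list[str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.order)


@dataclass
class EnrichmentProfile:
    """EF values at fixed fractions with the underlying counts."""

    n: int
    n_active: int
    fractions: tuple[float, ...]
    selected: dict[float, int]
    actives_found: dict[float, int]
    ef: dict[float, float]

    def as_dict(self) -> dict[str, float]:
        return {f"EF{round(f * 100):g}%": self.ef[f] for f in self.fractions}


@dataclass
class QualityValue:
    """Q = actives-in-cluster + (1 - mean normalized active rank).

    The integer cluster count dominates lexicographically (the fractional
    asymmetry term lies in [0, 1)), so maximizing Q first packs actives into
    the top cluster and only then pulls the remaining actives upward.
    """

    cluster_actives: int
    asymmetry: float
    q: float

    def __float__(self) -> float:
        return self.q


def rank_molecules(ids, combined_score) -> Ranking:
    """Rank molecules by descending combined score, ties by lexicographic id."""
    ids = np.asarray(ids, dtype=object).astype(str)
    s = np.asarray(combined_score, dtype=float)
    if s.shape != ids.shape:
        raise ValueError("combined_score must have one value per molecule")
    if not np.isfinite(s).all():
        raise ValueError("combined score contains non-finite values")
    order = np.lexsort((ids, -s))
    ranked_scores = s[order]
    tie_groups: list[list[str]] = []
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and ranked_scores[j + 1] == ranked_scores[i]:
            j += 1
        if j > i:
            tie_groups.append(list(ids[order[i : j + 1]]))
        i = j + 1
    return Ranking(order=order, ids=ids[order], scores=ranked_scores, tie_groups=tie_groups)


def _ranked_labels(ranking: Ranking, labels) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.shape != ranking.order.shape:
        raise ValueError("labels must align with the ranked table")
    return labels[ranking.order]


def enrichment_factor(ranking: Ranking, labels, fraction: float):
    """EF at one fraction: (a_f / s_f) / (A / N) with s_f = ceil(f * N).

    Returns ``(ef, selected, actives_found)``.  EF = 1 for a random ranking;
    its maximum is min(s_f, A)/s_f * N/A for a perfect one.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    ranked = _ranked_labels(ranking, labels)
    n = len(ranked)
    n_active = int(ranked.sum())
    if n_active == 0:
        raise ValueError("enrichment factor undefined without actives")
    s_f = math.ceil(fraction * n)
    if (
        ranking.tie_groups
        and s_f < n
        and ranking.scores[s_f - 1] == ranking.scores[s_f]
    ):
        logger.warning(
            "tie group straddles the top-%g%% selection boundary; "
            "EF depends on the lexicographic id tie-break", fraction * 100,
        )
    a_f = int(ranked[:s_f].sum())
    ef = (a_f / s_f) / (n_active / n)
    return ef, s_f, a_f


def enrichment_profile(
    ranking: Ranking, labels, fractions=DEFAULT_FRACTIONS
) -> EnrichmentProfile:
    """Enrichment factors at several fractions for one ranking."""
    ranked = _ranked_labels(ranking, labels)
    sel, found, efs = {}, {}, {}
    for f in fractions:
        ef, s_f, a_f = enrichment_factor(ranking, labels, f)
        sel[f], found[f], efs[f] = s_f, a_f, ef
    return EnrichmentProfile(
        n=len(ranked),
        n_active=int(ranked.sum()),
        fractions=tuple(fractions),
        selected=sel,
        actives_found=found,
        ef=efs,
    )


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve of ``scores`` against the binary labels.

    Computed as the rank-sum (Mann-Whitney) statistic with half credit for
    ties, i.e. the trapezoidal ROC area with tied scores pooled.  0.5 is
    random, 1.0 perfect separation.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both actives and decoys")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def rank_asymmetry(ranking: Ranking, labels) -> dict[str, float]:
    """Diagnostics of where the actives sit in the ranking.

    Returns the mean normalized active rank (mean rank / N, in (0, 1]; small
    is good) and, when at least three actives are present, the sample skewness
    of the active rank values (positive skew = actives concentrated early with
    a straggler tail).
    """
    ranked = _ranked_labels(ranking, labels)
    act_ranks = np.flatnonzero(ranked) + 1
    if len(act_ranks) == 0:
        raise ValueError("no actives in table")
    out = {"mean_normalized_rank": float(act_ranks.mean() / len(ranked))}
    if len(act_ranks) >= 3:
        out["skewness"] = float(stats.skew(act_ranks, bias=False))
    return out


def quality(ranking: Ranking, labels, cluster_size: int) -> QualityValue:
    """The enrichment-optimization objective Q = a_C + (1 - r̄/N).

    ``a_C`` is the number of actives among the top ``cluster_size`` molecules
    and r̄ the mean active rank.  Q strictly increases with a_C; the
    asymmetry term rewards pulling the remaining actives up the ranking.
    """
    ranked = _ranked_labels(ranking, labels)
    n = len(ranked)
    if not 1 <= cluster_size <= n:
        raise ValueError(f"cluster size must be in [1, {n}], got {cluster_size}")
    if ranked.sum() == 0:
        raise ValueError("quality undefined without actives")
    act_ranks = np.flatnonzero(ranked) + 1
    a_c = int((act_ranks <= cluster_size).sum())
    asym = 1.0 - float(act_ranks.mean()) / n
    return QualityValue(cluster_actives=a_c, asymmetry=asym, q=a_c + asym)
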