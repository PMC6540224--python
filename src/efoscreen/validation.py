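"""Repeated stratified train/test validation of consensus models.

Candidate score subsets are enumerated once (from the globally prefiltered
columns), then for every repeat the table is split 80/20 with stratification
on the activity label, each subset's coefficients are re-fitted on the
training rows only, and the resulting model is applied to the held-out test
rows.  Subsets are prioritized by their average test quality Q across the
repeats (default 5); the winner is finally refitted on the full table and its
full-dataset enrichment profile is reported next to the validation averages,
exposing any optimistic mismatch between validated and full-data performance.

Stratification is a necessity, not a refinement: with ~2-3% actives an
unstratified 20% draw can contain zero actives, leaving the test enrichment
factor undefined.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import DEFAULT_FRACTIONS, EnrichmentProfile
from .score_table import ScoreTable
from .search import (
    ConsensusModel,
    SearchConfig,
    apply_model,
    fit_all_subsets,
    optimize_coefficients,
)

__all__ = [
    "SplitPlan",
    "SubsetValidation",
    "ValidationReport",
    "make_splits",
    "validate_subsets",
    "finalize",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitPlan:
    """One stratified train/test partition of the table rows."""

    repeat: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int


@dataclass
class SubsetValidation:
    """Per-repeat test metrics and averages for one candidate subset."""

    subset: tuple[str, ...]
    test_q: list[float] = field(default_factory=list)
    test_auc: list[float] = field(default_factory=list)
    test_ef: list[dict[float, float]] = field(default_factory=list)
    failed: bool = False

    @property
    def avg_q(self) -> float:
        return float(np.mean(self.test_q))

    @property
    def avg_auc(self) -> float:
        return float(np.mean(self.test_auc))

    def avg_ef(self, fraction: float) -> float:
        return float(np.mean([e[fraction] for e in self.test_ef]))


@dataclass
class ValidationReport:
    subsets: dict[tuple[str, ...], SubsetValidation]
    selected: tuple[str, ...]
    repeats: int
    final_model: ConsensusModel | None = None
    final_profile: EnrichmentProfile | None = None
    final_auc: float | None = None

    def to_frame(self) -> pd.DataFrame:
        """One row per subset: averages then per-repeat values."""
        rows = []
        for subset, sv in sorted(self.subsets.items()):
            row: dict[str, object] = {
                "subset": "+".join(subset),
                "selected": subset == self.selected,
                "avg_test_Q": sv.avg_q if not sv.failed else np.nan,
                "avg_test_AUC": sv.avg_auc if not sv.failed else np.nan,
            }
            for f in DEFAULT_FRACTIONS:
                row[f"avg_test_EF{round(f * 100):g}%"] = (
                    sv.avg_ef(f) if not sv.failed else np.nan
                )
            for r, q in enumerate(sv.test_q, start=1):
                row[f"test_Q_rep{r}"] = q
            rows.append(row)
        return pd.DataFrame(rows)


def make_splits(
    table: ScoreTable,
    test_fraction: float = 0.2,
    repeats: int = 5,
    seed: int = 0,
) -> list[SplitPlan]:
    """Stratified random train/test splits, one per repeat.

    Repeat r uses its own derived seed (``seed + r``) so runs are reproducible
    and repeats independent.  The active fraction of each side matches the
    overall fraction to within one molecule, and every test set contains at
    least one active and one decoy.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    act_idx = np.flatnonzero(table.labels == 1)
    dec_idx = np.flatnonzero(table.labels == 0)
    n_test_act = int(round(test_fraction * len(act_idx)))
    n_test_act = min(max(n_test_act, 1), len(act_idx) - 1)
    n_test = int(round(test_fraction * table.n))
    n_test_dec = n_test - n_test_act
    if not 1 <= n_test_dec <= len(dec_idx) - 1:
        raise ValueError(
            "too few molecules per class for stratified splits; "
            "reduce repeats or test_fraction"
        )
    if len(act_idx) < repeats:
        raise ValueError(
            f"only {len(act_idx)} actives for {repeats} repeats; use fewer repeats"
        )
    splits = []
    for r in range(1, repeats + 1):
        rng = np.random.default_rng(seed + r)
        test_a = rng.choice(act_idx, size=n_test_act, replace=False)
        test_d = rng.choice(dec_idx, size=n_test_dec, replace=False)
        test = np.sort(np.concatenate([test_a, test_d]))
        mask = np.ones(table.n, dtype=bool)
        mask[test] = False
        splits.append(
            SplitPlan(repeat=r, train_idx=np.flatnonzero(mask), test_idx=test, seed=seed + r)
        )
    return splits


def _subtable(table: ScoreTable, idx: np.ndarray) -> ScoreTable:
    return ScoreTable(
        molecule_ids=table.molecule_ids[idx],
        labels=table.labels[idx],
        scores=table.scores.iloc[idx].reset_index(drop=True),
        properties=(
            table.properties.iloc[idx].reset_index(drop=True)
            if table.properties is not None
            else None
        ),
        source=table.source,
    )


def validate_subsets(
    table: ScoreTable,
    subsets: Sequence[tuple[str, ...]],
    splits: Sequence[SplitPlan],
    config: SearchConfig | None = None,
) -> ValidationReport:
    """Fit every subset on each training split, score it on the test split.

    Selection: maximal average test Q, ties broken by higher average test
    EF 1%, then lexicographic subset.  A subset whose optimization fails on
    any split is flagged and excluded from selection.
    """
    config = config or SearchConfig()
    subsets = [tuple(s) for s in subsets]
    results = {s: SubsetValidation(subset=s) for s in subsets}
    k_max = max(len(s) for s in subsets)
    columns = sorted({c for s in subsets for c in s})

    for split in splits:
        train = _subtable(table, split.train_idx)
        test = _subtable(table, split.test_idx)
        try:
            models = fit_all_subsets(train, columns, k_max, config)
        except Exception:
            # a global failure on this split invalidates every subset
            logger.exception("optimization failed on repeat %d", split.repeat)
            for sv in results.values():
                sv.failed = True
            continue
        for s in subsets:
            sv = results[s]
            try:
                _, profile, auc, qv = apply_model(
                    models[s], test, cluster_size=config.cluster_size
                )
            except Exception:
                logger.exception(
                    "subset %s failed on repeat %d; excluded", s, split.repeat
                )
                sv.failed = True
                continue
            sv.test_q.append(qv.q)
            sv.test_auc.append(auc)
            sv.test_ef.append(dict(profile.ef))

    viable = [s for s in subsets if not results[s].failed]
    if not viable:
        raise RuntimeError("every candidate subset failed validation")
    selected = min(
        viable,
        key=lambda s: (-results[s].avg_q, -results[s].avg_ef(0.01), s),
    )
    return ValidationReport(subsets=results, selected=selected, repeats=len(splits))


def finalize(
    table: ScoreTable,
    subset: tuple[str, ...],
    config: SearchConfig | None = None,
    warm_start: ConsensusModel | None = None,
) -> tuple[ConsensusModel, EnrichmentProfile, float]:
    """Refit the selected subset on the full table and report its metrics."""
    config = config or SearchConfig()
    if warm_start is None and config.warm_start and len(subset) >= 2:
        sub_models = [
            optimize_coefficients(table, s, config)
            for s in itertools.combinations(tuple(subset), len(subset) - 1)
        ]
        warm_start = max(sub_models, key=lambda m: m.train_quality.q)
    model = optimize_coefficients(table, subset, config, warm_start=warm_start)
    _, profile, auc, _ = apply_model(model, table, cluster_size=config.cluster_size)
    return model, profile, auc
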