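"""End-to-end screening: prefilter → enumerate → validate → finalize."""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .metrics import EnrichmentProfile
from .prefilter import (
    EffectivenessReport,
    VifReport,
    effectiveness_filter,
    vif_filter,
)
from .score_table import ScoreTable
from .search import ConsensusModel, SearchConfig, enumerate_subsets
from .validation import ValidationReport, finalize, make_splits, validate_subsets

__all__ = ["ScreenResult", "screen"]

logger = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    """Everything one screening run produces."""

    vif_report: VifReport
    effectiveness_report: EffectivenessReport
    surviving_columns: list[str]
    validation: ValidationReport
    model: ConsensusModel
    full_profile: EnrichmentProfile
    full_auc: float
    config: SearchConfig
    k: int
    repeats: int
    test_fraction: float


def screen(
    table: ScoreTable,
    k: int = 2,
    config: SearchConfig | None = None,
    vif_max: float = 5.0,
    min_ef5: float = 2.0,
    repeats: int = 5,
    test_fraction: float = 0.2,
) -> ScreenResult:
    """Run the full consensus-generation protocol on one score table.

    Interrelated columns (VIF > ``vif_max``) are discarded first, then
    individually ineffective ones (best-orientation EF5% < ``min_ef5``);
    all k-subsets of the survivors are validated by repeated stratified
    80/20 splits and the winner is refitted on the full table.
    """
    config = config or SearchConfig()
    if not 1 <= k <= 3:
        raise ValueError("k must be 1, 2 or 3")

    surviving, vif_rep = vif_filter(table, threshold=vif_max)
    logger.info(
        "VIF filter: %d/%d columns survive (removed: %s)",
        len(surviving), len(table.score_names),
        [name for name, _ in vif_rep.removal_sequence] or "none",
    )
    surviving, eff_rep = effectiveness_filter(table, surviving, min_ef=min_ef5)
    logger.info(
        "effectiveness filter: %d columns survive", len(surviving)
    )
    if k > len(surviving):
        raise ValueError(
            f"k={k} but only {len(surviving)} score columns survive the prefilters"
        )
    subsets = enumerate_subsets(surviving, k)
    splits = make_splits(
        table, test_fraction=test_fraction, repeats=repeats, seed=config.seed
    )
    report = validate_subsets(table, subsets, splits, config)
    model, profile, auc = finalize(table, report.selected, config)
    report.final_model = model
    report.final_profile = profile
    report.final_auc = auc
    return ScreenResult(
        vif_report=vif_rep,
        effectiveness_report=eff_rep,
        surviving_columns=surviving,
        validation=report,
        model=model,
        full_profile=profile,
        full_auc=auc,
        config=config,
        k=k,
        repeats=repeats,
        test_fraction=test_fraction,
    )
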