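"""DUD-like synthetic score tables with a planted linear signal.

The generator emulates the structure of a docking/rescoring benchmark table:
~3000 molecules of which fewer than 5% are active, and ~11 partially
redundant score columns.  A single latent "binding propensity" t drives all
scores:

    t        = u + effect_size * label,  u ~ N(0, 1)
    score_j  = loading_j * t + noise_sd_j * eps_j

so every column carries the same signal with its own loading and noise, which
reproduces the qualitative behaviour of real score sets (scores correlate
with each other, none is perfect, some are nearly useless).  Loadings are
negative by default — the energy convention, more negative = better — so the
pipeline must discover score orientation through coefficient signs.

Optional columns stress the prefilters: a near-duplicate of the first column
(pairwise r >= 0.999, VIF-filter bait) and a pure-noise zero-loading column
(effectiveness-filter bait).

Molecular-property columns (molecular weight 200-600 Da, heavy atoms 15-45)
are drawn independently of activity, purely to exercise normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .score_table import ScoreTable

__all__ = ["SyntheticConfig", "GroundTruth", "generate", "theoretical_best_subset"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for one benchmark table.

    n_molecules / n_active default to the DUD-scale 3000 / 80 (2.7% actives).
    ``effect_size`` is the latent mean shift of actives in latent SD units;
    2.0 yields single-score AUCs in the 0.75-0.9 range typical of competent
    docking scores.  ``loadings`` defaults to K=11 negative values tapering
    from -1.0 to -0.2; ``noise_sds`` defaults to 1.0 everywhere.
    """

    n_molecules: int = 3000
    n_active: int = 80
    n_scores: int = 11
    effect_size: float = 2.0
    loadings: tuple[float, ...] | None = None
    noise_sds: tuple[float, ...] | None = None
    include_duplicate: bool = False
    include_null: bool = False
    mw_range: tuple[float, float] = (200.0, 600.0)
    heavy_atom_range: tuple[int, int] = (15, 45)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_active < self.n_molecules:
            raise ValueError("need 0 < n_active < n_molecules")
        if self.n_scores < 1:
            raise ValueError("need at least one score column")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.loadings is not None and len(self.loadings) != self.n_scores:
            raise ValueError("loadings must have one value per score column")
        if self.noise_sds is not None:
            if len(self.noise_sds) != self.n_scores:
                raise ValueError("noise_sds must have one value per score column")
            if any(s < 0 for s in self.noise_sds):
                raise ValueError("noise sds must be >= 0")

    def resolved_loadings(self) -> np.ndarray:
        if self.loadings is not None:
            return np.asarray(self.loadings, dtype=float)
        return -np.linspace(1.0, 0.2, self.n_scores)

    def resolved_noise_sds(self) -> np.ndarray:
        if self.noise_sds is not None:
            return np.asarray(self.noise_sds, dtype=float)
        return np.ones(self.n_scores)


@dataclass
class GroundTruth:
    """What was planted: per-column loadings/noise and the latent effect."""

    loadings: np.ndarray
    noise_sds: np.ndarray
    effect_size: float
    seed: int
    column_names: list[str]
    active_fraction: float = 0.0
    duplicate_of: tuple[str, str] | None = None   # (copy, original)
    null_column: str | None = None


def generate(config: SyntheticConfig) -> tuple[ScoreTable, GroundTruth]:
    """Draw one labeled score table and its ground-truth record."""
    rng = np.random.default_rng(config.seed)
    n, a = config.n_molecules, config.n_active
    labels = np.zeros(n, dtype=int)
    labels[:a] = 1  # actives first; ids keep rows distinguishable
    loadings = config.resolved_loadings()
    noise = config.resolved_noise_sds()

    t = rng.standard_normal(n) + config.effect_size * labels
    eps = rng.standard_normal((n, config.n_scores))
    X = t[:, None] * loadings[None, :] + eps * noise[None, :]
    names = [f"score_{j + 1:02d}" for j in range(config.n_scores)]

    gt_loadings = list(loadings)
    gt_noise = list(noise)
    gt_names = list(names)
    duplicate_of = None
    null_column = None
    cols = [X[:, j] for j in range(config.n_scores)]
    if config.include_duplicate:
        # near-copy of column 1: tiny independent jitter keeps r >= 0.999
        base = cols[0]
        jitter_sd = 0.02 * float(base.std())
        dup = base + jitter_sd * rng.standard_normal(n)
        cols.append(dup)
        dup_name = f"{names[0]}_dup"
        gt_names.append(dup_name)
        gt_loadings.append(loadings[0])
        gt_noise.append(float(np.hypot(noise[0], jitter_sd)))
        duplicate_of = (dup_name, names[0])
    if config.include_null:
        cols.append(rng.standard_normal(n))
        gt_names.append("score_null")
        gt_loadings.append(0.0)
        gt_noise.append(1.0)
        null_column = "score_null"

    ids = np.array(
        [f"{'act' if l else 'dec'}_{i:05d}" for i, l in enumerate(labels)], dtype=object
    )
    scores = pd.DataFrame(
        {name: col for name, col in zip(gt_names, cols)}
    )
    props = pd.DataFrame(
        {
            "molecular_weight": rng.uniform(*config.mw_range, size=n),
            "heavy_atoms": rng.integers(
                config.heavy_atom_range[0], config.heavy_atom_range[1] + 1, size=n
            ).astype(float),
        }
    )
    table = ScoreTable(
        molecule_ids=ids,
        labels=labels,
        scores=scores,
        properties=props,
        source=f"synthetic(seed={config.seed})",
    )
    truth = GroundTruth(
        loadings=np.asarray(gt_loadings),
        noise_sds=np.asarray(gt_noise),
        effect_size=config.effect_size,
        seed=config.seed,
        column_names=gt_names,
        active_fraction=a / n,
        duplicate_of=duplicate_of,
        null_column=null_column,
    )
    return table, truth


def theoretical_best_subset(
    truth: GroundTruth, k: int, exclude_planted_extras: bool = True
) -> tuple[tuple[str, ...], np.ndarray]:
    """The k most informative columns and the implied optimal direction.

    Columns are ranked by signal-to-noise |loading| / noise_sd (ties broken
    lexicographically by name).  The direction is the linear-discriminant
    direction on the selected columns — under the generator's
    equal-covariance Gaussian model it maximizes every monotone
    early-recognition criterion, including the cluster quality Q:

        w_raw ∝ Σ_within^{-1} m,   m_j = loading_j * effect_size,
        Σ_within = loadings loadingsᵀ + diag(noise_sd²),

    re-expressed on the standardized columns the pipeline actually combines
    (coefficients scale with each column's population SD).

    ``exclude_planted_extras`` omits the duplicate/null bait columns, which
    the prefilters are expected to remove before subset enumeration.
    """
    names = list(truth.column_names)
    keep = []
    for name in names:
        if exclude_planted_extras and (
            name == truth.null_column
            or (truth.duplicate_of is not None and name == truth.duplicate_of[0])
        ):
            continue
        keep.append(name)
    idx = {n: i for i, n in enumerate(names)}
    snr = {n: abs(truth.loadings[idx[n]]) / max(truth.noise_sds[idx[n]], 1e-300) for n in keep}
    chosen = tuple(sorted(sorted(keep), key=lambda n: -snr[n])[:k])
    chosen = tuple(sorted(chosen))

    lam = np.array([truth.loadings[idx[n]] for n in chosen])
    sig = np.array([truth.noise_sds[idx[n]] for n in chosen])
    delta = truth.effect_size
    # raw-space LDA direction, then map onto the standardized columns:
    # combined = sum_j w_raw_j x_j = sum_j (w_raw_j * sd_j) z_j + const
    W = np.outer(lam, lam) + np.diag(sig**2)
    w_raw = np.linalg.solve(W, lam * delta)
    p = truth.active_fraction
    var_t = 1.0 + delta**2 * p * (1.0 - p)
    mixture_sd = np.sqrt(lam**2 * var_t + sig**2)
    w = w_raw * mixture_sd
    w = w / np.linalg.norm(w)
    return chosen, w
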