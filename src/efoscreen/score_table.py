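"""Labeled score tables for active/decoy virtual-screening benchmarks.

A :class:`ScoreTable` holds one row per docked molecule: a unique identifier,
a binary activity label (1 = active, 0 = decoy), one or more named numeric
score columns (docking / rescoring outputs such as ChemPLP, PLP, X-Score,
force-field interaction terms), and optional positive molecular-property
columns (molecular weight in Da, heavy-atom count) used only for score
normalization.

Column roles are explicit: the id and label columns are named by the caller,
property columns are matched against a fixed set of recognized names, and
every remaining column is a score.  Missing values are a hard load error —
a screening pipeline computes every score for every pose, so a hole in the
table signals an upstream failure, not something to impute.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScoreTable",
    "ScoreTableError",
    "KNOWN_PROPERTIES",
    "read_score_table",
    "write_score_table",
    "normalize_score",
]

#: Column names recognized as molecular properties (normalization denominators).
KNOWN_PROPERTIES = ("molecular_weight", "heavy_atoms")


class ScoreTableError(ValueError):
    """Raised when a score table violates its invariants at load or use."""


@dataclass
class ScoreTable:
    """Labeled molecules x named score columns.

    Parameters
    ----------
    molecule_ids : sequence of str
        Unique molecule identifiers, one per row.
    labels : array-like of {0, 1}
        Activity labels; 1 = active, 0 = decoy.
    scores : pandas.DataFrame
        Numeric score columns, aligned row-wise with ``molecule_ids``.
    properties : pandas.DataFrame, optional
        Positive numeric property columns (e.g. molecular weight).
    source : str
        Free-text provenance note.
    """

    molecule_ids: np.ndarray
    labels: np.ndarray
    scores: pd.DataFrame
    properties: pd.DataFrame | None = None
    source: str = ""
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=object)
        self.labels = np.asarray(self.labels)
        if not self._validated:
            self.validate()
            self._validated = True

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        n = len(self.molecule_ids)
        if n < 2:
            raise ScoreTableError(f"need at least 2 molecules, got {n}")
        ids, counts = np.unique(self.molecule_ids.astype(str), return_counts=True)
        if (counts > 1).any():
            dupes = ", ".join(ids[counts > 1][:5])
            raise ScoreTableError(f"duplicate molecule ids: {dupes}")
        if self.labels.shape != (n,):
            raise ScoreTableError("labels must be one value per molecule")
        lab = pd.Series(self.labels)
        if lab.isna().any():
            raise ScoreTableError("labels contain missing values")
        if not set(np.unique(self.labels.astype(int))) <= {0, 1}:
            raise ScoreTableError("labels must be binary (0 = decoy, 1 = active)")
        self.labels = self.labels.astype(np.int64)
        n_active = int(self.labels.sum())
        if n_active == 0 or n_active == n:
            raise ScoreTableError(
                f"need at least one active and one decoy (got {n_active}/{n} actives)"
            )
        if self.scores.shape[1] == 0:
            raise ScoreTableError("table has no score columns")
        if len(self.scores) != n:
            raise ScoreTableError("scores not aligned with molecule ids")
        for col in self.scores.columns:
            vals = self.scores[col]
            if not np.issubdtype(vals.dtype, np.number):
                raise ScoreTableError(f"score column {col!r} is not numeric")
            if vals.isna().any():
                rows = list(np.asarray(self.molecule_ids)[vals.isna().to_numpy()][:5])
                raise ScoreTableError(f"missing values in score column {col!r}: rows {rows}")
        if self.scores.columns.duplicated().any():
            raise ScoreTableError("duplicate score column names")
        if self.properties is not None:
            if len(self.properties) != n:
                raise ScoreTableError("properties not aligned with molecule ids")
            for col in self.properties.columns:
                if self.properties[col].isna().any():
                    raise ScoreTableError(f"missing values in property column {col!r}")

    # -- convenience -----------------------------------------------------

    @property
    def n(self) -> int:
        """Number of molecules N."""
        return len(self.molecule_ids)

    @property
    def n_active(self) -> int:
        """Number of actives A."""
        return int(self.labels.sum())

    @property
    def score_names(self) -> list[str]:
        return list(self.scores.columns)

    def score_matrix(self, columns: Sequence[str] | None = None) -> np.ndarray:
        cols = list(columns) if columns is not None else self.score_names
        missing = [c for c in cols if c not in self.scores.columns]
        if missing:
            raise ScoreTableError(f"missing score columns: {missing}")
        return np.ascontiguousarray(self.scores[cols].to_numpy(dtype=np.float64))

    def to_frame(self, id_col: str = "id", label_col: str = "active") -> pd.DataFrame:
        """Canonical frame: id, label, properties, scores (in that order)."""
        data: dict[str, object] = {
            id_col: self.molecule_ids.astype(str),
            label_col: self.labels,
        }
        if self.properties is not None:
            for col in self.properties.columns:
                data[col] = self.properties[col].to_numpy()
        for col in self.scores.columns:
            data[col] = self.scores[col].to_numpy()
        return pd.DataFrame(data)


def _resolve_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_score_table(
    path: str | Path,
    id_col: str = "id",
    label_col: str = "active",
    property_cols: Sequence[str] | None = None,
    delimiter: str | None = None,
) -> ScoreTable:
    """Read a delimited score table with header.

    Every column other than ``id_col``, ``label_col`` and the property columns
    is registered as a score.  Property columns default to any column whose
    name is in :data:`KNOWN_PROPERTIES`.  Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise ScoreTableError(f"no such file: {path}")
    sep = _resolve_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    for col in (id_col, label_col):
        if col not in df.columns:
            raise ScoreTableError(f"required column {col!r} not found in {path.name}")
    labels_raw = df[label_col]
    if labels_raw.dtype == object:
        mapping = {"true": 1, "false": 0, "1": 1, "0": 0}
        labels = labels_raw.astype(str).str.strip().str.lower().map(mapping)
        if labels.isna().any():
            raise ScoreTableError(f"label column {label_col!r} must contain only 0/1 or true/false")
        labels = labels.to_numpy()
    else:
        labels = labels_raw.to_numpy()
    if property_cols is None:
        property_cols = [c for c in df.columns if c in KNOWN_PROPERTIES]
    else:
        missing = [c for c in property_cols if c not in df.columns]
        if missing:
            raise ScoreTableError(f"property columns not found: {missing}")
    score_cols = [c for c in df.columns if c not in {id_col, label_col, *property_cols}]
    for col in score_cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ScoreTableError(
                f"non-numeric value {df[col].iloc[row]!r} in score column {col!r}, row {row + 2}"
            )
        df[col] = converted
    props = df[list(property_cols)].astype(float) if property_cols else None
    return ScoreTable(
        molecule_ids=df[id_col].astype(str).to_numpy(dtype=object),
        labels=labels,
        scores=df[score_cols].reset_index(drop=True),
        properties=props.reset_index(drop=True) if props is not None else None,
        source=str(path),
    )


def _fmt(x: float) -> str:
    # shortest decimal rendering that round-trips float64
    return repr(float(x))


def write_score_table(
    table: ScoreTable,
    path: str | Path,
    id_col: str = "id",
    label_col: str = "active",
    delimiter: str | None = None,
) -> None:
    """Write the canonical delimited form: id, label, properties, scores.

    Floats are rendered with full (round-trip) precision so that
    ``read_score_table(write_score_table(t))`` reproduces ``t`` exactly and
    re-serialization is byte-identical.
    """
    path = Path(path)
    sep = _resolve_delimiter(path, delimiter)
    frame = table.to_frame(id_col=id_col, label_col=label_col)
    lines = [sep.join(frame.columns)]
    float_cols = {c for c in frame.columns if np.issubdtype(frame[c].dtype, np.floating)}
    for _, row in frame.iterrows():
        cells = [
            _fmt(row[c]) if c in float_cols else str(row[c])
            for c in frame.columns
        ]
        lines.append(sep.join(cells))
    path.write_text("\n".join(lines) + "\n")


def normalize_score(table: ScoreTable, score: str, property: str) -> ScoreTable:
    """Append the size-normalized column ``<score>_per_<property>``.

    Dividing an energy-like score by molecular weight (or heavy-atom count)
    removes the ligand-size bias that inflates raw interaction scores for
    large molecules.  The original column is left untouched.
    """
    if score not in table.scores.columns:
        raise ScoreTableError(f"no score column {score!r}")
    if table.properties is None or property not in table.properties.columns:
        raise ScoreTableError(f"no property column {property!r}")
    prop = table.properties[property].to_numpy(dtype=float)
    nonpos = prop <= 0
    if nonpos.any():
        offender = table.molecule_ids[np.flatnonzero(nonpos)[0]]
        raise ScoreTableError(
            f"property {property!r} must be positive; molecule {offender!r} has {prop[nonpos][0]}"
        )
    new_name = f"{score}_per_{property}"
    if new_name in table.scores.columns:
        raise ScoreTableError(f"column {new_name!r} already exists")
    scores = table.scores.copy()
    scores[new_name] = scores[score].to_numpy(dtype=float) / prop
    return replace(table, scores=scores, _validated=False)
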