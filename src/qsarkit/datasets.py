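"""Compound/descriptor/activity tables: containers, I/O, and conversions.

The central container is :class:`QSARDataset`, an ordered collection of
:class:`CompoundRecord` sharing one descriptor-name list.  Activities are
pIC50 values (the negative base-10 logarithm of the molar IC50); splits are
``train`` / ``test`` / ``unassigned``.  Missing cells are stored as *absent*
(the descriptor key is simply not present), never as zero — operations that
need a column raise rather than impute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompoundRecord",
    "QSARDataset",
    "ParseError",
    "ic50_to_pic50",
    "load_table",
    "write_table",
    "split_dataset",
]

SPLITS = ("train", "test", "unassigned")


class ParseError(ValueError):
    """Raised when a delimited compound table cannot be interpreted."""


def ic50_to_pic50(ic50_um):
    """Convert an IC50 in micromolar to pIC50 = −log10(IC50 in mol/L).

    Since 1 μM = 1e-6 mol/L this is ``6 − log10(ic50_um)``; e.g. 0.016 μM
    → 7.7959, 1 μM → 6.  Accepts scalars or array-likes; strictly positive
    input required.

    Parameters
    ----------
    ic50_um : float or array-like
        Half-maximal inhibitory concentration in μM.

    Returns
    -------
    float or ndarray
        pIC50 (dimensionless; higher = more potent).
    """
    arr = np.asarray(ic50_um, dtype=float)
    if np.any(~(arr > 0)):
        raise ValueError(f"IC50 must be strictly positive, got {ic50_um!r}")
    out = 6.0 - np.log10(arr)
    return float(out) if np.isscalar(ic50_um) or arr.ndim == 0 else out


@dataclass
class CompoundRecord:
    """One compound: identifier, descriptors, activity, and annotations.

    Parameters
    ----------
    id : str
        Compound label (e.g. ``"10b"``).
    descriptors : dict
        Descriptor-name → value.  A missing descriptor is an absent key.
    activity : float, optional
        pIC50.  Required for records labelled ``train`` or ``test``.
    split : {"train", "test", "unassigned"}
    properties : dict, optional
        Physicochemical properties (MW in Da, LogP, TPSA in Å², ...).
    binding_affinity : float, optional
        Docking score in kcal/mol (more negative = stronger binding).
    """

    id: str
    descriptors: dict[str, float] = field(default_factory=dict)
    activity: float | None = None
    split: str = "unassigned"
    properties: dict[str, float] | None = None
    binding_affinity: float | None = None

    def __post_init__(self) -> None:
        if self.split not in SPLITS:
            raise ValueError(f"split must be one of {SPLITS}, got {self.split!r}")
        if self.split in ("train", "test") and self.activity is None:
            raise ValueError(
                f"compound {self.id!r}: activity required for split {self.split!r}"
            )


@dataclass
class QSARDataset:
    """Ordered compound collection with a shared descriptor-name list.

    Invariants enforced on construction: no duplicate compound ids; every
    record's descriptor keys are a subset of ``descriptor_names``; train and
    test subsets are disjoint by construction of the split label.
    """

    records: list[CompoundRecord]
    descriptor_names: list[str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate compound id {rec.id!r}")
            seen.add(rec.id)
            extra = set(rec.descriptors) - set(self.descriptor_names)
            if extra:
                raise ValueError(
                    f"compound {rec.id!r} has descriptors not in the dataset "
                    f"descriptor list: {sorted(extra)}"
                )

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    def __getitem__(self, compound_id: str) -> CompoundRecord:
        for rec in self.records:
            if rec.id == compound_id:
                return rec
        raise KeyError(compound_id)

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    # -- subsets -----------------------------------------------------------
    def subset(self, split: str) -> "QSARDataset":
        """Return the records carrying a given split label ("all" for every record)."""
        if split == "all":
            recs = list(self.records)
        else:
            if split not in SPLITS:
                raise ValueError(f"unknown subset {split!r}")
            recs = [r for r in self.records if r.split == split]
        return QSARDataset(recs, list(self.descriptor_names))

    @property
    def train(self) -> "QSARDataset":
        return self.subset("train")

    @property
    def test(self) -> "QSARDataset":
        return self.subset("test")

    # -- numeric views -----------------------------------------------------
    def descriptor_matrix(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Dense (n_records, n_descriptors) matrix; raises on absent cells."""
        names = list(self.descriptor_names if names is None else names)
        X = np.empty((len(self.records), len(names)))
        for i, rec in enumerate(self.records):
            for j, name in enumerate(names):
                if name not in rec.descriptors:
                    raise ValueError(
                        f"compound {rec.id!r} is missing descriptor {name!r}"
                    )
                X[i, j] = rec.descriptors[name]
        return X

    def activities(self) -> np.ndarray:
        """Activity vector; raises if any record lacks an activity."""
        out = np.empty(len(self.records))
        for i, rec in enumerate(self.records):
            if rec.activity is None:
                raise ValueError(f"compound {rec.id!r} has no activity")
            out[i] = rec.activity
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: id column, descriptor columns, pIC50, split."""
        rows = []
        for rec in self.records:
            row: dict[str, object] = {"compound": rec.id}
            for name in self.descriptor_names:
                row[name] = rec.descriptors.get(name, math.nan)
            row["pIC50"] = math.nan if rec.activity is None else rec.activity
            row["split"] = rec.split
            if rec.binding_affinity is not None:
                row["binding_affinity"] = rec.binding_affinity
            rows.append(row)
        return pd.DataFrame(rows)


def load_table(
    path: str | Path,
    *,
    id_column: str = "compound",
    activity_column: str = "pIC50",
    split_column: str = "split",
    affinity_column: str = "binding_affinity",
    descriptor_columns: Sequence[str] | None = None,
    sep: str = ",",
) -> QSARDataset:
    """Read a delimited compound table into a :class:`QSARDataset`.

    Expects a header row with one id column; every column that is not the
    id, activity, split, or binding-affinity column is taken as a descriptor
    unless ``descriptor_columns`` narrows the choice.  Empty cells become
    absent values.  Duplicate ids or non-numeric cells in numeric columns
    raise :class:`ParseError` naming the offending row/column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    if df.empty and len(df.columns) == 0:
        raise ParseError(f"{path}: no columns found")
    if id_column not in df.columns:
        raise ParseError(f"{path}: missing id column {id_column!r}")

    ids = df[id_column].astype(str)
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise ParseError(f"{path}: duplicate compound ids {sorted(set(dup))}")

    special = {id_column, activity_column, split_column, affinity_column}
    if descriptor_columns is None:
        descriptor_columns = [c for c in df.columns if c not in special]
    else:
        missing = set(descriptor_columns) - set(df.columns)
        if missing:
            raise ParseError(f"{path}: descriptor columns not found: {sorted(missing)}")

    numeric_cols = list(descriptor_columns)
    for col in (activity_column, affinity_column):
        if col in df.columns:
            numeric_cols.append(col)
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric value {df.loc[bad[0], col]!r} in "
                f"column {col!r}, row {bad[0] + 2}"  # +2: header + 1-based
            )
        df[col] = coerced

    records = []
    for i, row in df.iterrows():
        desc = {
            name: float(row[name])
            for name in descriptor_columns
            if pd.notna(row[name])
        }
        activity = None
        if activity_column in df.columns and pd.notna(row[activity_column]):
            activity = float(row[activity_column])
        split = "unassigned"
        if split_column in df.columns and pd.notna(row[split_column]):
            split = str(row[split_column])
        affinity = None
        if affinity_column in df.columns and pd.notna(row[affinity_column]):
            affinity = float(row[affinity_column])
        records.append(
            CompoundRecord(
                id=str(row[id_column]),
                descriptors=desc,
                activity=activity,
                split=split,
                binding_affinity=affinity,
            )
        )
    return QSARDataset(records, list(descriptor_columns))


def write_table(ds: QSARDataset, path: str | Path, *, sep: str = ",") -> None:
    """Write a dataset as delimited text preserving full float precision."""
    # default float formatting is shortest-roundtrip, preserving every bit
    ds.to_frame().to_csv(path, sep=sep, index=False)


def split_dataset(ds: QSARDataset, train_fraction: float, seed: int) -> QSARDataset:
    """Randomly assign train/test labels, overwriting any existing ones.

    ``round(n · train_fraction)`` records become the training set; the rest
    the test set.  The assignment is a deterministic function of ``seed``.
    Only records with an activity can be assigned, and at least two are
    required.
    """
    if not 0.0 < train_fraction <= 1.0:
        raise ValueError(f"train_fraction must be in (0, 1], got {train_fraction}")
    with_activity = [r for r in ds.records if r.activity is not None]
    if len(with_activity) < 2:
        raise ValueError("need at least 2 records with activity to split")

    n = len(with_activity)
    n_train = int(round(n * train_fraction))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_ids = {with_activity[i].id for i in order[:n_train]}

    records = []
    for rec in ds.records:
        if rec.activity is None:
            records.append(replace(rec, split="unassigned"))
        else:
            records.append(
                replace(rec, split="train" if rec.id in train_ids else "test")
            )
    return QSARDataset(records, list(ds.descriptor_names))
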