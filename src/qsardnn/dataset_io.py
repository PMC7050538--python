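"""Activity tables in the competition CSV layout, and vocabulary alignment.

A dataset split is one CSV per target: a molecule-identifier column
(default ``MOLECULE``), an activity column (default ``Act``) and one
column per substructure descriptor holding a non-negative integer count.
The distributed files omit descriptor columns that are all-zero within a
split, so the train and test matrices of one target usually disagree on
their column sets; :func:`align_vocabularies` restores a shared ordered
vocabulary by zero-filling the missing columns in each split.

Activities carry their native units (pIC50, log D, percent remaining,
...) and are never rescaled or centred here — they are already on a
logarithmic or bounded scale by construction of the assays.
"""

from __future__ import annotations

import csv
import gzip
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ActivityTable",
    "AlignedDataset",
    "read_activity_table",
    "write_activity_table",
    "align_vocabularies",
    "log_transform",
    "expected_mmac_summary",
    "verify_against_summary",
]

DEFAULT_ID_COLUMN = "MOLECULE"
DEFAULT_ACTIVITY_COLUMN = "Act"


@dataclass
class ActivityTable:
    """One split of one target: ids, activities, integer count matrix."""

    molecule_ids: list[str]
    activities: np.ndarray
    descriptors: pd.DataFrame

    def __post_init__(self) -> None:
        self.activities = np.asarray(self.activities, dtype=float)
        n = len(self.molecule_ids)
        if self.activities.shape != (n,):
            raise ValueError(
                f"{n} molecule ids but {self.activities.shape} activities"
            )
        if len(self.descriptors) != n:
            raise ValueError(
                f"{n} molecule ids but {len(self.descriptors)} descriptor rows"
            )
        if not np.all(np.isfinite(self.activities)):
            bad = int(np.flatnonzero(~np.isfinite(self.activities))[0])
            raise ValueError(
                f"non-finite activity for molecule {self.molecule_ids[bad]!r} "
                f"(row {bad})"
            )
        cols = self.descriptors.columns
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].tolist()
            raise ValueError(f"duplicate descriptor columns: {dupes}")
        if len(cols) and (self.descriptors.to_numpy() < 0).any():
            raise ValueError("negative descriptor counts are not allowed")

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_ids)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.descriptors.columns)

    def matrix(self, dtype=np.float64) -> np.ndarray:
        """Descriptor matrix as a dense array (one row per molecule)."""
        return self.descriptors.to_numpy(dtype=dtype)


@dataclass
class AlignedDataset:
    """Train and test splits sharing one ordered descriptor vocabulary."""

    train: ActivityTable
    test: ActivityTable
    vocabulary: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.train.descriptor_names != self.test.descriptor_names:
            raise ValueError("train and test do not share an ordered vocabulary")
        if not self.vocabulary:
            self.vocabulary = self.train.descriptor_names
        elif self.vocabulary != self.train.descriptor_names:
            raise ValueError("vocabulary does not match the table columns")

    @property
    def n_descriptors(self) -> int:
        return len(self.vocabulary)


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode, encoding="utf-8")
    return open(path, mode, encoding="utf-8", newline="")


def read_activity_table(
    path,
    id_column: str = DEFAULT_ID_COLUMN,
    activity_column: str = DEFAULT_ACTIVITY_COLUMN,
) -> ActivityTable:
    """Read one split from CSV (``.gz`` handled transparently).

    Missing descriptor cells become 0; a missing or non-numeric activity
    is an error naming the offending row.
    """
    with _open_text(path) as fh:
        header = next(csv.reader(fh))
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise ValueError(f"duplicate column names in {path}: {dupes}")
    for required in (id_column, activity_column):
        if required not in header:
            raise ValueError(f"column {required!r} missing from {path}")

    df = pd.read_csv(path, dtype={id_column: str}, float_precision="round_trip")
    ids = df[id_column].tolist()
    act_raw = pd.to_numeric(df[activity_column], errors="coerce")
    bad = act_raw.index[act_raw.isna()]
    if len(bad):
        row = int(bad[0])
        raise ValueError(
            f"non-numeric activity {df[activity_column].iloc[row]!r} for "
            f"molecule {ids[row]!r} (row {row}) in {path}"
        )
    desc = df.drop(columns=[id_column, activity_column])
    desc = desc.fillna(0)
    try:
        desc = desc.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric descriptor value in {path}: {exc}") from exc
    return ActivityTable(
        molecule_ids=ids,
        activities=act_raw.to_numpy(dtype=float),
        descriptors=desc,
    )


def write_activity_table(
    table: ActivityTable,
    path,
    id_column: str = DEFAULT_ID_COLUMN,
    activity_column: str = DEFAULT_ACTIVITY_COLUMN,
) -> None:
    """Write a split back to the competition CSV layout."""
    df = pd.DataFrame({id_column: table.molecule_ids})
    df[activity_column] = table.activities
    out = pd.concat([df, table.descriptors.reset_index(drop=True)], axis=1)
    compression = "gzip" if str(path).endswith(".gz") else None
    # %.17g round-trips doubles exactly through the text representation
    out.to_csv(path, index=False, compression=compression, float_format="%.17g")


def align_vocabularies(train: ActivityTable, test: ActivityTable) -> AlignedDataset:
    """Unify the two splits' descriptor vocabularies by zero-filling.

    The merged vocabulary is the sorted union of both column sets;
    counts of shared columns are preserved exactly, and a column absent
    from one split appears there as all-zero.
    """
    vocabulary = sorted(set(train.descriptor_names) | set(test.descriptor_names))

    def _reindex(table: ActivityTable) -> ActivityTable:
        desc = table.descriptors.reindex(columns=vocabulary, fill_value=0)
        return replace(table, descriptors=desc)

    return AlignedDataset(
        train=_reindex(train), test=_reindex(test), vocabulary=vocabulary
    )


def log_transform(table: ActivityTable) -> ActivityTable:
    """Replace each descriptor count x by log(1+x); activities untouched.

    log(1+x) rather than log(x) because count matrices are mostly zeros;
    it maps 0 to 0 and is finite everywhere on valid input.
    """
    values = table.matrix()
    if (values < 0).any():
        raise ValueError("cannot log-transform negative descriptor counts")
    transformed = pd.DataFrame(
        np.log1p(values), columns=table.descriptor_names, index=table.descriptors.index
    )
    return replace(table, descriptors=transformed)


# -- published dataset summary ---------------------------------------------

#: Per-target (training molecules, test molecules, merged descriptors) of the
#: 15 competition datasets, as published with the post-analysis study. Useful
#: for verifying a local copy of the distributed CSVs.
_MMAC_SUMMARY = {
    "3A4": (37241, 12338, 9491),
    "CB1": (8716, 2907, 5877),
    "DPP4": (6148, 2045, 5203),
    "HIVINT": (1815, 598, 4306),
    "HIVPROT": (3212, 1072, 6274),
    "LOGD": (37388, 12406, 8921),
    "METAB": (1569, 523, 4505),
    "NK1": (9965, 3335, 5803),
    "OX1": (5351, 1769, 4730),
    "OX2": (11151, 3704, 5790),
    "PGP": (6399, 2093, 5135),
    "PPB": (8651, 2899, 5470),
    "RAT_F": (6105, 1707, 5698),
    "TDI": (4165, 1382, 5945),
    "THROMBIN": (5059, 1698, 5552),
}


def expected_mmac_summary() -> pd.DataFrame:
    """Published per-target molecule and merged-descriptor counts."""
    return pd.DataFrame.from_dict(
        _MMAC_SUMMARY,
        orient="index",
        columns=["n_train", "n_test", "n_descriptors_merged"],
    ).rename_axis("target")


def verify_against_summary(target: str, dataset: AlignedDataset) -> dict[str, bool]:
    """Check an aligned dataset against the published counts for a target."""
    if target not in _MMAC_SUMMARY:
        raise KeyError(f"unknown target {target!r}")
    n_train, n_test, n_desc = _MMAC_SUMMARY[target]
    return {
        "n_train": dataset.train.n_molecules == n_train,
        "n_test": dataset.test.n_molecules == n_test,
        "n_descriptors_merged": dataset.n_descriptors == n_desc,
    }
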