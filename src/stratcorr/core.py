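"""Tabular subject data model and CSV I/O.

A :class:`Dataset` holds one row per subject with three blocks: a group
label, a block of classification features (biomarkers, test scores) and a
block of nuisance features (age, gender, education, ...). All downstream
operations — regression correction, stratification, classification,
cross-validation — consume this container.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["Dataset", "DatasetSchema", "GroupPair", "read_dataset", "write_dataset"]


@dataclass(frozen=True)
class DatasetSchema:
    """Column-role mapping for a subject CSV.

    Parameters
    ----------
    id_col : name of the subject-identifier column.
    group_col : name of the group-label column.
    feature_cols : columns holding classification features.
    nuisance_cols : columns holding nuisance features.
    """

    id_col: str
    group_col: str
    feature_cols: tuple[str, ...]
    nuisance_cols: tuple[str, ...]

    def __post_init__(self) -> None:
        feats = tuple(self.feature_cols)
        nuis = tuple(self.nuisance_cols)
        object.__setattr__(self, "feature_cols", feats)
        object.__setattr__(self, "nuisance_cols", nuis)
        if len(set(feats)) != len(feats):
            raise ValueError("duplicate classification-feature column names")
        if len(set(nuis)) != len(nuis):
            raise ValueError("duplicate nuisance-feature column names")
        overlap = set(feats) & set(nuis)
        if overlap:
            raise ValueError(f"columns assigned to both roles: {sorted(overlap)}")
        reserved = {self.id_col, self.group_col}
        if reserved & (set(feats) | set(nuis)):
            raise ValueError("id/group column also assigned a feature role")


@dataclass(frozen=True)
class GroupPair:
    """The two study groups being discriminated, plus the reference group.

    The reference group is the label whose subjects carry no disease-related
    variability (typically healthy controls); the regression correction is
    fitted on it. It may coincide with ``group_a`` (e.g. controls vs AD) or
    be a third label outside the pair (e.g. controls in a stable-vs-
    progressive MCI comparison).
    """

    group_a: str
    group_b: str
    reference_group: str | None = None

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("group_a and group_b must differ")

    @property
    def labels(self) -> tuple[str, str]:
        return (self.group_a, self.group_b)

    def resolve_reference(self, groups: Sequence[str]) -> str:
        """Reference label to use given the labels present in a dataset.

        Defaults to an explicit ``reference_group``; otherwise ``group_a``.
        """
        if self.reference_group is not None:
            if self.reference_group not in set(groups):
                raise ValueError(
                    f"reference group {self.reference_group!r} absent from dataset"
                )
            return self.reference_group
        return self.group_a


class Dataset:
    """Subjects x features table with group labels and missing-value support.

    All blocks share one subject ordering. Missing values are NaN.
    """

    def __init__(
        self,
        subject_ids: Sequence,
        groups: Sequence[str],
        features: pd.DataFrame,
        nuisance: pd.DataFrame,
    ) -> None:
        ids = pd.Index(subject_ids, name="subject_id")
        if ids.has_duplicates:
            dupes = ids[ids.duplicated()].unique().tolist()
            raise ValueError(f"duplicate subject ids: {dupes}")
        n = len(ids)
        groups = pd.Series(np.asarray(groups, dtype=object), index=ids, name="group")
        if len(groups) != n:
            raise ValueError("groups length does not match subject count")
        features = features.astype(float).set_axis(ids, axis=0)
        nuisance = nuisance.astype(float).set_axis(ids, axis=0)
        if len(features) != n or len(nuisance) != n:
            raise ValueError("feature/nuisance block row count mismatch")
        overlap = set(features.columns) & set(nuisance.columns)
        if overlap:
            raise ValueError(f"column names shared across blocks: {sorted(overlap)}")
        for block in (features, nuisance):
            if block.columns.has_duplicates:
                raise ValueError("duplicate column names within a block")
        self.subject_ids = ids
        self.groups = groups
        self.features = features
        self.nuisance = nuisance

    # -- basic introspection -------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def nuisance_names(self) -> list[str]:
        return list(self.nuisance.columns)

    @property
    def group_labels(self) -> list[str]:
        return sorted(self.groups.unique())

    def group_mask(self, *labels: str) -> np.ndarray:
        return self.groups.isin(labels).to_numpy()

    # -- manipulation --------------------------------------------------------

    def subset_subjects(self, mask: Sequence[bool]) -> "Dataset":
        """Subjects where ``mask`` is true, original order, metadata unchanged."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_subjects,):
            raise ValueError(
                f"mask length {mask.size} != subject count {self.n_subjects}"
            )
        return Dataset(
            self.subject_ids[mask],
            self.groups.iloc[mask].to_numpy(),
            self.features.iloc[mask],
            self.nuisance.iloc[mask],
        )

    def subset_by_ids(self, ids: Sequence) -> "Dataset":
        """Subjects with the given ids, in the order given."""
        idx = self.subject_ids.get_indexer(pd.Index(ids))
        if (idx < 0).any():
            raise KeyError("unknown subject id in selection")
        return Dataset(
            self.subject_ids[idx],
            self.groups.iloc[idx].to_numpy(),
            self.features.iloc[idx],
            self.nuisance.iloc[idx],
        )

    def with_features(self, features: pd.DataFrame) -> "Dataset":
        """Same subjects/groups/nuisance with a replaced feature block."""
        return Dataset(self.subject_ids, self.groups.to_numpy(), features, self.nuisance)

    def copy(self) -> "Dataset":
        return Dataset(
            self.subject_ids,
            self.groups.to_numpy(),
            self.features.copy(),
            self.nuisance.copy(),
        )

    def to_frame(self, id_col: str = "subject_id", group_col: str = "group") -> pd.DataFrame:
        out = pd.DataFrame({id_col: self.subject_ids, group_col: self.groups.to_numpy()})
        out = pd.concat(
            [out, self.features.reset_index(drop=True), self.nuisance.reset_index(drop=True)],
            axis=1,
        )
        return out

    def schema(self, id_col: str = "subject_id", group_col: str = "group") -> DatasetSchema:
        return DatasetSchema(
            id_col, group_col, tuple(self.feature_names), tuple(self.nuisance_names)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            self.subject_ids.equals(other.subject_ids)
            and self.groups.equals(other.groups)
            and self.features.equals(other.features)
            and self.nuisance.equals(other.nuisance)
        )

    def __repr__(self) -> str:
        return (
            f"Dataset(n={self.n_subjects}, features={len(self.features.columns)}, "
            f"nuisance={len(self.nuisance.columns)}, groups={self.group_labels})"
        )


def read_dataset(path: str | Path, schema: DatasetSchema | Mapping) -> Dataset:
    """Read a subject CSV into a :class:`Dataset`.

    The CSV is comma-separated with a header row; empty cells are missing.
    ``schema`` assigns every used column a role (see :class:`DatasetSchema`;
    a mapping with the same keys is accepted).
    """
    if isinstance(schema, Mapping):
        schema = DatasetSchema(
            schema["id_col"],
            schema["group_col"],
            tuple(schema["feature_cols"]),
            tuple(schema["nuisance_cols"]),
        )
    df = pd.read_csv(path, dtype={schema.id_col: str, schema.group_col: str})
    wanted = [schema.id_col, schema.group_col, *schema.feature_cols, *schema.nuisance_cols]
    missing = [c for c in wanted if c not in df.columns]
    if missing:
        raise ValueError(f"columns named in schema absent from {path}: {missing}")
    return Dataset(
        df[schema.id_col].tolist(),
        df[schema.group_col].tolist(),
        df[list(schema.feature_cols)],
        df[list(schema.nuisance_cols)],
    )


def write_dataset(
    dataset: Dataset,
    path: str | Path,
    id_col: str = "subject_id",
    group_col: str = "group",
) -> None:
    """Write a :class:`Dataset` as CSV (full float precision; NaN -> empty cell)."""
    dataset.to_frame(id_col, group_col).to_csv(path, index=False, float_format="%.17g")
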