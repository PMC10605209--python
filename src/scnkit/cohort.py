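"""Cohort-level data containers: regional gray-matter volumes and covariates.

A cohort is a subjects × regions table of gray-matter volume (GMV, in mL)
plus a covariate table (age in years, sex as a 0/1 indicator, total
intracranial volume in mL) keyed by subject id. Group membership is either
given directly or derived from a sleep-quality questionnaire score (PSQI,
score > 5 indicating a sleep disorder).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _check_unique(ids: tuple[str, ...]) -> None:
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if list(ids).count(s) > 1})
        raise ValueError(f"duplicate subject ids: {dupes}")


@dataclass
class GMVTable:
    """Subjects × regions gray-matter-volume matrix.

    Parameters
    ----------
    values
        ``(n_subjects, n_regions)`` array of regional volumes in mL;
        all entries must be finite.
    subject_ids
        Unique subject identifiers, one per row.
    region_labels
        Region (node) labels, one per column.
    group_labels
        Optional group label per subject (e.g. ``PWSD``/``PWoSD``/``HC``).
    """

    values: np.ndarray
    subject_ids: tuple[str, ...]
    region_labels: tuple[str, ...]
    group_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subject_ids = tuple(str(s) for s in self.subject_ids)
        self.region_labels = tuple(str(r) for r in self.region_labels)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x regions)")
        n, p = self.values.shape
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match row count")
        if len(self.region_labels) != p:
            raise ValueError("region_labels length does not match column count")
        _check_unique(self.subject_ids)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("GMV values must be finite (no missing values)")
        if self.group_labels is not None:
            self.group_labels = tuple(str(g) for g in self.group_labels)
            if len(self.group_labels) != n:
                raise ValueError("group_labels length does not match row count")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def groups(self) -> tuple[str, ...]:
        """Distinct group labels in first-appearance order."""
        if self.group_labels is None:
            return ()
        seen: dict[str, None] = {}
        for g in self.group_labels:
            seen.setdefault(g)
        return tuple(seen)

    def subset(self, group: str) -> "GMVTable":
        """Rows belonging to one group."""
        if self.group_labels is None:
            raise ValueError("table has no group labels")
        mask = np.array([g == group for g in self.group_labels])
        if not mask.any():
            raise KeyError(f"no subjects in group {group!r}")
        return GMVTable(
            self.values[mask],
            tuple(s for s, m in zip(self.subject_ids, mask) if m),
            self.region_labels,
            tuple(g for g, m in zip(self.group_labels, mask) if m),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=list(self.region_labels),
            index=pd.Index(self.subject_ids, name="subject_id"),
        )
        if self.group_labels is not None:
            df.insert(0, "group", list(self.group_labels))
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path, region_labels=None) -> "GMVTable":
        df = pd.read_csv(path, index_col="subject_id")
        _check_unique(tuple(str(s) for s in df.index))
        groups = None
        if "group" in df.columns:
            groups = tuple(df.pop("group").astype(str))
        if region_labels is not None:
            missing = [r for r in region_labels if r not in df.columns]
            if missing:
                raise ValueError(f"missing region columns: {missing}")
            df = df[list(region_labels)]
        bad = df.columns[~df.apply(
            lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
        if len(bad):
            raise ValueError(f"non-numeric cells in columns: {list(bad)}")
        return cls(df.to_numpy(float), tuple(map(str, df.index)),
                   tuple(df.columns), groups)


@dataclass
class CovariateTable:
    """Per-subject nuisance covariates: age (years), sex (0/1), TIV (mL)."""

    subject_ids: tuple[str, ...]
    age: np.ndarray
    sex: np.ndarray
    tiv: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = tuple(str(s) for s in self.subject_ids)
        _check_unique(self.subject_ids)
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=float)
        self.tiv = np.asarray(self.tiv, dtype=float)
        n = len(self.subject_ids)
        for name, arr in (("age", self.age), ("sex", self.sex), ("tiv", self.tiv)):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one value per subject")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains missing/non-finite values")
        if not np.all(np.isin(self.sex, (0.0, 1.0))):
            raise ValueError("sex must be a 0/1 indicator")

    def design_matrix(self) -> np.ndarray:
        """Intercept + age + sex + TIV, one row per subject."""
        n = len(self.subject_ids)
        return np.column_stack(
            [np.ones(n), self.age, self.sex, self.tiv])

    def reorder(self, subject_ids) -> "CovariateTable":
        """Rows re-ordered to the given subject id sequence."""
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        missing = [s for s in subject_ids if s not in pos]
        if missing:
            raise ValueError(f"covariates missing for subjects: {missing}")
        idx = np.array([pos[s] for s in subject_ids])
        return CovariateTable(tuple(subject_ids), self.age[idx],
                              self.sex[idx], self.tiv[idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.age, "sex": self.sex.astype(int), "tiv": self.tiv},
            index=pd.Index(self.subject_ids, name="subject_id"),
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "CovariateTable":
        df = pd.read_csv(path, index_col="subject_id")
        return cls(tuple(map(str, df.index)), df["age"].to_numpy(float),
                   df["sex"].to_numpy(float), df["tiv"].to_numpy(float))


@dataclass
class ResidualTable:
    """GMV residuals after regressing out nuisance covariates.

    Same shape as the source :class:`GMVTable`; every column sums to zero
    (the regression includes an intercept).
    """

    values: np.ndarray
    subject_ids: tuple[str, ...]
    region_labels: tuple[str, ...]
    group_labels: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subject_ids = tuple(str(s) for s in self.subject_ids)
        self.region_labels = tuple(str(r) for r in self.region_labels)
        _check_unique(self.subject_ids)
        if self.values.shape != (len(self.subject_ids), len(self.region_labels)):
            raise ValueError("values shape does not match labels")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def subset(self, group: str) -> "ResidualTable":
        if self.group_labels is None:
            raise ValueError("table has no group labels")
        mask = np.array([g == group for g in self.group_labels])
        return ResidualTable(
            self.values[mask],
            tuple(s for s, m in zip(self.subject_ids, mask) if m),
            self.region_labels,
            tuple(g for g, m in zip(self.group_labels, mask) if m),
        )


def assign_groups_by_psqi(
    scores, cutoff: float = 5.0,
    labels: tuple[str, str] = ("PWoSD", "PWSD"),
) -> tuple[str, ...]:
    """Label subjects by sleep-quality score: score > cutoff → second label.

    The PSQI convention: a total score above 5 indicates poor sleep quality
    (a sleep disorder), at or below 5 does not.
    """
    scores = np.asarray(scores, dtype=float)
    return tuple(labels[1] if s > cutoff else labels[0] for s in scores)
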