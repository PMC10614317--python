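"""Cohort table I/O, validation, outcome dichotomization and splitting.

A cohort is a plain :class:`pandas.DataFrame` (one row per patient) paired
with a data dictionary declaring the role of every column: ``id``,
``covariate``, ``score``, ``marker`` (with an ``ELISA``/``MRM`` assay tag)
or ``cac``. Markers may be missing (empty CSV cells); covariates, the
baseline score and the Agatston score may not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DataError

__all__ = [
    "DataDictionary",
    "CohortTable",
    "read_cohort",
    "write_cohort",
    "dichotomize",
    "split_cohort",
    "complete_case_subset",
    "dictionary_for_params",
]

ROLES = ("id", "covariate", "score", "marker", "cac")


@dataclass(frozen=True)
class DataDictionary:
    """Column roles; markers carry an assay tag."""

    roles: dict[str, str]
    assays: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for col, role in self.roles.items():
            if role not in ROLES:
                raise ConfigurationError(f"column {col!r}: unknown role {role!r}")
        for col, assay in self.assays.items():
            if self.roles.get(col) != "marker":
                raise ConfigurationError(f"column {col!r}: assay declared but role is not 'marker'")
            if assay not in ("ELISA", "MRM"):
                raise ConfigurationError(f"column {col!r}: assay must be ELISA or MRM")
        missing_assay = [c for c, r in self.roles.items() if r == "marker" and c not in self.assays]
        if missing_assay:
            raise ConfigurationError(f"marker columns without assay tag: {missing_assay}")

    def columns(self, role: str) -> list[str]:
        return [c for c, r in self.roles.items() if r == role]

    def markers(self, assay: str | None = None) -> list[str]:
        cols = self.columns("marker")
        if assay is None:
            return cols
        return [c for c in cols if self.assays[c] == assay]

    @property
    def id_column(self) -> str:
        ids = self.columns("id")
        if len(ids) != 1:
            raise ConfigurationError(f"exactly one 'id' column required, found {ids}")
        return ids[0]

    @property
    def score_column(self) -> str:
        cols = self.columns("score")
        if len(cols) != 1:
            raise ConfigurationError(f"exactly one 'score' column required, found {cols}")
        return cols[0]

    @property
    def cac_column(self) -> str:
        cols = self.columns("cac")
        if len(cols) != 1:
            raise ConfigurationError(f"exactly one 'cac' column required, found {cols}")
        return cols[0]

    def to_dict(self) -> dict:
        out = {}
        for col, role in self.roles.items():
            entry: dict = {"role": role}
            if col in self.assays:
                entry["assay"] = self.assays[col]
            out[col] = entry
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "DataDictionary":
        roles = {c: e["role"] for c, e in d.items()}
        assays = {c: e["assay"] for c, e in d.items() if "assay" in e}
        return cls(roles=roles, assays=assays)

    @classmethod
    def read(cls, path) -> "DataDictionary":
        text = open(path).read()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        if not isinstance(data, dict):
            raise DataError(f"data dictionary {path} is not a mapping")
        return cls.from_dict(data)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            if str(path).endswith((".yml", ".yaml")):
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
            else:
                json.dump(self.to_dict(), fh, indent=2)


@dataclass
class CohortTable:
    """A validated patient-level table plus its data dictionary."""

    data: pd.DataFrame
    dictionary: DataDictionary

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        df, dd = self.data, self.dictionary
        for col in dd.roles:
            if col not in df.columns:
                raise DataError(f"mandatory column missing: {col!r}")
        idc = dd.id_column
        dup = df[idc][df[idc].duplicated()]
        if len(dup):
            raise DataError(f"duplicate patient_id: {sorted(set(dup.astype(str)))}")
        score = pd.to_numeric(df[dd.score_column], errors="coerce")
        bad = df.index[score.isna() | (score <= 0) | (score >= 1)]
        if len(bad):
            raise DataError(
                f"baseline_score outside (0,1) or non-numeric at rows {list(bad[:10])} "
                f"(column {dd.score_column!r})"
            )
        cac = pd.to_numeric(df[dd.cac_column], errors="coerce")
        bad = df.index[cac.isna() | (cac < 0)]
        if len(bad):
            raise DataError(
                f"negative or non-numeric Agatston score at rows {list(bad[:10])} "
                f"(column {dd.cac_column!r})"
            )
        for col in dd.columns("covariate"):
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                rows = list(df.index[vals.isna()][:10])
                raise DataError(f"missing/non-numeric covariate {col!r} at rows {rows}")
        for col in dd.markers():
            vals = pd.to_numeric(df[col], errors="coerce")
            observed = df[col].notna()
            if (vals[observed] < 0).any():
                rows = list(df.index[observed & (vals < 0)][:10])
                raise DataError(f"negative marker value in {col!r} at rows {rows}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def patient_ids(self) -> pd.Series:
        return self.data[self.dictionary.id_column]

    @property
    def cac(self) -> pd.Series:
        return self.data[self.dictionary.cac_column].astype(float)

    @property
    def baseline_score(self) -> pd.Series:
        return self.data[self.dictionary.score_column].astype(float)

    def subset(self, mask_or_index) -> "CohortTable":
        return CohortTable(self.data.loc[mask_or_index].copy(), self.dictionary)


def dictionary_for_params(params) -> DataDictionary:
    """Data dictionary matching :func:`incrisk.simulate.generate_cohort` output."""
    roles = {
        "patient_id": "id",
        "age": "covariate",
        "female": "covariate",
        "hypertension": "covariate",
        "current_smoker": "covariate",
        "baseline_score": "score",
        "cac_agatston": "cac",
    }
    assays = {}
    for m in params.marker_panel:
        roles[m.name] = "marker"
        assays[m.name] = m.assay
    return DataDictionary(roles=roles, assays=assays)


def read_cohort(path, dictionary_path) -> CohortTable:
    """Read a cohort CSV with its data dictionary; missing marker cells are empty fields."""
    dd = DataDictionary.read(dictionary_path)
    df = pd.read_csv(path)
    return CohortTable(df, dd)


def write_cohort(table: CohortTable, path, dictionary_path=None) -> None:
    table.data.to_csv(path, index=False)
    if dictionary_path is not None:
        table.dictionary.write(dictionary_path)


def dichotomize(table: CohortTable, threshold: float) -> pd.Series:
    """Event indicator: 1 iff Agatston score strictly exceeds ``threshold``.

    The boundary value itself is a non-event; the >100 event set therefore
    nests the >300 one.
    """
    if threshold < 0:
        raise ConfigurationError("threshold must be >= 0")
    return (table.cac > threshold).astype(int)


def split_cohort(table: CohortTable, ratio: float = 0.5, seed: int = 0,
                 sizes: tuple[int, int] | None = None,
                 stratify_on=None) -> pd.Series:
    """Random training/validation partition.

    Returns a Series of labels ``{"training", "validation"}`` indexed like the
    table. Default sizes are ceil(r*n)/floor((1-r)*n); explicit ``sizes``
    override the ratio (e.g. a 284/277 split). ``stratify_on`` optionally
    names a binary column (or passes an indicator Series) within whose levels
    the split is randomized separately.
    """
    n = len(table)
    if n < 2:
        raise DataError("cannot split a cohort with fewer than 2 patients")
    if sizes is not None:
        n_train, n_valid = sizes
        if n_train + n_valid != n or min(n_train, n_valid) < 0:
            raise ConfigurationError(f"sizes {sizes} do not partition n={n}")
    else:
        if not 0 < ratio < 1:
            raise ConfigurationError("ratio must be in (0, 1)")
        n_train = int(np.ceil(ratio * n))
        n_valid = n - n_train
    rng = np.random.default_rng(seed)
    labels = pd.Series("validation", index=table.data.index, name="subset")
    if stratify_on is None:
        order = rng.permutation(n)
        labels.iloc[order[:n_train]] = "training"
    else:
        strata = (table.data[stratify_on] if isinstance(stratify_on, str) else stratify_on)
        strata = pd.Series(np.asarray(strata), index=table.data.index)
        assigned = 0
        levels = sorted(strata.unique(), key=str)
        for k, level in enumerate(levels):
            idx = np.flatnonzero((strata == level).to_numpy())
            take = int(round(n_train * len(idx) / n))
            if k == len(levels) - 1:
                take = n_train - assigned
            take = min(max(take, 0), len(idx))
            chosen = rng.permutation(idx)[:take]
            labels.iloc[chosen] = "training"
            assigned += take
    return labels


def complete_case_subset(table: CohortTable, predictors) -> CohortTable:
    """Rows with no missing value in any of ``predictors``.

    For a model comparison, pass the union of both models' predictors so both
    ROC curves are computed on the identical case set. Idempotent.
    """
    predictors = list(predictors)
    missing_cols = [c for c in predictors if c not in table.data.columns]
    if missing_cols:
        raise DataError(f"predictor columns absent from cohort: {missing_cols}")
    mask = table.data[predictors].notna().all(axis=1) if predictors else pd.Series(
        True, index=table.data.index
    )
    if not mask.any():
        raise DataError(f"no complete cases for predictors {predictors}")
    return table.subset(mask)
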