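"""Domain types, dataset validation, and CSV I/O.

A :class:`Dataset` is a thin wrapper around a pandas DataFrame holding one row
per patient: observed survival time (in days, log-transformed to ``y`` at
load), an event indicator, a binary focus variable (race, NHB=1 / NHW=0),
individual-level covariates ``z`` (continuous / ordinal / nominal), a census
tract identifier, and tract-level contextual variables ``w`` that are constant
within tract. All modelling downstream is on the natural-log time scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VariableSpec",
    "Dataset",
    "ValidationReport",
    "SchemaError",
    "DataError",
    "load_schema",
    "load_dataset",
    "write_dataset",
    "validate_dataset",
]

ROLES = {"focus", "individual", "contextual", "tract", "time", "event"}
SCALES = {"continuous", "ordinal", "nominal"}


class SchemaError(ValueError):
    """Schema is malformed or inconsistent with the data file."""


class DataError(ValueError):
    """A record violates a domain constraint (e.g. nonpositive time)."""


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one column: its role in the model and measurement scale.

    ``levels`` gives the ordered category labels for nominal/ordinal variables;
    ordinal variables are encoded by their level index for threshold splits.
    """

    name: str
    role: str
    scale: str = "continuous"
    levels: tuple | None = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r} for variable {self.name!r}")
        if self.scale not in SCALES:
            raise SchemaError(f"unknown scale {self.scale!r} for variable {self.name!r}")
        if self.scale in ("nominal", "ordinal"):
            if self.levels is None or len(self.levels) < 2:
                raise SchemaError(
                    f"{self.scale} variable {self.name!r} must list >=2 levels"
                )
            object.__setattr__(self, "levels", tuple(self.levels))


def _check_specs(specs):
    focus = [s for s in specs if s.role == "focus"]
    if len(focus) != 1:
        raise SchemaError(f"exactly one focus variable required, got {len(focus)}")
    for role in ("time", "event", "tract"):
        if sum(s.role == role for s in specs) != 1:
            raise SchemaError(f"exactly one variable with role {role!r} required")
    return specs


class Dataset:
    """Survival records plus their variable schema.

    Attributes
    ----------
    df : pandas.DataFrame
        One row per record; includes the raw columns plus ``y`` (natural log
        of the observed time in days). The integer index is the stable record
        identifier assigned at load.
    specs : list of VariableSpec
    """

    def __init__(self, df: pd.DataFrame, specs: list[VariableSpec]):
        self.specs = _check_specs(list(specs))
        self.df = df.reset_index(drop=True)
        if "y" not in self.df.columns:
            self.df["y"] = _log_time(self.df[self.time_name])
        for s in self.specs:
            if s.name not in self.df.columns:
                raise SchemaError(f"column {s.name!r} missing from data")

    # -- schema accessors ---------------------------------------------------
    def _one(self, role):
        return next(s.name for s in self.specs if s.role == role)

    @property
    def time_name(self):
        return self._one("time")

    @property
    def event_name(self):
        return self._one("event")

    @property
    def focus_name(self):
        return self._one("focus")

    @property
    def tract_name(self):
        return self._one("tract")

    @property
    def z_specs(self):
        return [s for s in self.specs if s.role == "individual"]

    @property
    def z_names(self):
        return [s.name for s in self.z_specs]

    @property
    def contextual_names(self):
        return [s.name for s in self.specs if s.role == "contextual"]

    def spec(self, name) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    # -- array views --------------------------------------------------------
    @property
    def y(self):
        return self.df["y"].to_numpy(float)

    @property
    def delta(self):
        return self.df[self.event_name].to_numpy(int)

    @property
    def x(self):
        return self.df[self.focus_name].to_numpy(float)

    def w(self, name=None):
        if name is None:
            name = self.contextual_names[0]
        return self.df[name].to_numpy(float)

    @property
    def tract(self):
        return self.df[self.tract_name].to_numpy()

    def encode(self, name) -> np.ndarray:
        """Numeric view of covariate ``name``: floats for continuous, level
        codes for ordinal/nominal (per the schema's level order)."""
        s = self.spec(name)
        col = self.df[name]
        if s.scale == "continuous":
            return col.to_numpy(float)
        # match levels by string form so CSV round trips (which drop the
        # distinction between "1" and 1) stay stable
        cats = [str(lv) for lv in s.levels]
        codes = pd.Categorical(col.astype(str), categories=cats).codes
        if (codes < 0).any():
            bad = sorted(set(col.astype(str)[codes < 0]))
            raise DataError(f"unknown level(s) {bad} for variable {name!r}")
        return codes.astype(float)

    # -- structure ----------------------------------------------------------
    @property
    def n(self):
        return len(self.df)

    @property
    def M(self):
        """Number of distinct tracts."""
        return int(self.df[self.tract_name].nunique())

    @property
    def n_m(self) -> pd.Series:
        """Record count per tract."""
        return self.df[self.tract_name].value_counts().sort_index()

    def subset(self, index) -> "Dataset":
        return Dataset(self.df.iloc[np.asarray(index)].copy(), self.specs)

    def __len__(self):
        return self.n


def _log_time(t: pd.Series) -> pd.Series:
    t = pd.to_numeric(t)
    bad = np.flatnonzero(~(t.to_numpy(float) > 0))
    if bad.size:
        raise DataError(f"nonpositive survival time at row {bad[0]}")
    return np.log(t.astype(float))


def load_schema(path) -> list[VariableSpec]:
    """Read the ``variables:`` list from a YAML config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "variables" not in cfg:
        raise SchemaError("config must contain a 'variables:' list")
    return [VariableSpec(**v) for v in cfg["variables"]]


def load_dataset(path, schema: list[VariableSpec]) -> Dataset:
    """Load a CSV into a :class:`Dataset`, log-transforming time at load.

    Raises :class:`SchemaError` if a declared column is absent, and
    :class:`DataError` (naming the offending row) for nonpositive times,
    missing essential values, or category levels not in the schema.
    """
    schema = _check_specs(list(schema))
    # '#' lines carry run metadata written by the CLI
    df = pd.read_csv(path, float_precision="round_trip", comment="#")
    missing = [s.name for s in schema if s.name not in df.columns]
    if missing:
        raise SchemaError(f"columns missing from {path}: {missing}")
    ds = Dataset(df, schema)
    essential = [ds.time_name, ds.event_name, ds.focus_name, ds.tract_name]
    na = df[essential].isna().any(axis=1)
    if na.any():
        raise DataError(f"missing essential value at row {int(np.flatnonzero(na)[0])}")
    naz = df[ds.z_names].isna().any(axis=1) if ds.z_names else pd.Series(False, index=df.index)
    if naz.any():
        raise DataError(
            f"missing covariate value at row {int(np.flatnonzero(naz)[0])}"
            " (records with missing z are rejected; no surrogate splits)"
        )
    if not df[ds.event_name].isin([0, 1]).all():
        raise DataError("event indicator must be 0/1")
    if not df[ds.focus_name].isin([0, 1]).all():
        raise DataError("focus variable must be coded 0/1")
    for s in schema:
        if s.scale in ("nominal", "ordinal") and s.role == "individual":
            ds.encode(s.name)  # raises on unknown levels
    return ds


def write_dataset(ds: Dataset, path) -> None:
    """Write the dataset back to CSV (raw columns; ``y`` is derived at load)."""
    cols = [s.name for s in ds.specs]
    # %.17g round-trips every double exactly
    ds.df[cols].to_csv(path, index=False, float_format="%.17g")


@dataclass
class ValidationReport:
    fatal: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    focus_group_sizes: dict = field(default_factory=dict)
    censoring_fraction: float = float("nan")
    single_record_tracts: list = field(default_factory=list)
    constant_covariates: list = field(default_factory=list)

    @property
    def ok(self):
        return not self.fatal


def validate_dataset(ds: Dataset) -> ValidationReport:
    """Report fitness of a dataset for node-model fitting (never raises).

    Fatal conditions: no events at all, a constant focus variable, or too few
    events to fit the root intercept+focus model with positive degrees of
    freedom.
    """
    rep = ValidationReport()
    delta = ds.delta
    x = ds.x
    rep.censoring_fraction = float(1.0 - delta.mean()) if len(ds) else float("nan")
    rep.focus_group_sizes = {0: int((x == 0).sum()), 1: int((x == 1).sum())}
    rep.single_record_tracts = list(ds.n_m[ds.n_m == 1].index)
    for name in ds.z_names:
        if np.unique(ds.encode(name)).size < 2:
            rep.constant_covariates.append(name)
    if delta.sum() == 0:
        rep.fatal.append("no events: the Kaplan-Meier weights are all zero")
    if x.min() == x.max():
        rep.fatal.append("focus variable constant: race effect not estimable")
    elif delta.sum() <= 2:
        rep.fatal.append("fewer than 3 events: root model underdetermined")
    else:
        for g in (0, 1):
            if delta[x == g].sum() == 0:
                rep.fatal.append(f"no events in focus group {g}")
    if rep.single_record_tracts:
        rep.warnings.append(
            f"{len(rep.single_record_tracts)} tract(s) with a single record"
        )
    if rep.constant_covariates:
        rep.warnings.append(f"constant covariates: {rep.constant_covariates}")
    return rep
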