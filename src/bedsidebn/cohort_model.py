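"""Domain types, cohort I/O, discretization and association screening.

A cohort is a patient x variable table of discrete state labels.  Every
variable is declared up front through a :class:`VariableSpec`; loading and
discretization validate cells against the declared states.  Only the
outcome variable (dichotomized cardiac index) may be missing, mirroring
patients without a validated reference measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

__all__ = [
    "MISSING",
    "VariableSpec",
    "Rule",
    "ThresholdRule",
    "MappingRule",
    "CompositeAnyRule",
    "DiscretizationRules",
    "Cohort",
    "SchemaError",
    "CohortValueError",
    "UndefinedAssociationError",
    "load_cohort",
    "write_cohort",
    "discretize",
    "cramers_v",
]

#: marker used for a missing outcome cell (empty cell in CSV)
MISSING = ""

ROLES = ("clinical", "estimate", "outcome")


class SchemaError(ValueError):
    """A table does not match the declared variable specs."""


class CohortValueError(ValueError):
    """A cell holds a value that is not a declared state."""


class UndefinedAssociationError(ValueError):
    """Association is undefined (a variable with a single observed state)."""


# --------------------------------------------------------------------------
# discretization rules
# --------------------------------------------------------------------------

_OPS = {
    ">": lambda v, c: v > c,
    ">=": lambda v, c: v >= c,
    "<": lambda v, c: v < c,
    "<=": lambda v, c: v <= c,
}


@dataclass(frozen=True)
class ThresholdRule:
    """Map a numeric raw column to a binary abnormal/normal state.

    ``op`` follows the convention that a value exactly equal to the cutoff
    of a strict rule falls in the lower (not-abnormal) bin; non-strict
    operators (``>=``/``<=``) are available for rules stated inclusively.
    """

    source: str
    op: str
    cutoff: float
    abnormal: str = "yes"
    normal: str = "no"
    lo: float = -np.inf
    hi: float = np.inf

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValueError(f"unknown comparison operator {self.op!r}")

    def apply(self, values: pd.Series) -> pd.Series:
        v = pd.to_numeric(values)
        out_of_range = (v < self.lo) | (v > self.hi) | v.isna()
        if out_of_range.any():
            i = int(np.flatnonzero(out_of_range.to_numpy())[0])
            raise CohortValueError(
                f"value {values.iloc[i]!r} in column {self.source!r} (row {i}) "
                f"outside rule range [{self.lo}, {self.hi}]"
            )
        flag = _OPS[self.op](v, self.cutoff)
        return pd.Series(np.where(flag, self.abnormal, self.normal), index=values.index)


@dataclass(frozen=True)
class MappingRule:
    """Map raw categorical labels onto declared states."""

    source: str
    mapping: Mapping[str, str]

    def apply(self, values: pd.Series) -> pd.Series:
        unknown = ~values.astype(str).isin(self.mapping)
        if unknown.any():
            i = int(np.flatnonzero(unknown.to_numpy())[0])
            raise CohortValueError(
                f"value {values.iloc[i]!r} in column {self.source!r} (row {i}) "
                "not covered by mapping rule"
            )
        return values.astype(str).map(self.mapping)


@dataclass(frozen=True)
class CompositeAnyRule:
    """Abnormal if ANY sub-rule flags abnormal (e.g. delayed CRT at any
    site OR mottling beyond none)."""

    parts: tuple = ()
    abnormal: str = "yes"
    normal: str = "no"

    def apply_frame(self, raw: pd.DataFrame) -> pd.Series:
        flags = []
        for part in self.parts:
            col = part.apply(raw[part.source])
            flags.append(col == part.abnormal)
        any_flag = np.logical_or.reduce(flags) if flags else np.zeros(len(raw), bool)
        return pd.Series(np.where(any_flag, self.abnormal, self.normal), index=raw.index)


Rule = ThresholdRule | MappingRule | CompositeAnyRule


@dataclass(frozen=True)
class DiscretizationRules:
    """Per-variable discretization rules, total over the plausible range."""

    rules: Mapping[str, Rule]

    def __getitem__(self, var: str) -> Rule:
        return self.rules[var]


# --------------------------------------------------------------------------
# variable specs and cohort
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class VariableSpec:
    name: str
    states: tuple[str, ...]
    role: str = "clinical"
    rule: Rule | None = None

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise ValueError(f"variable {self.name!r} needs >= 2 states")
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"duplicate state labels in {self.name!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for {self.name!r}")
        object.__setattr__(self, "states", tuple(self.states))


def _check_specs(specs: Sequence[VariableSpec]) -> None:
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise SchemaError("duplicate variable names in specs")
    for role in ("estimate", "outcome"):
        if sum(s.role == role for s in specs) > 1:
            raise SchemaError(f"more than one variable with role={role}")


@dataclass(frozen=True)
class Cohort:
    """Validated patient x variable table of state labels.

    ``data`` columns are exactly the spec'd variables (in spec order);
    the empty string marks a missing outcome cell.
    """

    specs: tuple[VariableSpec, ...]
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        specs = tuple(self.specs)
        object.__setattr__(self, "specs", specs)
        _check_specs(specs)
        cols = [s.name for s in specs]
        missing = set(cols) - set(self.data.columns)
        if missing:
            raise SchemaError(f"missing columns: {sorted(missing)}")
        extra = set(self.data.columns) - set(cols)
        if extra:
            raise SchemaError(f"undeclared columns: {sorted(extra)}")
        df = self.data[cols].reset_index(drop=True).astype(str)
        for s in specs:
            col = df[s.name]
            ok = col.isin(s.states)
            if s.role == "outcome":
                ok |= col == MISSING
            if not ok.all():
                i = int(np.flatnonzero(~ok.to_numpy())[0])
                raise CohortValueError(
                    f"row {i}: {col.iloc[i]!r} is not a declared state of {s.name!r}"
                )
        object.__setattr__(self, "data", df)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs)

    def spec(self, name: str) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def column(self, name: str) -> pd.Series:
        return self.data[name]

    def codes(self, name: str) -> np.ndarray:
        """Integer state codes for a complete column (missing not allowed)."""
        s = self.spec(name)
        col = self.data[name]
        if (col == MISSING).any():
            raise CohortValueError(f"column {name!r} has missing values")
        lut = {st: i for i, st in enumerate(s.states)}
        return col.map(lut).to_numpy(dtype=np.int64)

    def drop_variable(self, name: str) -> "Cohort":
        specs = tuple(s for s in self.specs if s.name != name)
        return Cohort(specs, self.data.drop(columns=[name]))

    def subset(self, rows: Iterable[int]) -> "Cohort":
        return Cohort(self.specs, self.data.iloc[list(rows)].reset_index(drop=True))


def load_cohort(path: str | Path, specs: Sequence[VariableSpec]) -> Cohort:
    """Read a cohort CSV (header row of variable names, empty cell = missing
    outcome) and validate it against the specs."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty and df.columns.size == 0:
        raise SchemaError(f"{path}: no header row")
    return Cohort(tuple(specs), df)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    cohort.data.to_csv(path, index=False)


def discretize(raw_table: pd.DataFrame, rules: DiscretizationRules,
               specs: Sequence[VariableSpec]) -> Cohort:
    """Apply the configured rules to a raw measurement table.

    Deterministic; a raw value outside a rule's declared range raises.
    Variables without a rule are taken verbatim from the raw table.
    """
    out: dict[str, pd.Series] = {}
    for s in specs:
        rule = rules.rules.get(s.name)
        if rule is None:
            if s.name not in raw_table.columns:
                raise SchemaError(f"raw table lacks column {s.name!r}")
            out[s.name] = raw_table[s.name].astype(str)
        elif isinstance(rule, CompositeAnyRule):
            out[s.name] = rule.apply_frame(raw_table)
        else:
            if rule.source not in raw_table.columns:
                raise SchemaError(f"raw table lacks column {rule.source!r}")
            out[s.name] = rule.apply(raw_table[rule.source])
    return Cohort(tuple(specs), pd.DataFrame(out))


def contingency(cohort: Cohort, a: str, b: str) -> np.ndarray:
    """Observed a x b contingency table over declared states."""
    sa, sb = cohort.spec(a), cohort.spec(b)
    ca, cb = cohort.codes(a), cohort.codes(b)
    ra, rb = len(sa.states), len(sb.states)
    return np.bincount(ca * rb + cb, minlength=ra * rb).reshape(ra, rb).astype(float)


def cramers_v(cohort: Cohort, a: str, b: str) -> float:
    """Cramér's V from the Pearson chi-square of the a x b table.

    ``V = sqrt(chi2 / (n * min(r-1, c-1)))`` over observed states; exactly
    symmetric in its arguments and invariant under state relabeling.
    """
    if cohort.n < 1:
        raise UndefinedAssociationError("empty cohort")
    if a > b:  # canonical orientation makes the symmetry exact, not approximate
        a, b = b, a
    table = contingency(cohort, a, b)
    # restrict to observed states: all-zero rows/cols carry no information
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    r, c = table.shape
    if min(r, c) < 2:
        var = a if r < 2 else b
        raise UndefinedAssociationError(
            f"variable {var!r} has a single observed state"
        )
    chi2 = chi2_contingency(table, correction=False).statistic
    n = table.sum()
    return float(np.sqrt(chi2 / (n * min(r - 1, c - 1))))
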