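"""Cohort data model: CSV I/O, validation and the missing-data policy.

A cohort is a rectangular table, one row per participant, carrying baseline
covariates, the PF instrument items, the 34 deficit items and the three
outcomes (falls in follow-up year 3, incident fracture with time, death).
The column manifest for the non-deficit part ships as a versioned YAML
schema file; deficit columns are declared by the deficit codebook.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .deficits import DeficitCodebook, default_codebook

__all__ = [
    "ColumnSpec",
    "CohortSchema",
    "CohortValidationError",
    "MissingPolicy",
    "load_schema",
    "default_schema",
    "validate_cohort",
    "read_cohort",
    "write_cohort",
    "apply_missing_policy",
]

#: outcome columns are never imputed by default
OUTCOME_COLUMNS = ("fall_year3", "fracture_event", "fracture_time", "death")


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the schema; carries all problems."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        preview = "\n  ".join(self.problems[:20])
        more = "" if len(self.problems) <= 20 else f"\n  ... {len(self.problems) - 20} more"
        super().__init__(f"cohort validation failed:\n  {preview}{more}")


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    kind: str  # id | numeric | integer | binary | ordinal | categorical
    levels: tuple | None = None
    min: float | None = None
    max: float | None = None
    min_exclusive: float | None = None
    allow_missing: bool = False


@dataclass(frozen=True)
class CohortSchema:
    columns: tuple[ColumnSpec, ...]

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.columns]

    def __getitem__(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)


def load_schema(path: str | Path) -> CohortSchema:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return _schema_from_mapping(raw)


def default_schema() -> CohortSchema:
    ref = resources.files("frailtycompare").joinpath("data/schema.yaml")
    return _schema_from_mapping(yaml.safe_load(ref.read_text(encoding="utf-8")))


def _schema_from_mapping(raw: Mapping) -> CohortSchema:
    cols = []
    for c in raw["columns"]:
        cols.append(
            ColumnSpec(
                name=str(c["name"]),
                kind=str(c["kind"]),
                levels=tuple(c["levels"]) if "levels" in c else None,
                min=c.get("min"),
                max=c.get("max"),
                min_exclusive=c.get("min_exclusive"),
                allow_missing=bool(c.get("allow_missing", False)),
            )
        )
    return CohortSchema(columns=tuple(cols))


def _check_column(spec: ColumnSpec, col: pd.Series, problems: list[str]) -> None:
    missing = col.isna()
    if missing.any() and not spec.allow_missing and spec.kind != "id":
        # missingness is legal pre-imputation for most fields; only flag
        # columns that must always be observed
        pass
    vals = col[~missing]
    if spec.kind == "id":
        if col.duplicated().any():
            dup = col[col.duplicated()].iloc[0]
            problems.append(f"column {spec.name!r}: duplicate id {dup!r}")
        return
    if spec.kind in ("numeric", "integer"):
        num = pd.to_numeric(vals, errors="coerce")
        bad = vals[num.isna()]
        for idx in bad.index[:5]:
            problems.append(
                f"column {spec.name!r}, row {idx}: non-numeric value {vals[idx]!r}"
            )
        num = num.dropna()
        if spec.kind == "integer" and not np.allclose(num, np.round(num)):
            problems.append(f"column {spec.name!r}: non-integer values present")
        if spec.min is not None:
            viol = num[num < spec.min]
            for idx in viol.index[:5]:
                problems.append(
                    f"column {spec.name!r}, row {idx}: value {num[idx]} below "
                    f"minimum {spec.min}"
                )
        if spec.min_exclusive is not None:
            viol = num[num <= spec.min_exclusive]
            for idx in viol.index[:5]:
                problems.append(
                    f"column {spec.name!r}, row {idx}: value {num[idx]} not above "
                    f"{spec.min_exclusive}"
                )
        if spec.max is not None:
            viol = num[num > spec.max]
            for idx in viol.index[:5]:
                problems.append(
                    f"column {spec.name!r}, row {idx}: value {num[idx]} above "
                    f"maximum {spec.max}"
                )
    elif spec.kind == "binary":
        num = pd.to_numeric(vals, errors="coerce")
        bad = vals[~num.isin([0, 1])]
        for idx in bad.index[:5]:
            problems.append(
                f"column {spec.name!r}, row {idx}: value {vals[idx]!r} is not "
                "binary (expected 0 or 1)"
            )
    elif spec.kind == "ordinal":
        num = pd.to_numeric(vals, errors="coerce")
        bad = vals[~num.isin(list(spec.levels))]
        for idx in bad.index[:5]:
            problems.append(
                f"column {spec.name!r}, row {idx}: value {vals[idx]!r} is not "
                f"one of the declared levels {list(spec.levels)}"
            )
    elif spec.kind == "categorical":
        bad = vals[~vals.astype(str).isin([str(lv) for lv in spec.levels])]
        for idx in bad.index[:5]:
            problems.append(
                f"column {spec.name!r}, row {idx}: value {vals[idx]!r} is not "
                f"one of the declared levels {list(spec.levels)}"
            )
    else:  # pragma: no cover - schema authoring error
        problems.append(f"column {spec.name!r}: unknown kind {spec.kind!r}")


def validate_cohort(
    table: pd.DataFrame,
    codebook: DeficitCodebook | None = None,
    schema: CohortSchema | None = None,
) -> list[str]:
    """Return a list of human-readable problems (empty when valid)."""
    schema = schema or default_schema()
    codebook = codebook or default_codebook()
    problems: list[str] = []
    for name in schema.names:
        if name not in table.columns:
            problems.append(f"missing required column {name!r}")
    for item in codebook.items:
        if item.item_id not in table.columns:
            problems.append(f"missing deficit column {item.item_id!r}")
    known = set(schema.names) | set(codebook.item_ids)
    for name in table.columns:
        if name not in known:
            problems.append(f"unknown column {name!r} not in the schema manifest")
    if problems:
        return problems

    for spec in schema.columns:
        _check_column(spec, table[spec.name], problems)
    for item in codebook.items:
        col = table[item.item_id]
        vals = col[~col.isna()].astype(str)
        bad = vals[~vals.isin(list(item.levels))]
        for idx in bad.index[:5]:
            problems.append(
                f"deficit {item.item_id!r}, row {idx}: response {vals[idx]!r} "
                f"is not one of the declared levels {list(item.levels)}"
            )
    # cross-field: fracture_time present iff follow-up observed
    ft = pd.to_numeric(table["fracture_time"], errors="coerce")
    ev = pd.to_numeric(table["fracture_event"], errors="coerce")
    bad = table.index[(ev == 1) & ft.isna()]
    for idx in bad[:5]:
        problems.append(
            f"row {idx}: fracture_event is 1 but fracture_time is missing"
        )
    return problems


def read_cohort(
    path: str | Path,
    codebook: DeficitCodebook | None = None,
    schema: CohortSchema | None = None,
) -> pd.DataFrame:
    """Read and validate a cohort CSV (UTF-8, header row, '' = missing)."""
    table = pd.read_csv(path, dtype={"participant_id": str}, keep_default_na=False,
                        na_values=[""])
    problems = validate_cohort(table, codebook=codebook, schema=schema)
    if problems:
        raise CohortValidationError(problems)
    return table


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as CSV with empty strings for missing cells."""
    table.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# missing-data policy


@dataclass(frozen=True)
class MissingPolicy:
    """Fill rule for missing cells before scoring.

    Variables missing in under ``threshold`` of rows are filled
    deterministically with the within-group median (numeric) or mode
    (categorical).  Variables at or above the threshold are filled cell by
    cell with a single seeded random draw from the variable's observed
    within-group empirical distribution — a deliberately simple stand-in for
    full multiple imputation, adequate because no downstream inference pools
    across imputations.
    """

    threshold: float = 0.10
    numeric_fill: str = "median"  # or "mean"
    group_key: str | None = None  # e.g. "pf_category"; None = whole sample
    exclude: tuple[str, ...] = OUTCOME_COLUMNS

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.numeric_fill not in ("median", "mean"):
            raise ValueError("numeric_fill must be 'median' or 'mean'")


def _is_numeric(col: pd.Series) -> bool:
    return pd.to_numeric(col.dropna(), errors="coerce").notna().all() and \
        col.dropna().size > 0


def apply_missing_policy(
    table: pd.DataFrame,
    policy: MissingPolicy | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing cells; returns (filled table, imputation log).

    The log has one row per filled cell: row index, column, fill value and
    the rule used.  Observed cells are never altered, so the call is
    idempotent on its own output.
    """
    policy = policy or MissingPolicy()
    rng = np.random.default_rng(seed)
    out = table.copy()
    log_rows: list[dict] = []

    if policy.group_key is not None and policy.group_key in out.columns:
        groups = out[policy.group_key].astype(str).fillna("__all__")
    else:
        groups = pd.Series("__all__", index=out.index)

    for name in out.columns:
        if name == "participant_id" or name in policy.exclude:
            continue
        col = out[name]
        miss = col.isna()
        if not miss.any():
            continue
        if miss.all():
            raise ValueError(
                f"column {name!r} is entirely missing; nothing to impute from"
            )
        frac = miss.mean()
        numeric = _is_numeric(col)
        for grp, idx in out.groupby(groups, sort=True).groups.items():
            sub = col.loc[idx]
            sub_miss = sub.isna()
            if not sub_miss.any():
                continue
            observed = sub[~sub_miss]
            if observed.empty:  # fall back to the whole sample
                observed = col[~miss]
            if frac < policy.threshold:
                if numeric:
                    obs_num = pd.to_numeric(observed, errors="coerce")
                    fillval = (
                        obs_num.median()
                        if policy.numeric_fill == "median"
                        else obs_num.mean()
                    )
                else:
                    fillval = observed.mode(dropna=True).iloc[0]
                fills = pd.Series(fillval, index=sub.index[sub_miss])
                rule = f"group-{policy.numeric_fill}" if numeric else "group-mode"
            else:
                draws = rng.choice(observed.to_numpy(), size=int(sub_miss.sum()))
                fills = pd.Series(draws, index=sub.index[sub_miss])
                rule = "group-empirical-draw"
            out.loc[fills.index, name] = fills.values
            for ridx, val in fills.items():
                log_rows.append(
                    {"row": ridx, "column": name, "value": val, "rule": rule}
                )

    log = pd.DataFrame(log_rows, columns=["row", "column", "value", "rule"])
    return out, log
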