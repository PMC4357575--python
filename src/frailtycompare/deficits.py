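"""Deficit-accumulation frailty index (FI).

The FI is the proportion of health deficits an individual has accumulated
out of a fixed panel of items.  Each questionnaire item is mapped to a
severity value in [0, 1] via a declarative :class:`DeficitCodebook`; the FI
is the sum of the coded values divided by the *total* number of items in
the panel (here 34), giving a continuous score in [0, 1] where higher means
frailer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DeficitItem",
    "DeficitCodebook",
    "FIValue",
    "default_codebook",
    "load_codebook",
    "code_deficit",
    "compute_fi",
    "fi_column",
]

#: Required number of items and per-domain counts for the default panel.
N_ITEMS = 34
DOMAIN_COUNTS = {
    "symptoms_signs": 6,
    "comorbidity": 15,
    "adl": 12,
    "healthcare_utilization": 1,
}


@dataclass(frozen=True)
class DeficitItem:
    """A single deficit: ordered response levels mapped to values in [0, 1]."""

    item_id: str
    domain: str
    levels: tuple[str, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.values):
            raise ValueError(
                f"item {self.item_id!r}: {len(self.levels)} levels but "
                f"{len(self.values)} values"
            )
        vals = np.asarray(self.values, dtype=float)
        if vals.min() != 0.0 or vals.max() != 1.0:
            raise ValueError(
                f"item {self.item_id!r}: value map must include 0 and 1"
            )
        if np.any(np.diff(vals) < 0):
            raise ValueError(
                f"item {self.item_id!r}: values must be non-decreasing over "
                "the declared level order"
            )

    def code(self, response: str) -> float:
        try:
            idx = self.levels.index(str(response))
        except ValueError:
            raise ValueError(
                f"item {self.item_id!r}: response {response!r} is not one of "
                f"the declared levels {list(self.levels)}"
            ) from None
        return self.values[idx]


@dataclass(frozen=True)
class DeficitCodebook:
    """Declarative map from the 34 deficit items to coded values."""

    items: tuple[DeficitItem, ...]
    enforce_panel: bool = True

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item ids in codebook")
        if self.enforce_panel:
            if len(self.items) != N_ITEMS:
                raise ValueError(
                    f"codebook must declare exactly {N_ITEMS} items, "
                    f"got {len(self.items)}"
                )
            counts: dict[str, int] = {}
            for it in self.items:
                counts[it.domain] = counts.get(it.domain, 0) + 1
            if counts != DOMAIN_COUNTS:
                raise ValueError(
                    f"domain counts {counts} do not match the required "
                    f"panel {DOMAIN_COUNTS}"
                )

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def __getitem__(self, item_id: str) -> DeficitItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(f"unknown deficit item {item_id!r}")

    def __contains__(self, item_id: str) -> bool:
        return any(it.item_id == item_id for it in self.items)

    def __len__(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class FIValue:
    """A frailty-index value together with the item count it used."""

    fi: float
    n_items_used: int = N_ITEMS

    def __post_init__(self) -> None:
        if not 0.0 <= self.fi <= 1.0:
            raise ValueError(f"FI must lie in [0, 1], got {self.fi}")


def load_codebook(path: str | Path, enforce_panel: bool = True) -> DeficitCodebook:
    """Load a codebook from a YAML file with an ``items`` list."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return _codebook_from_mapping(raw, enforce_panel=enforce_panel)


def default_codebook() -> DeficitCodebook:
    """The packaged 34-item default codebook (6/15/12/1 domain split)."""
    ref = resources.files("frailtycompare").joinpath("data/codebook.yaml")
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return _codebook_from_mapping(raw, enforce_panel=True)


def _codebook_from_mapping(raw: Mapping, enforce_panel: bool) -> DeficitCodebook:
    items = tuple(
        DeficitItem(
            item_id=str(spec["id"]),
            domain=str(spec["domain"]),
            levels=tuple(str(lv) for lv in spec["levels"]),
            values=tuple(float(v) for v in spec["values"]),
        )
        for spec in raw["items"]
    )
    return DeficitCodebook(items=items, enforce_panel=enforce_panel)


def code_deficit(codebook: DeficitCodebook, item_id: str, response: str) -> float:
    """Map one item response to its deficit value in [0, 1]."""
    if item_id not in codebook:
        raise KeyError(f"unknown deficit item {item_id!r}")
    return codebook[item_id].code(response)


def compute_fi(coded_values: Sequence[float], n_items: int = N_ITEMS) -> FIValue:
    """FI = sum of coded deficit values divided by the fixed item count.

    The denominator stays at ``n_items`` even when some responses were
    imputed upstream: the index is defined over the full panel, not the
    answered subset (pass a different ``n_items`` only for non-standard
    panels).
    """
    vals = np.asarray(list(coded_values), dtype=float)
    if vals.size != n_items:
        raise ValueError(f"expected {n_items} coded values, got {vals.size}")
    if np.any(np.isnan(vals)):
        raise ValueError("coded values contain NaN; resolve missing data first")
    if vals.min() < 0.0 or vals.max() > 1.0:
        bad = vals[(vals < 0.0) | (vals > 1.0)][0]
        raise ValueError(f"coded value {bad} outside [0, 1]")
    return FIValue(fi=float(vals.sum() / n_items), n_items_used=n_items)


def fi_column(
    table: pd.DataFrame, codebook: DeficitCodebook | None = None
) -> pd.Series:
    """Code every deficit item and compute a per-row FI for a cohort table.

    Expects one column per codebook item id; responses must already be
    complete (run the missing-data policy first).
    """
    codebook = codebook or default_codebook()
    coded = np.empty((len(table), len(codebook)), dtype=float)
    for j, item in enumerate(codebook.items):
        if item.item_id not in table.columns:
            raise KeyError(f"cohort table lacks deficit column {item.item_id!r}")
        col = table[item.item_id]
        mapping = dict(zip(item.levels, item.values))
        vals = col.astype(str).map(mapping)
        if vals.isna().any():
            bad = col[vals.isna()].iloc[0]
            raise ValueError(
                f"item {item.item_id!r}: response {bad!r} is not one of the "
                f"declared levels {list(item.levels)}"
            )
        coded[:, j] = vals.to_numpy(dtype=float)
    fi = coded.sum(axis=1) / len(codebook)
    return pd.Series(fi, index=table.index, name="fi")
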