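"""Phenotypic frailty (PF) instrument.

A questionnaire adaptation of the Fried physical-frailty phenotype for
cohorts without performance measures.  Four components are scored:

* slowness & weakness — mean of the 10 SF-36 physical-functioning items,
  each scored 0 ("limited a lot") / 50 ("limited a little") / 100 ("not
  limited"), so the component ranges 0–100 (lower = worse);
* endurance & exhaustion — mean of the 4 SF-36 vitality items on a
  0/25/50/75/100 frequency scale, reverse-coded for positively worded
  items, 0–100 (lower = worse);
* physical activity — days in the past 30 with a walk of at least
  20 minutes, 0–30;
* unintentional weight loss — lost 10 lb or more in the past year (binary).

Points follow the lowest-quartile rule: a participant in the lowest quarter
of slowness & weakness scores 2 points; lowest quartile of exhaustion, of
activity, or reporting weight loss score 1 point each.  The total (0–5)
classifies robust (0), pre-frail (1–2) and frail (3–5).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PF_LEVELS_SF36",
    "PF_LEVELS_VITALITY",
    "PFComponents",
    "PFResult",
    "QuartileCuts",
    "score_sf36_pf_item",
    "score_vitality_item",
    "compute_components",
    "compute_quartile_cuts",
    "score_pf",
    "pf_columns",
    "CATEGORY_ORDER",
]

PF_LEVELS_SF36 = ("limited a lot", "limited a little", "not limited")
_SF36_POINTS = {"limited a lot": 0.0, "limited a little": 50.0, "not limited": 100.0}

PF_LEVELS_VITALITY = (
    "none of the time",
    "a little of the time",
    "some of the time",
    "most of the time",
    "all of the time",
)
# Negatively worded items (worn out, tired): more often = worse = fewer points.
# "some of the time" sits midway between the printed 75 and 25 anchors.
_VITALITY_POINTS = {
    "none of the time": 100.0,
    "a little of the time": 75.0,
    "some of the time": 50.0,
    "most of the time": 25.0,
    "all of the time": 0.0,
}

#: vitality item -> whether it is positively worded (reverse-coded)
VITALITY_ITEMS = {
    "vitality_worn_out": False,
    "vitality_full_of_life": True,
    "vitality_tired": False,
    "vitality_energy": True,
}

SF36_PF_COLUMNS = tuple(f"sf36_pf_{i:02d}" for i in range(1, 11))

CATEGORY_ORDER = ("robust", "pre-frail", "frail")


def score_sf36_pf_item(response: str) -> float:
    """Points for one SF-36 physical-functioning item (0 / 50 / 100)."""
    try:
        return _SF36_POINTS[str(response)]
    except KeyError:
        raise ValueError(
            f"unknown SF-36 PF level {response!r}; expected one of "
            f"{list(PF_LEVELS_SF36)}"
        ) from None


def score_vitality_item(response: str, reverse: bool = False) -> float:
    """Points for one vitality item; ``reverse=True`` for positively worded items."""
    try:
        pts = _VITALITY_POINTS[str(response)]
    except KeyError:
        raise ValueError(
            f"unknown vitality level {response!r}; expected one of "
            f"{list(PF_LEVELS_VITALITY)}"
        ) from None
    return 100.0 - pts if reverse else pts


@dataclass(frozen=True)
class PFComponents:
    """Continuous component scores for one participant."""

    slowness_weakness_score: float  # 0-100, lower = worse
    endurance_exhaustion_score: float  # 0-100, lower = worse
    physical_activity_days: float  # 0-30
    weight_loss_flag: int  # 0/1

    def __post_init__(self) -> None:
        for name, val, hi in (
            ("slowness_weakness_score", self.slowness_weakness_score, 100.0),
            ("endurance_exhaustion_score", self.endurance_exhaustion_score, 100.0),
            ("physical_activity_days", self.physical_activity_days, 30.0),
        ):
            if not np.isnan(val) and not 0.0 <= val <= hi:
                raise ValueError(f"{name}={val} outside [0, {hi}]")
        if self.weight_loss_flag not in (0, 1):
            raise ValueError("weight_loss_flag must be 0 or 1")


@dataclass(frozen=True)
class QuartileCuts:
    """Empirical 25th percentiles of the three continuous PF components."""

    q1_slowness_weakness: float
    q1_exhaustion: float
    q1_activity: float

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "q1_slowness_weakness": self.q1_slowness_weakness,
                    "q1_exhaustion": self.q1_exhaustion,
                    "q1_activity": self.q1_activity,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "QuartileCuts":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(**d)


@dataclass(frozen=True)
class PFResult:
    """Point breakdown, aggregate score 0-5 and frailty category."""

    points_slowness_weakness: int
    points_exhaustion: int
    points_activity: int
    points_weight_loss: int
    total: int
    category: str

    def __post_init__(self) -> None:
        s = (
            self.points_slowness_weakness
            + self.points_exhaustion
            + self.points_activity
            + self.points_weight_loss
        )
        if s != self.total:
            raise ValueError("total must equal the sum of the point fields")
        if self.category != categorize(self.total):
            raise ValueError("category inconsistent with total")


def categorize(total: int) -> str:
    """Map the 0-5 aggregate score to robust / pre-frail / frail."""
    if total == 0:
        return "robust"
    if total in (1, 2):
        return "pre-frail"
    if total in (3, 4, 5):
        return "frail"
    raise ValueError(f"PF total must be an integer 0-5, got {total}")


def _component_mean(points: np.ndarray) -> float:
    """Mean of non-missing item points if at least half are present, else NaN."""
    ok = ~np.isnan(points)
    if ok.sum() * 2 >= points.size:
        return float(points[ok].mean())
    return float("nan")


def compute_components(table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant PF component scores from the instrument item columns.

    Missing item responses (NaN) are tolerated: a component is the mean of
    the answered items when at least half are answered, otherwise missing
    (to be resolved by the missing-data policy before point scoring).
    """
    n = len(table)
    sf = np.full((n, len(SF36_PF_COLUMNS)), np.nan)
    for j, col in enumerate(SF36_PF_COLUMNS):
        resp = table[col]
        sf[:, j] = [
            np.nan if pd.isna(r) else score_sf36_pf_item(r) for r in resp
        ]
    vit = np.full((n, len(VITALITY_ITEMS)), np.nan)
    for j, (col, reverse) in enumerate(VITALITY_ITEMS.items()):
        resp = table[col]
        vit[:, j] = [
            np.nan if pd.isna(r) else score_vitality_item(r, reverse=reverse)
            for r in resp
        ]
    out = pd.DataFrame(
        {
            "pf_slowness_weakness": [_component_mean(row) for row in sf],
            "pf_exhaustion": [_component_mean(row) for row in vit],
            "pf_activity_days": pd.to_numeric(table["walk20_days"], errors="coerce"),
            "pf_weight_loss": pd.to_numeric(table["weight_loss_10lb"], errors="coerce"),
        },
        index=table.index,
    )
    return out


def compute_quartile_cuts(components: pd.DataFrame) -> QuartileCuts:
    """Empirical 25th percentiles (linear interpolation) of each component.

    ``components`` is the output of :func:`compute_components` (or any frame
    with the three continuous component columns).
    """
    cuts = {}
    for key, col in (
        ("q1_slowness_weakness", "pf_slowness_weakness"),
        ("q1_exhaustion", "pf_exhaustion"),
        ("q1_activity", "pf_activity_days"),
    ):
        vals = pd.to_numeric(components[col], errors="coerce").dropna().to_numpy()
        if vals.size < 4:
            raise ValueError(
                f"component {col!r}: need at least 4 non-missing values to "
                "form a quartile cut"
            )
        # NumPy's default percentile is the linear-interpolation (R type-7)
        # definition; kept as the single config point for the cut rule.
        cuts[key] = float(np.percentile(vals, 25))
    return QuartileCuts(**cuts)


def score_pf(components: PFComponents, cuts: QuartileCuts) -> PFResult:
    """Score one participant given component values and quartile cuts.

    The lowest-quartile boundary is inclusive: a component exactly at its
    cut earns points, so ties at the cut score consistently.
    """
    for name, val in (
        ("slowness_weakness_score", components.slowness_weakness_score),
        ("endurance_exhaustion_score", components.endurance_exhaustion_score),
        ("physical_activity_days", components.physical_activity_days),
    ):
        if np.isnan(val):
            raise ValueError(
                f"component {name} is missing; apply the missing-data policy "
                "before scoring"
            )
    p_sw = 2 if components.slowness_weakness_score <= cuts.q1_slowness_weakness else 0
    p_ex = 1 if components.endurance_exhaustion_score <= cuts.q1_exhaustion else 0
    p_act = 1 if components.physical_activity_days <= cuts.q1_activity else 0
    p_wl = 1 if components.weight_loss_flag else 0
    total = p_sw + p_ex + p_act + p_wl
    return PFResult(
        points_slowness_weakness=p_sw,
        points_exhaustion=p_ex,
        points_activity=p_act,
        points_weight_loss=p_wl,
        total=total,
        category=categorize(total),
    )


def pf_columns(
    table: pd.DataFrame, cuts: QuartileCuts | None = None
) -> tuple[pd.DataFrame, QuartileCuts]:
    """Vectorised PF scoring for a whole cohort.

    Returns the component/point/score/category columns and the quartile
    cuts used.  When ``cuts`` is None they are computed on this sample;
    pass stored cuts for out-of-sample scoring.
    """
    comps = compute_components(table)
    if comps[["pf_slowness_weakness", "pf_exhaustion", "pf_activity_days",
              "pf_weight_loss"]].isna().any().any():
        raise ValueError(
            "PF components contain missing values; apply the missing-data "
            "policy before scoring"
        )
    if cuts is None:
        cuts = compute_quartile_cuts(comps)
    p_sw = np.where(comps["pf_slowness_weakness"] <= cuts.q1_slowness_weakness, 2, 0)
    p_ex = np.where(comps["pf_exhaustion"] <= cuts.q1_exhaustion, 1, 0)
    p_act = np.where(comps["pf_activity_days"] <= cuts.q1_activity, 1, 0)
    p_wl = comps["pf_weight_loss"].to_numpy().astype(int)
    total = p_sw + p_ex + p_act + p_wl
    out = comps.copy()
    out["pf_points_slowness_weakness"] = p_sw
    out["pf_points_exhaustion"] = p_ex
    out["pf_points_activity"] = p_act
    out["pf_points_weight_loss"] = p_wl
    out["pf_score"] = total
    out["pf_category"] = [categorize(int(t)) for t in total]
    if (out["pf_category"] == "robust").mean() < 0.05:
        warnings.warn(
            "fewer than 5% of participants scored robust; check the "
            "instrument columns", stacklevel=2
        )
    return out, cuts
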