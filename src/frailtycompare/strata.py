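"""Three strategies that put the PF score and the FI on a common footing.

The two frailty measures live on different scales (PF: integer 0-5; FI:
continuous in [0, 1]), so the comparison needs a common grouping:

1. **Per-one-fifth increments.**  The FI is binned at successive multiples
   of one fifth of its observed range (rounded to 2 dp for reporting), so
   both measures become six ordered levels 0-5.
2. **Density-overlap trichotomisation.**  Kernel densities of the FI are
   fitted within the three PF categories; the crossing points between
   adjacent group densities become FI cutpoints, yielding an FI-based
   robust / pre-frail / frail grouping.
3. **Predicted-probability grouping.**  A multivariable logistic model of
   falls in follow-up year 3 on the FI (adjusted for age, smoking,
   drinking, BMI, education and baseline falls) gives each participant a
   predicted fall probability, cut at 0.27 and 0.50 into low / medium /
   high risk.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import gaussian_kde

from .phenotype import CATEGORY_ORDER

__all__ = [
    "RiskCutoffs",
    "StrategyAssignment",
    "fi_increment",
    "strategy1_bins",
    "strategy2_cutpoints",
    "strategy3_groups",
    "assign_all_strategies",
    "FALLS_ADJUSTMENT",
]

logger = logging.getLogger(__name__)

#: covariates adjusting the strategy-3 falls model
FALLS_ADJUSTMENT = (
    "age", "smoker", "drinks_per_week", "bmi", "education", "baseline_falls",
)

#: KDE evaluation grid for strategy 2 (config constants)
KDE_GRID_SIZE = 512
KDE_GRID_RANGE = (0.0, 1.0)

RISK_LABELS = ("low", "medium", "high")


@dataclass(frozen=True)
class RiskCutoffs:
    """Predicted fall-probability cutoffs for strategy 3.

    Defaults follow the published annual fall-risk anchors: 0.27 is the
    estimated annual probability of falling among older adults, and 0.50
    the annual risk after a prior fall or gait/balance abnormality.
    """

    low_medium: float = 0.27
    medium_high: float = 0.50

    def __post_init__(self) -> None:
        if not 0.0 < self.low_medium < self.medium_high < 1.0:
            raise ValueError("need 0 < low_medium < medium_high < 1")


@dataclass(frozen=True)
class StrategyAssignment:
    """Per-participant group labels for one strategy, with its cut metadata."""

    strategy: int
    pf_group: pd.Series
    fi_group: pd.Series
    fi_cutpoints: tuple[float, ...]
    fi_increment: float | None = None


def fi_increment(fi_values: np.ndarray | pd.Series) -> float:
    """One fifth of the observed FI range (unrounded).

    Reporting layers round to 2 dp; the strategy-1 cutpoints are built from
    the rounded value so the printed cutpoints are exact multiples.
    """
    vals = np.asarray(fi_values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty FI vector")
    lo, hi = float(np.min(vals)), float(np.max(vals))
    if hi == lo:
        raise ValueError("constant FI vector: increment undefined (zero range)")
    return (hi - lo) / 5.0


def strategy1_bins(fi: np.ndarray | pd.Series, increment_rounded: float) -> np.ndarray:
    """Bin the FI into levels 0-5 at multiples of the rounded increment.

    Level 0 is reserved for an FI of exactly 0 (no deficits at all);
    otherwise level k covers (c_{k-1}, c_k] with c_k = k * increment,
    and level 5 anything above c_4.
    """
    if increment_rounded <= 0:
        raise ValueError("increment must be positive")
    vals = np.asarray(fi, dtype=float)
    cuts = np.array([k * increment_rounded for k in range(1, 5)])
    # right-closed bins: level = number of cutpoints strictly below fi, +1
    level = np.searchsorted(cuts, vals, side="left") + 1
    level = np.where(vals > cuts[-1], 5, level)
    level = np.where(vals == 0.0, 0, level)
    return level.astype(int)


def _density_crossing(
    fi_a: np.ndarray, fi_b: np.ndarray, label: str
) -> tuple[float, bool]:
    """FI value where the KDEs of two adjacent groups cross.

    Gaussian kernels with Silverman bandwidth on a fixed grid over [0, 1];
    among sign changes of (density_a - density_b) inside the inter-mean
    interval, the one nearest the midpoint of the two group means wins.
    Returns (cut, used_fallback).
    """
    mean_a, mean_b = float(np.mean(fi_a)), float(np.mean(fi_b))
    lo, hi = sorted((mean_a, mean_b))
    mid = 0.5 * (lo + hi)
    grid = np.linspace(*KDE_GRID_RANGE, KDE_GRID_SIZE)
    try:
        dens_a = gaussian_kde(fi_a, bw_method="silverman")(grid)
        dens_b = gaussian_kde(fi_b, bw_method="silverman")(grid)
    except np.linalg.LinAlgError:  # degenerate (constant) group
        warnings.warn(
            f"{label}: degenerate FI distribution, falling back to the "
            "midpoint of group means", stacklevel=3
        )
        return mid, True
    diff = dens_a - dens_b
    sign_change = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
    crossings = []
    for i in sign_change:
        x0, x1 = grid[i], grid[i + 1]
        y0, y1 = diff[i], diff[i + 1]
        x = x0 if y1 == y0 else x0 - y0 * (x1 - x0) / (y1 - y0)
        if lo <= x <= hi:
            crossings.append(x)
    if not crossings:
        warnings.warn(
            f"{label}: no density crossing between the group means, falling "
            "back to their midpoint", stacklevel=3
        )
        return mid, True
    cut = min(crossings, key=lambda x: abs(x - mid))
    return float(cut), False


def strategy2_cutpoints(
    fi: np.ndarray | pd.Series, pf_category: np.ndarray | pd.Series
) -> tuple[float, float]:
    """Trichotomise the FI where adjacent PF-group FI densities overlap.

    cut1 separates robust from pre-frail, cut2 pre-frail from frail.
    """
    fi = np.asarray(fi, dtype=float)
    cat = np.asarray(pf_category, dtype=object)
    groups = {g: fi[cat == g] for g in CATEGORY_ORDER}
    for g, vals in groups.items():
        if vals.size < 10:
            raise ValueError(
                f"PF category {g!r} has {vals.size} members; need >= 10 for a "
                "stable density estimate"
            )
    cut1, _ = _density_crossing(groups["robust"], groups["pre-frail"],
                                "robust vs pre-frail")
    cut2, _ = _density_crossing(groups["pre-frail"], groups["frail"],
                                "pre-frail vs frail")
    if not cut1 < cut2:
        raise ValueError(
            f"cutpoints are not ordered (cut1={cut1:.3f}, cut2={cut2:.3f}); "
            "the group densities do not separate"
        )
    return cut1, cut2


def trichotomize(fi: np.ndarray | pd.Series, cut1: float, cut2: float) -> np.ndarray:
    """FI -> robust / pre-frail / frail labels (left-closed intervals)."""
    vals = np.asarray(fi, dtype=float)
    out = np.where(vals < cut1, "robust",
                   np.where(vals < cut2, "pre-frail", "frail"))
    return out.astype(object)


def strategy3_groups(
    table: pd.DataFrame,
    fi: np.ndarray | pd.Series | None = None,
    cutoffs: RiskCutoffs | None = None,
    return_probs: bool = False,
):
    """Low/medium/high fall-risk groups from the FI-based falls model.

    Fits a multivariable logistic model of falls in follow-up year 3 on the
    FI adjusted for age, smoking, drinking, BMI, education and baseline
    falls; in-sample predicted probabilities are cut at the risk cutoffs
    (low < 0.27 <= medium < 0.50 <= high).
    """
    cutoffs = cutoffs or RiskCutoffs()
    fi = np.asarray(table["fi"] if fi is None else fi, dtype=float)
    y = pd.to_numeric(table["fall_year3"], errors="coerce")
    mask = y.notna()
    if y[mask].nunique() < 2:
        raise ValueError("falls outcome has a single class; cannot fit the model")
    X = table.loc[:, list(FALLS_ADJUSTMENT)].apply(pd.to_numeric)
    X = X.assign(fi=fi)
    X = sm.add_constant(X[["fi", *FALLS_ADJUSTMENT]], has_constant="add")
    try:
        fit = sm.Logit(y[mask].astype(float), X[mask.to_numpy()]).fit(disp=0)
    except Exception as exc:  # separation / non-convergence
        raise RuntimeError(
            "strategy-3 falls model failed to converge; consider a ridge "
            f"fallback (penalised fit): {exc}"
        ) from exc
    probs = np.asarray(fit.predict(X), dtype=float)
    group = np.where(probs < cutoffs.low_medium, "low",
                     np.where(probs < cutoffs.medium_high, "medium", "high"))
    group = group.astype(object)
    if return_probs:
        return group, probs
    return group


def assign_all_strategies(
    table: pd.DataFrame,
    cutoffs: RiskCutoffs | None = None,
) -> dict[int, StrategyAssignment]:
    """Run strategies 1-3 on a scored cohort (needs pf_score/pf_category/fi).

    Returns per-strategy group labels for both instruments plus the
    cutpoints / increment each strategy derived.
    """
    fi = pd.to_numeric(table["fi"])
    pf_score = pd.to_numeric(table["pf_score"]).astype(int)
    pf_cat = table["pf_category"].astype(object)

    inc = fi_increment(fi)
    inc_rounded = round(inc, 2)
    bins1 = strategy1_bins(fi, inc_rounded)
    s1 = StrategyAssignment(
        strategy=1,
        pf_group=pf_score.rename("pf_group"),
        fi_group=pd.Series(bins1, index=table.index, name="fi_group"),
        fi_cutpoints=tuple(round(k * inc_rounded, 10) for k in range(1, 5)),
        fi_increment=inc,
    )

    cut1, cut2 = strategy2_cutpoints(fi, pf_cat)
    s2 = StrategyAssignment(
        strategy=2,
        pf_group=pf_cat.rename("pf_group"),
        fi_group=pd.Series(trichotomize(fi, cut1, cut2), index=table.index,
                           name="fi_group"),
        fi_cutpoints=(cut1, cut2),
    )

    cutoffs = cutoffs or RiskCutoffs()
    grp3 = strategy3_groups(table, fi=fi, cutoffs=cutoffs)
    s3 = StrategyAssignment(
        strategy=3,
        pf_group=pf_cat.rename("pf_group"),
        fi_group=pd.Series(grp3, index=table.index, name="fi_group"),
        fi_cutpoints=(cutoffs.low_medium, cutoffs.medium_high),
    )
    return {1: s1, 2: s2, 3: s3}


def ordinal_codes(labels: pd.Series | np.ndarray, strategy: int) -> np.ndarray:
    """Map group labels to ordered integer codes for correlation/modelling."""
    arr = np.asarray(labels, dtype=object)
    if strategy == 1:
        return np.asarray(labels, dtype=int)
    order = CATEGORY_ORDER if set(arr) <= set(CATEGORY_ORDER) else RISK_LABELS
    lut = {lab: i for i, lab in enumerate(order)}
    return np.array([lut[x] for x in arr], dtype=int)
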