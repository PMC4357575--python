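"""Discrimination, calibration and agreement statistics, written from scratch.

These are the quantities on which the two frailty instruments are compared:

* AUC by the Mann–Whitney rank statistic with the DeLong structural-
  components variance, and the paired DeLong z-test for the difference of
  two correlated AUCs;
* Harrell's concordance index for censored survival data, with a paired
  bootstrap contrast;
* the Hosmer–Lemeshow decile-of-risk calibration chi-square;
* tie-corrected Spearman rank correlation with a Fisher-transform CI.

Implementations are deliberately independent of scikit-learn / lifelines /
scipy's versions of the same statistics, which serve as cross-checks in the
test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ROCComparison",
    "ConcordanceResult",
    "CalibrationResult",
    "AgreementResult",
    "auc_mann_whitney",
    "delong_contrast",
    "harrell_c",
    "concordance_contrast",
    "hosmer_lemeshow",
    "spearman_agreement",
]


@dataclass(frozen=True)
class ROCComparison:
    auc_a: float
    auc_b: float
    ci95_a: tuple[float, float]
    ci95_b: tuple[float, float]
    covariance: float
    z: float
    p: float


@dataclass(frozen=True)
class ConcordanceResult:
    c_index: float
    n_concordant: float
    n_discordant: float
    n_tied: float
    ci95: tuple[float, float] | None = None
    contrast_p: float | None = None


@dataclass(frozen=True)
class CalibrationResult:
    hl_statistic: float
    df: int
    p: float
    group_table: "np.ndarray"  # columns: n, observed, expected


@dataclass(frozen=True)
class AgreementResult:
    spearman_rho: float
    ci95: tuple[float, float]
    p: float
    n: int


# ---------------------------------------------------------------------------
# AUC / DeLong


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Placement values V10 (per case) and V01 (per control)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both outcome classes must be present")
    # pairwise comparison with ties counted half
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)  # per positive
    v01 = cmp.mean(axis=0)  # per negative
    return v10, v01


def auc_mann_whitney(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """AUC via the rank statistic, and its DeLong variance.

    Ties between a case and a control count one half.  Returns
    (auc, variance).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    v10, v01 = _delong_components(scores, labels)
    auc = float(v10.mean())
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = float(s10 / m + s01 / n)
    return auc, var


def auc_ci(auc: float, var: float) -> tuple[float, float]:
    half = stats.norm.ppf(0.975) * np.sqrt(max(var, 0.0))
    return (max(0.0, auc - half), min(1.0, auc + half))


def delong_contrast(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> ROCComparison:
    """Paired DeLong z-test for the difference of two correlated AUCs.

    Both score vectors are evaluated against the same labels (paired
    design); the covariance comes from the shared structural components.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("scores_a, scores_b and labels must share a shape")
    v10a, v01a = _delong_components(scores_a, labels)
    v10b, v01b = _delong_components(scores_b, labels)
    m, n = v10a.size, v01a.size
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())

    def _cov(x, y, size):
        if size < 2:
            return 0.0
        return float(np.cov(x, y, ddof=1)[0, 1])

    var_a = _cov(v10a, v10a, m) / m + _cov(v01a, v01a, n) / n
    var_b = _cov(v10b, v10b, m) / m + _cov(v01b, v01b, n) / n
    cov_ab = _cov(v10a, v10b, m) / m + _cov(v01a, v01b, n) / n
    var_diff = var_a + var_b - 2.0 * cov_ab
    if var_diff <= 0:
        # identical (or perfectly coupled) predictors: no evidence of a difference
        z, p = 0.0, 1.0
    else:
        z = (auc_a - auc_b) / np.sqrt(var_diff)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return ROCComparison(
        auc_a=auc_a,
        auc_b=auc_b,
        ci95_a=auc_ci(auc_a, var_a),
        ci95_b=auc_ci(auc_b, var_b),
        covariance=cov_ab,
        z=float(z),
        p=float(p),
    )


# ---------------------------------------------------------------------------
# Harrell's c


def _concordance_counts(
    times: np.ndarray, events: np.ndarray, scores: np.ndarray
) -> tuple[float, float, float]:
    """Concordant / discordant / score-tied counts over usable pairs.

    A pair is usable when the earlier time is an observed event (or the
    times tie with exactly one event, in which case the censored subject is
    known to survive longer).  Higher risk score predicting the shorter
    event time is concordant; tied scores count half each way.
    """
    conc = disc = tied = 0.0
    event_idx = np.nonzero(events == 1)[0]
    for i in event_idx:
        later = (times > times[i]) | ((times == times[i]) & (events == 0))
        later[i] = False
        s_later = scores[later]
        conc += float(np.sum(scores[i] > s_later))
        disc += float(np.sum(scores[i] < s_later))
        tied += float(np.sum(scores[i] == s_later))
    return conc, disc, tied


def harrell_c(
    times: np.ndarray, events: np.ndarray, scores: np.ndarray
) -> ConcordanceResult:
    """Harrell's concordance index for (possibly censored) survival data."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    scores = np.asarray(scores, dtype=float)
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    conc, disc, tied = _concordance_counts(times, events, scores)
    total = conc + disc + tied
    if total == 0:
        raise ValueError("no usable pairs (all censored or fully tied times)")
    c = (conc + 0.5 * tied) / total
    return ConcordanceResult(
        c_index=float(c), n_concordant=conc, n_discordant=disc, n_tied=tied
    )


def concordance_contrast(
    times: np.ndarray,
    events: np.ndarray,
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[ConcordanceResult, ConcordanceResult, float]:
    """Paired bootstrap test for the difference of two c-indices.

    Resamples participants with replacement, recomputes both c-indices on
    each resample and refers the observed difference to the bootstrap SE of
    the difference (normal reference).  Returns (result_a, result_b, p).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    res_a = harrell_c(times, events, scores_a)
    res_b = harrell_c(times, events, scores_b)
    delta = res_a.c_index - res_b.c_index
    rng = np.random.default_rng(seed)
    n = times.size
    diffs = np.empty(n_boot)
    cas = np.empty(n_boot)
    cbs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if events[idx].sum() == 0:
            diffs[b] = np.nan
            cas[b] = cbs[b] = np.nan
            continue
        ca = harrell_c(times[idx], events[idx], scores_a[idx]).c_index
        cb = harrell_c(times[idx], events[idx], scores_b[idx]).c_index
        cas[b], cbs[b] = ca, cb
        diffs[b] = ca - cb
    diffs = diffs[~np.isnan(diffs)]
    se = diffs.std(ddof=1) if diffs.size > 1 else 0.0
    if se == 0:
        p = 1.0 if delta == 0 else 0.0
    else:
        p = float(2.0 * stats.norm.sf(abs(delta) / se))

    def _ci(c_hat, boots):
        boots = boots[~np.isnan(boots)]
        if boots.size < 2:
            return None
        lo, hi = np.percentile(boots, [2.5, 97.5])
        return (float(lo), float(hi))

    res_a = ConcordanceResult(
        c_index=res_a.c_index, n_concordant=res_a.n_concordant,
        n_discordant=res_a.n_discordant, n_tied=res_a.n_tied,
        ci95=_ci(res_a.c_index, cas), contrast_p=p,
    )
    res_b = ConcordanceResult(
        c_index=res_b.c_index, n_concordant=res_b.n_concordant,
        n_discordant=res_b.n_discordant, n_tied=res_b.n_tied,
        ci95=_ci(res_b.c_index, cbs), contrast_p=p,
    )
    return res_a, res_b, p


# ---------------------------------------------------------------------------
# Hosmer-Lemeshow


def hosmer_lemeshow(
    pred_probs: np.ndarray, labels: np.ndarray, n_groups: int = 10
) -> CalibrationResult:
    """Decile-of-risk calibration chi-square (df = groups - 2).

    Groups are formed from quantiles of the predicted probabilities; the
    statistic is sum (O - E)^2 / (E (1 - E/n_g)).  Degenerate groups
    (zero binomial variance) are merged into their neighbour with a warning.
    """
    p = np.asarray(pred_probs, dtype=float)
    y = np.asarray(labels).astype(int)
    if p.size < 2 * n_groups:
        raise ValueError(f"need at least {2 * n_groups} observations")
    edges = np.quantile(p, np.linspace(0, 1, n_groups + 1))
    edges = np.unique(edges)
    if len(edges) < 3:
        raise ValueError("predicted probabilities too concentrated to group")
    grp = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for gi in range(len(edges) - 1):
        sel = grp == gi
        n_g = int(sel.sum())
        if n_g == 0:
            continue
        rows.append([n_g, float(y[sel].sum()), float(p[sel].sum())])
    table = np.array(rows, dtype=float)
    # merge groups whose binomial variance vanishes
    merged = []
    for row in table:
        if merged and (row[2] <= 0 or row[2] >= row[0]):
            warnings.warn(
                "merging a degenerate Hosmer-Lemeshow group with its "
                "neighbour", stacklevel=2
            )
            merged[-1] = [a + b for a, b in zip(merged[-1], row)]
        else:
            merged.append(list(row))
    table = np.array(merged, dtype=float)
    n_g, O, E = table[:, 0], table[:, 1], table[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = (O - E) ** 2 / (E * (1.0 - E / n_g))
    stat = float(np.nansum(contrib))
    df = max(int(table.shape[0]) - 2, 1)
    return CalibrationResult(
        hl_statistic=stat, df=df, p=float(stats.chi2.sf(stat, df)),
        group_table=table,
    )


# ---------------------------------------------------------------------------
# Spearman


def _rank_average(x: np.ndarray) -> np.ndarray:
    """Average ranks (mid-ranks for ties); 1-based."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(x.size, dtype=float)
    sx = x[order]
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman_agreement(x: np.ndarray, y: np.ndarray) -> AgreementResult:
    """Tie-corrected Spearman rho with Fisher-z CI and t-test p-value.

    Computed as the Pearson correlation of mid-ranks (the standard tie
    correction); CI via the Fisher transform with SE 1/sqrt(n - 3).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    rx, ry = _rank_average(x), _rank_average(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))
    rho_c = min(max(rho, -0.999999999), 0.999999999)
    zf = np.arctanh(rho_c)
    half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
    ci = (float(np.tanh(zf - half)), float(np.tanh(zf + half)))
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return AgreementResult(spearman_rho=rho, ci95=ci, p=p, n=n)
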