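"""Outcome models: logistic fits for falls/death, Cox fits for fractures.

Each outcome has its own adjustment set (drinking enters as an ordinal
0-3 score and baseline falls as an ordinal 0-2 score; swap to dummy coding
via ``ordinal_as_dummies=True`` if preferred):

* falls (>= 1 fall during follow-up year 3, binary) — age, smoking,
  drinking, BMI, education, baseline falls;
* fractures (time to first incident fracture, 3-year administrative
  censoring, deaths censor at the death time) — age, smoking, drinking,
  baseline fracture, family history of fractures, BMI, education;
* death (binary over 3 years) — age, smoking, drinking, BMI, education.

Frailty effects are expressed per increment: one point of the PF score, or
one fifth of the FI range for the FI, via exp(beta * delta).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats

__all__ = [
    "ADJUSTMENT_SETS",
    "ModelSpec",
    "EffectEstimate",
    "LogisticFit",
    "CoxFit",
    "fit_logistic",
    "fit_cox",
    "effect_per_increment",
    "schoenfeld_ph_check",
]

ADJUSTMENT_SETS: dict[str, tuple[str, ...]] = {
    "falls_y3": ("age", "smoker", "drinks_per_week", "bmi", "education",
                 "baseline_falls"),
    "fracture": ("age", "smoker", "drinks_per_week", "prior_fracture",
                 "family_history_fracture", "bmi", "education"),
    "death": ("age", "smoker", "drinks_per_week", "bmi", "education"),
}

OUTCOME_COLUMN = {"falls_y3": "fall_year3", "death": "death",
                  "fracture": "fracture_event"}

CONVERGENCE_TOL = 1e-8


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, exposure column(s) and adjustment level."""

    outcome: str  # falls_y3 | death | fracture
    exposure: str  # name of the exposure column (e.g. "fi", "pf_score")
    adjustment: str = "multivariable"  # or "age_only"

    def __post_init__(self) -> None:
        if self.outcome not in ADJUSTMENT_SETS:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.adjustment not in ("age_only", "multivariable"):
            raise ValueError("adjustment must be 'age_only' or 'multivariable'")

    @property
    def family(self) -> str:
        return "proportional_hazards" if self.outcome == "fracture" else "logistic"

    @property
    def covariates(self) -> tuple[str, ...]:
        return ("age",) if self.adjustment == "age_only" else ADJUSTMENT_SETS[self.outcome]


@dataclass(frozen=True)
class EffectEstimate:
    """An OR or HR per stated increment, with its 95% CI."""

    scale: str  # "OR" | "HR"
    estimate: float
    ci95: tuple[float, float]
    per: str

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (0 < lo <= self.estimate <= hi):
            raise ValueError("need 0 < lo <= estimate <= hi")


@dataclass
class LogisticFit:
    """A fitted logistic model plus what downstream comparison needs."""

    spec: ModelSpec
    params: pd.Series
    cov: pd.DataFrame
    linear_predictor: np.ndarray  # in-sample, rows used in the fit
    fitted_probs: np.ndarray
    y: np.ndarray
    llf: float
    aic: float
    n: int
    exposure_terms: tuple[str, ...]

    def se(self, term: str) -> float:
        return float(np.sqrt(self.cov.loc[term, term]))


@dataclass
class CoxFit:
    """A fitted Cox model (Efron ties) plus discrimination inputs."""

    spec: ModelSpec
    params: pd.Series
    cov: pd.DataFrame
    risk_score: np.ndarray  # in-sample partial linear predictor
    times: np.ndarray
    events: np.ndarray
    log_partial_likelihood: float
    aic_partial: float
    n: int
    n_events: int
    exposure_terms: tuple[str, ...]
    fitter: CoxPHFitter = field(repr=False)
    design: pd.DataFrame = field(repr=False)

    def se(self, term: str) -> float:
        return float(np.sqrt(self.cov.loc[term, term]))


def _design_matrix(
    table: pd.DataFrame, spec: ModelSpec, exposure_frame: pd.DataFrame | None
) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Numeric design columns: exposure term(s) first, then the adjustment set."""
    if exposure_frame is not None:
        expo = exposure_frame.copy()
    else:
        expo = pd.DataFrame(
            {spec.exposure: pd.to_numeric(table[spec.exposure])}, index=table.index
        )
    exposure_terms = tuple(expo.columns)
    covs = table.loc[:, list(spec.covariates)].apply(pd.to_numeric)
    X = pd.concat([expo, covs], axis=1)
    const = X.columns[X.nunique() <= 1]
    if len(const):
        warnings.warn(
            f"dropping constant covariates {list(const)}", stacklevel=3
        )
        X = X.drop(columns=const)
        exposure_terms = tuple(t for t in exposure_terms if t not in const)
    return X, exposure_terms


def fit_logistic(
    table: pd.DataFrame,
    spec: ModelSpec,
    exposure_frame: pd.DataFrame | None = None,
) -> LogisticFit:
    """Maximum-likelihood logistic fit of a binary outcome on exposure + adjustment.

    ``exposure_frame`` overrides the single exposure column with one or more
    columns (e.g. group dummies for the trichotomised strategies).
    Rows with a missing outcome are excluded from the fit.
    """
    ycol = OUTCOME_COLUMN[spec.outcome]
    y = pd.to_numeric(table[ycol], errors="coerce")
    X, exposure_terms = _design_matrix(table, spec, exposure_frame)
    mask = y.notna().to_numpy()
    y = y[mask].astype(float)
    if y.nunique() < 2:
        raise ValueError(f"outcome {ycol!r} has a single class")
    Xc = sm.add_constant(X[mask], has_constant="add")
    if len(y) <= 10 * Xc.shape[1]:
        warnings.warn(
            f"only {len(y)} rows for {Xc.shape[1]} parameters; estimates may "
            "be unstable", stacklevel=2
        )
    model = sm.Logit(y, Xc)
    try:
        from statsmodels.tools.sm_exceptions import (
            ConvergenceWarning,
            PerfectSeparationWarning,
        )

        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            warnings.simplefilter("error", category=ConvergenceWarning)
            warnings.simplefilter("error", category=PerfectSeparationWarning)
            res = model.fit(disp=0, tol=CONVERGENCE_TOL, maxiter=200)
    except Exception as exc:
        raise RuntimeError(
            "logistic fit failed (possible separation); retry with a "
            f"ridge-penalised fit (fit_regularized): {exc}"
        ) from exc
    eta = np.asarray(Xc @ res.params, dtype=float)
    return LogisticFit(
        spec=spec,
        params=res.params,
        cov=res.cov_params(),
        linear_predictor=eta,
        fitted_probs=np.asarray(res.predict(Xc), dtype=float),
        y=y.to_numpy(),
        llf=float(res.llf),
        aic=float(res.aic),
        n=int(len(y)),
        exposure_terms=exposure_terms,
    )


def fit_cox(
    table: pd.DataFrame,
    spec: ModelSpec,
    exposure_frame: pd.DataFrame | None = None,
) -> CoxFit:
    """Cox partial-likelihood fit (Efron ties) for time to first fracture."""
    if spec.outcome != "fracture":
        raise ValueError("Cox models are fitted for the fracture outcome")
    times = pd.to_numeric(table["fracture_time"], errors="coerce")
    events = pd.to_numeric(table["fracture_event"], errors="coerce")
    X, exposure_terms = _design_matrix(table, spec, exposure_frame)
    mask = (times.notna() & events.notna()).to_numpy()
    df = X[mask].copy()
    df["__time"] = times[mask].astype(float).to_numpy()
    df["__event"] = events[mask].astype(int).to_numpy()
    if (df["__time"] <= 0).any():
        raise ValueError("fracture times must be positive")
    n_events = int(df["__event"].sum())
    if n_events == 0:
        raise ValueError("no fracture events; Cox model is not estimable")
    if n_events < 10:
        warnings.warn(
            f"only {n_events} events; Cox estimates may be unstable",
            stacklevel=2,
        )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="__time", event_col="__event")
    covariate_cols = [c for c in df.columns if c not in ("__time", "__event")]
    risk = np.asarray(
        df[covariate_cols] @ cph.params_.reindex(covariate_cols), dtype=float
    )
    k = len(cph.params_)
    logpl = float(cph.log_likelihood_)
    return CoxFit(
        spec=spec,
        params=cph.params_,
        cov=cph.variance_matrix_,
        risk_score=risk,
        times=df["__time"].to_numpy(),
        events=df["__event"].to_numpy(),
        log_partial_likelihood=logpl,
        aic_partial=2.0 * k - 2.0 * logpl,
        n=int(len(df)),
        n_events=n_events,
        exposure_terms=exposure_terms,
        fitter=cph,
        design=df,
    )


def effect_per_increment(
    fit: LogisticFit | CoxFit, increment: float, term: str | None = None
) -> EffectEstimate:
    """exp(beta * delta) with Wald 95% CI exp((beta +/- 1.96 SE) * delta)."""
    term = term or fit.exposure_terms[0]
    beta = float(fit.params[term])
    se = fit.se(term)
    z = stats.norm.ppf(0.975)
    est = float(np.exp(beta * increment))
    lo = float(np.exp((beta - z * se) * increment))
    hi = float(np.exp((beta + z * se) * increment))
    scale = "HR" if isinstance(fit, CoxFit) else "OR"
    return EffectEstimate(
        scale=scale, estimate=est, ci95=(min(lo, hi), max(lo, hi)),
        per=f"{increment:g} units of {term}",
    )


def schoenfeld_ph_check(fit: CoxFit) -> pd.DataFrame:
    """Grambsch–Therneau proportional-hazards test from Schoenfeld residuals.

    Correlates the per-event Schoenfeld residuals with the rank of the event
    time: per-covariate chi-square(1) statistics plus a GLOBAL chi-square(p)
    row.  Small p-values indicate a time-varying effect.
    """
    if fit.n_events < 3:
        raise ValueError("need at least 3 events for the PH check")
    resid = fit.fitter.compute_residuals(fit.design, kind="schoenfeld")
    # rank transform of the event times (the time-scale choice g(t)): the
    # event's rank in time order, centred; ties broken by sort order
    dur = fit.fitter.durations
    ev = fit.fitter.event_observed
    g_all = pd.Series(
        np.cumsum(np.asarray(ev, dtype=float)), index=dur.index
    )
    g = g_all.loc[resid.index].to_numpy(dtype=float)
    g = g - g.mean()
    S = resid.to_numpy(dtype=float)  # d x p, per-event residuals
    d = S.shape[0]
    V = fit.cov.reindex(index=resid.columns, columns=resid.columns).to_numpy()
    u = g @ S  # p-vector; Var(u) ~ (sum g^2 / d) * V^{-1} under PH
    vu = V @ u
    gg = float(np.sum(g**2))
    rows = []
    for j, name in enumerate(resid.columns):
        chi2 = d * vu[j] ** 2 / (V[j, j] * gg) if V[j, j] > 0 else np.nan
        rows.append((name, chi2, 1, float(stats.chi2.sf(chi2, 1))))
    chi2_g = float(d * (u @ vu) / gg)
    p_global = float(stats.chi2.sf(chi2_g, S.shape[1]))
    rows.append(("GLOBAL", chi2_g, S.shape[1], p_global))
    return pd.DataFrame(rows, columns=["covariate", "chi2", "df", "p"]).set_index(
        "covariate"
    )
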