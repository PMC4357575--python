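"""Synthetic cohort generator with a latent frailty trait.

Emulates a postmenopausal osteoporosis-study cohort (women aged >= 55,
age-stratified so two thirds are >= 65) in which a single latent frailty
trait Z — standard normal plus an age slope — jointly drives the 34 deficit
items, the four PF instrument components and the outcome risks.  One factor
is the simplest mechanism that yields the observed PF-FI correlation
(Spearman around 0.6) with a tunable knob (the loadings).

Outcomes are drawn from the *realised* frailty index, so downstream model
fits are correctly specified and parameter recovery is well posed:

* falls in follow-up year 3 and death are logistic in FI (expressed per
  one-fifth of the 0-0.72 reference FI range) plus covariate effects;
* fracture times are exponential given covariates (the simplest generator
  for which proportional hazards holds exactly), censored at 3 years or at
  the death time.

Intercepts are calibrated by bisection so the expected marginal rates hit
the configured targets (falls 0.32, fractures 0.064, death 0.027).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .deficits import DeficitCodebook, default_codebook, fi_column
from .phenotype import PF_LEVELS_SF36, PF_LEVELS_VITALITY, SF36_PF_COLUMNS, VITALITY_ITEMS

__all__ = ["GeneratorConfig", "TruthRecord", "generate", "make_missing"]


@dataclass(frozen=True)
class GeneratorConfig:
    """All generator knobs; defaults emulate the study conditions."""

    n: int = 4000
    seed: int = 0
    # age structure: two strata with 2/3 of women aged >= 65
    age_mix: float = 2.0 / 3.0
    age_young: tuple[float, float] = (60.0, 2.8)  # mean, sd on [55, 65)
    age_old: tuple[float, float] = (73.8, 6.6)  # mean, sd on [65, 97]
    # latent trait Z = age_slope * (age - 70)/10 + N(0, 1)
    age_slope: float = 0.55
    # deficit loadings (per domain) and level thresholds on the latent scale
    symptom_loading: float = 0.7
    symptom_thresholds: tuple[float, ...] = (-0.25, 0.75, 1.75, 2.75)
    comorbidity_loading: float = 0.5
    comorbidity_intercepts: tuple[float, ...] = (
        0.35, -0.35, 0.15, -0.95, -1.15, -1.35, -2.05, -1.25, -1.05, -2.75,
        -2.05, -2.45, -1.65, -0.65, -1.75,
    )
    adl_loading: float = 0.75
    adl_thresholds: tuple[float, float] = (0.4, 1.75)
    hosp_loading: float = 0.8
    hosp_thresholds: tuple[float, float] = (1.6, 2.7)
    # PF component loadings (higher Z -> worse responses)
    sf36_loading: float = 0.62
    sf36_noise: float = 1.0
    sf36_thresholds: tuple[float, float] = (0.9, 2.2)  # little / a lot
    vitality_loading: float = 0.56
    vitality_noise: float = 1.0
    vitality_thresholds: tuple[float, ...] = (-0.6, 0.5, 1.5, 2.5)
    walk_center: float = 15.0
    walk_loading: float = 0.56
    walk_slope: float = 6.0
    walk_noise: float = 1.0
    weight_loss_intercept: float = -2.3
    weight_loss_loading: float = 0.35
    # true outcome effects per one-fifth (0.144) of the 0-0.72 reference FI range
    fi_increment_ref: float = 0.144
    falls_log_or: float = float(np.log(1.4))
    death_log_or: float = float(np.log(1.8))
    fracture_log_hr: float = float(np.log(1.25))
    # covariate effects (log-odds / log-hazard per unit)
    falls_covariate_effects: dict = field(default_factory=lambda: {
        "baseline_falls": 0.55, "age_c": 0.018, "bmi_c": 0.010,
        "smoker": 0.15, "education": -0.10, "drinks_per_week": 0.05,
    })
    death_covariate_effects: dict = field(default_factory=lambda: {
        "age_c": 0.07, "smoker": 0.50, "education": -0.10,
        "bmi_c": 0.010, "drinks_per_week": -0.05,
    })
    fracture_covariate_effects: dict = field(default_factory=lambda: {
        "age_c": 0.03, "prior_fracture": 0.50, "family_history_fracture": 0.25,
        "bmi_c": -0.010, "smoker": 0.10, "education": -0.05,
        "drinks_per_week": 0.00,
    })
    # target marginal rates
    event_rates: dict = field(default_factory=lambda: {
        "falls": 0.32, "fracture": 0.064, "death": 0.027,
    })
    rate_tolerance: float = 0.01
    followup_years: float = 3.0


@dataclass
class TruthRecord:
    """Everything needed to regenerate and check a synthetic cohort."""

    seed: int
    z: np.ndarray
    fall_prob: np.ndarray
    death_prob: np.ndarray
    fracture_rate: np.ndarray
    intercepts: dict
    config: GeneratorConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "intercepts": self.intercepts,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(self.config).items()},
            "z": self.z.tolist(),
            "fall_prob": self.fall_prob.tolist(),
            "death_prob": self.death_prob.tolist(),
            "fracture_rate": self.fracture_rate.tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)


def _truncnorm(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out >= hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out >= hi)
    return out


def _ordered_levels(rng, z, loading, thresholds, n_levels):
    """Latent = loading*Z + N(0,1), cut at thresholds -> 0..n_levels-1 (worse)."""
    latent = loading * z + rng.normal(0.0, 1.0, size=z.size)
    idx = np.searchsorted(np.asarray(thresholds, dtype=float), latent, side="left")
    return np.clip(idx, 0, n_levels - 1)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _calibrate_intercept(target, expected_fn, lo=-20.0, hi=10.0, tol=1e-8):
    """Bisection on the intercept so expected_fn(alpha) == target."""
    f_lo, f_hi = expected_fn(lo) - target, expected_fn(hi) - target
    if f_lo > 0 or f_hi < 0:
        raise ValueError(
            f"target rate {target} unattainable within the intercept bounds"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected_fn(mid) - target > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def generate(
    config: GeneratorConfig | None = None,
    codebook: DeficitCodebook | None = None,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Draw a synthetic cohort table and its ground-truth record."""
    cfg = config or GeneratorConfig()
    codebook = codebook or default_codebook()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n

    # --- age and latent trait ---------------------------------------------
    old = rng.random(n) < cfg.age_mix
    age = np.where(
        old,
        _truncnorm(rng, *cfg.age_old, 65.0, 97.0, n),
        _truncnorm(rng, *cfg.age_young, 55.0, 65.0, n),
    )
    z = cfg.age_slope * (age - 70.0) / 10.0 + rng.normal(0.0, 1.0, size=n)

    # --- covariates --------------------------------------------------------
    bmi = np.clip(27.0 + 1.0 * z + rng.normal(0.0, 5.3, size=n), 15.0, 60.0)
    smoker = (rng.random(n) < _sigmoid(-2.2 + 0.25 * z)).astype(int)
    drinks_latent = -0.35 * z + rng.normal(0.0, 1.0, size=n)
    # thresholds give roughly 51 / 36 / 11 / 2 percent from heaviest category down
    drinks = np.digitize(drinks_latent, [-2.15, -1.30, -0.03])
    education = (rng.random(n) < _sigmoid(-0.55 - 0.20 * z)).astype(int)
    falls_latent = 0.55 * z + rng.normal(0.0, 1.0, size=n)
    baseline_falls = np.digitize(falls_latent, [0.40, 1.15])
    prior_fracture = (rng.random(n) < _sigmoid(-1.35 + 0.20 * z)).astype(int)
    family_history = (rng.random(n) < 0.30).astype(int)

    table = pd.DataFrame(
        {
            "participant_id": [f"P{i:05d}" for i in range(n)],
            "age": np.round(age, 1),
            "bmi": np.round(bmi, 1),
            "smoker": smoker,
            "drinks_per_week": drinks,
            "education": education,
            "baseline_falls": baseline_falls,
            "prior_fracture": prior_fracture,
            "family_history_fracture": family_history,
        }
    )

    # --- PF instrument items ------------------------------------------------
    for col in SF36_PF_COLUMNS:
        idx = _ordered_levels(rng, z, cfg.sf36_loading, cfg.sf36_thresholds, 3)
        # badness 0/1/2 -> not limited / limited a little / limited a lot
        table[col] = np.array(PF_LEVELS_SF36[::-1], dtype=object)[idx]
    for col, reverse in VITALITY_ITEMS.items():
        idx = _ordered_levels(rng, z, cfg.vitality_loading,
                              cfg.vitality_thresholds, 5)
        if reverse:  # positively worded: worse = less of the time
            lv = np.array(PF_LEVELS_VITALITY[::-1], dtype=object)
        else:  # negatively worded: worse = more of the time
            lv = np.array(PF_LEVELS_VITALITY, dtype=object)
        table[col] = lv[idx]
    walk_latent = cfg.walk_loading * z + rng.normal(0.0, cfg.walk_noise, size=n)
    table["walk20_days"] = np.clip(
        np.round(cfg.walk_center - cfg.walk_slope * walk_latent), 0, 30
    ).astype(int)
    table["weight_loss_10lb"] = (
        rng.random(n)
        < _sigmoid(cfg.weight_loss_intercept + cfg.weight_loss_loading * z)
    ).astype(int)

    # --- deficit items -------------------------------------------------------
    comorb_i = 0
    for item in codebook.items:
        k = len(item.levels)
        if item.domain == "symptoms_signs":
            idx = _ordered_levels(rng, z, cfg.symptom_loading,
                                  cfg.symptom_thresholds, k)
        elif item.domain == "comorbidity":
            c0 = cfg.comorbidity_intercepts[comorb_i]
            comorb_i += 1
            idx = (rng.random(n)
                   < _sigmoid(c0 + cfg.comorbidity_loading * z)).astype(int)
        elif item.domain == "adl":
            idx = _ordered_levels(rng, z, cfg.adl_loading, cfg.adl_thresholds, k)
        else:  # healthcare utilization
            idx = _ordered_levels(rng, z, cfg.hosp_loading, cfg.hosp_thresholds, k)
        table[item.item_id] = np.array(item.levels, dtype=object)[idx]

    fi = fi_column(table, codebook).to_numpy()

    # --- outcomes ------------------------------------------------------------
    age_c = age - 70.0
    bmi_c = bmi - 27.7
    covs = {
        "age_c": age_c, "bmi_c": bmi_c, "smoker": smoker,
        "education": education, "drinks_per_week": drinks,
        "baseline_falls": baseline_falls, "prior_fracture": prior_fracture,
        "family_history_fracture": family_history,
    }

    def _eta(effects):
        out = np.zeros(n)
        for name, beta in effects.items():
            out += beta * covs[name]
        return out

    fi_scaled = fi / cfg.fi_increment_ref

    eta_falls = cfg.falls_log_or * fi_scaled + _eta(cfg.falls_covariate_effects)
    a_falls = _calibrate_intercept(
        cfg.event_rates["falls"], lambda a: float(_sigmoid(a + eta_falls).mean())
    )
    fall_prob = _sigmoid(a_falls + eta_falls)
    table["fall_year3"] = (rng.random(n) < fall_prob).astype(int)

    eta_death = cfg.death_log_or * fi_scaled + _eta(cfg.death_covariate_effects)
    a_death = _calibrate_intercept(
        cfg.event_rates["death"], lambda a: float(_sigmoid(a + eta_death).mean())
    )
    death_prob = _sigmoid(a_death + eta_death)
    death = (rng.random(n) < death_prob).astype(int)
    table["death"] = death
    # deaths censor fracture follow-up at the death time
    death_time = np.where(death == 1,
                          rng.uniform(0.2, cfg.followup_years, size=n),
                          cfg.followup_years)

    eta_frac = cfg.fracture_log_hr * fi_scaled + _eta(cfg.fracture_covariate_effects)
    censor = death_time

    def _expected_fracture_rate(a):
        lam = np.exp(a + eta_frac)
        return float((1.0 - np.exp(-lam * censor)).mean())

    a_frac = _calibrate_intercept(cfg.event_rates["fracture"],
                                  _expected_fracture_rate)
    frac_rate = np.exp(a_frac + eta_frac)
    t_frac = rng.exponential(1.0 / frac_rate)
    event = (t_frac <= censor).astype(int)
    table["fracture_event"] = event
    # rounding for CSV friendliness; keep times strictly positive
    table["fracture_time"] = np.maximum(
        np.round(np.minimum(t_frac, censor), 4), 1e-4
    )

    truth = TruthRecord(
        seed=cfg.seed, z=z, fall_prob=fall_prob, death_prob=death_prob,
        fracture_rate=frac_rate,
        intercepts={"falls": a_falls, "death": a_death, "fracture": a_frac},
        config=cfg,
    )
    return table, truth


def make_missing(
    table: pd.DataFrame,
    rate: float,
    columns: list[str],
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mask cells completely at random; returns (table, mask log)."""
    if not 0.0 <= rate <= 0.5:
        raise ValueError("rate must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    out = table.copy()
    rows = []
    for col in columns:
        mask = rng.random(len(out)) < rate
        out.loc[mask, col] = np.nan
        for idx in out.index[mask]:
            rows.append({"row": idx, "column": col})
    return out, pd.DataFrame(rows, columns=["row", "column"])
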