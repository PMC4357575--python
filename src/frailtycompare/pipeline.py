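"""End-to-end comparison pipeline: score -> stratify -> model -> compare.

The public surface follows the familiar model/results split: build a
:class:`FrailtyComparison` from a cohort table (or simulate one), call
``fit()``, and read the estimates, discrimination contrasts, calibration
checks and agreement statistics off the returned
:class:`FrailtyComparisonResults`, whose ``summary()`` renders the report
tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import discrimination as disc
from .cohort import (
    MissingPolicy,
    apply_missing_policy,
    default_schema,
    read_cohort,
    validate_cohort,
    write_cohort,
)
from .deficits import DeficitCodebook, default_codebook, fi_column
from .models import (
    CoxFit,
    LogisticFit,
    ModelSpec,
    effect_per_increment,
    fit_cox,
    fit_logistic,
    schoenfeld_ph_check,
)
from .phenotype import CATEGORY_ORDER, QuartileCuts, pf_columns
from .simulate import GeneratorConfig, generate
from .strata import RISK_LABELS, RiskCutoffs, StrategyAssignment, assign_all_strategies, ordinal_codes

__all__ = ["RunConfig", "FrailtyComparison", "FrailtyComparisonResults"]

logger = logging.getLogger(__name__)

OUTCOMES = ("falls_y3", "fracture", "death")
ADJUSTMENTS = ("age_only", "multivariable")


@dataclass(frozen=True)
class RunConfig:
    """What to run and how."""

    strategies: tuple[int, ...] = (1, 2, 3)
    outcomes: tuple[str, ...] = OUTCOMES
    adjustments: tuple[str, ...] = ADJUSTMENTS
    subgroup: str = "all"  # "all" | "<65" | ">=65"
    seed: int = 0
    n_boot: int = 1000  # paired bootstrap resamples for c-index contrasts
    risk_cutoffs: RiskCutoffs = field(default_factory=RiskCutoffs)
    missing_policy: MissingPolicy = field(default_factory=MissingPolicy)

    def __post_init__(self) -> None:
        if not self.strategies or not self.outcomes:
            raise ValueError("need at least one strategy and one outcome")
        if self.subgroup not in ("all", "<65", ">=65"):
            raise ValueError("subgroup must be 'all', '<65' or '>=65'")


def _group_dummies(labels: pd.Series, order: tuple[str, ...], prefix: str) -> pd.DataFrame:
    """Indicator columns for the non-reference groups (first label = reference)."""
    out = {}
    for lab in order[1:]:
        out[f"{prefix}_{lab}"] = (labels == lab).astype(float)
    return pd.DataFrame(out, index=labels.index)


class FrailtyComparison:
    """Comparison of the PF and FI instruments on one cohort.

    Parameters
    ----------
    table : DataFrame
        A cohort table conforming to the shipped schema (one row per
        participant; instrument items, deficits and outcomes).
    codebook : DeficitCodebook, optional
        Level -> value coding of the 34 deficits; the packaged default is a
        structural stand-in with the standard 6/15/12/1 domain split.
    config : RunConfig, optional
    validate : bool
        Run schema validation on construction (default True).
    """

    def __init__(
        self,
        table: pd.DataFrame,
        codebook: DeficitCodebook | None = None,
        config: RunConfig | None = None,
        validate: bool = True,
    ) -> None:
        self.codebook = codebook or default_codebook()
        self.config = config or RunConfig()
        if validate:
            problems = validate_cohort(table, codebook=self.codebook)
            if problems:
                from .cohort import CohortValidationError

                raise CohortValidationError(problems)
        self.table = table.reset_index(drop=True)
        self.truth = None

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        codebook: DeficitCodebook | None = None,
        config: RunConfig | None = None,
    ) -> "FrailtyComparison":
        codebook = codebook or default_codebook()
        table = read_cohort(path, codebook=codebook)
        return cls(table, codebook=codebook, config=config, validate=False)

    @classmethod
    def simulate(
        cls,
        generator: GeneratorConfig | None = None,
        config: RunConfig | None = None,
    ) -> "FrailtyComparison":
        """Build the model on a freshly simulated cohort (truth attached)."""
        gen = generator or GeneratorConfig(seed=(config.seed if config else 0))
        table, truth = generate(gen)
        obj = cls(table, config=config, validate=False)
        obj.truth = truth
        return obj

    # ------------------------------------------------------------------
    def fit(self) -> "FrailtyComparisonResults":
        cfg = self.config
        table = self.table
        if cfg.subgroup == "<65":
            table = table[table["age"] < 65].reset_index(drop=True)
        elif cfg.subgroup == ">=65":
            table = table[table["age"] >= 65].reset_index(drop=True)
        logger.info("cohort size after subgroup filter: %d", len(table))

        table, imputation_log = apply_missing_policy(
            table, cfg.missing_policy, seed=cfg.seed
        )

        pf, cuts = pf_columns(table)
        scored = pd.concat([table, pf], axis=1)
        scored["fi"] = fi_column(table, self.codebook)
        logger.info(
            "quartile cuts: slowness/weakness %.2f, exhaustion %.2f, "
            "activity %.1f", cuts.q1_slowness_weakness, cuts.q1_exhaustion,
            cuts.q1_activity,
        )

        assignments = assign_all_strategies(scored, cutoffs=cfg.risk_cutoffs)
        assignments = {s: assignments[s] for s in cfg.strategies}
        for s, a in assignments.items():
            logger.info("strategy %d cutpoints: %s", s,
                        [round(c, 4) for c in a.fi_cutpoints])

        agreement = self._agreement(assignments)
        effects, fits = self._effects(scored, assignments)
        discrim, calibration, ph = self._discrimination(fits)
        group_counts = self._group_counts(assignments)

        return FrailtyComparisonResults(
            config=cfg,
            table=scored,
            quartile_cuts=cuts,
            assignments=assignments,
            agreement=agreement,
            effects=effects,
            discrimination=discrim,
            calibration=calibration,
            ph_checks=ph,
            group_counts=group_counts,
            imputation_log=imputation_log,
            truth=self.truth,
        )

    # ------------------------------------------------------------------
    def _agreement(self, assignments) -> pd.DataFrame:
        rows = []
        for s, a in assignments.items():
            res = disc.spearman_agreement(
                ordinal_codes(a.pf_group, s), ordinal_codes(a.fi_group, s)
            )
            rows.append(
                {"strategy": s, "spearman_rho": res.spearman_rho,
                 "ci_lo": res.ci95[0], "ci_hi": res.ci95[1], "p": res.p}
            )
        return pd.DataFrame(rows).set_index("strategy")

    def _exposure_frame(
        self, scored: pd.DataFrame, a: StrategyAssignment, instrument: str
    ) -> tuple[pd.DataFrame | None, str, float | None]:
        """Exposure columns, main term name and per-increment delta."""
        if a.strategy == 1:
            if instrument == "pf":
                return (pd.DataFrame({"pf_score": scored["pf_score"].astype(float)}),
                        "pf_score", 1.0)
            inc = round(a.fi_increment, 2)
            return pd.DataFrame({"fi": scored["fi"].astype(float)}), "fi", inc
        labels = a.pf_group if instrument == "pf" else a.fi_group
        order = CATEGORY_ORDER if set(labels) <= set(CATEGORY_ORDER) else RISK_LABELS
        dummies = _group_dummies(labels, order, instrument)
        return dummies, dummies.columns[-1], None

    def _effects(self, scored, assignments):
        cfg = self.config
        rows = []
        fits: dict[tuple, LogisticFit | CoxFit] = {}
        for s, a in assignments.items():
            for outcome in cfg.outcomes:
                for instrument in ("pf", "fi"):
                    expo, term, delta = self._exposure_frame(scored, a, instrument)
                    for adj in cfg.adjustments:
                        spec = ModelSpec(outcome, term, adjustment=adj)
                        if outcome == "fracture":
                            fit = fit_cox(scored, spec, exposure_frame=expo)
                        else:
                            fit = fit_logistic(scored, spec, exposure_frame=expo)
                        fits[(s, outcome, instrument, adj)] = fit
                        for t in fit.exposure_terms:
                            d = delta if delta is not None else 1.0
                            eff = effect_per_increment(fit, d, term=t)
                            rows.append({
                                "strategy": s, "outcome": outcome,
                                "instrument": instrument.upper(),
                                "adjustment": adj, "term": t,
                                "scale": eff.scale, "estimate": eff.estimate,
                                "ci_lo": eff.ci95[0], "ci_hi": eff.ci95[1],
                                "per": eff.per,
                            })
        return pd.DataFrame(rows), fits

    def _discrimination(self, fits):
        cfg = self.config
        rows, cal_rows, ph_frames = [], [], {}
        for s in cfg.strategies:
            for outcome in cfg.outcomes:
                for adj in cfg.adjustments:
                    fit_pf = fits.get((s, outcome, "pf", adj))
                    fit_fi = fits.get((s, outcome, "fi", adj))
                    if fit_pf is None or fit_fi is None:
                        continue
                    if outcome == "fracture":
                        res_pf, res_fi, p = disc.concordance_contrast(
                            fit_pf.times, fit_pf.events,
                            fit_pf.risk_score, fit_fi.risk_score,
                            n_boot=cfg.n_boot, seed=cfg.seed,
                        )
                        rows.append({
                            "strategy": s, "outcome": outcome,
                            "adjustment": adj, "metric": "c-index",
                            "stat_pf": res_pf.c_index,
                            "pf_ci_lo": res_pf.ci95[0] if res_pf.ci95 else np.nan,
                            "pf_ci_hi": res_pf.ci95[1] if res_pf.ci95 else np.nan,
                            "stat_fi": res_fi.c_index,
                            "fi_ci_lo": res_fi.ci95[0] if res_fi.ci95 else np.nan,
                            "fi_ci_hi": res_fi.ci95[1] if res_fi.ci95 else np.nan,
                            "p_contrast": p,
                        })
                        cal_rows.append({
                            "strategy": s, "outcome": outcome, "adjustment": adj,
                            "statistic": "AIC(partial)",
                            "pf": fit_pf.aic_partial, "fi": fit_fi.aic_partial,
                            "pf_p": np.nan, "fi_p": np.nan,
                        })
                        if adj == "multivariable":
                            ph_frames[(s, "pf")] = schoenfeld_ph_check(fit_pf)
                            ph_frames[(s, "fi")] = schoenfeld_ph_check(fit_fi)
                    else:
                        contrast = disc.delong_contrast(
                            fit_pf.linear_predictor, fit_fi.linear_predictor,
                            fit_pf.y,
                        )
                        rows.append({
                            "strategy": s, "outcome": outcome,
                            "adjustment": adj, "metric": "AUC",
                            "stat_pf": contrast.auc_a,
                            "pf_ci_lo": contrast.ci95_a[0],
                            "pf_ci_hi": contrast.ci95_a[1],
                            "stat_fi": contrast.auc_b,
                            "fi_ci_lo": contrast.ci95_b[0],
                            "fi_ci_hi": contrast.ci95_b[1],
                            "p_contrast": contrast.p,
                        })
                        hl_pf = disc.hosmer_lemeshow(fit_pf.fitted_probs, fit_pf.y)
                        hl_fi = disc.hosmer_lemeshow(fit_fi.fitted_probs, fit_fi.y)
                        cal_rows.append({
                            "strategy": s, "outcome": outcome, "adjustment": adj,
                            "statistic": "Hosmer-Lemeshow",
                            "pf": hl_pf.hl_statistic, "fi": hl_fi.hl_statistic,
                            "pf_p": hl_pf.p, "fi_p": hl_fi.p,
                        })
        return pd.DataFrame(rows), pd.DataFrame(cal_rows), ph_frames

    def _group_counts(self, assignments) -> pd.DataFrame:
        rows = []
        for s, a in assignments.items():
            for instrument, labels in (("PF", a.pf_group), ("FI", a.fi_group)):
                vc = pd.Series(labels).value_counts()
                for lab, n in vc.items():
                    rows.append({
                        "strategy": s, "instrument": instrument,
                        "group": lab, "n": int(n),
                        "pct": 100.0 * n / len(labels),
                    })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------


@dataclass
class FrailtyComparisonResults:
    """Fitted pipeline output: estimates, contrasts, diagnostics, report."""

    config: RunConfig
    table: pd.DataFrame
    quartile_cuts: QuartileCuts
    assignments: dict[int, StrategyAssignment]
    agreement: pd.DataFrame
    effects: pd.DataFrame
    discrimination: pd.DataFrame
    calibration: pd.DataFrame
    ph_checks: dict
    group_counts: pd.DataFrame
    imputation_log: pd.DataFrame
    truth: object | None = None

    def summary(self) -> str:
        """Render the comparison report as plain text tables."""
        cfg = self.config
        lines = []
        lines.append("Frailty instrument comparison")
        lines.append("=" * 60)
        lines.append(f"participants: {len(self.table)}   subgroup: {cfg.subgroup}")
        s1 = self.assignments.get(1)
        if s1 is not None:
            lines.append(
                f"FI increment (1/5 of range): {s1.fi_increment:.4f} "
                f"(reported {round(s1.fi_increment, 2):.2f}); "
                f"strategy-1 cutpoints: "
                + ", ".join(f"{c:.2f}" for c in s1.fi_cutpoints)
            )
        s2 = self.assignments.get(2)
        if s2 is not None:
            lines.append(
                "strategy-2 density-overlap cutpoints: "
                + ", ".join(f"{c:.3f}" for c in s2.fi_cutpoints)
            )
        lines.append("")
        lines.append("Group frequencies (per strategy, instrument)")
        lines.append(self.group_counts.to_string(index=False,
                                                 float_format="%.2f"))
        lines.append("")
        lines.append("PF-FI agreement (Spearman)")
        lines.append(self.agreement.to_string(float_format="%.3f"))
        lines.append("")
        lines.append("Effect estimates (per increment / vs reference group)")
        eff = self.effects.copy()
        eff["95% CI"] = eff.apply(
            lambda r: f"({r.ci_lo:.2f}-{r.ci_hi:.2f})", axis=1
        )
        lines.append(
            eff[["strategy", "outcome", "instrument", "adjustment", "term",
                 "scale", "estimate", "95% CI"]]
            .to_string(index=False, float_format="%.2f")
        )
        lines.append("")
        lines.append("Discrimination (AUC for falls/death, c-index for fractures)")
        lines.append(self.discrimination.to_string(index=False,
                                                   float_format="%.3f"))
        lines.append("")
        lines.append("Calibration / model fit")
        lines.append(self.calibration.to_string(index=False,
                                                float_format="%.3f"))
        return "\n".join(lines)

    def to_json(self) -> dict:
        """JSON-serialisable report (cutpoints, counts, estimates, contrasts)."""
        payload = {
            "config": {
                "strategies": list(self.config.strategies),
                "outcomes": list(self.config.outcomes),
                "adjustments": list(self.config.adjustments),
                "subgroup": self.config.subgroup,
                "seed": self.config.seed,
                "n_boot": self.config.n_boot,
            },
            "n": int(len(self.table)),
            "strategy_cutpoints": {
                str(s): list(map(float, a.fi_cutpoints))
                for s, a in self.assignments.items()
            },
            "fi_increment": (
                float(self.assignments[1].fi_increment)
                if 1 in self.assignments else None
            ),
            "agreement": self.agreement.reset_index().to_dict(orient="records"),
            "effects": self.effects.to_dict(orient="records"),
            "discrimination": self.discrimination.to_dict(orient="records"),
            "calibration": self.calibration.to_dict(orient="records"),
            "group_counts": self.group_counts.to_dict(orient="records"),
        }
        return payload

    def save_artifacts(self, outdir: str | Path) -> None:
        """Write per-stage CSV/JSON artifacts under ``outdir``."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort(self.table, out / "scored_cohort.csv")
        self.quartile_cuts.to_json(out / "pf_quartile_cuts.json")
        assign = pd.DataFrame({"participant_id": self.table["participant_id"]})
        for s, a in self.assignments.items():
            assign[f"pf_group_s{s}"] = np.asarray(a.pf_group)
            assign[f"fi_group_s{s}"] = np.asarray(a.fi_group)
        assign.to_csv(out / "strategy_assignments.csv", index=False)
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(self.to_json(), fh, indent=2, default=float)
        with open(out / "report.txt", "w", encoding="utf-8") as fh:
            fh.write(self.summary())
        if not self.imputation_log.empty:
            self.imputation_log.to_csv(out / "imputation_log.csv", index=False)

    def plot_fi_densities(self, ax=None):
        """FI kernel densities by PF category with the strategy-2 cutpoints."""
        import matplotlib.pyplot as plt
        from scipy.stats import gaussian_kde

        if ax is None:
            _, ax = plt.subplots()
        grid = np.linspace(0, 1, 512)
        fi = self.table["fi"].to_numpy(dtype=float)
        cat = self.table["pf_category"].to_numpy(dtype=object)
        for g in CATEGORY_ORDER:
            vals = fi[cat == g]
            if vals.size >= 10:
                ax.plot(grid, gaussian_kde(vals, bw_method="silverman")(grid),
                        label=g)
        if 2 in self.assignments:
            for c in self.assignments[2].fi_cutpoints:
                ax.axvline(c, color="grey", linestyle="--")
        ax.set_xlabel("frailty index")
        ax.set_ylabel("density")
        ax.legend()
        return ax
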