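import json

import numpy as np
import pandas as pd
import pytest

from frailtycompare.phenotype import (
    PF_LEVELS_SF36,
    PF_LEVELS_VITALITY,
    PFComponents,
    QuartileCuts,
    categorize,
    compute_components,
    compute_quartile_cuts,
    pf_columns,
    score_pf,
    score_sf36_pf_item,
    score_vitality_item,
)


class TestItemScoring:
    @pytest.mark.parametrize(
        "response,points",
        [("limited a lot", 0.0), ("limited a little", 50.0), ("not limited", 100.0)],
    )
    def test_sf36_three_point_scale(self, response, points):
        assert score_sf36_pf_item(response) == points

    def test_sf36_unknown_level(self):
        with pytest.raises(ValueError, match="unknown SF-36"):
            score_sf36_pf_item("somewhat limited")

    @pytest.mark.parametrize(
        "response,points",
        [("none of the time", 100.0), ("a little of the time", 75.0),
         ("some of the time", 50.0), ("most of the time", 25.0),
         ("all of the time", 0.0)],
    )
    def test_vitality_negative_items(self, response, points):
        # negatively worded ("worn out"): happening all the time is worst
        assert score_vitality_item(response) == points

    def test_vitality_reverse_coding_for_positive_items(self):
        # positively worded ("full of energy"): all the time is best
        for resp in PF_LEVELS_VITALITY:
            assert (
                score_vitality_item(resp, reverse=True)
                == 100.0 - score_vitality_item(resp, reverse=False)
            )

    def test_vitality_midpoint_interpolation(self):
        assert score_vitality_item("some of the time") == 50.0


class TestCategorize:
    @pytest.mark.parametrize(
        "total,cat",
        [(0, "robust"), (1, "pre-frail"), (2, "pre-frail"),
         (3, "frail"), (4, "frail"), (5, "frail")],
    )
    def test_mapping(self, total, cat):
        assert categorize(total) == cat

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            categorize(6)


class TestScorePF:
    cuts = QuartileCuts(q1_slowness_weakness=60.0, q1_exhaustion=50.0,
                        q1_activity=4.0)

    def test_all_good_is_robust(self):
        comp = PFComponents(100.0, 100.0, 30.0, 0)
        res = score_pf(comp, self.cuts)
        assert res.total == 0 and res.category == "robust"

    def test_all_bad_is_frail_with_five_points(self):
        comp = PFComponents(0.0, 0.0, 0.0, 1)
        res = score_pf(comp, self.cuts)
        assert res.total == 5 and res.category == "frail"
        assert res.points_slowness_weakness == 2

    def test_cut_boundary_is_inclusive(self):
        at_cut = PFComponents(60.0, 50.0, 4.0, 0)
        res = score_pf(at_cut, self.cuts)
        assert (res.points_slowness_weakness, res.points_exhaustion,
                res.points_activity) == (2, 1, 1)
        above = PFComponents(60.0 + 1e-9, 50.0 + 1e-9, 5.0, 0)
        assert score_pf(above, self.cuts).total == 0

    def test_slowness_weakness_carries_double_weight(self):
        only_sw = PFComponents(10.0, 100.0, 30.0, 0)
        res = score_pf(only_sw, self.cuts)
        assert res.total == 2 and res.category == "pre-frail"

    def test_missing_component_rejected(self):
        comp = PFComponents(float("nan"), 100.0, 30.0, 0)
        with pytest.raises(ValueError, match="missing"):
            score_pf(comp, self.cuts)


class TestComponents:
    def _one_row(self, sf_level, vit_levels, walk, wl):
        row = {f"sf36_pf_{i:02d}": sf_level for i in range(1, 11)}
        row.update(
            vitality_worn_out=vit_levels[0], vitality_full_of_life=vit_levels[1],
            vitality_tired=vit_levels[2], vitality_energy=vit_levels[3],
            walk20_days=walk, weight_loss_10lb=wl,
        )
        return pd.DataFrame([row])

    def test_component_means(self):
        tab = self._one_row(
            "limited a little",
            ("some of the time",) * 4,
            12, 1,
        )
        comps = compute_components(tab)
        assert comps.loc[0, "pf_slowness_weakness"] == 50.0
        # two negative items at 50, two positive reverse-coded to 50
        assert comps.loc[0, "pf_exhaustion"] == 50.0
        assert comps.loc[0, "pf_activity_days"] == 12
        assert comps.loc[0, "pf_weight_loss"] == 1

    def test_half_rule_for_missing_items(self):
        tab = self._one_row("not limited", ("none of the time",
                                            "all of the time",
                                            "none of the time",
                                            "all of the time"), 30, 0)
        for col in [f"sf36_pf_{i:02d}" for i in range(1, 6)]:
            tab[col] = np.nan
        comps = compute_components(tab)
        assert comps.loc[0, "pf_slowness_weakness"] == 100.0  # 5 of 10 answered
        tab2 = tab.copy()
        tab2["sf36_pf_06"] = np.nan  # only 4 of 10 answered -> missing
        assert np.isnan(compute_components(tab2).loc[0, "pf_slowness_weakness"])


class TestQuartileCuts:
    def test_matches_numpy_percentile(self, rng):
        comps = pd.DataFrame({
            "pf_slowness_weakness": rng.uniform(0, 100, 97),
            "pf_exhaustion": rng.uniform(0, 100, 97),
            "pf_activity_days": rng.integers(0, 31, 97),
        })
        cuts = compute_quartile_cuts(comps)
        assert cuts.q1_slowness_weakness == pytest.approx(
            np.percentile(comps["pf_slowness_weakness"], 25))
        assert cuts.q1_activity == pytest.approx(
            np.percentile(comps["pf_activity_days"], 25))

    def test_too_few_values(self):
        comps = pd.DataFrame({
            "pf_slowness_weakness": [1.0, 2.0, 3.0],
            "pf_exhaustion": [1.0, 2.0, 3.0],
            "pf_activity_days": [1.0, 2.0, 3.0],
        })
        with pytest.raises(ValueError, match="at least 4"):
            compute_quartile_cuts(comps)

    def test_json_round_trip(self, tmp_path):
        cuts = QuartileCuts(57.5, 43.75, 6.0)
        p = tmp_path / "cuts.json"
        cuts.to_json(p)
        assert QuartileCuts.from_json(p) == cuts
        with open(p) as fh:
            assert set(json.load(fh)) == {
                "q1_slowness_weakness", "q1_exhaustion", "q1_activity"}


class TestPFColumns:
    def test_cohort_scoring_consistency(self, small_cohort):
        pf, cuts = pf_columns(small_cohort)
        assert len(pf) == len(small_cohort)
        assert pf["pf_score"].between(0, 5).all()
        # each row's total is reproduced by the scalar scorer
        for ridx in [0, 42, 250]:
            comp = PFComponents(
                pf.loc[ridx, "pf_slowness_weakness"],
                pf.loc[ridx, "pf_exhaustion"],
                pf.loc[ridx, "pf_activity_days"],
                int(pf.loc[ridx, "pf_weight_loss"]),
            )
            res = score_pf(comp, cuts)
            assert res.total == pf.loc[ridx, "pf_score"]
            assert res.category == pf.loc[ridx, "pf_category"]

    def test_quartile_point_prevalence(self, default_cohort):
        # roughly a quarter of the cohort should earn each quartile point
        pf, _ = pf_columns(default_cohort)
        for col in ["pf_points_exhaustion", "pf_points_activity"]:
            share = (pf[col] > 0).mean()
            assert 0.20 <= share <= 0.40

    def test_stored_cuts_reused_verbatim(self, small_cohort):
        _, cuts = pf_columns(small_cohort)
        pf2, cuts2 = pf_columns(small_cohort, cuts=cuts)
        assert cuts2 == cuts
        pf1, _ = pf_columns(small_cohort)
        assert (pf1["pf_score"] == pf2["pf_score"]).all()
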