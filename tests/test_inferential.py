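"""Within-subject ANOVA, pairwise follow-ups, paired t and normality checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gripdisc import (
    bonferroni_pairwise,
    cell_means,
    paired_t,
    partition_eligibility,
    rm_anova,
    shapiro_wilk,
)
from gripdisc.inferential import _anova_from_matrix
from gripdisc.trial_data import TrialRecord


def _cells_frame(data, factors):
    """data: {participant: {cell-tuple: value}} -> tidy cell-mean frame."""
    rows = []
    for pid, cells in data.items():
        for cell, value in cells.items():
            rows.append({"participant_id": pid, **dict(zip(factors, cell)), "mga_mm": value})
    return pd.DataFrame(rows)


class TestCellMeans:
    def _mini_records(self):
        recs = []
        mgas = {
            (40.0, True): [80.0, 84.0],
            (40.0, False): [70.0],
            (40.5, True): [90.0],
            (40.5, False): [75.0],
        }
        for block in (1, 2, 3):
            for (target, correct), values in mgas.items():
                response = "larger" if (target == 40.5) == correct else "smaller"
                for mga in values:
                    recs.append(
                        TrialRecord(
                            participant_id="P01", experiment="E1", block=block,
                            vision="none", target_size_mm=target,
                            distractor_size_mm=80.5 - target,
                            verbal_response=response, mga_mm=mga,
                        )
                    )
        return recs

    def test_two_trial_cell_averages(self):
        pset = partition_eligibility(self._mini_records())
        cells = cell_means(pset, ["size", "verbal", "block"])
        small_correct = cells.query("size == 'small' and verbal == 'correct'")
        assert small_correct["mga_mm"].tolist() == [82.0, 82.0, 82.0]
        single = cells.query("size == 'big' and verbal == 'correct'")
        assert single["mga_mm"].tolist() == [90.0, 90.0, 90.0]

    def test_matches_groupby_oracle_on_synthetic_data(self, small_e1_records):
        pset = partition_eligibility(small_e1_records)
        cells = cell_means(pset, ["size", "verbal", "block"])
        df = pd.DataFrame(
            {
                "participant_id": [r.participant_id for r in small_e1_records],
                "size": ["small" if r.target_size_mm == 40.0 else "big" for r in small_e1_records],
                "verbal": ["correct" if r.verbal_correct else "incorrect" for r in small_e1_records],
                "block": [r.block for r in small_e1_records],
                "mga_mm": [r.mga_mm for r in small_e1_records],
            }
        )
        df = df[df["participant_id"].isin(pset.anova_eligible)]
        oracle = df.groupby(["participant_id", "size", "verbal", "block"])["mga_mm"].mean()
        for _, row in cells.iterrows():
            key = (row["participant_id"], row["size"], row["verbal"], row["block"])
            assert row["mga_mm"] == pytest.approx(oracle.loc[key])

    def test_empty_cell_for_included_participant_is_error(self):
        recs = [r for r in self._mini_records() if not (r.block == 2 and not r.verbal_correct)]
        pset = partition_eligibility(recs)
        with pytest.raises(ValueError, match="empty design cells|restrict"):
            cell_means(pset, ["size", "verbal", "block"], participants={"P01"})


class TestRmAnova:
    def test_two_subject_hand_example(self):
        # paired t on (1,2) vs (2,4) is 3.0 -> F(1,1) = 9
        cells = _cells_frame(
            {"P1": {("small",): 1.0, ("big",): 2.0}, "P2": {("small",): 2.0, ("big",): 4.0}},
            ["size"],
        )
        table = rm_anova(cells, within=["size"])
        row = table.iloc[0]
        assert row["F"] == pytest.approx(9.0)
        assert (row["df_effect"], row["df_error"]) == (1, 1)

    def test_f_equals_t_squared_identity(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 12))
            x, y = rng.normal(0, 1, n), rng.normal(0.3, 1, n)
            cells = _cells_frame(
                {f"P{i}": {("small",): x[i], ("big",): y[i]} for i in range(n)}, ["size"]
            )
            row = rm_anova(cells, within=["size"]).iloc[0]
            t = paired_t(x, y)
            assert row["F"] == pytest.approx(t.t**2, abs=1e-10, rel=1e-10)
            assert row["p"] == pytest.approx(t.p, abs=1e-12)

    def test_matches_statsmodels_three_way(self, rng):
        from statsmodels.stats.anova import AnovaRM

        n = 10
        rows = []
        for i in range(n):
            for b in (1, 2, 3):
                for s in ("small", "big"):
                    for v in ("correct", "incorrect"):
                        rows.append(
                            {
                                "participant_id": f"P{i:02d}", "block": b, "size": s,
                                "verbal": v, "mga_mm": rng.normal(80, 3),
                            }
                        )
        cells = pd.DataFrame(rows)
        mine = rm_anova(cells, within=["block", "size", "verbal"]).set_index("effect")
        ref = AnovaRM(
            cells, depvar="mga_mm", subject="participant_id",
            within=["block", "size", "verbal"],
        ).fit().anova_table
        name_map = {
            "block": "block", "size": "size", "verbal": "verbal",
            "block:size": "block x size", "block:verbal": "block x verbal",
            "size:verbal": "size x verbal",
            "block:size:verbal": "block x size x verbal",
        }
        for ref_name, my_name in name_map.items():
            assert mine.loc[my_name, "F"] == pytest.approx(
                ref.loc[ref_name, "F Value"], rel=1e-8
            )
            assert mine.loc[my_name, "p"] == pytest.approx(
                ref.loc[ref_name, "Pr > F"], abs=1e-10
            )
            assert mine.loc[my_name, "df_effect"] == ref.loc[ref_name, "Num DF"]
            assert mine.loc[my_name, "df_error"] == ref.loc[ref_name, "Den DF"]

    def test_sum_of_squares_conservation(self, rng):
        Y = rng.normal(80, 4, size=(8, 12))
        table = _anova_from_matrix(Y, [3, 2, 2], ["block", "size", "verbal"])
        total_within = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum()
        assert (table["SS_effect"] + table["SS_error"]).sum() == pytest.approx(total_within)
        assert ((table["partial_eta_sq"] >= 0) & (table["partial_eta_sq"] <= 1)).all()

    def test_gg_epsilon_reported_for_three_level_factor(self, rng):
        Y = rng.normal(0, 1, size=(12, 6))
        table = _anova_from_matrix(Y, [3, 2], ["block", "size"]).set_index("effect")
        assert 0.5 <= table.loc["block", "gg_epsilon"] <= 1.0
        assert table.loc["size", "gg_epsilon"] == 1.0
        assert table.loc["size", "p_gg"] == table.loc["size", "p"]

    def test_partial_eta_sq_increases_with_effect_size(self, rng):
        base = rng.normal(0, 1, size=(10, 2))
        etas = []
        for bump in (0.0, 0.5, 1.0, 2.0):
            Y = base.copy()
            Y[:, 1] += bump
            etas.append(
                _anova_from_matrix(Y, [2], ["size"]).iloc[0]["partial_eta_sq"]
            )
        assert etas == sorted(etas)

    def test_type_one_error_calibrated_on_null(self, rng):
        reject = 0
        reps = 600
        for _ in range(reps):
            Y = rng.normal(0, 1, size=(12, 4))
            p = _anova_from_matrix(Y, [2, 2], ["size", "verbal"]).iloc[0]["p"]
            reject += p < 0.05
        rate = reject / reps
        assert abs(rate - 0.05) < 0.025

    def test_incomplete_table_and_tiny_n_are_errors(self):
        cells = _cells_frame({"P1": {("small",): 1.0, ("big",): 2.0}}, ["size"])
        with pytest.raises(ValueError):
            rm_anova(cells, within=["size"])
        cells2 = _cells_frame(
            {"P1": {("small",): 1.0}, "P2": {("small",): 2.0, ("big",): 1.0}}, ["size"]
        )
        with pytest.raises(ValueError):
            rm_anova(cells2, within=["size"])


class TestPairedT:
    def test_identical_samples(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (res.t, res.p) == (0.0, 1.0)

    def test_hand_computed_diffs(self):
        # diffs [1,2,3]: mean 2, sd 1, t = 2 / (1/sqrt(3))
        res = paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(2 * np.sqrt(3), abs=1e-10)
        assert res.df == 2
        assert res.mean_diff == 2.0

    def test_matches_scipy_on_random_pairs(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 20))
            x, y = rng.normal(0, 1, n), rng.normal(0.2, 1, n)
            res = paired_t(x, y)
            t_ref, p_ref = stats.ttest_rel(x, y)
            assert res.t == pytest.approx(t_ref, abs=1e-12)
            assert res.p == pytest.approx(p_ref, abs=1e-12)

    def test_zero_variance_conventions(self):
        res = paired_t([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
        assert np.isinf(res.t) and res.t > 0 and res.p == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0], [1.0])


class TestBonferroniPairwise:
    def test_identical_conditions_adjusted_to_one(self, rng):
        vals = rng.normal(80, 2, 8)
        cells = _cells_frame(
            {f"P{i}": {("small",): vals[i], ("big",): vals[i]} for i in range(8)},
            ["size"],
        )
        out = bonferroni_pairwise(cells, compare="size", family_size=4)
        assert out["p_adj"].tolist() == [1.0]
        assert out["ci_lo_1"].iloc[0] <= out["mean_2"].iloc[0] <= out["ci_hi_1"].iloc[0]

    def test_family_of_one_is_identity(self, rng):
        cells = _cells_frame(
            {f"P{i}": {("small",): rng.normal(), ("big",): rng.normal(0.5)} for i in range(9)},
            ["size"],
        )
        out = bonferroni_pairwise(cells, compare="size", family_size=1)
        assert out["p_adj"].iloc[0] == pytest.approx(out["p"].iloc[0])

    def test_decomposes_interaction_within_strata(self, rng):
        # size effect present only within correct judgements
        data = {}
        for i in range(12):
            base = rng.normal(80, 1)
            data[f"P{i}"] = {
                ("small", "correct"): base + rng.normal(0, 0.3),
                ("big", "correct"): base + 1.5 + rng.normal(0, 0.3),
                ("small", "incorrect"): base + rng.normal(0, 0.3),
                ("big", "incorrect"): base + rng.normal(0, 0.3),
            }
        cells = _cells_frame(data, ["size", "verbal"])
        out = bonferroni_pairwise(cells, compare="size", within_levels_of="verbal")
        out = out.set_index("stratum")
        assert out.loc["correct", "p_adj"] < 0.01
        assert out.loc["incorrect", "p_adj"] > 0.05

    def test_invalid_family_size(self):
        cells = _cells_frame({"P1": {("small",): 1.0, ("big",): 2.0},
                              "P2": {("small",): 1.5, ("big",): 2.5}}, ["size"])
        with pytest.raises(ValueError):
            bonferroni_pairwise(cells, compare="size", family_size=0)


class TestShapiroWilk:
    def test_matches_scipy(self, rng):
        x = rng.normal(0, 1, 30)
        w, p = shapiro_wilk(x)
        w_ref, p_ref = stats.shapiro(x)
        assert (w, p) == (pytest.approx(w_ref), pytest.approx(p_ref))

    def test_rejects_heavy_skew(self, rng):
        rejections = sum(
            shapiro_wilk(rng.exponential(1.0, 30))[1] < 0.05 for _ in range(100)
        )
        assert rejections > 50

    def test_null_p_roughly_uniform(self, rng):
        ps = [shapiro_wilk(rng.normal(0, 1, 30))[1] for _ in range(200)]
        assert 0.01 < np.mean(ps) < 0.99
        assert sum(p < 0.05 for p in ps) < 30

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(ValueError):
            shapiro_wilk([3.0, 3.0, 3.0, 3.0])
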