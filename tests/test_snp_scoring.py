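"""Rule-based scoring, ledger merging/ranking, and SNP-set selection."""

import numpy as np
import pandas as pd
import pytest

import pigsnp as pg
from pigsnp.feature_selection import ALPHA_GRID, FeatureScoreTable, LassoPath
from pigsnp.snp_scoring import (
    POOLED_EYE_RULES,
    POOLED_HAIR_RULES,
    REGIONAL_EYE_RULES,
    EmptySnpSetError,
    Rule,
    ScoringRuleSet,
)


def make_scores(n_samples=100, **columns):
    """Build a FeatureScoreTable directly from rank/coefficient columns.

    ``columns`` maps snp_id -> dict with optional keys rank_f, rank_mi and
    coef_<alpha>; anything missing defaults to unranked / zero coefficient.
    """
    ids = sorted(columns)
    table = pd.DataFrame(index=pd.Index(ids, name="snp_id"))
    table["pearson_r"] = 0.5
    table["f_score"] = 1.0
    table["p_value"] = 0.5
    table["mi"] = 0.0
    table["rank_f"] = [columns[s].get("rank_f", np.nan) for s in ids]
    table["rank_mi"] = [columns[s].get("rank_mi", np.nan) for s in ids]
    coefs = pd.DataFrame(
        {a: [columns[s].get(f"coef_{a:g}", 0.0) for s in ids] for a in ALPHA_GRID},
        index=table.index,
    )
    path = LassoPath(
        alphas=ALPHA_GRID, coefs=coefs,
        intercepts={a: 0.0 for a in ALPHA_GRID},
        nonzero_counts={a: int((coefs[a].abs() > 1e-8).sum()) for a in ALPHA_GRID},
        train_r2={a: 0.0 for a in ALPHA_GRID},
        converged={a: True for a in ALPHA_GRID},
    )
    return FeatureScoreTable(table=table, path=path, n_samples=n_samples)


class TestPooledEyeRules:
    def test_top_five_f_scores_three(self):
        scores = make_scores(a={"rank_f": 1}, b={"rank_f": 6})
        out = pg.assign_pooled_eye_scores(scores)
        assert out["a"] == 3

    def test_top_ten_mi_only_scores_two(self):
        scores = make_scores(a={"rank_mi": 8}, b={"rank_mi": 30})
        out = pg.assign_pooled_eye_scores(scores)
        assert out["a"] == 2 and out["b"] == 0

    def test_coef_at_alpha_0005_scores_one(self):
        scores = make_scores(a={"coef_0.005": 0.12}, b={"coef_0.005": 0.09})
        out = pg.assign_pooled_eye_scores(scores)
        assert out["a"] == 1 and out["b"] == 0

    def test_coef_threshold_at_alpha_02_is_inclusive(self):
        scores = make_scores(a={"coef_0.2": 0.1}, b={"coef_0.2": -0.1})
        out = pg.assign_pooled_eye_scores(scores)
        assert out["a"] == 3 and out["b"] == 3  # >= 0.1 in absolute value

    def test_nonzero_at_alpha_05_scores_three(self):
        scores = make_scores(a={"coef_0.5": 1e-3})
        assert pg.assign_pooled_eye_scores(scores)["a"] == 3

    def test_maximum_matching_rule_wins(self):
        scores = make_scores(a={"rank_f": 2, "coef_0.005": 0.5})
        assert pg.assign_pooled_eye_scores(scores)["a"] == 3


class TestRegionalEyeRules:
    def test_top_five_requires_both_f_and_mi(self):
        both = make_scores(a={"rank_f": 3, "rank_mi": 4})
        only_f = make_scores(a={"rank_f": 3, "rank_mi": 40})
        assert pg.assign_regional_eye_scores(both)["a"] == 2
        assert pg.assign_regional_eye_scores(only_f)["a"] == 0

    def test_nonzero_alpha_07_scores_two(self):
        scores = make_scores(a={"coef_0.7": 0.01})
        assert pg.assign_regional_eye_scores(scores)["a"] == 2

    def test_top_six_both_scores_one(self):
        scores = make_scores(a={"rank_f": 6, "rank_mi": 6})
        assert pg.assign_regional_eye_scores(scores)["a"] == 1

    def test_no_rule_matched_scores_zero(self):
        scores = make_scores(a={})
        assert pg.assign_regional_eye_scores(scores)["a"] == 0

    def test_score_three_reserved_for_pooled_rulesets(self):
        with pytest.raises(ValueError, match="score 3"):
            ScoringRuleSet(name="bad", kind="regional", trait="eye",
                           rules=(Rule(3, ({"top": {"metric": "f", "k": 5}},)),))


class TestHairRules:
    def test_strict_005_coefficient_rule(self):
        scores = make_scores(a={"coef_0.2": 0.06}, b={"coef_0.2": 0.05})
        out = pg.assign_hair_scores(scores, best_members=[])
        assert out["a"] == 3  # strictly greater than 0.05
        assert out["b"] == 0

    def test_top_five_mi_alone_scores_three(self):
        scores = make_scores(a={"rank_mi": 5})
        assert pg.assign_hair_scores(scores, best_members=[])["a"] == 3

    def test_rest_of_best_list_scores_one(self):
        scores = make_scores(a={}, b={})
        out = pg.assign_hair_scores(scores, best_members=["a"])
        assert out["a"] == 1 and out["b"] == 0


def brute_force_scores(scores, ruleset, members=None):
    """Independent per-SNP rule evaluator (no vectorization, no max trick)."""
    tab = scores.table
    out = {}
    for snp in tab.index:
        matched = [0]
        for rule in ruleset.rules:
            hit = False
            for cond in rule.any_of:
                (kind, params), = cond.items()
                if kind == "top":
                    r = tab.loc[snp, f"rank_{params['metric']}"]
                    hit = hit or (pd.notna(r) and r <= params["k"])
                elif kind == "top_all":
                    hit = hit or all(
                        pd.notna(tab.loc[snp, f"rank_{m}"])
                        and tab.loc[snp, f"rank_{m}"] <= params["k"]
                        for m in params["metrics"]
                    )
                elif kind == "nonzero":
                    hit = hit or all(
                        abs(scores.path.coef(a)[snp]) > 1e-8
                        for a in params["alphas"]
                    )
                elif kind == "abs_coef":
                    c = abs(scores.path.coef(params["alpha"])[snp])
                    hit = hit or (c > params["min"] if params.get("strict")
                                  else c >= params["min"])
                elif kind == "member":
                    hit = hit or snp in (members or [])
            if hit:
                matched.append(rule.score)
        out[snp] = max(matched)
    return pd.Series(out)


@pytest.mark.parametrize("ruleset,needs_members", [
    (POOLED_EYE_RULES, False),
    (REGIONAL_EYE_RULES, False),
    (POOLED_HAIR_RULES, True),
])
def test_vectorized_scores_match_brute_force_on_random_tables(
    rng, ruleset, needs_members
):
    for trial in range(10):
        r = np.random.default_rng(1000 + trial)
        cols = {}
        ids = [f"s{i:02d}" for i in range(30)]
        for s in ids:
            entry = {}
            if r.random() < 0.5:
                entry["rank_f"] = int(r.integers(1, 40))
            if r.random() < 0.5:
                entry["rank_mi"] = int(r.integers(1, 40))
            for a in (0.7, 0.5, 0.2, 0.005):
                if r.random() < 0.3:
                    entry[f"coef_{a:g}"] = float(r.normal(scale=0.15))
            cols[s] = entry
        scores = make_scores(**cols)
        members = list(r.choice(ids, size=10, replace=False)) if needs_members else None
        got = pg.assign_scores(scores, ruleset, members=members)
        expected = brute_force_scores(scores, ruleset, members=members)
        pd.testing.assert_series_equal(got.sort_index(), expected.sort_index(),
                                       check_names=False, check_dtype=False)


def test_improving_rank_or_coefficient_never_lowers_score():
    base = make_scores(a={"rank_f": 11, "coef_0.005": 0.05})
    better_rank = make_scores(a={"rank_f": 4, "coef_0.005": 0.05})
    better_coef = make_scores(a={"rank_f": 11, "coef_0.005": 0.2})
    s0 = pg.assign_pooled_eye_scores(base)["a"]
    assert pg.assign_pooled_eye_scores(better_rank)["a"] >= s0
    assert pg.assign_pooled_eye_scores(better_coef)["a"] >= s0


class TestMergeAndRank:
    def test_total_is_sum_and_descending(self):
        ledger = pg.merge_and_rank({
            "Caucasus": pd.Series({"a": 2, "b": 0}),
            "WestSiberia": pd.Series({"a": 2, "b": 1}),
            "EuropeanRussia": pd.Series({"a": 2}),
            "pooled": pd.Series({"a": 3, "b": 2}),
        })
        assert ledger.loc["a", "total"] == 9  # 2+2+2+3, the top-tier pattern
        assert list(ledger.index) == ["a", "b"]

    def test_missing_dataset_contributes_zero(self):
        ledger = pg.merge_and_rank({
            "r1": pd.Series({"a": 2}),
            "pooled": pd.Series({"a": 1, "b": 2}),
        })
        assert ledger.loc["b", "r1"] == 0 and ledger.loc["b", "total"] == 2

    def test_all_zero_snp_excluded(self):
        ledger = pg.merge_and_rank({"pooled": pd.Series({"a": 1, "z": 0})})
        assert "z" not in ledger.index

    def test_dataset_order_does_not_change_totals(self):
        scores = {"r1": pd.Series({"a": 1, "b": 2}),
                  "pooled": pd.Series({"a": 3, "b": 1})}
        forward = pg.merge_and_rank(dict(scores))
        reverse = pg.merge_and_rank(dict(reversed(list(scores.items()))))
        pd.testing.assert_series_equal(forward["total"], reverse["total"])


class TestSelectSnpSets:
    def _ledger(self, rows):
        frame = pd.DataFrame(rows).T
        frame.index.name = "snp_id"
        frame["total"] = frame.sum(axis=1)
        frame["n_datasets"] = (frame.drop(columns="total") > 0).sum(axis=1)
        return frame

    def test_eye_minimal_takes_total_score_tier(self):
        ledger = self._ledger({
            "a": {"pooled": 3, "r1": 2}, "b": {"pooled": 3, "r1": 0},
            "c": {"pooled": 2, "r1": 0}, "d": {"pooled": 1, "r1": 1},
        })
        sets = pg.select_snp_sets(ledger, "eye")
        assert sets["minimal"] == ["a", "b"]
        assert set(sets["optimal"]) == {"a", "b", "c", "d"}

    def test_hair_minimal_is_pooled_score_three(self):
        ledger = self._ledger({"a": {"pooled": 3}, "b": {"pooled": 2},
                               "c": {"pooled": 1}})
        sets = pg.select_snp_sets(ledger, "hair")
        assert sets["minimal"] == ["a"]
        assert set(sets["optimal"]) == {"a", "b", "c"}

    def test_zero_score_snp_changes_nothing(self):
        base = self._ledger({"a": {"pooled": 3}})
        widened = self._ledger({"a": {"pooled": 3}, "z": {"pooled": 0}})
        assert pg.select_snp_sets(base, "hair") == pg.select_snp_sets(widened, "hair")

    def test_empty_sets_raise(self):
        ledger = self._ledger({"a": {"pooled": 1}})
        with pytest.raises(EmptySnpSetError):
            pg.select_snp_sets(ledger, "eye")


class TestReferenceLedgerWorkedExample:
    """The published 36-SNP eye-color score matrix as a worked example."""

    def test_exactly_five_snps_carry_pooled_score_three(self):
        ref = pg.reference_eye_score_ledger()
        assert int((ref["pooled"] == 3).sum()) == 5

    def test_ranking_reproduces_seven_top_total_snps(self):
        ref = pg.reference_eye_score_ledger()
        ledger = pg.merge_and_rank({
            col: ref[col] for col in
            ("Caucasus", "EuropeanRussia", "WestSiberia", "pooled")
        })
        assert int((ledger["total"] >= 3).sum()) == 7
        sets = pg.select_snp_sets(ledger, "eye")
        assert len(sets["minimal"]) == 7
        assert len(sets["optimal"]) == 36
        # the two known strongest SNPs top the ranking with total 9
        assert set(ledger.index[:2]) == {"chr15:28356859_C_T", "chr15:28365618_A_G"}
        assert (ledger["total"].iloc[:2] == 9).all()
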