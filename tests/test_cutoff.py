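"""Rule evaluation, the single-marker table and the grid search."""

import math

import numpy as np
import pandas as pd
import pytest

from methpanel import reference
from methpanel.calling import DEFAULT_PANEL_RULE, MarkerRule, PanelRule, call_panel
from methpanel.cutoff import (
    GroupMissingError,
    RuleGrid,
    evaluate_rule,
    optimize,
    single_marker_table,
)
from methpanel.stats import round_half_up

from conftest import make_cohort, make_record, random_cohort

NAN = math.nan


class TestEvaluateRule:
    def test_reference_training_performance(self, training_cohort):
        perf = evaluate_rule(training_cohort, DEFAULT_PANEL_RULE)
        assert perf.groups["CRC"].n_positive == 49
        assert perf.groups["control"].n_positive == 6
        assert perf.groups["AA"].n_positive == 4
        assert round_half_up(100 * perf.youden_crc) == 79.9
        assert round_half_up(100 * perf.youden_aa) == 57.4

    def test_constructed_extreme(self):
        rows = [make_record(f"C{i}", "CRC", sdc2=(36.0, 36.5, NAN))
                for i in range(5)]
        rows += [make_record(f"N{i}", "control") for i in range(5)]
        perf = evaluate_rule(make_cohort(rows), DEFAULT_PANEL_RULE)
        assert perf.sensitivity_crc == 1.0 and perf.specificity == 1.0
        assert perf.youden_crc == pytest.approx(1.0)

    def test_order_invariance(self, training_cohort):
        from methpanel.cohort import Cohort
        shuffled = Cohort(
            training_cohort.frame.sample(frac=1, random_state=3).reset_index(drop=True))
        a = evaluate_rule(training_cohort, DEFAULT_PANEL_RULE)
        b = evaluate_rule(shuffled, DEFAULT_PANEL_RULE)
        assert a.groups == b.groups

    def test_invalid_samples_excluded_from_denominators(self):
        rows = [make_record(f"C{i}", "CRC", sdc2=(36.0,) * 3) for i in range(4)]
        rows.append(make_record("C9", "CRC", actb=(NAN,) * 3, sdc2=(36.0,) * 3))
        rows += [make_record(f"N{i}", "control") for i in range(3)]
        perf = evaluate_rule(make_cohort(rows), DEFAULT_PANEL_RULE)
        assert perf.groups["CRC"].n_valid == 4
        assert perf.groups["CRC"].n_positive == 4

    def test_single_arm_panel_matches_marker_table(self, training_cohort):
        # a panel whose mSEPT9 arm can never fire reduces to the mSDC2 2/3 row
        muted = PanelRule(MarkerRule("sept9", 3, mean_ct_cutoff=25.0),
                          MarkerRule("sdc2", 2))
        perf = evaluate_rule(training_cohort, muted)
        row = single_marker_table(training_cohort).set_index(
            ["marker", "algorithm"]).loc[("sdc2", "2/3")]
        for g in ("control", "AA", "CRC"):
            assert perf.groups[g].n_positive == row[f"{g}_positive"]

    def test_missing_group_raises(self):
        rows = [make_record(f"C{i}", "CRC", sdc2=(36.0,) * 3) for i in range(3)]
        with pytest.raises(GroupMissingError, match="control"):
            evaluate_rule(make_cohort(rows), DEFAULT_PANEL_RULE)


class TestSingleMarkerTable:
    def test_reference_counts(self, training_cohort):
        table = single_marker_table(training_cohort)
        counts = reference.SINGLE_MARKER_COUNTS["training"]
        for _, row in table.iterrows():
            k = int(row["algorithm"][0])
            for group in ("control", "AA", "CRC"):
                n, *ks = counts[(row["marker"], group)]
                assert row[f"{group}_n"] == n
                assert row[f"{group}_positive"] == ks[k - 1], (row["marker"], k, group)

    def test_forced_two_of_three(self):
        rows = [make_record(f"C{i}", "CRC", sdc2=(36.0, 37.0, NAN)) for i in range(4)]
        rows += [make_record(f"N{i}", "control") for i in range(4)]
        table = single_marker_table(make_cohort(rows)).set_index(["marker", "algorithm"])
        assert table.loc[("sdc2", "1/3"), "CRC_rate"] == 1.0
        assert table.loc[("sdc2", "2/3"), "CRC_rate"] == 1.0
        assert table.loc[("sdc2", "3/3"), "CRC_rate"] == 0.0

    def test_rates_monotone_in_k(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            table = single_marker_table(random_cohort(rng, (10, 3, 10)))
            for marker in ("sept9", "sdc2"):
                sub = table[table["marker"] == marker].set_index("algorithm")
                for group in ("control", "AA", "CRC"):
                    rates = [sub.loc[f"{k}/3", f"{group}_rate"] for k in (1, 2, 3)]
                    assert rates[0] >= rates[1] >= rates[2]


def naive_optimize(cohort, grid, ranking):
    """Independent oracle: per-sample python loop + explicit lexicographic scan."""
    results = []
    for rule in grid.rules():
        counts = {g: [0, 0] for g in ("control", "AA", "CRC")}
        for rec in cohort.records():
            call = call_panel(rec, rule)
            if not call.validity.valid:
                continue
            counts[rec["group"]][0] += 1
            counts[rec["group"]][1] += int(call.panel_positive)
        rate = {g: (pos / n if n else float("nan")) for g, (n, pos) in counts.items()}
        keys = {
            "youden_crc": rate["CRC"] - rate["control"],
            "youden_aa": (rate["AA"] - rate["control"]
                          if not math.isnan(rate["AA"]) else -math.inf),
            "specificity": 1 - rate["control"],
        }
        results.append((rule, counts, tuple(keys[k] for k in ranking)))
    best = max(enumerate(results), key=lambda item: (item[1][2], -item[0]))
    return best[0], results


class TestOptimize:
    def test_exhaustive_grid_size(self, training_cohort):
        result = optimize(training_cohort)
        assert len(result.summaries) == 8
        assert len(result.to_frame()) == 8
        labels = {(s.rule.sept9.label, s.rule.sdc2.label) for s in result.summaries}
        assert len(labels) == 8

    def test_agrees_with_naive_oracle(self, training_cohort):
        grid = RuleGrid()
        ranking = ("youden_crc", "youden_aa", "specificity")
        result = optimize(training_cohort, grid, ranking)
        best_idx, oracle = naive_optimize(training_cohort, grid, ranking)
        assert result.best_index == best_idx
        for summary, (_, counts, _) in zip(result.summaries, oracle):
            for g in ("control", "AA", "CRC"):
                assert summary.groups[g].n_valid == counts[g][0]
                assert summary.groups[g].n_positive == counts[g][1]

    def test_agrees_with_naive_oracle_random(self):
        rng = np.random.default_rng(5)
        cohort = random_cohort(rng, (12, 4, 12))
        ranking = ("youden_crc", "youden_aa", "specificity")
        result = optimize(cohort, ranking=ranking)
        best_idx, _ = naive_optimize(cohort, RuleGrid(), ranking)
        assert result.best_index == best_idx

    def test_single_rule_grid(self, training_cohort):
        grid = RuleGrid(sept9_mean_cutoffs=(38.0,), sdc2_k=(2,))
        result = optimize(training_cohort, grid)
        assert len(result.summaries) == 1
        assert result.best_rule == DEFAULT_PANEL_RULE

    def test_specificity_breaks_youden_ties(self):
        # engineered so the 2/3 and 3/3 mSDC2 arms tie exactly on CRC Youden
        rows = [make_record(f"C{i}", "CRC", sdc2=(36.0,) * 3) for i in range(6)]
        rows.append(make_record("C6", "CRC", sdc2=(36.0, 36.0, NAN)))
        rows += [make_record(f"C{i}", "CRC") for i in range(7, 10)]
        rows.append(make_record("N0", "control", sdc2=(43.0, 43.0, NAN)))
        rows.append(make_record("N1", "control", sdc2=(43.0,) * 3))
        rows += [make_record(f"N{i}", "control") for i in range(2, 10)]
        cohort = make_cohort(rows)
        grid = RuleGrid(sept9_mean_cutoffs=(38.0,), sdc2_k=(2, 3))
        r23 = evaluate_rule(cohort, PanelRule(MarkerRule("sept9", 3, mean_ct_cutoff=38.0),
                                              MarkerRule("sdc2", 2)))
        r33 = evaluate_rule(cohort, PanelRule(MarkerRule("sept9", 3, mean_ct_cutoff=38.0),
                                              MarkerRule("sdc2", 3)))
        assert r23.youden_crc == pytest.approx(r33.youden_crc)
        result = optimize(cohort, grid, ranking=("youden_crc", "specificity"))
        assert result.best_rule.sdc2.k_of_n == 3  # higher specificity wins

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            RuleGrid(sept9_k=())
        with pytest.raises(ValueError):
            RuleGrid(sept9_mean_cutoffs=(38.0, 40.0))  # must be loosest first
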