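import numpy as np
import pandas as pd
import pytest

import abmtrial as ab
from abmtrial.config import CleaningConfig


def cell(pid, rts, correct=None, timepoint="pre", trial_type="congruent"):
    correct = correct if correct is not None else [True] * len(rts)
    return [(pid, timepoint, trial_type, c, r) for c, r in zip(correct, rts)]


class TestDiscardRules:
    def test_hand_computed_sd_outlier_cell(self, trials_factory):
        # nine 500 ms + one 1000 ms: m=550, s=158.11, bounds [233.8, 866.2]
        trials = trials_factory(cell("P1", [500.0] * 9 + [1000.0]))
        cleaned, report = ab.clean_trials(trials)
        assert (cleaned["discard_reason"] == "sd_outlier").sum() == 1
        assert cleaned.loc[cleaned["rt_ms"] == 1000.0, "discard_reason"].item() == "sd_outlier"
        row = report.cells.iloc[0]
        assert row["n_retained"] == 9
        assert row["n_sd_outlier"] == 1

    def test_absolute_bounds_override_sd_rule(self, trials_factory):
        trials = trials_factory(cell("P1", [150.0, 2500.0]))
        cleaned, _ = ab.clean_trials(trials)
        assert (cleaned["discard_reason"] == "absolute_bounds").all()

    def test_bounds_are_exclusive(self, trials_factory):
        # exactly 200 and 2000 ms survive ("<200 or >2000")
        trials = trials_factory(cell("P1", [200.0, 2000.0, 201.0, 1999.0]))
        cleaned, _ = ab.clean_trials(trials, CleaningConfig(sd_multiplier=100.0))
        assert not cleaned["discarded"].any()

    def test_zero_variance_cell_has_no_sd_discards(self, trials_factory):
        trials = trials_factory(cell("P1", [500.0] * 10))
        cleaned, _ = ab.clean_trials(trials)
        assert not cleaned["discarded"].any()

    def test_error_reason_takes_precedence(self, trials_factory):
        trials = trials_factory(cell("P1", [150.0, 500.0], correct=[False, True]))
        cleaned, _ = ab.clean_trials(trials)
        assert cleaned.loc[0, "discard_reason"] == "error"

    def test_sd_pass_is_single_not_iterative(self, trials_factory):
        # after removing 1000, the nine 500s would have s=0 and a second
        # pass would discard nothing more; but with a milder outlier the
        # single pass must keep values a recursive pass would drop
        rts = [480.0, 490, 500, 500, 500, 510, 520, 500, 500, 900]
        trials = trials_factory(cell("P1", rts))
        cleaned, _ = ab.clean_trials(trials)
        m, s = np.mean(rts), np.std(rts, ddof=1)
        expected = [r for r in rts if abs(r - m) > 2 * s]
        assert sorted(cleaned.loc[cleaned["discarded"], "rt_ms"]) == sorted(expected)


class TestReportInvariants:
    def test_counts_partition_per_cell(self, small_cohort):
        cells = small_cohort["report"].cells
        total = cells["n_error"] + cells["n_absolute"] + cells["n_sd_outlier"] + cells["n_retained"]
        assert (total == cells["n_total"]).all()
        assert cells["discard_fraction"].between(0, 1).all()

    def test_row_order_does_not_change_decisions(self, small_cohort):
        trials = small_cohort["trials"]
        shuffled = trials.sample(frac=1.0, random_state=5).reset_index(drop=True)
        c1, _ = ab.clean_trials(trials)
        c2, _ = ab.clean_trials(shuffled)
        key = ["participant_id", "timepoint", "trial_type", "rt_ms", "correct"]
        m1 = c1.sort_values(key).reset_index(drop=True)
        m2 = c2.sort_values(key).reset_index(drop=True)
        pd.testing.assert_series_equal(m1["discard_reason"], m2["discard_reason"])

    def test_lower_sd_multiplier_never_decreases_outliers(self, small_cohort):
        trials = small_cohort["trials"]
        n_outliers = []
        for mult in (3.0, 2.0, 1.0):
            cleaned, _ = ab.clean_trials(trials, CleaningConfig(sd_multiplier=mult))
            n_outliers.append((cleaned["discard_reason"] == "sd_outlier").sum())
        assert n_outliers == sorted(n_outliers)


class TestExclusion:
    @pytest.mark.parametrize("n_bad,expected", [(21, True), (20, False), (0, False)])
    def test_strict_twenty_percent_rule(self, trials_factory, n_bad, expected):
        rts = [2500.0] * n_bad + [500.0] * (100 - n_bad)
        trials = trials_factory(cell("P1", rts))
        _, report = ab.clean_trials(trials, CleaningConfig(sd_multiplier=1e6))
        assert ("P1" in report.excluded_participants) is expected

    def test_any_single_cell_can_trigger(self, trials_factory):
        rows = cell("P1", [500.0] * 100, timepoint="pre") + cell(
            "P1", [2500.0] * 30 + [500.0] * 70, timepoint="post"
        )
        _, report = ab.clean_trials(trials_factory(rows), CleaningConfig(sd_multiplier=1e6))
        assert report.excluded["P1"] == ("post", "congruent")

    def test_error_trials_count_in_denominator_and_numerator(self, trials_factory):
        # 15 errors + 10 absolute = 25% discarded of 100
        rts = [500.0] * 90 + [2500.0] * 10
        correct = [False] * 15 + [True] * 85
        trials = trials_factory(cell("P1", rts, correct=correct))
        _, report = ab.clean_trials(trials, CleaningConfig(sd_multiplier=1e6))
        assert report.cells.iloc[0]["discard_fraction"] == pytest.approx(0.25)
        assert "P1" in report.excluded_participants
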