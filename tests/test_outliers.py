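"""The 3σ residual criterion, the ensemble vote, and the curation report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stereoflag.dataset_io import Dataset, ReactionRecord
from stereoflag.outliers import (
    OutlierCriterion,
    count_votes,
    curation_report,
    detect_outliers,
    flag_outliers_one_process,
    vote,
)


def brute_force_flags(errors, multiplier=3.0, centering="mean"):
    """Independent two-pass oracle: explicit mean, explicit SD, explicit
    comparison — no shared code with the production path."""
    n = len(errors)
    mean = sum(errors) / n
    sd = (sum((e - mean) ** 2 for e in errors) / n) ** 0.5
    if centering == "mean":
        return [e - mean > multiplier * sd for e in errors]
    return [e > multiplier * sd for e in errors]


class TestCriterion:
    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(2024)
        for trial in range(1000):
            n = int(rng.integers(2, 120))
            errors = rng.exponential(5.0, n)
            if trial % 3 == 0:  # plant a gross outlier sometimes
                errors[int(rng.integers(n))] += 80.0
            for centering in ("mean", "none"):
                got = flag_outliers_one_process(
                    errors, OutlierCriterion(centering=centering)
                )
                assert got.tolist() == brute_force_flags(
                    list(errors), centering=centering
                )

    def test_uniformly_poor_model_flags_nothing(self):
        # identical errors everywhere: centered criterion stays silent
        errors = np.full(50, 37.5)
        assert not flag_outliers_one_process(errors).any()

    def test_single_gross_error_among_zeros(self):
        # mean 0.1, population SD ~0.995: deviation 9.9 > 3*SD flags only it
        errors = np.zeros(100)
        errors[42] = 10.0
        flags = flag_outliers_one_process(errors)
        assert flags[42] and flags.sum() == 1

    def test_population_sd_bounds_zscore_for_tiny_n(self):
        # max z-score is sqrt(n-1) = 2 for n=5: the centered 3-SD rule
        # cannot fire regardless of the error values
        rng = np.random.default_rng(0)
        for _ in range(200):
            errors = rng.uniform(0, 100, 5)
            assert not flag_outliers_one_process(errors).any()

    @given(
        st.lists(st.floats(0.0, 100.0), min_size=2, max_size=60),
        st.floats(0.01, 1000.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_scale_equivariance(self, errors, c):
        """Multiplying all errors by c > 0 leaves the flag set unchanged."""
        e = np.asarray(errors)
        base = flag_outliers_one_process(e)
        scaled = flag_outliers_one_process(c * e)
        assert np.array_equal(base, scaled)

    def test_monotone_in_the_raised_error_uncentered(self):
        rng = np.random.default_rng(1)
        errors = rng.exponential(3.0, 80)
        errors[7] = 60.0
        crit = OutlierCriterion(centering="none")
        assert flag_outliers_one_process(errors, crit)[7]
        for bump in (10, 50, 200):
            raised = errors.copy()
            raised[7] += bump
            assert flag_outliers_one_process(raised, crit)[7]

    def test_monotone_in_the_raised_error_centered_large_n(self):
        rng = np.random.default_rng(1)
        errors = rng.exponential(3.0, 200)  # n >= 50
        errors[7] = 80.0
        assert flag_outliers_one_process(errors)[7]
        for bump in (10, 50, 400):
            raised = errors.copy()
            raised[7] += bump
            assert flag_outliers_one_process(raised)[7]

    def test_fewer_than_two_errors_rejected(self):
        with pytest.raises(ValueError):
            flag_outliers_one_process([5.0])

    def test_criterion_validation(self):
        with pytest.raises(ValueError):
            OutlierCriterion(sd_multiplier=0)
        with pytest.raises(ValueError):
            OutlierCriterion(centering="median")


def _counts_frame(times, n_processes=9):
    return pd.DataFrame(
        {
            "reaction_id": range(len(times)),
            "times_as_outlier": times,
            "n_processes": n_processes,
        }
    )


class TestVote:
    @pytest.mark.parametrize(
        "times, expect",
        [(5, True), (4, False), (9, True), (0, False)],
    )
    def test_majority_boundary(self, times, expect):
        out = vote(_counts_frame([times]))
        assert bool(out.loc[0, "flagged"]) is expect

    def test_threshold_monotonicity(self):
        times = list(range(10))
        flags = {
            thr: set(
                vote(_counts_frame(times), thr).query("flagged")["reaction_id"]
            )
            for thr in (4, 5, 6)
        }
        assert flags[6] <= flags[5] <= flags[4]

    def test_counts_from_prediction_table(self):
        # two processes of one test fold; the last reaction extreme in both
        # (n=12 keeps its z-score sqrt(11) ~ 3.32 above the 3-SD line;
        # n=10 would sit exactly at the sqrt(n-1)=3 bound and not fire)
        rows = []
        for v in (1, 2):
            errors = [0.1] * 11 + [50.0]
            for rid, e in enumerate(errors):
                rows.append(
                    {"reaction_id": rid, "test_fold": 0, "val_fold": v,
                     "label": 50.0, "prediction": 50.0 + e, "abs_error": e}
                )
        counts = count_votes(pd.DataFrame(rows))
        assert counts.loc[counts["reaction_id"] == 11, "times_as_outlier"].item() == 2
        assert (counts.loc[counts["reaction_id"] != 11, "times_as_outlier"] == 0).all()

    def test_detect_outliers_end_to_end_frame(self):
        rows = []
        for v in range(1, 10):  # 9 processes
            for rid in range(20):
                e = 60.0 if rid == 13 and v <= 6 else 0.5
                rows.append(
                    {"reaction_id": rid, "test_fold": 0, "val_fold": v,
                     "label": 50.0, "prediction": 50.0 + e, "abs_error": e}
                )
        report = detect_outliers(pd.DataFrame(rows))
        flagged = report.query("flagged")
        assert flagged["reaction_id"].tolist() == [13]
        assert flagged["times_as_outlier"].item() == 6


class TestCurationReport:
    def _dataset(self, n):
        return Dataset(
            [
                ReactionRecord(i, "C[C@H](O)CC", "O=C1CCCC=C1", "OB(O)C", 50.0,
                               source_ref=f"ref{i}")
                for i in range(n)
            ]
        )

    def test_ranked_by_votes_then_id(self):
        rep = vote(_counts_frame([9, 5, 7, 9, 0, 3]))
        table, _ = curation_report(rep)
        assert table["reaction_id"].tolist() == [0, 3, 2, 1]

    def test_flagged_fraction_headline(self):
        times = [9] * 15 + [0] * 673  # 15 flagged of 688
        rep = vote(_counts_frame(times))
        _, summary = curation_report(rep, self._dataset(688))
        assert summary["n_flagged"] == 15
        assert summary["flagged_fraction"] == pytest.approx(15 / 688)
        assert 100 * summary["flagged_fraction"] == pytest.approx(2.18, abs=0.01)

    def test_nothing_flagged_gives_empty_table(self):
        rep = vote(_counts_frame([0, 1, 4]))
        table, summary = curation_report(rep, self._dataset(3))
        assert table.empty
        assert summary["n_flagged"] == 0 and summary["flagged_fraction"] == 0.0

    def test_metadata_joined_from_dataset(self):
        rep = vote(_counts_frame([9, 0]))
        table, _ = curation_report(rep, self._dataset(2))
        assert table.loc[0, "source_ref"] == "ref0"
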