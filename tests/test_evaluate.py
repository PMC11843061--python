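"""Risk groups, KS, PSI, AUC, incidence, lead times, escalation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sorpkit import evaluate


def brute_force_ks(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    best = 0.0
    for thr in np.r_[np.unique(s), np.inf]:
        f1 = np.mean(s[y == 1] <= thr)
        f0 = np.mean(s[y == 0] <= thr)
        best = max(best, abs(f1 - f0))
    return best


def brute_force_auc(scores, labels):
    """Pairwise concordance of the reversed (risk-oriented) ranking."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    total = conc = 0.0
    for p in pos:
        for n in neg:
            total += 1
            if p < n:          # lower score = riskier = ranked above
                conc += 1
            elif p == n:
                conc += 0.5
    return conc / total


class TestAssignGroup:
    @pytest.mark.parametrize("score,group", [
        (35.0, "HR"), (0.0, "HR"), (39.99, "HR"),
        (40.0, "MR"), (59.0, "MR"),
        (60.0, "LR"), (79.9, "LR"),
        (80.0, "ULR"), (100.0, "ULR"),
    ])
    def test_interval_lookup(self, score, group):
        assert evaluate.assign_group(score) == group

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            evaluate.assign_group(101.0)
        with pytest.raises(ValueError):
            evaluate.assign_groups([-0.5, 20.0])

    def test_vectorized_agrees_with_scalar(self, rng):
        s = rng.uniform(0, 100, 200)
        vec = evaluate.assign_groups(s)
        assert all(vec[i] == evaluate.assign_group(s[i]) for i in range(200))


class TestKS:
    def test_identical_distributions_zero(self):
        s = np.r_[np.arange(10.0), np.arange(10.0)]
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        assert evaluate.ks_curve(s, y).statistic == pytest.approx(0.0)

    def test_perfect_separation_one(self):
        s = np.r_[np.arange(10.0), np.arange(50.0, 60.0)]
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        assert evaluate.ks_curve(s, y).statistic == pytest.approx(1.0)

    def test_matches_bruteforce_and_scipy(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 31))
            s = np.round(rng.uniform(0, 100, n), 1)
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            ks = evaluate.ks_curve(s, y)
            assert ks.statistic == pytest.approx(brute_force_ks(s, y), abs=1e-12)
            ref = stats.ks_2samp(s[y == 1], s[y == 0], method="exact").statistic
            assert ks.statistic == pytest.approx(ref, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            evaluate.ks_curve([1.0, 2.0], [1, 1])

    def test_monotone_invariance(self, rng):
        s = rng.uniform(0, 1, 60)
        y = rng.integers(0, 2, 60)
        a = evaluate.ks_curve(100 * s, y).statistic
        b = evaluate.ks_curve(100 * s ** 3, y).statistic
        assert a == pytest.approx(b, abs=1e-12)


class TestIncidence:
    def test_printed_group_rates(self):
        """Per-group incidence arithmetic reproduces the published table."""
        printed = {"HR": (433, 489, 88.6), "MR": (262, 760, 34.5),
                   "LR": (67, 2707, 2.5), "ULR": (4, 1301, 0.3)}
        groups, outcomes = [], []
        for g, (pos, n, _) in printed.items():
            groups += [g] * n
            outcomes += [1] * pos + [0] * (n - pos)
        table = evaluate.group_incidence(groups, outcomes).set_index("group")
        for g, (pos, n, pct) in printed.items():
            assert table.loc[g, "positives"] == pos
            assert table.loc[g, "n"] == n
            assert abs(table.loc[g, "pct"] - pct) <= 0.1

    def test_zero_numerator(self):
        table = evaluate.group_incidence(["HR"] * 5, [0] * 5).set_index("group")
        assert table.loc["HR", "pct"] == 0.0

    def test_empty_group_reported_absent(self):
        table = evaluate.group_incidence(["HR"], [1]).set_index("group")
        assert np.isnan(table.loc["ULR", "rate"])

    def test_incidence_pct_helper(self):
        assert evaluate.incidence_pct(262, 760) == 34.5
        assert evaluate.incidence_pct(4, 1301) == 0.3
        with pytest.raises(ValueError):
            evaluate.incidence_pct(1, 0)


class TestPSI:
    def test_identical_zero(self, rng):
        s = rng.uniform(0, 100, 500)
        assert evaluate.psi(s, s) == pytest.approx(0.0)

    def test_two_bin_value(self):
        got = evaluate.psi(np.array([0.5, 0.5]), np.array([0.25, 0.75]))
        expected = 0.25 * np.log(2) - 0.25 * np.log(1 / 1.5)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.2746, abs=1e-4)

    def test_symmetry(self, rng):
        a, b = rng.uniform(0, 100, 400), rng.uniform(0, 100, 400) ** 0.9
        b = np.clip(b, 0, 100)
        assert evaluate.psi(a, b) == pytest.approx(evaluate.psi(b, a), abs=1e-12)

    def test_nonnegative(self, rng):
        for _ in range(50):
            p = rng.integers(0, 30, 4).astype(float)
            q = rng.integers(1, 30, 4).astype(float)
            if p.sum() == 0:
                continue
            assert evaluate.psi(p, q) >= 0.0

    def test_smoothing_perturbation_small(self, rng):
        p = rng.integers(10, 100, 4).astype(float)
        q = rng.integers(10, 100, 4).astype(float)
        assert abs(evaluate.psi(p, q, eps=1e-4)
                   - evaluate.psi(p, q, eps=1e-12)) <= 1e-3

    def test_incompatible_binnings_rejected(self):
        with pytest.raises(ValueError, match="incompatible"):
            evaluate.psi(np.array([0.5, 0.5]), np.array([0.2, 0.3, 0.5]))


class TestAUC:
    def test_perfect_inverse_ranking(self):
        s = np.array([10.0, 20.0, 80.0, 90.0])
        y = np.array([1, 1, 0, 0])
        assert evaluate.auc(s, y) == 1.0

    def test_null_case(self, rng):
        s = rng.uniform(0, 100, 20_000)
        y = rng.integers(0, 2, 20_000)
        assert evaluate.auc(s, y) == pytest.approx(0.5, abs=0.02)

    def test_matches_bruteforce_concordance(self, rng):
        for _ in range(200):
            s = np.round(rng.uniform(0, 100, 20), 0)
            y = rng.integers(0, 2, 20)
            if y.sum() in (0, 20):
                continue
            assert evaluate.auc(s, y) == pytest.approx(
                brute_force_auc(s, y), abs=1e-12)

    def test_monotone_invariance(self, rng):
        s = rng.uniform(0, 1, 100)
        y = rng.integers(0, 2, 100)
        assert evaluate.auc(100 * s, y) == pytest.approx(
            evaluate.auc(100 * np.sqrt(s), y), abs=1e-12)


class TestLeadTimes:
    def test_single_entry_lead(self):
        series = {"P0": pd.Series([80, 50, 30, 20], index=[20, 21, 22, 23])}
        rep = evaluate.forewarning_leadtimes(series, {"P0": 32.0})
        assert rep.leads["P0"] == 10.0

    def test_never_in_hr_counts_in_denominator(self):
        series = {"P0": pd.Series([80, 30], index=[10, 11]),
                  "P1": pd.Series([80, 90], index=[10, 11])}
        rep = evaluate.forewarning_leadtimes(series, {"P0": 17.0, "P1": 17.0})
        assert rep.median_lead == 6.0
        assert rep.frac_at(6) == 0.5
        assert np.isnan(rep.leads["P1"])

    def test_cohort_median_of_three(self):
        series = {p: pd.Series([30.0], index=[t])
                  for p, t in [("A", 10), ("B", 5), ("C", 3)]}
        onsets = {"A": 14.0, "B": 18.0, "C": 25.0}  # leads 4, 13, 22
        rep = evaluate.forewarning_leadtimes(series, onsets)
        assert rep.median_lead == 13.0

    def test_fraction_nondecreasing_toward_onset(self, rng):
        series, onsets = {}, {}
        for i in range(30):
            hours = np.arange(0, 40)
            scores = np.clip(rng.normal(60, 25, 40), 0, 100)
            series[i] = pd.Series(scores, index=hours)
            onsets[i] = 39.0
        rep = evaluate.forewarning_leadtimes(series, onsets)
        fr = [rep.frac_at(L) for L in (24, 13, 6, 0)]
        assert all(a <= b for a, b in zip(fr, fr[1:]))


class TestEscalation:
    def test_lr_to_mr_flagged(self):
        gs = {"P0": pd.Series(["LR", "LR", "MR"], index=[27, 28, 29])}
        flags = evaluate.escalation_detect(gs, {"P0": 30.0})
        assert flags["P0"] is True

    def test_constant_lr_not_flagged(self):
        gs = {"P0": pd.Series(["LR", "LR", "LR"], index=[27, 28, 29])}
        assert evaluate.escalation_detect(gs, {"P0": 30.0})["P0"] is False

    def test_jump_past_target_counts(self):
        gs = {"P0": pd.Series(["LR", "HR"], index=[28, 29])}
        assert evaluate.escalation_detect(gs, {"P0": 30.0})["P0"] is True

    def test_transition_outside_window_ignored(self):
        gs = {"P0": pd.Series(["LR", "MR", "MR", "MR", "MR"],
                              index=[20, 21, 27, 28, 29])}
        flags = evaluate.escalation_detect(gs, {"P0": 30.0}, within_h=3)
        assert flags["P0"] is False

    def test_printed_fraction(self):
        flags = {i: i < 35 for i in range(67)}
        assert round(100 * evaluate.escalation_fraction(flags)) == 52
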