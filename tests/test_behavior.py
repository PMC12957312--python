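"""Behavioral metrics and statistics against closed forms and oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from popgeom.behavior import (effect_size_suite, hedges_g, reaction_time,
                              regress_reuse_vs_learning, trials_to_criterion,
                              watson_williams)


def _criterion_oracle(x, threshold=0.9, window=15):
    """Brute-force sliding-window scan."""
    for t in range(window, len(x) + 1):
        if np.mean(x[t - window:t]) >= threshold - 1e-12:
            return t
    return None


class TestTrialsToCriterion:
    def test_immediate_acquisition(self):
        out = trials_to_criterion(np.ones(30, dtype=int))
        assert out.criterion_trial == 15
        assert out.normalized_trials == pytest.approx(0.5)

    def test_never_acquired_falls_back_to_total(self):
        out = trials_to_criterion(np.zeros(40, dtype=int))
        assert out.criterion_trial is None
        assert out.normalized_trials == 1.0

    def test_fourteen_of_fifteen_suffices(self):
        seq = np.ones(15, dtype=int)
        seq[7] = 0  # 14/15 = 0.933 >= 0.9
        assert trials_to_criterion(seq).criterion_trial == 15
        seq[8] = 0  # 13/15 = 0.867 < 0.9
        assert trials_to_criterion(seq).criterion_trial is None

    def test_thousand_random_sequences_match_oracle(self, rng):
        for _ in range(1000):
            n = int(rng.integers(15, 80))
            x = (rng.random(n) < rng.uniform(0.5, 0.95)).astype(int)
            got = trials_to_criterion(x)
            assert got.criterion_trial == _criterion_oracle(x)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 1), min_size=15, max_size=60))
    def test_adding_correct_trials_never_delays(self, seq):
        base = trials_to_criterion(np.array(seq))
        extended = trials_to_criterion(np.array(seq + [1]))
        if base.criterion_trial is not None:
            assert extended.criterion_trial is not None
            assert extended.criterion_trial <= base.criterion_trial

    def test_window_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            trials_to_criterion(np.ones(10, dtype=int), window=15)


class TestReactionTime:
    def test_simple_difference(self):
        rt = reaction_time({"go_cue": np.array([0.0]),
                            "touch": np.array([0.8])})
        assert rt[0] == pytest.approx(0.8)

    def test_inverted_events_excluded(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="popgeom.behavior"):
            rt = reaction_time({"go_cue": np.array([0.0, 1.0]),
                                "touch": np.array([0.8, 0.5])})
        assert np.isnan(rt[1]) and rt[0] == pytest.approx(0.8)
        assert any("excluding" in r.message for r in caplog.records)

    def test_per_task_means_match_direct_subtraction(self, rng):
        go = rng.uniform(0.9, 1.1, 60)
        touch = go + rng.uniform(0.2, 0.8, 60)
        tasks = np.repeat(["A", "B", "C"], 20)
        out = reaction_time({"go_cue": go, "touch": touch}, tasks)
        for task in "ABC":
            mask = tasks == task
            assert out[task][0] == pytest.approx((touch - go)[mask].mean())
            assert out[task][2] == 20


class TestRegression:
    def test_collinear_points(self):
        x = np.array([0.0, 0.5, 1.0])
        slope, icept, r2, p = regress_reuse_vs_learning(x, -200 * x + 50)
        assert slope == pytest.approx(-200)
        assert r2 == pytest.approx(1.0)

    def test_constant_y_gives_zero_r2(self):
        slope, _, r2, _ = regress_reuse_vs_learning(
            np.array([0.1, 0.5, 0.9]), np.array([5.0, 5.0, 5.0]))
        assert r2 == pytest.approx(0.0)

    def test_known_slope_recovered_and_matches_normal_equations(self, rng):
        n = 100
        x = rng.uniform(-1, 1, n)
        y = -200.0 * x + 30.0 + rng.normal(0, 20, n)
        slope, icept, r2, p = regress_reuse_vs_learning(x, y)
        # normal-equations oracle
        A = np.column_stack([x, np.ones(n)])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert slope == pytest.approx(beta[0], abs=1e-8)
        assert icept == pytest.approx(beta[1], abs=1e-8)
        se = 20.0 / np.sqrt(np.sum((x - x.mean()) ** 2))
        assert abs(slope + 200.0) < 3 * se

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            regress_reuse_vs_learning(np.ones(5), np.arange(5.0))


class TestEffectSizes:
    def test_identical_groups_zero(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        out = effect_size_suite(a, a.copy())
        assert out.hedges_g == pytest.approx(0.0)
        assert out.eta_squared == pytest.approx(0.0)

    def test_hedges_g_closed_form(self):
        # means 0 and 1, SD exactly 1, n = 10 each -> g = 1 * (1 - 3/71)
        base = np.arange(10, dtype=float)
        a = (base - base.mean()) / base.std(ddof=1)
        b = a + 1.0
        assert abs(hedges_g(b, a) - (1.0 - 3.0 / 71.0)) <= 1e-10

    def test_three_group_anova_matches_ss_oracle(self, rng):
        groups = [rng.normal(loc, 1.0, 12) for loc in (0.0, 0.4, 1.0)]
        out = effect_size_suite(*groups)
        grand = np.concatenate(groups)
        ss_tot = ((grand - grand.mean()) ** 2).sum()
        ss_b = sum(len(g) * (g.mean() - grand.mean()) ** 2 for g in groups)
        eta2 = ss_b / ss_tot
        assert abs(out.eta_squared - eta2) <= 1e-10
        assert abs(out.cohens_f - np.sqrt(eta2 / (1 - eta2))) <= 1e-10
        f_ref, p_ref = stats.f_oneway(*groups)
        assert out.f_statistic == pytest.approx(f_ref)

    def test_scale_invariance(self, rng):
        a, b, c = (rng.normal(m, 1, 10) for m in (0, 0.5, 1))
        base = effect_size_suite(a, b, c)
        scaled = effect_size_suite(7.3 * a, 7.3 * b, 7.3 * c)
        assert abs(base.eta_squared - scaled.eta_squared) <= 1e-10
        assert abs(base.cohens_f - scaled.cohens_f) <= 1e-10
        g0 = hedges_g(a, b)
        assert abs(g0 - hedges_g(7.3 * a, 7.3 * b)) <= 1e-10

    def test_paired_vs_unpaired_differ(self, rng):
        a = rng.normal(0, 1, 12)
        b = a + rng.normal(0.5, 0.1, 12)  # strongly paired
        paired = effect_size_suite(b, a, paired=True)
        unpaired = effect_size_suite(b, a, paired=False)
        assert paired.p_value < unpaired.p_value

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            effect_size_suite(np.ones(5), np.ones(5))


def _ww_permutation_p(a_deg, b_deg, n_perm, rng):
    """Permutation oracle: statistic R1 + R2 (sum of within-group
    resultant lengths), which is monotone in the Watson–Williams F."""
    z = np.exp(1j * np.deg2rad(np.concatenate([a_deg, b_deg])))
    n1 = len(a_deg)
    obs = np.abs(z[:n1].sum()) + np.abs(z[n1:].sum())
    perms = np.argsort(rng.random((n_perm, z.size)), axis=1)
    zp = z[perms]
    stat = np.abs(zp[:, :n1].sum(axis=1)) + np.abs(zp[:, n1:].sum(axis=1))
    return (1 + np.sum(stat >= obs - 1e-12)) / (n_perm + 1)


class TestWatsonWilliams:
    def test_identical_samples_f_zero_p_one(self):
        a = np.array([40.0, 42.0, 44.0, 41.0])
        f, p = watson_williams(a, a.copy())
        assert f == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-8)

    def test_separated_von_mises_significant(self, rng):
        a = np.rad2deg(stats.vonmises.rvs(20, loc=np.deg2rad(80), size=30,
                                          random_state=1))
        b = np.rad2deg(stats.vonmises.rvs(20, loc=np.deg2rad(40), size=30,
                                          random_state=2))
        f, p = watson_williams(a, b)
        assert p < 0.01
        p_perm = _ww_permutation_p(a, b, 10_000, rng)
        assert (p < 0.05) == (p_perm < 0.05)

    def test_units_invariance(self, rng):
        a = rng.uniform(30, 60, 20)
        b = rng.uniform(50, 80, 20)
        f_deg, p_deg = watson_williams(a, b, degrees=True)
        f_rad, p_rad = watson_williams(np.deg2rad(a), np.deg2rad(b),
                                       degrees=False)
        assert f_deg == pytest.approx(f_rad, rel=1e-10)
        assert p_deg == pytest.approx(p_rad, rel=1e-10)

    def test_bounds(self, rng):
        for _ in range(20):
            a = rng.uniform(0, 90, 10)
            b = rng.uniform(0, 90, 10)
            f, p = watson_williams(a, b)
            assert f >= 0.0
            assert 0.0 <= p <= 1.0

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            watson_williams([10.0], [20.0, 30.0])
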