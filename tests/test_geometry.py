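"""Reuse correlation, basis selection, principal angles, shuffle null."""

import numpy as np
import pytest

from popgeom.demix import DemixResult, fit_demix
from popgeom.geometry import (ManifoldPair, decision_manifolds, manifold_reuse,
                              select_components, session_angle, shuffle_null,
                              subspace_angle)
from popgeom.simulate import SimConfig, make_session


def _pair(s_i, s_j):
    return ManifoldPair(S_i=s_i, S_j=s_j,
                        classes=[f"c{k}" for k in range(s_i.shape[0])])


class TestManifoldReuse:
    def test_identical_trajectories(self, rng):
        s = rng.standard_normal((2, 50))
        assert manifold_reuse(_pair(s, s.copy())) == pytest.approx(1.0)

    def test_sign_flip(self, rng):
        s = rng.standard_normal((2, 50))
        assert manifold_reuse(_pair(s, -s)) == pytest.approx(-1.0)

    def test_known_snr_attenuation(self, rng):
        # rho between x and x+noise is (1 + 1/SNR)^(-1/2)
        t = 10_000
        snr = 4.0
        s = rng.standard_normal((2, t))
        noisy = s + rng.standard_normal((2, t)) / np.sqrt(snr)
        expected = (1 + 1 / snr) ** -0.5
        got = manifold_reuse(_pair(s, noisy))
        # direct oracle
        oracle = np.mean([np.corrcoef(s[c], noisy[c])[0, 1] for c in range(2)])
        assert got == pytest.approx(oracle, abs=1e-12)
        assert got == pytest.approx(expected, abs=0.03)

    def test_affine_invariance(self, rng):
        s = rng.standard_normal((2, 40))
        j = rng.standard_normal((2, 40))
        base = manifold_reuse(_pair(s, j))
        scaled = manifold_reuse(_pair(3.0 * s + 1.0, 0.5 * j - 2.0))
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_zero_variance_rejected(self):
        s = np.ones((2, 10))
        with pytest.raises(ValueError, match="zero-variance"):
            manifold_reuse(_pair(s, s))


def _fake_result(factor_evs: dict[str, list[float]], n_units: int = 20):
    facs, evs = [], []
    for fac, vals in factor_evs.items():
        facs += [fac] * len(vals)
        evs += list(vals)
    p = len(evs)
    rng = np.random.default_rng(0)
    enc, _ = np.linalg.qr(rng.standard_normal((n_units, p)))
    return DemixResult(W=enc.copy(), encoders=enc, factor_of_component=facs,
                       explained_variance_ratio=np.asarray(evs),
                       stimuli=["s0", "s1"], decisions=["down", "up"], p=p)


class TestSelectComponents:
    def test_stimulus_cumulative_rule(self):
        res = _fake_result({"stimulus": [0.50, 0.30, 0.15, 0.05]})
        basis = select_components(res, "stimulus")
        assert basis.k == 2  # 0.50 + 0.30 = 0.80 >= 0.70
        assert basis.variance_kept == pytest.approx(0.80)

    def test_decision_one_percent_rule(self):
        res = _fake_result({"decision": [0.60, 0.009]})
        basis = select_components(res, "decision")
        assert basis.k == 1

    def test_random_spectra_match_rule_oracle(self, rng):
        for _ in range(50):
            k = int(rng.integers(1, 8))
            ev = rng.dirichlet(np.ones(k))
            res = _fake_result({"stimulus": ev.tolist()})
            basis = select_components(res, "stimulus")
            # exhaustive oracle
            frac = ev / ev.sum()
            order = np.argsort(frac)[::-1]
            expected = []
            cum = 0.0
            for i in order:
                if ev[i] <= 0.01:
                    continue
                expected.append(i)
                cum += frac[i]
                if cum >= 0.70:
                    break
            if not expected:
                with pytest.raises(ValueError):
                    select_components(res, "stimulus")
            else:
                assert basis.k == len(expected)

    def test_no_component_passes_raises(self):
        # >100 components each below 1% of the subspace variance
        res = _fake_result({"stimulus": [1.0 / 123] * 123}, n_units=150)
        with pytest.raises(ValueError, match="1%"):
            select_components(res, "stimulus")
        # missing factor also raises
        res2 = _fake_result({"decision": [0.6, 0.4]})
        with pytest.raises(ValueError, match="no components"):
            select_components(res2, "stimulus")

    def test_basis_is_orthonormal(self, small_session):
        res = fit_demix(small_session, tasks="A")
        for factor in ("stimulus", "decision"):
            u = select_components(res, factor).U
            np.testing.assert_allclose(u.T @ u, np.eye(u.shape[1]), atol=1e-10)


class TestSubspaceAngle:
    def test_identical_bases(self, rng):
        u, _ = np.linalg.qr(rng.standard_normal((10, 3)))
        assert subspace_angle(u, u) == pytest.approx(0.0, abs=1e-6)

    def test_orthogonal_axes(self):
        e1 = np.eye(10)[:, :1]
        e2 = np.eye(10)[:, 1:2]
        assert subspace_angle(e1, e2) == pytest.approx(90.0)

    @pytest.mark.parametrize("phi", [10.0, 37.5, 62.0, 85.0])
    def test_planted_rotation_recovered(self, phi, rng):
        # plane 1 = span{e1, e2}; plane 2 = rotate e1 by phi toward e3
        n = 12
        e = np.eye(n)
        u1 = e[:, [0, 1]]
        v = np.cos(np.deg2rad(phi)) * e[:, 0] + np.sin(np.deg2rad(phi)) * e[:, 2]
        u2 = np.column_stack([v, e[:, 3]])
        theta, spectrum = subspace_angle(u1, u2, return_spectrum=True)
        assert theta == pytest.approx(phi, abs=1e-8)
        # brute-force SVD of the cross-Gram matrix
        sv = np.linalg.svd(u1.T @ u2, compute_uv=False)
        np.testing.assert_allclose(np.cos(np.deg2rad(spectrum)),
                                   np.sort(sv)[::-1], atol=1e-10)

    def test_symmetry_and_joint_rotation_invariance(self, rng):
        u1, _ = np.linalg.qr(rng.standard_normal((15, 2)))
        u2, _ = np.linalg.qr(rng.standard_normal((15, 3)))
        q, _ = np.linalg.qr(rng.standard_normal((15, 15)))
        a = subspace_angle(u1, u2)
        assert subspace_angle(u2, u1) == pytest.approx(a, abs=1e-8)
        assert subspace_angle(q @ u1, q @ u2) == pytest.approx(a, abs=1e-8)

    def test_cos_equals_sigma_max(self, rng):
        u1, _ = np.linalg.qr(rng.standard_normal((15, 2)))
        u2, _ = np.linalg.qr(rng.standard_normal((15, 3)))
        theta = subspace_angle(u1, u2)
        smax = np.linalg.svd(u1.T @ u2, compute_uv=False)[0]
        assert np.cos(np.deg2rad(theta)) == pytest.approx(min(smax, 1.0),
                                                          abs=1e-10)
        assert 0.0 <= theta <= 90.0

    def test_non_orthonormal_input_reorthonormalized(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="popgeom.geometry"):
            theta = subspace_angle(np.eye(5)[:, :1] * 3.0, np.eye(5)[:, 1:2])
        assert theta == pytest.approx(90.0)
        assert any("orthonormal" in r.message for r in caplog.records)


class TestPipelineRecovery:
    def test_cross_projection_reuse_regimes(self):
        # reuse 1 -> trajectories overlay; reversed mapping -> sign flip
        session, _ = make_session(SimConfig(
            n_units=40, trials_per_condition=25, n_bins=60, reuse_rho=1.0,
            seed=31))
        res = fit_demix(session, tasks="A")
        same = manifold_reuse(decision_manifolds(session, res, "A", "B"))
        rev = manifold_reuse(decision_manifolds(session, res, "A", "Reverse-A"))
        assert same >= 0.9
        assert rev <= -0.5

    def test_shuffle_null_deterministic(self, small_session):
        a = shuffle_null(small_session, tasks="A", n_shuffles=3, seed=5)
        b = shuffle_null(small_session, tasks="A", n_shuffles=3, seed=5)
        assert a.observed_deg == b.observed_deg
        assert a.null_deg == b.null_deg
        assert all(0.0 <= x <= 90.0 for x in a.null_deg + [a.observed_deg])

    def test_no_signal_angle_within_null_range(self):
        session, _ = make_session(SimConfig(
            n_units=40, trials_per_condition=15, n_bins=60, tasks=("A",),
            signal_gain=0.0, seed=42))
        null = shuffle_null(session, tasks="A", n_shuffles=10, seed=0)
        assert min(null.null_deg) <= null.observed_deg <= max(null.null_deg)

    def test_orthogonal_session_beats_null(self):
        session, _ = make_session(SimConfig(
            n_units=40, trials_per_condition=25, n_bins=60,
            target_angle_deg=90.0, seed=51))
        null = shuffle_null(session, tasks="A", n_shuffles=10, seed=1)
        assert null.observed_deg > np.mean(null.null_deg)

    def test_angle_recovery_mid_range(self):
        session, truth = make_session(SimConfig(
            n_units=40, trials_per_condition=25, n_bins=60,
            target_angle_deg=60.0, seed=61))
        theta, _ = session_angle(session, tasks="A")
        assert theta == pytest.approx(truth.realized_angle_deg, abs=5.0)
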