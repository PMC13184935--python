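"""Unit and property tests for the three-state washout model."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from washkin import (
    KineticParams,
    OccupancyTrajectory,
    classify_regime,
    effective_tau,
    scenario1_tau,
    scenario2_tau,
    washout_linear,
    washout_saturable,
)
from washkin.kinetics import clamped_water_trajectory, membrane_free_conc


def integrate_linear_oracle(params, b0, m0, times):
    """Independent stiff integration of the linear washout ODEs."""
    kap = params.k_a * params.P_t

    def rhs(t, y):
        B, M = y
        return [kap * M - params.k_minus_a * B, params.k_minus_a * B - (kap + params.k_lw) * M]

    sol = solve_ivp(
        rhs,
        (0, times[-1]),
        [params.P_t * b0, m0],
        t_eval=times,
        method="LSODA",
        rtol=1e-11,
        atol=1e-14,
    )
    return sol.y[0] / params.P_t, sol.y[1]


class TestKineticParams:
    def test_kd_and_binding_favorable(self):
        p = KineticParams(k_a=10.0, k_minus_a=1.0, k_lw=1.0, k_wl=1.0, P_t=1.0)
        assert p.K_d == pytest.approx(0.1)
        assert p.binding_favorable
        assert not KineticParams(k_a=0.5, k_minus_a=1.0, k_lw=1, k_wl=1).binding_favorable

    def test_kd_requires_association(self):
        p = KineticParams(k_a=0.0, k_minus_a=1.0, k_lw=1.0, k_wl=1.0)
        with pytest.raises(ValueError, match="k_a"):
            p.K_d

    @pytest.mark.parametrize("bad", [dict(k_a=-1), dict(k_lw=-0.1), dict(P_t=0.0)])
    def test_invalid_parameters_rejected(self, bad):
        kwargs = dict(k_a=1.0, k_minus_a=1.0, k_lw=1.0, k_wl=1.0, P_t=1.0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            KineticParams(**kwargs)

    def test_json_round_trip(self):
        p = KineticParams(k_a=2.0, k_minus_a=0.5, k_lw=0.3, k_wl=1.5, P_t=2.0)
        assert KineticParams.from_json(p.to_json()) == p


class TestWashoutLinear:
    def test_pure_protein_decay_when_no_association(self):
        p = KineticParams(k_a=0.0, k_minus_a=0.25, k_lw=1.0, k_wl=1.0)
        t = np.linspace(0, 20, 400)
        traj = washout_linear(p, b0=1.0, m0=0.0, times=t)
        np.testing.assert_allclose(traj.bound, np.exp(-0.25 * t), rtol=1e-9, atol=1e-12)

    def test_mass_conservation_without_membrane_exit(self):
        p = KineticParams(k_a=5.0, k_minus_a=0.5, k_lw=0.0, k_wl=0.0, P_t=2.0)
        t = np.linspace(0, 10, 300)
        traj = washout_linear(p, b0=0.4, m0=0.3, times=t)
        total = traj.membrane + p.P_t * traj.bound
        np.testing.assert_allclose(total, total[0], rtol=1e-8)

    def test_matches_stiff_integrator(self):
        p = KineticParams(k_a=10.0, k_minus_a=0.1, k_lw=1.0, k_wl=1.0, P_t=1.0)
        t = np.linspace(0, 50, 500)
        traj = washout_linear(p, b0=0.9, m0=0.01, times=t)
        b_ref, m_ref = integrate_linear_oracle(p, 0.9, 0.01, t)
        assert np.max(np.abs(traj.bound - b_ref)) / b_ref.max() < 1e-6

    def test_eigen_solution_equivalence_random_draws(self):
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(25):
            ka, kma, klw = 10.0 ** rng.uniform(-2, 2, 3)
            p = KineticParams(k_a=ka, k_minus_a=kma, k_lw=klw, k_wl=1.0, P_t=1.0)
            tau_slow = 1.0 / min(kma + 1e-12, klw + kma)
            t = np.linspace(0, 5 * tau_slow, 200)
            traj = washout_linear(p, b0=0.5, m0=0.0, times=t)
            b_ref, _ = integrate_linear_oracle(p, 0.5, 0.0, t)
            worst = max(worst, np.max(np.abs(traj.bound - b_ref)) / max(b_ref.max(), 1e-12))
        assert worst < 1e-5

    def test_occupancy_stays_in_unit_interval(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            ka, kma, klw = 10.0 ** rng.uniform(-1, 1, 3)
            p = KineticParams(k_a=ka, k_minus_a=kma, k_lw=klw, k_wl=1.0, P_t=1.0)
            t = np.linspace(0, 20, 200)
            traj = washout_linear(p, b0=rng.uniform(0, 1), m0=0.0, times=t)
            assert np.all(traj.bound >= 0) and np.all(traj.bound <= 1)

    def test_rejects_bad_grid_and_inputs(self, scenario2_params):
        with pytest.raises(ValueError):
            washout_linear(scenario2_params, 0.5, 0.0, np.array([0.0, 2.0, 1.0]))
        with pytest.raises(ValueError):
            washout_linear(scenario2_params, 0.5, 0.0, np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            washout_linear(scenario2_params, -0.1, 0.0, np.linspace(0, 1, 10))
        with pytest.raises(ValueError):
            washout_linear(scenario2_params, 0.5, -1.0, np.linspace(0, 1, 10))


class TestWashoutSaturable:
    def test_vanishing_protein_pool_is_pure_membrane_exit(self):
        p = KineticParams(k_a=10.0, k_minus_a=1.0, k_lw=0.7, k_wl=1.0, P_t=1e-9)
        t = np.linspace(0, 8, 300)
        traj = washout_saturable(p, L_tot0=0.5, times=t)
        total = traj.membrane + p.P_t * traj.bound
        np.testing.assert_allclose(total, 0.5 * np.exp(-0.7 * t), rtol=1e-6)

    def test_linear_binding_limit_decays_at_klw(self):
        # K_d >> L_tot0 and K_d >> P_t: the protein barely buffers the decay
        p = KineticParams(k_a=0.01, k_minus_a=10.0, k_lw=1.0, k_wl=1.0, P_t=1.0)
        t = np.linspace(0, 8, 800)
        traj = washout_saturable(p, L_tot0=1.0, times=t)
        fit = effective_tau(traj)
        assert 1.0 / fit.tau == pytest.approx(p.k_lw, rel=0.05)

    def test_quasi_equilibrium_matches_full_kinetics(self):
        # k_a*P_t = 1000*k_lw: binding equilibrates much faster than exit
        p = KineticParams(k_a=100_000.0, k_minus_a=1000.0, k_lw=1.0, k_wl=1.0, P_t=1.0)
        assert p.K_d == pytest.approx(0.01)
        t = np.linspace(0, 30, 600)
        qe = washout_saturable(p, L_tot0=0.5, times=t)
        full = washout_saturable(p, L_tot0=0.5, times=t, method="full")
        assert np.max(np.abs(qe.bound - full.bound)) < 1e-3

    def test_mass_balance_consistency(self, scenario2_params):
        t = np.linspace(0, 40, 500)
        traj = washout_saturable(scenario2_params, L_tot0=2.0, times=t)
        # bound and membrane must satisfy the binding isotherm at every step
        np.testing.assert_allclose(
            traj.bound,
            traj.membrane / (scenario2_params.K_d + traj.membrane),
            rtol=1e-6,
        )

    def test_errors(self, scenario2_params):
        t = np.linspace(0, 1, 10)
        with pytest.raises(ValueError):
            washout_saturable(scenario2_params, -1.0, t)
        p0 = KineticParams(k_a=0.0, k_minus_a=1.0, k_lw=1.0, k_wl=1.0)
        with pytest.raises(ValueError):
            washout_saturable(p0, 1.0, t)


class TestScenarioTaus:
    @pytest.mark.parametrize("kma,expected", [(0.1, 10.0), (1.0, 1.0), (2.5, 0.4)])
    def test_scenario1_reciprocal(self, kma, expected):
        p = KineticParams(k_a=1.0, k_minus_a=kma, k_lw=1.0, k_wl=1.0)
        assert scenario1_tau(p) == pytest.approx(expected)

    def test_scenario1_infinite_residence(self):
        p = KineticParams(k_a=1.0, k_minus_a=0.0, k_lw=1.0, k_wl=1.0)
        with pytest.raises(ValueError, match="infinite"):
            scenario1_tau(p)

    def test_scenario2_value(self):
        # P_t = 1, K_d = 0.01, k_lw = 1 -> 1/(1.53*0.01) = 65.359...
        p = KineticParams(k_a=100.0, k_minus_a=1.0, k_lw=1.0, k_wl=1.0, P_t=1.0)
        assert scenario2_tau(p) == pytest.approx(1.0 / (1.53 * 0.01), rel=1e-12)

    def test_scenario2_prefactor_cancellation(self):
        p = KineticParams(k_a=1.0, k_minus_a=1.0, k_lw=1.0, k_wl=1.0, P_t=1.53)
        assert scenario2_tau(p) == pytest.approx(1.0)

    def test_scenario2_inverse_in_klw(self):
        p1 = KineticParams(k_a=5.0, k_minus_a=1.0, k_lw=0.4, k_wl=1.0, P_t=2.0)
        p2 = KineticParams(k_a=5.0, k_minus_a=1.0, k_lw=0.8, k_wl=1.0, P_t=2.0)
        assert scenario2_tau(p1) == pytest.approx(2 * scenario2_tau(p2))

    def test_scenario2_requires_rates(self):
        with pytest.raises(ValueError):
            scenario2_tau(KineticParams(k_a=0.0, k_minus_a=1.0, k_lw=1.0, k_wl=1.0))
        with pytest.raises(ValueError):
            scenario2_tau(KineticParams(k_a=1.0, k_minus_a=1.0, k_lw=0.0, k_wl=1.0))


class TestEffectiveTau:
    def test_self_fit_exact_exponential(self):
        t = np.linspace(0, 40, 2000)
        traj = OccupancyTrajectory(t, np.exp(-t / 5.0), np.zeros_like(t))
        fit = effective_tau(traj)
        assert fit.tau == pytest.approx(5.0, rel=1e-6)
        assert fit.amplitude == pytest.approx(1.0, rel=1e-6)

    def test_biexponential_matches_grid_search(self):
        t = np.linspace(0, 30, 3000)
        y = 0.5 * np.exp(-t) + 0.5 * np.exp(-t / 10.0)
        traj = OccupancyTrajectory(t, y, np.zeros_like(t))
        fit = effective_tau(traj)
        # independent oracle: dense scan over T with closed-form optimal A
        end = np.nonzero(y <= 0.05 * y[0])[0][0]
        tf, yf = t[: end + 1], y[: end + 1]
        taus = np.linspace(1.0, 15.0, 20001)
        best_sse, best_tau = np.inf, None
        for T in taus:
            e = np.exp(-tf / T)
            A = (yf @ e) / (e @ e)
            sse = float(((A * e - yf) ** 2).sum())
            if sse < best_sse:
                best_sse, best_tau = sse, T
        assert abs(fit.tau - best_tau) <= 2 * (taus[1] - taus[0])

    def test_scenario1_limit_recovers_protein_off_rate(self):
        # k_lw = 1000 * k_a * P_t: exit so fast the membrane never rebinds
        p = KineticParams(k_a=0.1, k_minus_a=0.5, k_lw=100.0, k_wl=1.0, P_t=1.0)
        t = np.linspace(0, 15, 3000)
        traj = washout_linear(p, b0=0.9, m0=0.0, times=t)
        fit = effective_tau(traj)
        assert fit.tau == pytest.approx(scenario1_tau(p), rel=0.05)

    @pytest.mark.parametrize("vary", ["P_t", "k_lw", "K_d"])
    def test_scenario2_scaling_slopes(self, vary):
        """log-log slope of the effective tau vs P_t, 1/k_lw, 1/K_d is +-1.

        Conditions sit deep in the fast-rebinding, saturated regime with a
        small membrane load (M0 = 50*K_d << P_t) so the reservoir-drain
        plateau is negligible.
        """
        taus, xs = [], []
        for f in (1.0, 10.0):
            kd = 0.001 * (f if vary == "K_d" else 1.0)
            pt = 2.0 * (f if vary == "P_t" else 1.0)
            klw = 0.5 * (f if vary == "k_lw" else 1.0)
            p = KineticParams(k_a=1000.0, k_minus_a=1000.0 * kd, k_lw=klw, k_wl=1.0, P_t=pt)
            m0 = 50 * kd
            L0 = m0 + pt * m0 / (kd + m0)
            t_end = 3.5 * pt / (kd * klw)
            t = np.linspace(0, t_end, 4000)
            traj = washout_saturable(p, L_tot0=L0, times=t)
            taus.append(effective_tau(traj).tau)
            xs.append(f)
        slope = np.log(taus[1] / taus[0]) / np.log(xs[1] / xs[0])
        expected = 1.0 if vary == "P_t" else -1.0
        assert slope == pytest.approx(expected, abs=0.02)

    def test_rejects_short_or_flat_trajectories(self):
        t = np.linspace(0, 1, 100)
        with pytest.raises(ValueError, match="too short"):
            effective_tau(OccupancyTrajectory(t, np.exp(-t / 5.0), np.zeros_like(t)))
        with pytest.raises(ValueError):
            effective_tau(OccupancyTrajectory(t, np.zeros_like(t), np.zeros_like(t)))


class TestClassifyRegime:
    @pytest.mark.parametrize(
        "ka,klw,expected",
        [
            (1.0, 100.0, "scenario-1"),
            (10.0, 0.01, "scenario-2"),
            (1.0, 1.0, "intermediate"),
            (1.0, 10.0, "scenario-1"),  # boundary: exactly 10x counts
        ],
    )
    def test_threshold(self, ka, klw, expected):
        p = KineticParams(k_a=ka, k_minus_a=0.1, k_lw=klw, k_wl=1.0, P_t=1.0)
        assert classify_regime(p) == expected


class TestTrajectoryContainer:
    def test_csv_round_trip(self, tmp_path, scenario2_params):
        t = np.linspace(0, 5, 50)
        traj = washout_linear(scenario2_params, 0.5, 0.1, t)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = OccupancyTrajectory.from_csv(path)
        np.testing.assert_allclose(back.bound, traj.bound, rtol=1e-12)
        np.testing.assert_allclose(back.membrane, traj.membrane, rtol=1e-12)

    def test_rejects_occupancy_outside_unit_interval(self):
        t = np.linspace(0, 1, 10)
        with pytest.raises(ValueError, match="saturable"):
            OccupancyTrajectory(t, np.full(10, 1.5), np.zeros(10))


def test_membrane_free_conc_inverts_isotherm(scenario2_params):
    M = np.array([0.01, 0.1, 1.0, 10.0])
    kd, pt = scenario2_params.K_d, scenario2_params.P_t
    L = M + pt * M / (kd + M)
    np.testing.assert_allclose(membrane_free_conc(L, scenario2_params), M, rtol=1e-10)


def test_clamped_water_steady_state(scenario2_params):
    # with the bath clamped, membrane settles at bath*k_wl/k_lw exactly
    t = np.linspace(0, 60, 600)
    traj = clamped_water_trajectory(scenario2_params, 5.0, 0.0, 0.0, t)
    m_star = 5.0 * scenario2_params.k_wl / scenario2_params.k_lw
    assert traj.membrane[-1] == pytest.approx(m_star, rel=1e-6)
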