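"""Forcing signals, model right-hand side, integration and the NCI map."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nfkbsync.model_core import (
    BASELINE,
    ConfigurationError,
    ForcingSignal,
    GeneParameters,
    KineticParameters,
    ModelState,
    dose_to_rate,
    nci_of,
    resting_state,
    rhs,
    simulate,
    _make_rhs,
)
from conftest import jittered_params


class TestForcing:
    def test_square_high_phase(self):
        sig = ForcingSignal(kind="square", S_high=2.0, S_low=0.0, T1=45, T2=45)
        assert sig.evaluate(10.0) == 2.0       # saturating 10 ng/ml dose window
        assert sig.evaluate(50.0) == 0.0
        assert sig.evaluate(90.0) == 2.0       # next cycle

    def test_sawtooth_halflife(self):
        sig = ForcingSignal(kind="sawtooth", S_high=2.0, T1=30, T2=60,
                            pulse_len=15.0, decay_halflife=30.0)
        assert sig.evaluate(5.0) == 2.0
        assert sig.evaluate(45.0) == pytest.approx(1.0)   # one half-life after pulse end

    def test_constant(self):
        sig = ForcingSignal(kind="constant", S_high=2.0)
        assert sig.evaluate(0.0) == sig.evaluate(1e5) == 2.0

    def test_active_window(self):
        sig = ForcingSignal(kind="constant", S_high=2.0, S_low=0.0,
                            t_start=60.0, t_end=120.0)
        assert sig.evaluate(30.0) == 0.0
        assert sig.evaluate(90.0) == 2.0
        assert sig.evaluate(180.0) == 0.0

    def test_negative_durations_rejected(self):
        with pytest.raises(ConfigurationError):
            ForcingSignal(kind="square", T1=-5.0, T2=45.0)
        with pytest.raises(ConfigurationError):
            ForcingSignal(kind="square", T1=0.0, T2=0.0)
        with pytest.raises(ConfigurationError):
            ForcingSignal(kind="square", S_high=1.0, S_low=2.0)

    def test_non_negative_everywhere(self):
        for kind in ("constant", "square", "sawtooth"):
            sig = ForcingSignal(kind=kind, S_high=2.0, S_low=0.1, T1=30, T2=60)
            t = np.linspace(0, 1000, 2000)
            assert np.all(sig.evaluate(t) >= 0.0)

    def test_cycle_starts(self):
        sig = ForcingSignal(kind="square", S_high=2.0, T1=45, T2=45)
        assert np.allclose(sig.cycle_starts(200.0), [0.0, 90.0, 180.0])


class TestDoseToRate:
    def test_reference_dose(self):
        assert dose_to_rate(10.0) == pytest.approx(2.0)

    def test_zero(self):
        assert dose_to_rate(0.0) == 0.0

    def test_linear_half_dose(self):
        assert dose_to_rate(5.0) == pytest.approx(1.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            dose_to_rate(-1.0)


class TestParameters:
    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            BASELINE.with_values(d_K=-1.0)

    def test_hill_below_one_rejected(self):
        with pytest.raises(ConfigurationError):
            BASELINE.with_values(n=0.5)

    def test_gene_parameters_nonnegative(self):
        with pytest.raises(ConfigurationError):
            GeneParameters(k_on_G=-1, k_on0_G=0, k_off_G=0, k_off0_G=0, d_R_G=1)


class TestRHS:
    def test_boundary_pushes_inward_at_N_one(self, constant_forcing):
        state = ModelState(K=0.2, N=1.0, G_I=0.5, R_I=0.5, I=0.4, G_A=0.5, R_A=0.5, A=0.5)
        dy = rhs(state, 0.0, BASELINE, constant_forcing)
        assert dy[1] == pytest.approx(-BASELINE.a * 0.4 * 1.0)
        assert dy[1] <= 0

    def test_gene_fraction_bounds(self, constant_forcing):
        top = ModelState(K=0.1, N=0.5, G_I=1.0, R_I=0.5, I=0.3, G_A=0.5, R_A=0.5, A=0.5)
        assert rhs(top, 0.0, BASELINE, constant_forcing)[2] <= 0
        bottom = ModelState(K=0.1, N=0.5, G_I=0.0, R_I=0.5, I=0.3, G_A=0.5, R_A=0.5, A=0.5)
        assert rhs(bottom, 0.0, BASELINE, constant_forcing)[2] > 0

    def test_null_dynamics_fixed_point(self):
        zero = KineticParameters(**{k: (1.0 if k == "n" else 0.0)
                                    for k in KineticParameters.RATE_NAMES})
        off = ForcingSignal(kind="constant", S_high=0.0)
        state = ModelState(K=0.1, N=0.2, G_I=0.3, R_I=0.4, I=0.5, G_A=0.6, R_A=0.7, A=0.8)
        assert np.allclose(rhs(state, 0.0, zero, off), 0.0)

    def test_nonfinite_state_rejected(self, constant_forcing):
        y = np.full(8, np.nan)
        with pytest.raises(ValueError):
            rhs(y, 0.0, BASELINE, constant_forcing)

    def test_repressor_flag_drops_I_terms(self, constant_forcing):
        state = ModelState(K=0.1, N=0.3, G_I=0.5, R_I=0.5, I=0.8, G_A=0.5, R_A=0.5, A=0.5)
        with_rep = rhs(state, 0.0, BASELINE, constant_forcing)
        without = rhs(state, 0.0, BASELINE.with_values(repressor_active=False),
                      constant_forcing)
        # dropping the I-repression term can only slow gene inactivation
        assert without[2] > with_rep[2]
        assert without[5] > with_rep[5]


class TestRestingState:
    def test_rhs_vanishes_at_rest(self):
        rest = resting_state(BASELINE)
        off = ForcingSignal(kind="constant", S_high=0.0)
        assert np.max(np.abs(rhs(rest, 0.0, BASELINE, off))) < 1e-8

    def test_no_basal_activation_strong_sequestration(self):
        params = BASELINE.with_values(k_on0_I=0.0, k_on0_A=0.0, a=300.0)
        rest = resting_state(params)
        assert rest.K == pytest.approx(0.0, abs=1e-12)
        assert rest.N < 0.1

    def test_rest_is_invariant_under_unstimulated_flow(self):
        rest = resting_state(BASELINE)
        off = ForcingSignal(kind="constant", S_high=0.0)
        t = np.linspace(0.0, 50 * 60.0, 200)
        traj = simulate(BASELINE, off, t, initial=rest)
        assert np.max(np.abs(traj.states - traj.states[0])) < 1e-6


def rk4_oracle(params, forcing, y0, t_end_min, dt_min=0.06):
    """Brute-force fixed-step RK4 integration (dt = 0.001 h)."""
    f = _make_rhs(params, forcing.evaluate, ())
    n = int(round(t_end_min / dt_min))
    t_vals = np.empty(n + 1)
    ys = np.empty((n + 1, len(y0)))
    y = np.asarray(y0, dtype=float).copy()
    t = 0.0
    t_vals[0] = t
    ys[0] = y
    for i in range(n):
        k1 = f(t, y)
        k2 = f(t + dt_min / 2, y + dt_min / 2 * k1)
        k3 = f(t + dt_min / 2, y + dt_min / 2 * k2)
        k4 = f(t + dt_min, y + dt_min * k3)
        y = y + dt_min / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt_min
        t_vals[i + 1] = t
        ys[i + 1] = y
    return t_vals, ys


class TestSimulate:
    def test_deterministic(self, constant_forcing):
        t = np.arange(0.0, 600.0, 6.0)
        a = simulate(BASELINE, constant_forcing, t)
        b = simulate(BASELINE, constant_forcing, t)
        assert np.array_equal(a.states, b.states)

    def test_state_bounds_on_trajectories(self, square_tf90):
        t = np.arange(0.0, 900.0, 6.0)
        for params in jittered_params(5, degree=0.3, seed=21):
            traj = simulate(params, square_tf90, t)
            assert np.all(traj.states >= 0.0)
            for name in ("N", "G_I", "R_I", "G_A", "R_A"):
                col = traj.column(name)
                assert np.all(col <= 1.0)

    def test_adaptive_agrees_with_rk4_oracle(self, constant_forcing):
        t_grid = np.arange(0.0, 300.0 + 1, 6.0)
        for params in jittered_params(5, degree=0.3, seed=31):
            traj = simulate(params, constant_forcing, t_grid)
            t_rk, y_rk = rk4_oracle(params, constant_forcing,
                                    traj.states[0], 300.0)
            idx = np.rint(t_grid / 0.06).astype(int)
            err = np.max(np.abs(traj.N - y_rk[idx, 1]))
            assert err < 1e-4

    def test_gene_modules_attached(self, square_tf180):
        gene = GeneParameters(k_on_G=5.0, k_on0_G=0.05, k_off_G=1.0,
                              k_off0_G=0.3, d_R_G=2.0)
        t = np.arange(0.0, 720.0, 6.0)
        traj = simulate(BASELINE, square_tf180, t, genes=[gene])
        G, R = traj.gene_series(0)
        assert traj.n_genes == 1
        assert np.all((0 <= G) & (G <= 1)) and np.all((0 <= R) & (R <= 1))

    def test_decreasing_grid_rejected(self, constant_forcing):
        with pytest.raises(ValueError):
            simulate(BASELINE, constant_forcing, np.array([0.0, 10.0, 5.0]))

    def test_trajectory_frame_has_nci(self, constant_forcing):
        t = np.arange(0.0, 120.0, 6.0)
        df = simulate(BASELINE, constant_forcing, t).to_frame()
        assert {"time_min", "N", "nci"}.issubset(df.columns)


class TestNCI:
    def test_zero(self):
        assert nci_of(0.0) == 0.0

    def test_half(self):
        assert nci_of(0.5) == pytest.approx(1.0 / 3.0)

    def test_out_of_domain(self):
        with pytest.raises(ValueError):
            nci_of(1.0)
        with pytest.raises(ValueError):
            nci_of(-0.1)

    @given(st.floats(min_value=0.0, max_value=0.999),
           st.floats(min_value=1e-6, max_value=0.999))
    @settings(deadline=None, max_examples=50)
    def test_strictly_increasing(self, n1, delta):
        n2 = n1 + delta * (0.9999 - n1)
        assert nci_of(n1) < nci_of(n2)

    def test_peak_colocation_with_N(self, square_tf90):
        t = np.arange(0.0, 900.0, 6.0)
        traj = simulate(BASELINE, square_tf90, t)
        from scipy.signal import argrelmax
        assert np.array_equal(argrelmax(traj.N)[0], argrelmax(traj.nci)[0])


class TestSawtoothForcing:
    def test_simulation_bounded_and_pulse_driven(self):
        sig = ForcingSignal(kind="sawtooth", S_high=2.0, T1=45.0, T2=45.0,
                            pulse_len=15.0, decay_halflife=30.0)
        t = np.arange(0.0, 720.0, 6.0)
        traj = simulate(BASELINE, sig, t)
        assert np.all(traj.states >= 0.0) and np.all(traj.N <= 1.0)
        assert traj.N.max() > 0.4          # pulses drive a response
        # IKK activity rises during pulses and relaxes during clearance
        K = traj.column("K")
        assert K.max() > 5 * K[0] + 1e-6


class TestNoRepressorVariant:
    def test_bounded_response_without_repression(self, square_tf90):
        params = BASELINE.with_values(repressor_active=False)
        t = np.arange(0.0, 1200.0, 6.0)
        traj = simulate(params, square_tf90, t)
        assert np.all(np.isfinite(traj.states))
        assert np.all(traj.N <= 1.0)
        assert traj.N.max() > 0.1   # still responds
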