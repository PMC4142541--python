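"""GABA-A receptor kinetics: presets, generator matrix, propagation,
steady state, dose-response and current."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.integrate import solve_ivp

from glomsim import receptor as rec


class TestPresets:
    def test_alpha1_rates_match_published_table(self, alpha1):
        r = alpha1.rates
        assert (r.k_on, r.k_off) == (20.0, 6.0)
        assert (r.d3, r.r3) == (15.0, 3.75)
        assert (r.d1, r.r1) == (3.3e-4, 7e-4)
        assert alpha1.g_max == 1323.25

    def test_alpha6_rates_match_published_table(self, alpha6):
        r = alpha6.rates
        assert (r.k_on, r.k_off) == (54.8, 0.31)
        assert (r.d1d2, r.r1r2) == (24.2, 0.09)
        assert alpha6.g_max == 491.58
        assert alpha6.e_rev == -65.0

    def test_unknown_subtype_rejected(self):
        with pytest.raises(ValueError):
            rec.build_preset("alpha2")

    def test_negative_rate_rejected(self, alpha1):
        with pytest.raises(ValueError):
            replace(alpha1.rates, k_on=-1.0)


class TestRateMatrix:
    def test_columns_sum_to_zero(self, alpha1, alpha6):
        for s in (alpha1, alpha6):
            for c in (0.0, 1e-4, 1.0):
                q = rec.rate_matrix(s, c)
                np.testing.assert_allclose(q.sum(axis=0), 0.0, atol=1e-12)
                off = q - np.diag(np.diag(q))
                assert off.min() >= 0.0

    def test_zero_gaba_has_no_binding_flux(self, alpha6):
        q0 = rec.rate_matrix(alpha6, 0.0)
        # unbound -> singly bound and the desensitized binding step vanish
        assert q0[1, 0] == 0.0
        assert q0[6, 5] == 0.0

    def test_ligand_entries_scale_linearly(self, alpha6):
        q1 = rec.rate_matrix(alpha6, 0.5)
        q2 = rec.rate_matrix(alpha6, 1.0)
        assert q2[1, 0] == pytest.approx(2.0 * q1[1, 0])
        assert q2[6, 5] == pytest.approx(2.0 * q1[6, 5])

    def test_negative_concentration_rejected(self, alpha1):
        with pytest.raises(ValueError):
            rec.rate_matrix(alpha1, -0.1)

    def test_first_binding_flux_matches_monte_carlo(self, alpha1, rng):
        """Single-channel Gillespie simulation of the same scheme agrees
        with the matrix propagator on a short 1 mM exposure."""
        q = rec.rate_matrix(alpha1, 1.0)
        t_end, n_chan = 0.5, 4000
        occupied = np.zeros(8)
        for _ in range(n_chan):
            state, t = 0, 0.0
            while True:
                out = -q[state, state]
                t += rng.exponential(1.0 / out)
                if t >= t_end:
                    break
                rates = q[:, state].copy()
                rates[state] = 0.0
                state = rng.choice(8, p=rates / rates.sum())
            occupied[state] += 1
        mc = occupied / n_chan
        exact = rec.propagate(alpha1, rec.resting_occupancy(),
                              np.full(20, 1.0), t_end / 20)[-1]
        np.testing.assert_allclose(mc, exact, atol=0.03)


class TestPropagate:
    def test_zero_gaba_keeps_resting_state(self, alpha1):
        traj = rec.propagate(alpha1, rec.resting_occupancy(),
                             np.zeros(200), 0.1)
        np.testing.assert_allclose(traj, np.tile(traj[0], (traj.shape[0], 1)),
                                   atol=1e-12)

    def test_occupancy_conserved_and_nonnegative(self, alpha6, rng):
        wave = rng.uniform(0, 2.0, size=400)
        traj = rec.propagate(alpha6, rec.resting_occupancy(), wave, 0.05)
        np.testing.assert_allclose(traj.sum(axis=1), 1.0, atol=1e-9)
        assert traj.min() >= -1e-12

    def test_brief_pulse_transient_then_decay(self, alpha1):
        wave = np.zeros(8000)
        wave[:40] = 1.0
        po = rec.open_probability(
            rec.propagate(alpha1, rec.resting_occupancy(), wave, 0.025))
        assert po.max() > 0.3
        assert po[-1] < 0.01 * po.max()

    def test_alpha1_decays_faster_than_alpha6(self, alpha1, alpha6):
        wave = np.zeros(8000)
        wave[:40] = 1.0

        def efold_time(s):
            po = rec.open_probability(
                rec.propagate(s, rec.resting_occupancy(), wave, 0.025))
            pk = po.argmax()
            below = np.flatnonzero(po[pk:] < po[pk] / np.e)
            return below[0] * 0.025

        assert efold_time(alpha1) < efold_time(alpha6)

    def test_dt_refinement_converged(self, alpha6):
        def po_at(dt):
            n = int(20.0 / dt)
            wave = np.zeros(n)
            wave[: int(1.0 / dt)] = 1.0
            return rec.open_probability(
                rec.propagate(alpha6, rec.resting_occupancy(), wave, dt))[-1]

        assert abs(po_at(0.025) - po_at(0.0125)) < 1e-4

    def test_unnormalized_initial_state_rejected(self, alpha1):
        with pytest.raises(ValueError):
            rec.propagate(alpha1, np.full(8, 0.2), np.zeros(10), 0.1)

    def test_matrix_propagator_matches_stiff_ode(self, alpha1):
        q = rec.rate_matrix(alpha1, 1.0)
        sol = solve_ivp(lambda t, x: q @ x, (0.0, 5.0),
                        rec.resting_occupancy(), method="Radau",
                        rtol=1e-10, atol=1e-12)
        traj = rec.propagate(alpha1, rec.resting_occupancy(),
                             np.full(200, 1.0), 0.025)
        np.testing.assert_allclose(traj[-1], sol.y[:, -1], atol=1e-6)


class TestSteadyState:
    def test_zero_gaba_all_unbound(self, alpha1):
        ss = rec.steady_state(alpha1, 0.0)
        assert ss[0] == pytest.approx(1.0)
        assert rec.open_probability(ss) == pytest.approx(0.0)

    @pytest.mark.parametrize("conc", [1e-4, 1e-3, 1e-2])
    def test_matches_long_time_propagation(self, alpha6, conc):
        ss = rec.steady_state(alpha6, conc)
        wave = np.full(20000, conc)
        long = rec.propagate(alpha6, rec.resting_occupancy(), wave, 0.5)[-1]
        np.testing.assert_allclose(ss, long, atol=1e-6)

    def test_random_rate_sets_consistent(self, rng):
        for _ in range(5):
            vals = {k: float(rng.uniform(0.01, 10.0))
                    for k in ("k_on", "k_off", "a1", "b1", "a2", "b2", "d1",
                              "r1", "d2", "r2", "d3", "r3", "d1d2", "r1r2")}
            s = rec.ReceptorScheme(rates=rec.RateSet(**vals), g_max=100.0)
            ss = rec.steady_state(s, 0.005)
            long = rec.propagate(s, rec.resting_occupancy(),
                                 np.full(40000, 0.005), 0.5)[-1]
            np.testing.assert_allclose(ss, long, atol=1e-6)

    def test_alpha6_long_pulse_plateau(self, alpha6):
        """A 200 ms 1 mM exposure sits on a near-constant plateau: the
        response at 100 ms differs from the steady state by only a few
        percent of the peak."""
        wave = np.full(8000, 1.0)
        po = rec.open_probability(
            rec.propagate(alpha6, rec.resting_occupancy(), wave, 0.025))
        ss = rec.open_probability(rec.steady_state(alpha6, 1.0))
        assert abs(po[4000] - ss) < 0.05 * po.max()
        assert po[-1] == pytest.approx(ss, rel=0.02)


class TestDoseResponse:
    def test_alpha6_ec50_near_published_value(self, alpha6):
        ec50, _, po = rec.dose_response_ec50(alpha6)
        assert ec50 == pytest.approx(1.5, rel=0.20)

    def test_alpha1_ec50_in_low_affinity_range(self, alpha1):
        ec50, _, _ = rec.dose_response_ec50(alpha1)
        assert 10.0 <= ec50 <= 100.0

    def test_rate_rescaling_shifts_ec50(self, alpha6):
        """Scaling both binding rates tenfold shifts the EC50 about
        tenfold down (affinity scaling)."""
        ec50, _, _ = rec.dose_response_ec50(alpha6)
        fast = replace(alpha6, rates=replace(
            alpha6.rates, k_on=alpha6.rates.k_on * 10,
            d1d2=alpha6.rates.d1d2 * 10))
        ec50_fast, _, _ = rec.dose_response_ec50(
            fast, np.logspace(-7, 0, 121))
        assert ec50_fast == pytest.approx(ec50 / 10.0, rel=0.35)

    def test_narrow_grid_rejected(self, alpha6):
        with pytest.raises(ValueError):
            rec.dose_response_ec50(alpha6, np.logspace(-4, -3, 10))


class TestReceptorCurrent:
    def test_zero_at_reversal(self, alpha1):
        occ = np.zeros(8)
        occ[4] = 1.0
        assert rec.receptor_current(alpha1, occ, -65.0) == 0.0

    def test_zero_when_closed(self, alpha1):
        assert rec.receptor_current(alpha1, rec.resting_occupancy(), 0.0) == 0.0

    def test_ohmic_arithmetic(self, alpha1):
        occ = np.zeros(8)
        occ[3] = occ[4] = 0.25
        occ[0] = 0.5
        expected = 1323.25 * 0.5 * 65.0 * 1e-3
        assert rec.receptor_current(alpha1, occ, 0.0) == pytest.approx(expected)


class TestPropagatorTable:
    def test_table_step_matches_expm(self, alpha6):
        levels, props = rec.propagator_table(alpha6, 0.025)
        idx = rec.concentration_to_level(np.array([0.0, 1e-3, 1.0]))
        assert idx[0] == 0
        x = rec.resting_occupancy()
        stepped = props[idx[2]] @ x
        exact = rec.propagate(alpha6, x, np.array([levels[idx[2]]]), 0.025)[-1]
        np.testing.assert_allclose(stepped, exact, atol=1e-12)

    def test_level_snapping_resolution(self):
        c = np.logspace(-6, 0, 300)
        levels, _ = rec.propagator_table(
            rec.build_preset("alpha1"), 0.025)
        snapped = levels[rec.concentration_to_level(c)]
        assert np.max(np.abs(np.log(snapped / c))) < 0.02
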