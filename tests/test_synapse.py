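"""Composite IPSC assembly, charge transfer, tonic current and the
release-probability experiment."""

import numpy as np
import pytest
from dataclasses import replace

from glomsim import synapse as syn
from glomsim.synapse import (InhibitorySynapse, TonicInhibition,
                             charge_transfer, mg_block,
                             raise_release_probability_experiment,
                             simulate_eipsc, tonic_current, train_stimulus)


@pytest.fixture(scope="module")
def inhibitory():
    return InhibitorySynapse()


@pytest.fixture(scope="module")
def train_trace(inhibitory):
    return simulate_eipsc(inhibitory, train_stimulus(), v_clamp=-10.0,
                          duration=200.0)


class TestEIPSC:
    def test_component_additivity_is_exact(self, train_trace):
        np.testing.assert_array_equal(
            train_trace.total, train_trace.alpha1 + train_trace.alpha6)

    def test_zero_at_chloride_reversal(self, inhibitory):
        tr = simulate_eipsc(inhibitory, train_stimulus(), v_clamp=-65.0,
                            duration=100.0)
        np.testing.assert_array_equal(tr.total, 0.0)

    def test_empty_stimulus_gives_zero_trace(self, inhibitory):
        tr = simulate_eipsc(inhibitory, [], v_clamp=0.0, duration=50.0)
        np.testing.assert_array_equal(tr.total, 0.0)

    def test_silenced_receptors_give_zero_current(self, inhibitory):
        silent = replace(inhibitory, alpha1=inhibitory.alpha1.with_g_max(0.0),
                         alpha6=inhibitory.alpha6.with_g_max(0.0))
        tr = simulate_eipsc(silent, train_stimulus(), v_clamp=0.0,
                            duration=100.0)
        np.testing.assert_array_equal(tr.total, 0.0)

    def test_fast_alpha1_peak_slow_alpha6_tail(self, inhibitory):
        """Single stimulus at 0 mV: the early peak is alpha1-dominated,
        the late tail alpha6-dominated."""
        tr = simulate_eipsc(inhibitory, [10.0], v_clamp=0.0, duration=150.0)
        dt = 0.025
        early = slice(int(10.0 / dt), int(14.0 / dt))
        late = slice(int(40.0 / dt), int(120.0 / dt))
        assert tr.alpha1[early].max() > tr.alpha6[early].max()
        assert tr.alpha6[late].sum() > tr.alpha1[late].sum()

    def test_train_peak_depression_and_tail_summation(self, train_trace):
        stim = train_stimulus()
        peaks = syn._train_peaks(train_trace, stim, 0.025)
        assert np.all(np.diff(peaks) < 0)
        # the slow component sums: the current floor just before each later
        # pulse stays a large fraction of the first peak instead of decaying
        dt = 0.025
        floors = np.array([train_trace.total[int((t - 0.3) / dt)]
                           for t in stim[1:]])
        assert np.all(floors > 0.25 * peaks[0])

    def test_alpha6_charge_fraction_dominates(self, train_trace):
        q1 = charge_transfer(train_trace.alpha1, 0.025)
        q6 = charge_transfer(train_trace.alpha6, 0.025)
        assert q6 > q1

    def test_stochastic_mode_reproducible(self, inhibitory):
        a = simulate_eipsc(inhibitory, train_stimulus(), v_clamp=-10.0,
                           mode="stochastic", seed=42, duration=100.0)
        b = simulate_eipsc(inhibitory, train_stimulus(), v_clamp=-10.0,
                           mode="stochastic", seed=42, duration=100.0)
        np.testing.assert_array_equal(a.total, b.total)


class TestChargeTransfer:
    def test_zero_trace(self):
        assert charge_transfer(np.zeros(1000), 0.025) == 0.0

    def test_rectangle_analytic(self):
        trace = np.zeros(4001)
        trace[1000:1400] = 10.0  # 10 pA for 10 ms at dt=0.025
        assert charge_transfer(trace, 0.025) == pytest.approx(0.1, rel=1e-3)

    def test_window_restricts_integral(self):
        trace = np.ones(4000)
        full = charge_transfer(trace, 0.025)
        half = charge_transfer(trace, 0.025, window=(0.0, 50.0))
        assert half == pytest.approx(full / 2.0, rel=0.01)


class TestReleaseProbabilityExperiment:
    def test_identical_probabilities_identical_traces(self, inhibitory):
        ex = raise_release_probability_experiment(inhibitory, 0.42, 0.42,
                                                  duration=150.0)
        np.testing.assert_array_equal(ex.trace_a.total, ex.trace_b.total)
        assert ex.first_peak_ratio == pytest.approx(1.0)

    def test_raising_pi_boosts_first_peak_with_convergence(self, inhibitory):
        ex = raise_release_probability_experiment(inhibitory, 0.42, 0.67,
                                                  duration=200.0)
        assert ex.first_peak_ratio > 1.0
        norm_a = ex.peaks_a / ex.peaks_a[0]
        norm_b = ex.peaks_b / ex.peaks_b[0]
        # later normalized peaks converge toward (fall below) control
        assert np.all(norm_b[1:] < norm_a[1:])

    def test_charge_change_smaller_than_first_peak_change(self, inhibitory):
        ex = raise_release_probability_experiment(inhibitory, 0.42, 0.67,
                                                  duration=200.0)
        rel_charge = abs(ex.charge_b / ex.charge_a - 1.0)
        rel_peak = abs(ex.first_peak_ratio - 1.0)
        assert rel_charge < rel_peak

    def test_invalid_probability_rejected(self, inhibitory):
        with pytest.raises(ValueError):
            raise_release_probability_experiment(inhibitory, 0.42, 1.2)


class TestTonic:
    def test_disabled_gives_zero(self):
        t = TonicInhibition(enabled=False)
        assert tonic_current(t, -10.0) == 0.0

    def test_zero_at_reversal(self):
        assert tonic_current(TonicInhibition(), -65.0) == 0.0

    def test_matches_measured_mean_current(self):
        """Default conductance reproduces the ~21.5 pA tonic current at
        the -10 mV holding potential."""
        assert tonic_current(TonicInhibition(), -10.0) == pytest.approx(
            21.5, abs=0.1)

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            TonicInhibition(g_tonic=-1.0)


class TestMgBlock:
    def test_monotone_in_voltage_and_bounded(self):
        v = np.linspace(-90.0, 40.0, 50)
        b = mg_block(v)
        assert np.all(np.diff(b) > 0)
        assert 0.0 < b.min() and b.max() <= 1.0
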