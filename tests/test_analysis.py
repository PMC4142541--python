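"""E/I coordinates and maps, Lorentzian fitting, coding fraction."""

import numpy as np
import pandas as pd
import pytest

from glomsim import analysis as ana
from glomsim.fixtures import make_lorentzian_fixture, make_raster_fixture
from glomsim.protocols import trial_metrics


class TestFiberEstimates:
    def test_published_worked_examples(self):
        """Printed mean amplitudes reproduce the published fiber counts:
        -81.0/-25.8 -> 3.14 mossy fibers; 48.5/16.3 -> 2.97 Golgi axons."""
        mf = ana.estimate_active_fibers(-81.0, -25.8)
        goc = ana.estimate_active_fibers(48.5, 16.3)
        assert mf == pytest.approx(3.14, abs=0.01)
        assert goc == pytest.approx(2.97, abs=0.01)

    def test_zero_unitary_rejected(self):
        with pytest.raises(ValueError):
            ana.estimate_active_fibers(10.0, 0.0)


class TestEIMap:
    def test_coordinates(self):
        assert ana.ei_coordinates(2, 0.3, 2, 0.2) == (2.3, 2.2)

    def test_uniform_metric_gives_flat_map(self):
        rows = [{"n_mf": mf, "pe": pe, "n_goc": goc, "pi": pi, "sn": 3.0}
                for mf in (1, 2) for pe in (0.3, 0.6)
                for goc in (1, 2) for pi in (0.3, 0.6)]
        out = ana.ei_map(pd.DataFrame(rows), "sn")
        assert np.nanstd(out["grid"]) == 0.0
        means = [s["mean"] for s in out["subregions"].values()]
        assert np.ptp(means) == 0.0

    def test_subregion_strengths_average_fibers_and_probabilities(self):
        rows = [{"n_mf": 2, "pe": pe, "n_goc": 1, "pi": pi, "sn": 1.0}
                for pe in (0.2, 0.4) for pi in (0.6, 0.8)]
        out = ana.ei_map(pd.DataFrame(rows), "sn")
        sub = out["subregions"][(2, 1)]
        assert sub["s_e"] == pytest.approx(2.3)
        assert sub["s_i"] == pytest.approx(1.7)

    def test_missing_cells_stay_nan(self):
        rows = [{"n_mf": 1, "pe": 0.3, "n_goc": 1, "pi": 0.3, "sn": 2.0}]
        out = ana.ei_map(pd.DataFrame(rows), "sn")
        assert np.isnan(out["grid"]).sum() == out["grid"].size - 1


class TestLorentzian:
    def test_noiseless_parameter_recovery(self):
        lags, y, truth = make_lorentzian_fixture(area=2.0, theta_max=-10.0,
                                                 omega=30.0)
        fit = ana.fit_lorentzian(lags, y)
        assert fit.area == pytest.approx(truth["area"], abs=1e-6)
        assert fit.theta_max == pytest.approx(truth["theta_max"], abs=1e-6)
        assert fit.omega == pytest.approx(truth["omega"], abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_peak_value_identity(self):
        lags, y, _ = make_lorentzian_fixture(area=1.3, theta_max=5.0,
                                             omega=22.0)
        fit = ana.fit_lorentzian(lags, y)
        assert fit.peak_value == pytest.approx(
            ana.lorentzian(np.array([fit.theta_max]), fit.area,
                           fit.theta_max, fit.omega)[0])
        assert fit.q == pytest.approx(fit.peak_value / fit.omega)

    def test_noisy_recovery_over_replicates(self):
        """SNR ~ 10 replicates recover the parameters within 10% on
        average (seeded)."""
        errs = []
        for seed in range(30):
            peak = 2 * 2.0 / (np.pi * 30.0)
            lags, y, truth = make_lorentzian_fixture(
                area=2.0, theta_max=-10.0, omega=30.0,
                noise_sigma=peak / 10.0, seed=seed)
            fit = ana.fit_lorentzian(lags, y)
            errs.append([abs(fit.area / 2.0 - 1.0),
                         abs((fit.theta_max + 10.0) / 30.0),
                         abs(fit.omega / 30.0 - 1.0)])
        assert np.median(errs, axis=0).max() < 0.10

    def test_negative_peak_curves_fit(self):
        lags, y, _ = make_lorentzian_fixture(area=-1.5, theta_max=15.0,
                                             omega=40.0)
        fit = ana.fit_lorentzian(lags, y)
        assert fit.area == pytest.approx(-1.5, abs=1e-5)
        assert fit.theta_max == pytest.approx(15.0, abs=1e-4)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ana.fit_lorentzian(np.arange(4), np.ones(4))


def _trials_from_fixture(fx):
    frames = []
    for cid, rasters in fx.rasters.items():
        df = trial_metrics(rasters, fx.t_ref)
        df.insert(0, "config_id", cid)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


class TestCodingFraction:
    def test_stimulus_entropy_closed_form(self):
        assert ana.stimulus_entropy(1620) == pytest.approx(np.log2(1620))
        assert ana.stimulus_entropy(1620) == pytest.approx(10.66, abs=0.01)

    def test_identical_distributions_give_zero_cf(self):
        fx = make_raster_fixture(
            {c: {"rate": 2.0, "latency_mean": 8.0, "latency_sd": 1.0}
             for c in range(8)}, n_trials=200, seed=1)
        res = ana.coding_fraction(_trials_from_fixture(fx), "ttfs",
                                  bin_width=1.0)
        assert 0.0 <= res.cf < 0.02

    def test_disjoint_latency_supports_give_cf_one(self):
        fx = make_raster_fixture(
            {c: {"rate": 1.0, "latency_mean": 5.0 + 10.0 * c,
                 "latency_sd": 0.0, "span": 0.1} for c in range(4)},
            n_trials=50, seed=2)
        trials = _trials_from_fixture(fx)
        trials = trials[trials["sn"] > 0]  # keep deterministic spikes only
        counts = trials.groupby("config_id").size().min()
        trials = trials.groupby("config_id").head(counts)
        res = ana.coding_fraction(trials, "ttfs", bin_width=1.0)
        assert res.cf == pytest.approx(1.0, abs=1e-9)

    def test_cf_bounds_and_mi_cap(self):
        fx = make_raster_fixture(
            {c: {"rate": 1.0 + c, "latency_mean": 5.0 + c,
                 "latency_sd": 1.0} for c in range(6)},
            n_trials=100, seed=3)
        res = ana.coding_fraction(_trials_from_fixture(fx), "sn")
        assert 0.0 <= res.cf <= 1.0
        assert res.mi <= res.h_stimulus

    def test_unequal_trial_counts_rejected(self):
        df = pd.DataFrame({"config_id": [0, 0, 1], "sn": [1.0, 2.0, 1.0]})
        with pytest.raises(ValueError):
            ana.coding_fraction(df, "sn")

    def test_bias_correction_suppresses_spurious_information(self, rng):
        """Pure noise with many response bins: the plug-in MI is inflated,
        the corrected CF stays near zero."""
        n_cfg, n_tr = 16, 120
        stim = np.repeat(np.arange(n_cfg), n_tr)
        resp = rng.integers(0, 30, size=stim.size)
        mi_plugin = ana.mutual_information(stim, resp, bias_correction=False)
        mi_corr = ana.mutual_information(stim, resp, bias_correction=True)
        assert mi_corr < mi_plugin
        assert abs(mi_corr) < 0.02 * np.log2(n_cfg)
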