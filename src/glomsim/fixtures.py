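"""Synthetic test-data generators with stored ground truth.

Every fixture is produced by the model itself (or a prescribed statistical
process) from known parameters plus seeded Gaussian noise, and is returned
together with its truth record, so recovery tests never hard-code derived
numbers and regeneration from the same spec is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import lorentzian
from .synapse import InhibitorySynapse, simulate_eipsc

__all__ = [
    "EIPSCFixture",
    "make_eipsc_fixture",
    "make_train_pair_fixture",
    "RasterFixture",
    "make_raster_fixture",
    "make_lorentzian_fixture",
]


@dataclass(frozen=True)
class EIPSCFixture:
    """A noisy model-generated IPSC trace plus its generating truth."""

    time: np.ndarray
    current: np.ndarray
    truth: dict
    noise_sigma: float
    seed: int


def make_eipsc_fixture(synapse: InhibitorySynapse, stim_times,
                       v_clamp: float = -10.0, duration: float = 200.0,
                       dt: float = 0.1, noise_sigma: float = 0.0,
                       seed: int = 0) -> EIPSCFixture:
    """Deterministic IPSC simulation plus additive Gaussian noise (pA)."""
    tr = simulate_eipsc(synapse, stim_times, v_clamp=v_clamp,
                        duration=duration, dt=dt)
    rng = np.random.default_rng(seed)
    noisy = tr.total + (noise_sigma * rng.standard_normal(tr.total.size)
                        if noise_sigma > 0 else 0.0)
    truth = {
        "g_max_alpha1": synapse.alpha1.g_max,
        "g_max_alpha6": synapse.alpha6.g_max,
        "a_molecules": synapse.diffusion.m_molecules,
        "r_um": synapse.diffusion.r,
        "tau_rec": synapse.release.tau_rec,
        "tau_fac": synapse.release.tau_fac,
        "p": synapse.release.p,
        "v_clamp": v_clamp,
    }
    return EIPSCFixture(tr.time, noisy, truth, noise_sigma, seed)


def make_train_pair_fixture(p_control: float = 0.42, p_cgp: float = 0.67,
                            stim_times=None, noise_sigma: float = 0.0,
                            seed: int = 0, dt: float = 0.1,
                            duration: float = 200.0,
                            template: InhibitorySynapse | None = None
                            ) -> tuple[EIPSCFixture, EIPSCFixture]:
    """Control/CGP train pair differing only in release probability."""
    syn = template or InhibitorySynapse()
    if stim_times is None:
        stim_times = 10.0 + 10.0 * np.arange(4)
    fx_c = make_eipsc_fixture(syn.with_p(p_control), stim_times,
                              noise_sigma=noise_sigma, seed=seed,
                              dt=dt, duration=duration)
    fx_g = make_eipsc_fixture(syn.with_p(p_cgp), stim_times,
                              noise_sigma=noise_sigma, seed=seed + 1,
                              dt=dt, duration=duration)
    return fx_c, fx_g


@dataclass(frozen=True)
class RasterFixture:
    """Spike rasters with prescribed count/latency statistics per config."""

    rasters: dict            # config_id -> list of per-trial spike arrays
    truth: dict
    t_ref: float
    seed: int


def make_raster_fixture(config_truth: dict, n_trials: int, seed: int = 0,
                        t_ref: float = 50.0) -> RasterFixture:
    """Generate rasters from per-configuration spike statistics.

    ``config_truth`` maps config_id -> dict with keys ``rate`` (mean spike
    count, Poisson), ``latency_mean`` and ``latency_sd`` (ms, first-spike
    normal distribution), ``span`` (ms, uniform placement of later spikes
    after the first).  A config with rate 0 yields empty trials.
    """
    rng = np.random.default_rng(seed)
    rasters: dict = {}
    for cid, tr in config_truth.items():
        trials = []
        for _ in range(n_trials):
            n = rng.poisson(tr.get("rate", 1.0))
            if n == 0:
                trials.append(np.empty(0))
                continue
            first = t_ref + max(0.05, rng.normal(tr.get("latency_mean", 5.0),
                                                 tr.get("latency_sd", 0.0)))
            later = first + 0.5 + np.sort(rng.uniform(
                0.0, tr.get("span", 20.0), size=n - 1))
            spikes = np.concatenate([[first], later])
            trials.append(np.unique(spikes))
        rasters[cid] = trials
    return RasterFixture(rasters, dict(config_truth), t_ref, seed)


def make_lorentzian_fixture(area: float = 2.0, theta_max: float = -10.0,
                            omega: float = 30.0, lags=None,
                            noise_sigma: float = 0.0, seed: int = 0):
    """Sampled Lorentzian curve plus truth, optionally with noise."""
    lags = np.linspace(-100.0, 100.0, 41) if lags is None else np.asarray(lags)
    y = lorentzian(lags, area, theta_max, omega)
    if noise_sigma > 0:
        y = y + noise_sigma * np.random.default_rng(seed).standard_normal(y.size)
    return lags, y, {"area": area, "theta_max": theta_max, "omega": omega}
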