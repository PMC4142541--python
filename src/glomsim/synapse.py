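"""Assembly of glomerular synapses and voltage-clamp IPSC simulation.

An inhibitory (Golgi cell -> granule cell) synapse couples the stochastic
release machinery to alpha1 and alpha6 receptor populations through the
shared pulse+spillover GABA field; the composite evoked IPSC is the sum of
the alpha1- and alpha6-mediated components.  An excitatory (mossy fiber)
synapse drives AMPA and NMDA conductances through the analogous glutamate
field.  Tonic inhibition is a fixed background chloride conductance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

from . import receptor as _rec
from . import release as _rel
from .diffusion import DiffusionParams, spillover_kernel

__all__ = [
    "InhibitorySynapse",
    "ExcitatorySynapse",
    "TonicInhibition",
    "IPSCTrace",
    "simulate_eipsc",
    "charge_transfer",
    "raise_release_probability_experiment",
    "tonic_current",
    "mg_block",
    "excitatory_current",
]


@dataclass(frozen=True)
class InhibitorySynapse:
    """One Golgi-cell connection: release sites + alpha1/alpha6 receptors.

    The postsynaptic conductances ``g_max`` of the two receptor populations
    are totals per synapse; each of the ``n_sites`` release sites faces a
    PSD carrying ``g_max / n_sites`` of each population.
    """

    release: _rel.ReleaseParams = field(default_factory=_rel.ReleaseParams)
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    alpha1: _rec.ReceptorScheme = field(
        default_factory=lambda: _rec.build_preset("alpha1"))
    alpha6: _rec.ReceptorScheme = field(
        default_factory=lambda: _rec.build_preset("alpha6"))

    def with_p(self, p: float) -> "InhibitorySynapse":
        return replace(self, release=replace(self.release, p=p))


@dataclass(frozen=True)
class ExcitatorySynapse:
    """One mossy-fiber connection: release sites + AMPA/NMDA receptors.

    AMPA and NMDA receptors are represented by two-state (closed/open)
    schemes driven by the glutamate concentration ``c``:
    ``dr/dt = alpha*c*(1 - r) - beta*r``.  The NMDA conductance is further
    multiplied by the voltage-dependent magnesium unblock factor.
    """

    release: _rel.ReleaseParams = field(
        default_factory=lambda: _rel.ReleaseParams(p=0.51))
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    g_ampa: float = 720.0        # pS per synapse
    g_nmda: float = 650.0        # pS per synapse
    ampa_alpha: float = 4.0      # mM^-1 ms^-1
    ampa_beta: float = 0.6       # ms^-1
    nmda_alpha: float = 0.5      # mM^-1 ms^-1
    nmda_beta: float = 0.015     # ms^-1
    e_rev: float = 0.0
    mg_mM: float = 1.2

    def with_p(self, p: float) -> "ExcitatorySynapse":
        return replace(self, release=replace(self.release, p=p))


@dataclass(frozen=True)
class TonicInhibition:
    """Steady background chloride conductance from ambient GABA.

    The default matches the measured mean tonic current of ~21.5 pA at a
    -10 mV holding potential: g = 21.5 pA / 55 mV = 391 pS.
    """

    g_tonic: float = 391.0  # pS
    e_rev: float = -65.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.g_tonic < 0:
            raise ValueError("g_tonic must be non-negative")


def tonic_current(tonic: TonicInhibition, v: float) -> float:
    """Tonic chloride current (pA, outward positive) at potential ``v``."""
    if not tonic.enabled:
        return 0.0
    return tonic.g_tonic * (v - tonic.e_rev) * 1e-3


def mg_block(v: np.ndarray | float, mg_mM: float = 1.2) -> np.ndarray | float:
    """Voltage-dependent magnesium unblock factor of the NMDA receptor."""
    return 1.0 / (1.0 + (mg_mM / 3.57) * np.exp(-0.062 * np.asarray(v, dtype=float)))


@lru_cache(maxsize=16)
def _cached_table(scheme: _rec.ReceptorScheme, dt: float):
    return _rec.propagator_table(scheme, dt)


def _release_plan(params: _rel.ReleaseParams, stim_times: np.ndarray,
                  mode: str, seed: int | None) -> np.ndarray:
    """Per-site release amounts (quanta) at each stimulus.

    Deterministic mode releases ``u*x`` quanta per site (the trial mean of
    the quantal model, so the two modes agree on average); stochastic mode
    emits whole quanta.  Returns an array of shape ``(n_sites, n_stim)``.
    """
    stim_times = np.asarray(stim_times, dtype=float)
    if mode == "deterministic":
        frac = _rel.deterministic_release_fractions(params, stim_times)
        amounts = np.tile(frac, (params.n_sites, 1))
    elif mode == "stochastic":
        rng = np.random.default_rng(seed)
        amounts = _rel.stochastic_release_matrix(
            params, stim_times, 1, rng)[0].astype(float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return amounts


@dataclass(frozen=True)
class IPSCTrace:
    """Voltage-clamp IPSC simulation output (currents in pA, time in ms)."""

    time: np.ndarray
    total: np.ndarray
    alpha1: np.ndarray
    alpha6: np.ndarray
    gaba_per_site: np.ndarray  # (n_steps, n_sites) mM
    v_clamp: float


def simulate_eipsc(syn: InhibitorySynapse, stim_times,
                   v_clamp: float = 0.0, mode: str = "deterministic",
                   seed: int | None = None, duration: float = 400.0,
                   dt: float = 0.025) -> IPSCTrace:
    """Composite evoked IPSC under voltage clamp.

    The returned total current is exactly the sum of the alpha1 and alpha6
    component traces.  An empty stimulus list yields a zero trace.
    """
    stim_times = np.asarray(stim_times, dtype=float)
    n_steps = int(round(duration / dt))
    time = np.arange(n_steps) * dt
    n_sites = syn.release.n_sites

    if stim_times.size == 0:
        z = np.zeros(n_steps)
        return IPSCTrace(time, z, z.copy(), z.copy(),
                         np.zeros((n_steps, n_sites)), v_clamp)

    amounts = _release_plan(syn.release, stim_times, mode, seed)
    stim_steps = np.round(stim_times / dt).astype(int)
    pulse_len = int(round(syn.release.pulse_duration / dt))

    # spillover superposes from neighboring release events only; the fitted
    # source A is a per-synapse quantity, so each of the n_sites quanta
    # carries A/n_sites molecules
    kernel = spillover_kernel(syn.diffusion, dt, n_steps) / n_sites
    spill_tot = np.zeros(n_steps)
    spill_own = np.zeros((n_steps, n_sites))
    for k, s0 in enumerate(stim_steps):
        if s0 >= n_steps:
            continue
        spill_tot[s0:] += amounts[:, k].sum() * kernel[:n_steps - s0]
        spill_own[s0:] += amounts[:, k][None, :] * kernel[:n_steps - s0, None]

    # per-PSD concentration: neighboring spillover + own-site pulse
    conc = spill_tot[:, None] - spill_own
    for k, s0 in enumerate(stim_steps):
        hi = min(s0 + pulse_len, n_steps)
        conc[s0:hi] += syn.release.t_max * amounts[:, k][None, :]

    levels1, props1 = _cached_table(syn.alpha1, dt)
    _, props6 = _cached_table(syn.alpha6, dt)
    idx = _rec.concentration_to_level(conc)

    x1 = np.tile(_rec.resting_occupancy(), (n_sites, 1))
    x6 = x1.copy()
    po1 = np.empty((n_steps, n_sites))
    po6 = np.empty((n_steps, n_sites))
    for j in range(n_steps):
        pj = props1[idx[j]]
        x1 = np.einsum("sij,sj->si", pj, x1)
        pj = props6[idx[j]]
        x6 = np.einsum("sij,sj->si", pj, x6)
        po1[j] = x1[:, 3] + x1[:, 4]
        po6[j] = x6[:, 3] + x6[:, 4]

    drive = (v_clamp - syn.alpha1.e_rev) * 1e-3
    i1 = syn.alpha1.g_max / n_sites * po1.sum(axis=1) * drive
    i6 = syn.alpha6.g_max / n_sites * po6.sum(axis=1) * drive
    return IPSCTrace(time, i1 + i6, i1, i6, conc, v_clamp)


def charge_transfer(current: np.ndarray, dt: float,
                    window: tuple[float, float] | None = None,
                    time: np.ndarray | None = None) -> float:
    """Trapezoidal charge (pC) of a uniformly sampled current trace (pA, ms)."""
    current = np.asarray(current, dtype=float)
    if window is not None:
        t = np.arange(current.size) * dt if time is None else time
        mask = (t >= window[0]) & (t <= window[1])
        current = current[mask]
    return float(np.trapezoid(current, dx=dt)) * 1e-3


@dataclass(frozen=True)
class ReleaseProbabilityExperiment:
    """Paired-train comparison at two inhibitory release probabilities."""

    trace_a: IPSCTrace
    trace_b: IPSCTrace
    peaks_a: np.ndarray
    peaks_b: np.ndarray
    first_peak_ratio: float
    charge_a: float
    charge_b: float


def _train_peaks(trace: IPSCTrace, stim_times: np.ndarray, dt: float) -> np.ndarray:
    """Per-pulse peak amplitudes of a train IPSC (max within each interval)."""
    stim_steps = np.round(np.asarray(stim_times) / dt).astype(int)
    bounds = list(stim_steps) + [trace.total.size]
    return np.array([trace.total[bounds[k]:bounds[k + 1]].max()
                     for k in range(len(stim_steps))])


def raise_release_probability_experiment(
        syn: InhibitorySynapse, pI_a: float, pI_b: float,
        stim_times=None, v_clamp: float = 0.0, duration: float = 400.0,
        dt: float = 0.025) -> ReleaseProbabilityExperiment:
    """Deterministic train IPSCs at two release probabilities.

    Reports per-pulse peak amplitudes, the first-peak ratio (b/a) and the
    total charge of both conditions.
    """
    for p in (pI_a, pI_b):
        if not 0.0 <= p <= 1.0:
            raise ValueError("release probabilities must lie in [0, 1]")
    if stim_times is None:
        stim_times = train_stimulus()
    stim_times = np.asarray(stim_times, dtype=float)
    window = (0.0, stim_times[-1] + float(np.diff(stim_times).mean())
              if stim_times.size > 1 else duration)
    tr_a = simulate_eipsc(syn.with_p(pI_a), stim_times, v_clamp,
                          duration=duration, dt=dt)
    tr_b = simulate_eipsc(syn.with_p(pI_b), stim_times, v_clamp,
                          duration=duration, dt=dt)
    pk_a = _train_peaks(tr_a, stim_times, dt)
    pk_b = _train_peaks(tr_b, stim_times, dt)
    return ReleaseProbabilityExperiment(
        tr_a, tr_b, pk_a, pk_b,
        first_peak_ratio=float(pk_b[0] / pk_a[0]),
        charge_a=charge_transfer(tr_a.total, dt, window),
        charge_b=charge_transfer(tr_b.total, dt, window),
    )


def train_stimulus(n_pulses: int = 4, freq_hz: float = 100.0,
                   start: float = 10.0) -> np.ndarray:
    """Stimulus times (ms) of the standard evoked train: 4 pulses at 100 Hz."""
    return start + 1e3 / freq_hz * np.arange(n_pulses)


def train_charge(syn: InhibitorySynapse, p: float,
                 v_clamp: float = -10.0, dt: float = 0.025) -> float:
    """Charge (pC) transferred during the evoked IPSC train at probability ``p``.

    The composite alpha1+alpha6 IPSC is simulated deterministically under
    voltage clamp at the experimental holding potential and integrated over
    the stimulation period (train span plus one inter-pulse interval).
    """
    stim = train_stimulus()
    tr = simulate_eipsc(syn.with_p(p), stim, v_clamp, duration=200.0, dt=dt)
    return charge_transfer(tr.total, dt, window=(0.0, stim[-1] + 10.0))


def excitatory_current(syn: ExcitatorySynapse, r_ampa: np.ndarray,
                       r_nmda: np.ndarray, v: np.ndarray | float
                       ) -> tuple[np.ndarray, np.ndarray]:
    """AMPA and NMDA currents (pA, outward positive) from open fractions.

    ``r_ampa``/``r_nmda`` are summed open fractions over the release sites
    of the synapse; the per-site conductance is ``g / n_sites``.
    """
    n = syn.release.n_sites
    i_ampa = syn.g_ampa / n * np.asarray(r_ampa) * (np.asarray(v) - syn.e_rev) * 1e-3
    i_nmda = (syn.g_nmda / n * np.asarray(r_nmda) * mg_block(v, syn.mg_mM)
              * (np.asarray(v) - syn.e_rev) * 1e-3)
    return i_ampa, i_nmda
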