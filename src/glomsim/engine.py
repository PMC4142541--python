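"""Vectorized trial engine for the glomerular microcircuit.

One run simulates ``n_trials`` independent trials of a granule cell
receiving ``n_mf`` excitatory and ``n_goc`` inhibitory synapses, each with
three stochastic releasing sites, on a common time grid.  All trials are
advanced in lockstep with numpy array operations; receptor Markov states
are propagated with precomputed exact step propagators gathered from a
log-spaced concentration table.

Stochasticity enters only through quantal release at the (known) stimulus
times, so all release outcomes are drawn up front; the release random
stream depends only on ``(seed, circuit sizes, stimulus counts)``, which
makes paired condition comparisons (receptor switch-off, tonic variation)
use common random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import receptor as _rec
from . import release as _rel
from .diffusion import spillover_kernel
from functools import lru_cache

from .neuron import (GranuleCell, TrialResult, detect_spikes, init_gates,
                     resting_potential, step_membrane)
from .synapse import (ExcitatorySynapse, InhibitorySynapse, TonicInhibition,
                      _cached_table, mg_block)

__all__ = ["GlomerulusCircuit", "CONDITIONS", "apply_condition",
           "BatchResult", "simulate_batch", "integrate"]

#: Receptor/conductance switch-off conditions, as (alpha1, alpha6, tonic)
#: enabled flags.
CONDITIONS = {
    "control": (True, True, True),
    "alpha1-off": (False, True, True),
    "alpha6-off": (True, False, True),
    "phasic-off": (False, False, True),
    "tonic-off": (True, True, False),
    "all-off": (False, False, False),
}


@dataclass(frozen=True)
class GlomerulusCircuit:
    """Complete microcircuit configuration for one simulated condition."""

    n_mf: int = 2
    n_goc: int = 2
    pe: float = 0.51
    pi: float = 0.42
    inhibitory: InhibitorySynapse = field(default_factory=InhibitorySynapse)
    excitatory: ExcitatorySynapse = field(default_factory=ExcitatorySynapse)
    tonic: TonicInhibition = field(default_factory=TonicInhibition)
    cell: GranuleCell = field(default_factory=GranuleCell)
    alpha1_on: bool = True
    alpha6_on: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.n_mf <= 4 and 0 <= self.n_goc <= 4):
            raise ValueError("fiber counts must lie in 0..4")
        if not (0.0 <= self.pe <= 1.0 and 0.0 <= self.pi <= 1.0):
            raise ValueError("release probabilities must lie in [0, 1]")


def apply_condition(circuit: GlomerulusCircuit, condition: str) -> GlomerulusCircuit:
    """Return the circuit with one of the named switch-off conditions applied."""
    try:
        a1, a6, ton = CONDITIONS[condition]
    except KeyError:
        raise ValueError(f"unknown condition {condition!r}") from None
    return replace(circuit, alpha1_on=a1, alpha6_on=a6,
                   tonic=replace(circuit.tonic, enabled=ton))


@dataclass
class BatchResult:
    """Traces and spikes for a batch of seeded trials."""

    time: np.ndarray
    vm: np.ndarray        # (n_trials, n_steps) float32
    i_vdcc: np.ndarray
    i_nmda: np.ndarray
    spike_times: list
    seed: int
    condition: str = ""
    dt: float = 0.025


def _release_amounts(params: _rel.ReleaseParams, n_fibers: int,
                     stim_times: np.ndarray, n_trials: int, mode: str,
                     rng: np.random.Generator) -> np.ndarray:
    """Quanta released per (trial, site, stimulus) for a fiber population."""
    n_sites = n_fibers * params.n_sites
    n_stim = stim_times.size
    if n_sites == 0 or n_stim == 0:
        return np.zeros((n_trials, n_sites, n_stim))
    if mode == "stochastic":
        return _rel.stochastic_release_matrix(params, stim_times, n_trials,
                                              rng, n_sites=n_sites).astype(float)
    frac = _rel.deterministic_release_fractions(params, stim_times)
    return np.broadcast_to(frac, (n_trials, n_sites, n_stim)).copy()


def simulate_batch(circuit: GlomerulusCircuit,
                   stim_e: np.ndarray, stim_i: np.ndarray,
                   n_trials: int = 100, seed: int = 0,
                   mode: str = "stochastic",
                   duration: float = 300.0, dt: float = 0.025) -> BatchResult:
    """Simulate a batch of trials of the full microcircuit.

    ``stim_e``/``stim_i`` are the stimulus times (ms) of the excitatory and
    inhibitory fiber populations (every fiber of a population shares the
    train; its sites draw release independently).
    """
    stim_e = np.asarray(stim_e, dtype=float)
    stim_i = np.asarray(stim_i, dtype=float)
    n_steps = int(round(duration / dt))
    time = np.arange(n_steps) * dt
    cell = circuit.cell
    inh, exc = circuit.inhibitory, circuit.excitatory

    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF]))
    rel_i = _release_amounts(replace_p(inh.release, circuit.pi),
                             circuit.n_goc, stim_i, n_trials, mode, rng)
    rel_e = _release_amounts(replace_p(exc.release, circuit.pe),
                             circuit.n_mf, stim_e, n_trials, mode, rng)

    n_si = rel_i.shape[1]
    n_se = rel_e.shape[1]

    # pulse window lookup: which stimulus (if any) covers each step
    def pulse_index(stim: np.ndarray, pulse_ms: float) -> np.ndarray:
        widx = np.full(n_steps, -1, dtype=np.int64)
        plen = int(round(pulse_ms / dt))
        for k, t0 in enumerate(stim):
            s0 = int(round(t0 / dt))
            widx[s0:min(s0 + plen, n_steps)] = k
        return widx

    widx_i = pulse_index(stim_i, inh.release.pulse_duration)
    widx_e = pulse_index(stim_e, exc.release.pulse_duration)

    # spillover kernel values per (stimulus, step); quanta carry A/n_sites
    def kernel_matrix(stim: np.ndarray, params) -> np.ndarray:
        kern = spillover_kernel(params, dt, n_steps) / 3.0
        km = np.zeros((stim.size, n_steps))
        for k, t0 in enumerate(stim):
            s0 = int(round(t0 / dt))
            km[k, s0:] = kern[:n_steps - s0]
        return km

    km_i = kernel_matrix(stim_i, inh.diffusion)
    km_e = kernel_matrix(stim_e, exc.diffusion)
    tot_i = rel_i.sum(axis=1)   # (n_trials, n_stim)
    tot_e = rel_e.sum(axis=1)

    # receptor propagator tables
    _, props1 = _cached_table(inh.alpha1, dt)
    _, props6 = _cached_table(inh.alpha6, dt)
    x1 = np.broadcast_to(_rec.resting_occupancy(),
                         (n_trials, n_si, 8)).copy()
    x6 = x1.copy()
    r_ampa = np.zeros((n_trials, n_se))
    r_nmda = np.zeros((n_trials, n_se))

    g1 = inh.alpha1.g_max * 1e-3 / 3.0 if circuit.alpha1_on else 0.0   # nS/site
    g6 = inh.alpha6.g_max * 1e-3 / 3.0 if circuit.alpha6_on else 0.0
    g_ton = circuit.tonic.g_tonic * 1e-3 if circuit.tonic.enabled else 0.0
    ga_site = exc.g_ampa * 1e-3 / 3.0
    gn_site = exc.g_nmda * 1e-3 / 3.0
    e_cl = inh.alpha1.e_rev

    v_rest = _cached_rest(cell, g_ton, e_cl)
    v = np.full(n_trials, v_rest)
    gates = init_gates(v_rest, (n_trials,))
    vm = np.empty((n_trials, n_steps), dtype=np.float32)
    i_vdcc = np.empty((n_trials, n_steps), dtype=np.float32)
    i_nmda = np.empty((n_trials, n_steps), dtype=np.float32)

    t_max_i = inh.release.t_max
    t_max_e = exc.release.t_max

    for j in range(n_steps):
        # inhibitory transmitter per PSD: neighboring spillover + own pulse
        if n_si:
            kv = km_i[:, j]
            spill_tot = tot_i @ kv
            own = rel_i @ kv
            c = spill_tot[:, None] - own
            if widx_i[j] >= 0:
                c = c + t_max_i * rel_i[:, :, widx_i[j]]
            idx = _rec.concentration_to_level(c)
            x1 = np.einsum("tsij,tsj->tsi", props1[idx], x1)
            x6 = np.einsum("tsij,tsj->tsi", props6[idx], x6)
            po1 = x1[:, :, 3].sum(axis=1) + x1[:, :, 4].sum(axis=1)
            po6 = x6[:, :, 3].sum(axis=1) + x6[:, :, 4].sum(axis=1)
            g_phasic = g1 * po1 + g6 * po6
        else:
            g_phasic = 0.0

        # excitatory transmitter and AMPA/NMDA two-state receptors
        if n_se:
            kv = km_e[:, j]
            spill_tot = tot_e @ kv
            own = rel_e @ kv
            ce = spill_tot[:, None] - own
            if widx_e[j] >= 0:
                ce = ce + t_max_e * rel_e[:, :, widx_e[j]]
            ka = exc.ampa_alpha * ce
            tau = 1.0 / (ka + exc.ampa_beta)
            r_inf = ka * tau
            r_ampa = r_inf + (r_ampa - r_inf) * np.exp(-dt / tau)
            kn = exc.nmda_alpha * ce
            tau = 1.0 / (kn + exc.nmda_beta)
            r_inf = kn * tau
            r_nmda = r_inf + (r_nmda - r_inf) * np.exp(-dt / tau)
            g_ampa = ga_site * r_ampa.sum(axis=1)
            g_nmda_open = gn_site * r_nmda.sum(axis=1) * mg_block(v, exc.mg_mM)
        else:
            g_ampa = np.zeros(n_trials)
            g_nmda_open = np.zeros(n_trials)

        v, ica = step_membrane(cell, v, gates, dt,
                               g_syn_e=g_ampa + g_nmda_open,
                               g_syn_i=g_phasic + g_ton,
                               e_syn_i=e_cl)
        vm[:, j] = v
        i_vdcc[:, j] = ica
        i_nmda[:, j] = g_nmda_open * v   # e_rev = 0 mV

    spikes = [detect_spikes(vm[i], dt, cell.spike_threshold)
              for i in range(n_trials)]
    return BatchResult(time, vm, i_vdcc, i_nmda, spikes, seed, dt=dt)


def replace_p(params: _rel.ReleaseParams, p: float) -> _rel.ReleaseParams:
    return replace(params, p=p)


@lru_cache(maxsize=8)
def _cached_rest(cell: GranuleCell, g_background_i: float = 0.0,
                 e_background_i: float = -65.0) -> float:
    return resting_potential(cell, g_background_i=g_background_i,
                             e_background_i=e_background_i)


def integrate(circuit: GlomerulusCircuit, stim_e, stim_i,
              duration: float = 300.0, dt: float = 0.025,
              seed: int = 0, mode: str = "stochastic",
              condition: str = "control") -> TrialResult:
    """Single-trial convenience wrapper returning a :class:`TrialResult`."""
    circ = apply_condition(circuit, condition)
    batch = simulate_batch(circ, np.asarray(stim_e, dtype=float),
                           np.asarray(stim_i, dtype=float),
                           n_trials=1, seed=seed, mode=mode,
                           duration=duration, dt=dt)
    return TrialResult(batch.time, batch.vm[0].astype(float),
                       batch.spike_times[0], batch.i_vdcc[0].astype(float),
                       batch.i_nmda[0].astype(float), seed=seed,
                       condition=condition)
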