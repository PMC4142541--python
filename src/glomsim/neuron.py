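"""Conductance-based single-compartment cerebellar granule cell.

Granule cells are electrotonically compact, so a single compartment with
Hodgkin-Huxley-style channels captures their firing behavior.  The model
carries a fast transient Na current, a delayed-rectifier K current, an
A-type K current (which delays firing onset), a high-voltage-activated Ca
current (the VDCC, recorded as a proxy for spike-associated calcium
influx) and an ohmic leak.  Channel densities are set to reproduce the
hallmark granule-cell phenotype: resting potential near -70 mV with a
~1.5 GOhm input resistance, no spontaneous firing, and fast repetitive
spiking under sustained depolarization.

Voltages in mV, time in ms, conductances in nS, capacitance in pF,
currents in pA (outward positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GranuleCell",
    "TrialResult",
    "gate_tables",
    "init_gates",
    "step_membrane",
    "integrate_current_clamp",
    "detect_spikes",
    "mean_current",
    "resting_potential",
    "fi_curve",
]


@dataclass(frozen=True)
class GranuleCell:
    """Channel densities and passive properties of the granule cell."""

    c_m: float = 3.0           # pF
    g_na: float = 110.0        # nS, fast transient Na
    g_nap: float = 0.22         # persistent Na (supports firing tails)
    e_na: float = 55.0
    g_kdr: float = 30.0        # delayed rectifier
    e_k: float = -90.0
    g_ka: float = 8.0          # A-type K
    g_ca: float = 1.6          # high-voltage-activated Ca (VDCC)
    e_ca: float = 60.0
    g_leak: float = 0.55
    e_leak: float = -71.0
    spike_threshold: float = -20.0  # mV, detection threshold


@dataclass
class TrialResult:
    """Membrane trace and recorded currents of one seeded trial."""

    time: np.ndarray
    vm: np.ndarray
    spike_times: np.ndarray
    i_vdcc: np.ndarray
    i_nmda: np.ndarray
    seed: int | None = None
    condition: str = ""

    def __post_init__(self) -> None:
        if np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike times must be strictly increasing")


# -- channel kinetics ---------------------------------------------------

def _vtrap(x: np.ndarray, y: float) -> np.ndarray:
    """x / (1 - exp(-x/y)) with the removable singularity handled."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / y) < 1e-6
    return np.where(small, y * (1.0 + x / (2.0 * y)), x / (1.0 - np.exp(-x / y)))


def gate_tables(v: np.ndarray) -> dict[str, np.ndarray]:
    """Steady-state values and time constants of every gate at potential v.

    Na activation is treated as instantaneous (its time constant is well
    below the integration step); Na inactivation ``h`` and the delayed
    rectifier ``n`` use scaled alpha/beta kinetics; the A-current gates and
    the Ca activation gate use Boltzmann steady states with fixed taus.
    """
    v = np.asarray(v, dtype=float)
    phi = 5.0

    a_m = 0.1 * _vtrap(v + 35.0, 10.0)
    b_m = 4.0 * np.exp(-(v + 60.0) / 18.0)
    m_inf = a_m / (a_m + b_m)

    a_h = phi * 0.07 * np.exp(-(v + 58.0) / 20.0)
    b_h = phi / (np.exp(-0.1 * (v + 28.0)) + 1.0)
    h_inf = a_h / (a_h + b_h)
    tau_h = 1.0 / (a_h + b_h)

    a_n = phi * 0.01 * _vtrap(v + 34.0, 10.0)
    b_n = phi * 0.125 * np.exp(-(v + 44.0) / 80.0)
    n_inf = a_n / (a_n + b_n)
    tau_n = 1.0 / (a_n + b_n)

    ka_a_inf = 1.0 / (1.0 + np.exp(-(v + 45.0) / 10.0))
    ka_b_inf = 1.0 / (1.0 + np.exp((v + 70.0) / 6.0))

    ca_s_inf = 1.0 / (1.0 + np.exp(-(v + 20.0) / 7.0))

    nap_inf = 1.0 / (1.0 + np.exp(-(v + 52.0) / 5.0))

    return {
        "nap_inf": nap_inf,
        "m_inf": m_inf,
        "h_inf": h_inf, "tau_h": tau_h,
        "n_inf": n_inf, "tau_n": tau_n,
        "ka_a_inf": ka_a_inf, "tau_ka_a": 0.4,
        "ka_b_inf": ka_b_inf, "tau_ka_b": 15.0,
        "ca_s_inf": ca_s_inf, "tau_ca_s": 1.0,
    }


def init_gates(v0: float | np.ndarray, shape: tuple = ()) -> dict[str, np.ndarray]:
    """Gate variables equilibrated at ``v0``."""
    g = gate_tables(np.broadcast_to(np.asarray(v0, dtype=float), shape).copy())
    return {"h": g["h_inf"].copy(), "n": g["n_inf"].copy(),
            "ka_a": g["ka_a_inf"].copy(), "ka_b": g["ka_b_inf"].copy(),
            "ca_s": g["ca_s_inf"].copy()}


def step_membrane(cell: GranuleCell, v: np.ndarray, gates: dict, dt: float,
                  g_syn_e: np.ndarray | float = 0.0,
                  g_syn_i: np.ndarray | float = 0.0,
                  e_syn_i: float = -65.0,
                  i_inj: np.ndarray | float = 0.0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Advance the membrane by one step (exponential Euler on V,
    Rush-Larsen on the gates).

    ``g_syn_e`` is the total excitatory conductance at 0 mV reversal (AMPA
    plus Mg-unblocked NMDA), ``g_syn_i`` the total chloride conductance
    (phasic + tonic).  Returns the new potential and the VDCC current.
    """
    t = gate_tables(v)
    # Rush-Larsen gate update
    for key, (inf, tau) in {"h": ("h_inf", "tau_h"), "n": ("n_inf", "tau_n"),
                            "ka_a": ("ka_a_inf", "tau_ka_a"),
                            "ka_b": ("ka_b_inf", "tau_ka_b"),
                            "ca_s": ("ca_s_inf", "tau_ca_s")}.items():
        gates[key] = t[inf] + (gates[key] - t[inf]) * np.exp(-dt / t[tau])

    m = t["m_inf"]
    g_na = cell.g_na * m ** 3 * gates["h"] + cell.g_nap * t["nap_inf"]
    g_kdr = cell.g_kdr * gates["n"] ** 4
    g_ka = cell.g_ka * gates["ka_a"] ** 3 * gates["ka_b"]
    g_ca = cell.g_ca * gates["ca_s"] ** 2

    g_tot = g_na + g_kdr + g_ka + g_ca + cell.g_leak + g_syn_e + g_syn_i
    i_rev = (g_na * cell.e_na + (g_kdr + g_ka) * cell.e_k + g_ca * cell.e_ca
             + cell.g_leak * cell.e_leak + g_syn_i * e_syn_i + i_inj)
    v_inf = i_rev / g_tot
    v_new = v_inf + (v - v_inf) * np.exp(-dt * g_tot / cell.c_m)
    i_vdcc = g_ca * (v_new - cell.e_ca)
    return v_new, i_vdcc


def detect_spikes(vm: np.ndarray, dt: float, threshold: float = -20.0,
                  refractory: float = 1.0) -> np.ndarray:
    """Times of upward threshold crossings, pruned by a refractory guard."""
    vm = np.asarray(vm, dtype=float)
    up = np.flatnonzero((vm[1:] >= threshold) & (vm[:-1] < threshold)) + 1
    times = up * dt
    if times.size < 2:
        return times
    keep = [times[0]]
    for t in times[1:]:
        if t - keep[-1] >= refractory:
            keep.append(t)
    return np.array(keep)


def mean_current(trace: np.ndarray, dt: float, start: float = 0.0,
                 window: float = 130.0) -> float:
    """Mean of a current trace over ``window`` ms starting at ``start``."""
    i0 = int(round(start / dt))
    i1 = int(round((start + window) / dt))
    if i1 > trace.size:
        raise ValueError("averaging window exceeds the trace")
    return float(np.mean(trace[i0:i1]))


def integrate_current_clamp(cell: GranuleCell, i_inj: np.ndarray | float,
                            duration: float, dt: float = 0.025,
                            v0: float | None = None) -> TrialResult:
    """Current-clamp integration with an injected current.

    ``i_inj`` may be a scalar (step for the whole duration) or a waveform
    sampled on the grid.  Deterministic.
    """
    n_steps = int(round(duration / dt))
    inj = np.broadcast_to(np.asarray(i_inj, dtype=float), (n_steps,))
    v = np.array(resting_potential(cell) if v0 is None else v0, dtype=float)
    gates = init_gates(float(v))
    vm = np.empty(n_steps)
    i_ca = np.empty(n_steps)
    for j in range(n_steps):
        v, ica = step_membrane(cell, v, gates, dt, i_inj=inj[j])
        vm[j] = v
        i_ca[j] = ica
    time = np.arange(n_steps) * dt
    return TrialResult(time, vm, detect_spikes(vm, dt, cell.spike_threshold),
                       i_ca, np.zeros(n_steps))


def resting_potential(cell: GranuleCell, t_settle: float = 500.0,
                      dt: float = 0.1, g_background_i: float = 0.0,
                      e_background_i: float = -65.0) -> float:
    """Settled membrane potential with synaptic inputs silent.

    ``g_background_i`` adds a steady chloride conductance (nS), used to
    include tonic inhibition in the resting state.
    """
    v = np.array(cell.e_leak, dtype=float)
    gates = init_gates(float(v))
    for _ in range(int(t_settle / dt)):
        v, _ = step_membrane(cell, v, gates, dt, g_syn_i=g_background_i,
                             e_syn_i=e_background_i)
    return float(v)


def fi_curve(cell: GranuleCell, amplitudes_pA: np.ndarray,
             duration: float = 500.0, dt: float = 0.025) -> np.ndarray:
    """Firing rate (Hz) for each step-current amplitude."""
    rates = []
    for amp in amplitudes_pA:
        res = integrate_current_clamp(cell, amp, duration, dt)
        rates.append(res.spike_times.size / duration * 1e3)
    return np.array(rates)
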