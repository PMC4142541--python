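"""Short-term vesicular release dynamics (Tsodyks-Markram 3-state scheme).

Each synapse is split into independent releasing sites.  A site carries a
resource variable ``x`` (fraction of the reserve pool available) and a
utilization variable ``u``; on a presynaptic spike the released fraction is
``u*x``, after which the resource is depleted and recovers with time
constant ``tau_rec``.  With ``tau_fac = 0`` (the fitted value for the
glomerular synapses) ``u`` is constant and equal to the baseline release
probability ``p``.

The stochastic variant is quantal: a site holds at most one releasable
vesicle, recovery after depletion is a Poisson event with rate
``1/tau_rec``, and on each spike a uniform random number is compared with
the actual releasable resource ``Y = u*x`` (``x`` being the binary
occupancy).  Averaged over trials this reproduces the deterministic
dynamics exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ReleaseParams",
    "ReleaseSiteState",
    "ReleaseEvent",
    "rested_state",
    "on_spike_deterministic",
    "on_spike_stochastic",
    "deterministic_release_fractions",
    "stochastic_release_matrix",
    "mean_field_check",
]


@dataclass(frozen=True)
class ReleaseParams:
    """Presynaptic parameters of one synapse.

    ``p`` baseline release probability, ``tau_rec``/``tau_fac`` recovery and
    facilitation time constants (ms), ``n_sites`` independent releasing
    sites, ``t_max`` transmitter pulse concentration (mM) at the facing PSD.
    """

    p: float = 0.42
    tau_rec: float = 38.7
    tau_fac: float = 0.0
    n_sites: int = 3
    t_max: float = 1.0
    pulse_duration: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.tau_rec <= 0:
            raise ValueError("tau_rec must be positive")
        if self.tau_fac < 0:
            raise ValueError("tau_fac must be non-negative")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")


@dataclass(frozen=True)
class ReleaseSiteState:
    """State of one releasing site between spikes.

    ``x`` is the available resource fraction (deterministic mode) or the
    binary vesicle occupancy (stochastic mode); ``u`` the utilization
    variable after the last spike; ``last_event_time`` the time of the last
    processed spike (ms, ``-inf`` for a rested site).
    """

    x: float = 1.0
    u: float = 0.0
    last_event_time: float = -np.inf


@dataclass(frozen=True)
class ReleaseEvent:
    """A quantal release emitted by one site."""

    site_id: int
    time: float
    released_fraction: float
    quantum: float = 1.0


def rested_state() -> ReleaseSiteState:
    return ReleaseSiteState()


def _advance(state: ReleaseSiteState, params: ReleaseParams,
             t: float) -> tuple[float, float]:
    """Resource recovery and utilization decay over the inter-spike interval."""
    if t < state.last_event_time:
        raise ValueError("spikes must be processed in time order")
    dt = t - state.last_event_time
    decay_rec = np.exp(-dt / params.tau_rec)
    x = 1.0 - (1.0 - state.x) * decay_rec
    if params.tau_fac > 0:
        u_decay = state.u * np.exp(-dt / params.tau_fac)
        u = u_decay + params.p * (1.0 - u_decay)
    else:
        u = params.p
    return x, u


def on_spike_deterministic(state: ReleaseSiteState, params: ReleaseParams,
                           t: float) -> tuple[ReleaseSiteState, float]:
    """Process one presynaptic spike; return new state and released fraction."""
    x, u = _advance(state, params, t)
    released = u * x
    return ReleaseSiteState(x=x - released, u=u, last_event_time=t), released


def on_spike_stochastic(state: ReleaseSiteState, params: ReleaseParams,
                        t: float, rng: np.random.Generator,
                        site_id: int = 0) -> tuple[ReleaseSiteState, ReleaseEvent | None]:
    """Quantal stochastic release at one site.

    The site occupancy ``x`` is binary.  An empty site refills during the
    inter-spike interval with probability ``1 - exp(-dt/tau_rec)``; release
    then occurs when a uniform draw falls below ``Y = u*x``.
    """
    dt = t - state.last_event_time
    if dt < 0:
        raise ValueError("spikes must be processed in time order")
    x = state.x
    if x < 0.5 and rng.random() < 1.0 - np.exp(-dt / params.tau_rec):
        x = 1.0
    if params.tau_fac > 0:
        u_decay = state.u * np.exp(-dt / params.tau_fac)
        u = u_decay + params.p * (1.0 - u_decay)
    else:
        u = params.p
    if rng.random() < u * x:
        new = ReleaseSiteState(x=0.0, u=u, last_event_time=t)
        return new, ReleaseEvent(site_id=site_id, time=t, released_fraction=u * x)
    return ReleaseSiteState(x=x, u=u, last_event_time=t), None


def deterministic_release_fractions(params: ReleaseParams,
                                    spike_times: np.ndarray) -> np.ndarray:
    """Released fraction ``u*x`` at each spike of a train (one site)."""
    state = rested_state()
    out = np.empty(len(spike_times))
    for k, t in enumerate(np.asarray(spike_times, dtype=float)):
        state, out[k] = on_spike_deterministic(state, params, t)
    return out


def stochastic_release_matrix(params: ReleaseParams, spike_times: np.ndarray,
                              n_trials: int, rng: np.random.Generator,
                              n_sites: int | None = None) -> np.ndarray:
    """Vectorized quantal release outcomes for repeated trials.

    Returns a 0/1 array of shape ``(n_trials, n_sites, n_spikes)``.  Site
    occupancies start full; refill between spikes is sampled per interval.
    Trials and sites use independent substreams of ``rng``.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if n_trials < 1:
        raise ValueError("need at least one trial")
    ns = params.n_sites if n_sites is None else n_sites
    n_spk = spike_times.size
    occupied = np.ones((n_trials, ns), dtype=bool)
    out = np.zeros((n_trials, ns, n_spk))
    u = params.p  # tau_fac = 0 path; facilitation handled scalar below
    u_state = np.zeros((n_trials, ns))
    last_t = -np.inf
    for k, t in enumerate(spike_times):
        dt = t - last_t
        refill = rng.random((n_trials, ns)) < 1.0 - np.exp(-dt / params.tau_rec)
        occupied |= refill
        if params.tau_fac > 0:
            u_decay = u_state * np.exp(-dt / params.tau_fac)
            u_state = u_decay + params.p * (1.0 - u_decay)
            u_arr = u_state
        else:
            u_arr = u
        release = (rng.random((n_trials, ns)) < u_arr) & occupied
        occupied &= ~release
        out[:, :, k] = release
        last_t = t
    return out


@dataclass(frozen=True)
class MeanFieldCheck:
    """Comparison of trial-averaged quantal release with the deterministic rule."""

    spike_times: np.ndarray
    deterministic: np.ndarray
    stochastic_mean: np.ndarray
    stochastic_sem: np.ndarray
    within_3se: bool


def mean_field_check(params: ReleaseParams, spike_times: np.ndarray,
                     n_trials: int = 1000,
                     rng: np.random.Generator | None = None) -> MeanFieldCheck:
    """Law-of-large-numbers check: mean quantal release vs ``u*x`` per pulse."""
    if n_trials < 1:
        raise ValueError("need at least one trial")
    rng = np.random.default_rng(0) if rng is None else rng
    det = deterministic_release_fractions(params, spike_times)
    rel = stochastic_release_matrix(params, spike_times, n_trials, rng,
                                    n_sites=1)[:, 0, :]
    mean = rel.mean(axis=0)
    sem = rel.std(axis=0, ddof=1) / np.sqrt(n_trials)
    ok = bool(np.all(np.abs(mean - det) <= 3.0 * np.maximum(sem, 1e-12)))
    return MeanFieldCheck(np.asarray(spike_times, dtype=float), det, mean, sem, ok)
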