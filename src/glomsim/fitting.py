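"""Two-step fitting of the synapse model to evoked IPSC data.

Step one fits single evoked IPSCs to recover the diffusion source ``A``,
the spillover distance ``r`` and the receptor conductances, with the cleft
thickness and diffusion coefficient held at their literature values.  Step
two fits trains to recover the short-term dynamics (tau_rec, tau_fac) and
release probability ``p``; a control/CGP55845 pair of trains is fitted
simultaneously with every parameter shared except ``p``, testing whether a
release-probability change alone explains the drug effect.

Optimization is bounded least squares on the time-domain residuals with
multi-start initial values drawn log-uniformly over the bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .diffusion import DiffusionParams
from .synapse import InhibitorySynapse, simulate_eipsc

__all__ = [
    "FitSpec",
    "FitResult",
    "PARAM_BOUNDS",
    "fit_single_eipsc",
    "fit_train_pair",
]

#: Bounds for every fittable parameter.
PARAM_BOUNDS = {
    "g_max_alpha1": (100.0, 5000.0),      # pS
    "g_max_alpha6": (50.0, 2000.0),       # pS
    "a_molecules": (1000.0, 100000.0),
    "r_um": (0.2, 5.0),
    "tau_rec": (5.0, 500.0),              # ms
    "tau_fac": (0.0, 100.0),
    "p": (0.05, 0.95),
}


@dataclass(frozen=True)
class FitSpec:
    """Free parameters, bounds and optimizer settings of one fit."""

    free: tuple[str, ...]
    bounds: dict = field(default_factory=dict)
    n_starts: int = 4
    seed: int = 0
    dt: float = 0.1

    def bound(self, name: str) -> tuple[float, float]:
        if name in self.bounds:
            return self.bounds[name]
        return PARAM_BOUNDS[name]


@dataclass
class FitResult:
    """Point estimates, residual norm and convergence diagnostics."""

    estimates: dict
    residual_norm: float
    converged: bool
    n_starts: int
    messages: list = field(default_factory=list)


def _apply(syn: InhibitorySynapse, names, values) -> InhibitorySynapse:
    upd = dict(zip(names, values))
    diff = syn.diffusion
    rel = syn.release
    a1, a6 = syn.alpha1, syn.alpha6
    if "a_molecules" in upd or "r_um" in upd:
        diff = replace(diff,
                       m_molecules=upd.get("a_molecules", diff.m_molecules),
                       r=upd.get("r_um", diff.r))
    if "tau_rec" in upd or "tau_fac" in upd or "p" in upd:
        rel = replace(rel, tau_rec=upd.get("tau_rec", rel.tau_rec),
                      tau_fac=upd.get("tau_fac", rel.tau_fac),
                      p=upd.get("p", rel.p))
    if "g_max_alpha1" in upd:
        a1 = a1.with_g_max(upd["g_max_alpha1"])
    if "g_max_alpha6" in upd:
        a6 = a6.with_g_max(upd["g_max_alpha6"])
    return replace(syn, diffusion=diff, release=rel, alpha1=a1, alpha6=a6)


def _model_trace(syn: InhibitorySynapse, stim_times, v_clamp, t_grid, dt):
    tr = simulate_eipsc(syn, stim_times, v_clamp=v_clamp,
                        duration=float(t_grid[-1]) + dt, dt=dt)
    return np.interp(t_grid, tr.time, tr.total)


def _multistart_lsq(objective, names, spec: FitSpec) -> FitResult:
    rng = np.random.default_rng(spec.seed)
    lo = np.array([spec.bound(n)[0] for n in names])
    hi = np.array([spec.bound(n)[1] for n in names])
    # loguniform starts (linear for parameters whose range includes zero)
    best, msgs = None, []
    for k in range(spec.n_starts):
        if k == 0:
            x0 = np.sqrt(np.maximum(lo, 1e-3) * hi)
        else:
            u = rng.random(len(names))
            safe_lo = np.maximum(lo, 1e-3)
            x0 = np.where(lo > 0,
                          np.exp(np.log(safe_lo) + u * np.log(hi / safe_lo)),
                          lo + u * (hi - lo))
        try:
            sol = least_squares(objective, x0, bounds=(lo, hi),
                                diff_step=1e-3, xtol=1e-10, ftol=1e-10)
        except Exception as err:  # keep going; report at the end
            msgs.append(str(err))
            continue
        msgs.append(sol.message)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return FitResult({}, np.inf, False, spec.n_starts, msgs)
    return FitResult(dict(zip(names, best.x)),
                     float(np.sqrt(2.0 * best.cost)),
                     bool(best.success), spec.n_starts, msgs)


def fit_single_eipsc(time_ms: np.ndarray, current_pA: np.ndarray,
                     stim_times, spec: FitSpec | None = None,
                     v_clamp: float = -10.0,
                     template: InhibitorySynapse | None = None) -> FitResult:
    """Fit diffusion/conductance parameters to a single evoked IPSC.

    ``h`` and ``D_eff`` stay at their literature values; the default free
    set is (g_max_alpha1, g_max_alpha6, A, r).  The source strength and
    distance are jointly identifiable only when the trace contains both the
    fast (pulse-driven) and slow (spillover-driven) components; fits on
    tail-only data are flagged as non-converged/degenerate by the optimizer
    diagnostics.
    """
    spec = spec or FitSpec(free=("g_max_alpha1", "g_max_alpha6",
                                 "a_molecules", "r_um"))
    syn0 = template or InhibitorySynapse()
    time_ms = np.asarray(time_ms, dtype=float)
    current_pA = np.asarray(current_pA, dtype=float)

    def objective(x):
        syn = _apply(syn0, spec.free, x)
        return _model_trace(syn, stim_times, v_clamp, time_ms, spec.dt) \
            - current_pA

    return _multistart_lsq(objective, spec.free, spec)


def fit_train_pair(time_ms: np.ndarray, control_pA: np.ndarray,
                   cgp_pA: np.ndarray, stim_times,
                   spec: FitSpec | None = None, v_clamp: float = -10.0,
                   template: InhibitorySynapse | None = None) -> FitResult:
    """Simultaneous fit of control and CGP55845 train IPSCs.

    All parameters are shared between the two traces except the release
    probability, returned as ``p_control`` and ``p_cgp``.
    """
    spec = spec or FitSpec(free=("tau_rec", "p_control", "p_cgp"))
    shared = tuple(n for n in spec.free if n not in ("p_control", "p_cgp"))
    syn0 = template or InhibitorySynapse()
    time_ms = np.asarray(time_ms, dtype=float)
    control_pA = np.asarray(control_pA, dtype=float)
    cgp_pA = np.asarray(cgp_pA, dtype=float)
    names = list(spec.free)
    bounds = dict(spec.bounds)
    for alias in ("p_control", "p_cgp"):
        bounds.setdefault(alias, PARAM_BOUNDS["p"])
    spec = replace(spec, bounds=bounds)

    def objective(x):
        vals = dict(zip(names, x))
        sh = [vals[n] for n in shared]
        syn_c = _apply(_apply(syn0, shared, sh), ("p",), (vals["p_control"],))
        syn_g = _apply(_apply(syn0, shared, sh), ("p",), (vals["p_cgp"],))
        rc = _model_trace(syn_c, stim_times, v_clamp, time_ms, spec.dt) \
            - control_pA
        rg = _model_trace(syn_g, stim_times, v_clamp, time_ms, spec.dt) \
            - cgp_pA
        return np.concatenate([rc, rg])

    return _multistart_lsq(objective, names, spec)
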