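"""GABA concentration at receptor locations: direct pulse plus spillover.

The transmitter seen by a postsynaptic density is the sum of a brief
rectangular pulse (release at the facing site) and a diffusive spillover
term from every release event in the glomerulus.  Spillover follows the
two-dimensional disc solution of the diffusion equation for an instantaneous
point source of ``M`` molecules spreading in a cleft of thickness ``h``:

    C(r, t) = M / (4 pi h D_eff t) * exp(-r^2 / (4 t D_eff))

converted from molecules/um^3 to mM.  A single effective distance ``r``
is used for every source/PSD pair, as constrained by the train fittings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "DiffusionParams",
    "spillover_concentration",
    "spillover_kernel",
    "total_concentration",
    "MM_PER_MOLEC_UM3",
]

#: Avogadro's number.
N_AVOGADRO = 6.02214076e23

#: molecules/um^3 -> mM:  1 um^3 = 1e-15 L, 1 mM = 1e-3 mol/L.
MM_PER_MOLEC_UM3 = 1.0 / (N_AVOGADRO * 1e-15 * 1e-3)


@dataclass(frozen=True)
class DiffusionParams:
    """Spillover geometry and source strength.

    Defaults are the fitted glomerular values: ``m_molecules`` released
    molecules per quantum, effective diffusion coefficient ``d_eff``
    (um^2/ms), cleft thickness ``h`` (um) and diffusion distance ``r`` (um).

    ``geometry`` selects the Green's function of the instantaneous source:
    ``"point"`` (default) is the three-dimensional solution
    ``M / (8 (pi D t)^{3/2}) * exp(-r^2/(4 D t))``, appropriate for a
    transmitter that spreads through the porous glomerular volume and
    whose concentration decays as t^(-3/2); ``"disc"`` is the
    two-dimensional cleft solution ``M / (4 pi h D t) * exp(-r^2/(4 D t))``
    in which the transmitter never leaves a cleft of thickness ``h`` and
    the tail decays only as 1/t.
    """

    m_molecules: float = 10573.0
    d_eff: float = 0.221
    h: float = 0.05
    r: float = 1.07
    geometry: str = "point"

    def __post_init__(self) -> None:
        for name in ("m_molecules", "d_eff", "h", "r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.geometry not in ("point", "disc"):
            raise ValueError("geometry must be 'point' or 'disc'")

    @property
    def t_peak(self) -> float:
        """Time (ms) at which the spillover transient peaks.

        ``r^2/(4D)`` for the disc solution, ``r^2/(6D)`` for the point
        source.
        """
        denom = 4.0 if self.geometry == "disc" else 6.0
        return self.r ** 2 / (denom * self.d_eff)


def spillover_concentration(params: DiffusionParams,
                            dt_since_release: np.ndarray | float) -> np.ndarray | float:
    """Spillover concentration (mM) at lag ``dt_since_release`` (ms).

    Zero at and before the release instant.
    """
    t = np.asarray(dt_since_release, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since release must be non-negative")
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    if params.geometry == "disc":
        dens = (params.m_molecules / (4.0 * np.pi * params.h * params.d_eff * tp)
                * np.exp(-params.r ** 2 / (4.0 * tp * params.d_eff)))
    else:
        dens = (params.m_molecules / (8.0 * (np.pi * params.d_eff * tp) ** 1.5)
                * np.exp(-params.r ** 2 / (4.0 * tp * params.d_eff)))
    out[pos] = dens * MM_PER_MOLEC_UM3
    if out.ndim == 0:
        return float(out)
    return out


def spillover_kernel(params: DiffusionParams, dt: float, n_steps: int,
                     amount: float = 1.0) -> np.ndarray:
    """Spillover waveform sampled on the simulation grid.

    ``kernel[k]`` is the concentration ``k`` steps after a release of
    ``amount`` quanta (``amount * m_molecules`` molecules).
    """
    t = np.arange(n_steps) * dt
    return amount * spillover_concentration(params, t)


@dataclass(frozen=True)
class ReleaseEventRecord:
    """One quantal release: site, time and size (in quanta)."""

    site_id: int
    time: float
    amount: float = 1.0


def total_concentration(params: DiffusionParams,
                        events: Iterable,
                        site_of_psd: int,
                        t: float,
                        t_max: float = 1.0,
                        pulse_duration: float = 1.0,
                        include_own_spillover: bool = False) -> float:
    """Total [GABA] (mM) at one PSD at time ``t``.

    The direct pulse (``t_max`` mM for ``pulse_duration`` ms) applies only
    to releases at the PSD's own facing site; spillover from neighboring
    release events superposes linearly at the single distance ``r``.  The
    facing site's own events contribute the pulse, not spillover, unless
    ``include_own_spillover`` is set.  Event ``amount`` scales both the
    pulse amplitude and the spillover source.
    """
    c = 0.0
    for ev in events:
        lag = t - ev.time
        if lag <= 0:
            continue
        own = ev.site_id == site_of_psd
        if own and lag <= pulse_duration:
            c += t_max * ev.amount
        if not own or include_own_spillover:
            c += ev.amount * spillover_concentration(params, lag)
    return c
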