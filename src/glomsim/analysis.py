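"""Response-space maps, Lorentzian resonance fits and coding fraction.

The excitation/inhibition response space is summarized by the strengths
``S_E = MF + Pe`` and ``S_I = GoC + Pi`` (active fibers plus release
probability).  Phase-lag tuning curves are characterized by a Lorentzian

    y(theta) = (2 A / pi) * omega / (4 (theta - theta_max)^2 + omega^2)

whose quality factor ``Q = y(theta_max) / omega = 2 A / (pi omega^2)``
measures tuning sharpness.  Information transfer is quantified by the
coding fraction ``CF = MI / H(S)``: the mutual information between the
configuration identity (each cell of the response space an equiprobable
stimulus) and a discretized single-trial output metric, normalized by the
stimulus entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "estimate_active_fibers",
    "ei_coordinates",
    "ei_map",
    "LorentzFit",
    "lorentzian",
    "fit_lorentzian",
    "stimulus_entropy",
    "mutual_information",
    "CodingFractionResult",
    "coding_fraction",
]


def estimate_active_fibers(compound_amplitude_pA: float,
                           unitary_amplitude_pA: float) -> float:
    """Number of active fibers from the compound/unitary amplitude ratio.

    E.g. the mean EPSC over the mean single-fiber EPSC, or the mean evoked
    IPSC over the mean spontaneous (single-connection) IPSC.
    """
    if unitary_amplitude_pA == 0:
        raise ValueError("unitary amplitude must be non-zero")
    return float(compound_amplitude_pA) / float(unitary_amplitude_pA)


def ei_coordinates(n_mf: float, pe: float, n_goc: float, pi: float
                   ) -> tuple[float, float]:
    """(S_E, S_I) coordinates of one configuration."""
    return float(n_mf) + float(pe), float(n_goc) + float(pi)


def ei_map(sweep: pd.DataFrame, metric: str,
           condition: str | None = None) -> dict:
    """Arrange a sweep table as the gridded E/I response-space map.

    Returns a dict with the 2-D ``grid`` (rows: S_I descending, columns:
    S_E ascending; each (E, I) quadrant is a 9x9 pe/pi subgrid; missing
    cells are NaN), the axis coordinate vectors, and per-quadrant
    ``subregions``: mean metric, mean S_E and mean S_I, keyed by
    ``(n_mf, n_goc)``.
    """
    df = sweep
    if condition is not None:
        df = df[df["condition"] == condition]
    pe_vals = np.sort(df["pe"].unique())
    pi_vals = np.sort(df["pi"].unique())
    mf_vals = np.sort(df["n_mf"].unique())
    goc_vals = np.sort(df["n_goc"].unique())
    npe, npi = pe_vals.size, pi_vals.size
    grid = np.full((goc_vals.size * npi, mf_vals.size * npe), np.nan)
    s_e = np.concatenate([mf + pe_vals for mf in mf_vals])
    s_i = np.concatenate([goc + pi_vals for goc in goc_vals])
    subregions: dict[tuple, dict] = {}
    for _, row in df.iterrows():
        ci = np.searchsorted(mf_vals, row["n_mf"]) * npe + \
            np.searchsorted(pe_vals, row["pe"])
        ri = np.searchsorted(goc_vals, row["n_goc"]) * npi + \
            np.searchsorted(pi_vals, row["pi"])
        grid[ri, ci] = row[metric]
    for mf in mf_vals:
        for goc in goc_vals:
            cell = df[(df["n_mf"] == mf) & (df["n_goc"] == goc)]
            if cell.empty:
                continue
            subregions[(int(mf), int(goc))] = {
                "mean": float(cell[metric].mean()),
                "s_e": float((cell["n_mf"] + cell["pe"]).mean()),
                "s_i": float((cell["n_goc"] + cell["pi"]).mean()),
            }
    return {"grid": grid, "s_e": s_e, "s_i": s_i, "subregions": subregions}


# -- Lorentzian resonance fitting --------------------------------------

def lorentzian(theta: np.ndarray, area: float, theta_max: float,
               omega: float) -> np.ndarray:
    """The Lorentz tuning function; peak value is 2*area/(pi*omega)."""
    theta = np.asarray(theta, dtype=float)
    return 2.0 * area / np.pi * omega / (4.0 * (theta - theta_max) ** 2
                                         + omega ** 2)


@dataclass(frozen=True)
class LorentzFit:
    """Fitted Lorentzian descriptors of a phase-lag tuning curve."""

    area: float
    theta_max: float
    omega: float
    q: float
    r_squared: float
    converged: bool

    @property
    def peak_value(self) -> float:
        return 2.0 * self.area / (np.pi * self.omega)


def fit_lorentzian(theta: np.ndarray, y: np.ndarray,
                   omega_max: float = 400.0,
                   theta_bounds: tuple[float, float] = (-100.0, 100.0),
                   n_starts: int = 7) -> LorentzFit:
    """Least-squares Lorentzian fit with multi-start in the peak lag.

    The area may take either sign (difference curves can dip).  A
    non-convergent or degenerate fit is returned flagged, never silently.
    """
    theta = np.asarray(theta, dtype=float)
    y = np.asarray(y, dtype=float)
    if theta.size < 5:
        raise ValueError("need at least 5 points spanning the peak")
    span = theta_bounds[1] - theta_bounds[0]
    y_scale = np.max(np.abs(y)) or 1.0

    def resid(p):
        return lorentzian(theta, *p) - y

    best = None
    starts = np.linspace(theta_bounds[0], theta_bounds[1], n_starts)
    i_ext = theta[int(np.argmax(np.abs(y)))]
    for th0 in np.concatenate(([i_ext], starts)):
        for om0 in (span / 10.0, span / 3.0):
            a0 = y[np.argmin(np.abs(theta - th0))] * np.pi * om0 / 2.0
            try:
                sol = least_squares(
                    resid, [a0, th0, om0],
                    bounds=([-np.inf, theta_bounds[0], 1e-6],
                            [np.inf, theta_bounds[1], omega_max]))
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        return LorentzFit(np.nan, np.nan, np.nan, np.nan, np.nan, False)
    area, theta_max, omega = best.x
    ss_res = 2.0 * best.cost
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    q = 2.0 * area / (np.pi * omega ** 2)
    converged = bool(best.success) and np.isfinite(r2)
    return LorentzFit(float(area), float(theta_max), float(omega),
                      float(q), float(r2), converged)


# -- coding fraction ----------------------------------------------------

def stimulus_entropy(n_configurations: int) -> float:
    """Entropy (bits) of the equiprobable configuration set."""
    if n_configurations < 1:
        raise ValueError("need at least one configuration")
    return float(np.log2(n_configurations))


def _discretize(values: np.ndarray, bin_width: float | None,
                no_spike_symbol: bool) -> np.ndarray:
    """Integer response symbols; NaN (no-spike trials) get a dedicated one."""
    values = np.asarray(values, dtype=float)
    nan = np.isnan(values)
    out = np.zeros(values.size, dtype=np.int64)
    if (~nan).any():
        v = values[~nan]
        if bin_width is None:
            out[~nan] = np.round(v).astype(np.int64)
        else:
            out[~nan] = np.floor(v / bin_width).astype(np.int64)
        out[~nan] -= out[~nan].min()
    if nan.any():
        if not no_spike_symbol:
            raise ValueError("metric contains undefined (no-spike) values")
        out[nan] = out[~nan].max() + 1 if (~nan).any() else 0
    return out


def mutual_information(stimulus: np.ndarray, response: np.ndarray,
                       bias_correction: bool = True) -> float:
    """Plug-in MI (bits) with Panzeri-Treves bias correction.

    ``stimulus`` and ``response`` are integer label arrays of equal length;
    stimuli are assumed equiprobable by construction (equal trial counts).
    """
    stimulus = np.asarray(stimulus)
    response = np.asarray(response)
    if stimulus.size != response.size or stimulus.size == 0:
        raise ValueError("stimulus and response must be equal-length, non-empty")
    n = stimulus.size
    s_vals, s_idx = np.unique(stimulus, return_inverse=True)
    r_vals, r_idx = np.unique(response, return_inverse=True)
    joint = np.zeros((s_vals.size, r_vals.size))
    np.add.at(joint, (s_idx, r_idx), 1.0)
    p_sr = joint / n
    p_s = p_sr.sum(axis=1, keepdims=True)
    p_r = p_sr.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p_sr * np.log2(p_sr / (p_s * p_r))
    mi = float(np.nansum(term))
    if bias_correction:
        occupied_per_s = (joint > 0).sum(axis=1)
        occupied = (joint.sum(axis=0) > 0).sum()
        bias = (occupied_per_s.sum() - s_vals.size - (occupied - 1)) \
            / (2.0 * n * np.log(2.0))
        mi -= bias
    return mi


@dataclass(frozen=True)
class CodingFractionResult:
    """Coding fraction of one output metric over the response space."""

    metric: str
    h_stimulus: float
    mi: float
    cf: float
    n_configurations: int
    n_trials_per_config: int


def coding_fraction(trials: pd.DataFrame, metric: str,
                    bin_width: float | None = None,
                    bias_correction: bool = True) -> CodingFractionResult:
    """Coding fraction of a per-trial metric.

    ``trials`` must hold one row per trial with a ``config_id`` column and
    the metric column; every configuration must contribute the same number
    of trials.  ``bin_width`` discretizes continuous metrics (1 ms for the
    timing metrics); spike counts are used as-is.  Undefined values
    (no-spike trials) map to a dedicated response symbol.
    """
    counts = trials.groupby("config_id").size()
    if counts.nunique() != 1:
        raise ValueError("all configurations need equal trial counts")
    vals = trials[metric].to_numpy(dtype=float)
    if np.all(np.isnan(vals)):
        raise ValueError(f"metric {metric!r} has no defined values")
    resp = _discretize(vals, bin_width, no_spike_symbol=True)
    stim = pd.factorize(trials["config_id"])[0]
    h_s = stimulus_entropy(counts.size)
    mi = mutual_information(stim, resp, bias_correction)
    mi = float(np.clip(mi, 0.0, h_s))
    return CodingFractionResult(metric, h_s, mi, mi / h_s,
                                counts.size, int(counts.iloc[0]))
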