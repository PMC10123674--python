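"""Model-independent thermodynamics from a heat-capacity trace.

DSC measures the molar excess heat capacity C_p(T) directly, so the
unfolding enthalpy, entropy and free energy follow from the trace alone,
without assuming any unfolding model:

    dH(T) = cumulative sum of C_p * dT        (enthalpy)
    dS(T) = cumulative sum of (C_p / T) * dT  (entropy)
    dG(T) = dH(T) - T * dS(T)                 (Gibbs free energy)

The running sums start at the native-state end of the scan (the first
recorded point, for both heating and cooling scans), so the native
protein sits at dH = dS = dG = 0.  On a cooling scan the temperature
steps are negative and an exothermic cold-denaturation transition
accumulates negative enthalpy.

The default rule is the left-Riemann running sum over the recorded
discrete temperature steps; trapezoidal integration is available as an
option and converges to the same totals as the grid is refined.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks

from .thermogram import Thermogram, ThermogramError, TransitionWindow

__all__ = [
    "ThermoProfile",
    "DecompositionResult",
    "integrate_profiles",
    "total_changes",
    "cp_step_enthalpy",
    "estimate_cp_step",
    "midpoint_from_ratio",
    "detect_transitions",
    "rebase_profiles",
]


@dataclass(frozen=True)
class ThermoProfile:
    """Cumulative unfolding thermodynamics on a thermogram's grid.

    ``dH`` (kcal/mol) and ``dS`` (kcal/mol/K) are zero at the native-state
    reference point; ``dG = dH - T*dS`` holds exactly at every grid point.
    """

    temperature: np.ndarray
    dH: np.ndarray
    dS: np.ndarray
    dG: np.ndarray

    def value_at(self, t_kelvin: float) -> tuple[float, float, float]:
        """(dH, dS, dG) at the grid point nearest to ``t_kelvin``."""
        i = int(np.argmin(np.abs(self.temperature - t_kelvin)))
        return float(self.dH[i]), float(self.dS[i]), float(self.dG[i])


@dataclass(frozen=True)
class DecompositionResult:
    """Totals over a transition window and their enthalpy decomposition.

    The calorimetric enthalpy splits into the conformational (van't Hoff)
    part and the part contributed by the heat-capacity step:
    ``dH_total = dH_conf + dH_cp_step``.
    """

    dH_total: float
    dS_total: float
    dG_total: float
    dH_cp_step: float | None = None
    dH_conf: float | None = None
    cp_step: float | None = None


def integrate_profiles(
    thermogram: Thermogram, rule: str = "riemann"
) -> ThermoProfile:
    """Integrate C_p(T) into cumulative dH, dS and dG profiles.

    Parameters
    ----------
    thermogram : Thermogram
        Valid thermogram; integration starts at its first recorded point
        (the native-state end for scans recorded in scan order).
    rule : {'riemann', 'trapezoid'}
        Discrete sum rule.  'riemann' accumulates ``C_p[i] * dT[i]`` over
        each recorded step (left rule); 'trapezoid' averages the step's
        endpoints.
    """
    t = thermogram.temperature
    cp = thermogram.cp
    dt = np.diff(t)
    if np.any(dt == 0.0):
        raise ThermogramError("zero-length temperature step")

    if rule == "riemann":
        h_inc = cp[:-1] * dt
        s_inc = (cp[:-1] / t[:-1]) * dt
    elif rule == "trapezoid":
        h_inc = 0.5 * (cp[:-1] + cp[1:]) * dt
        s_inc = 0.5 * (cp[:-1] / t[:-1] + cp[1:] / t[1:]) * dt
    else:
        raise ValueError(f"unknown integration rule {rule!r}")

    dH = np.concatenate(([0.0], np.cumsum(h_inc)))
    dS = np.concatenate(([0.0], np.cumsum(s_inc)))
    dG = dH - t * dS
    return ThermoProfile(temperature=t, dH=dH, dS=dS, dG=dG)


def total_changes(
    profile: ThermoProfile, window: TransitionWindow
) -> DecompositionResult:
    """Differences of the cumulative profiles between t_ini and t_end."""
    t = profile.temperature
    lo, hi = min(t.min(), t.max()), max(t.min(), t.max())
    for edge in (window.t_ini, window.t_end):
        if not (lo - 1e-9 <= edge <= hi + 1e-9):
            raise ThermogramError(
                f"window edge {edge} K outside profile grid [{lo}, {hi}] K"
            )
    i_ini = int(np.argmin(np.abs(t - window.t_ini)))
    i_end = int(np.argmin(np.abs(t - window.t_end)))
    dH = float(profile.dH[i_end] - profile.dH[i_ini])
    dS = float(profile.dS[i_end] - profile.dS[i_ini])
    # free energy evaluated from the window's own totals at t_end
    dG = float(profile.dG[i_end] - profile.dG[i_ini])
    return DecompositionResult(dH_total=dH, dS_total=dS, dG_total=dG)


def cp_step_enthalpy(cp_step: float, window: TransitionWindow) -> float:
    """Enthalpy contributed by the heat-capacity step over a transition.

    The step dCp0 ramps up sigmoidally between t_ini and t_end; the area
    under that ramp is well approximated by a triangle with a sigmoidal
    hypotenuse, giving ``dCp0 * (t_end - t_ini) / 3`` (the sigmoidal
    hypotenuse motivates the factor 3 instead of the plain triangle's 2).
    The result is signed by scan direction: negative when t_end < t_ini.
    """
    return cp_step * (window.t_end - window.t_ini) / 3.0


def estimate_cp_step(
    thermogram: Thermogram, window: TransitionWindow, flank_fraction: float = 0.10
) -> float:
    """Estimate dCp0 as post-transition minus pre-transition plateau C_p.

    Each plateau is the mean C_p over the outer ``flank_fraction`` of the
    window's span, just inside t_ini and t_end.
    """
    t = thermogram.temperature
    span = window.span
    flank = max(flank_fraction * span, 2 * float(np.median(np.abs(np.diff(t)))))
    lo_ini, hi_ini = window.t_ini - flank, window.t_ini + flank
    lo_end, hi_end = window.t_end - flank, window.t_end + flank
    pre = thermogram.cp[(t >= min(lo_ini, hi_ini)) & (t <= max(lo_ini, hi_ini))]
    post = thermogram.cp[(t >= min(lo_end, hi_end)) & (t <= max(lo_end, hi_end))]
    if pre.size == 0 or post.size == 0:
        raise ThermogramError("window flanks do not overlap the grid")
    return float(post.mean() - pre.mean())


def midpoint_from_ratio(dH_total: float, dS_total: float) -> float:
    """Midpoint temperature T_m = dH_total / dS_total.

    A first-order transition has dG = 0 at its midpoint, so the ratio of
    the calorimetric totals predicts T_m.  Valid for both heat and cold
    denaturation: the signs of dH and dS cancel.
    """
    if dS_total == 0.0:
        raise ZeroDivisionError(
            "total entropy change is zero; midpoint temperature undefined"
        )
    return dH_total / dS_total


def _noise_threshold(cp: np.ndarray, k: float = 5.0) -> float:
    """k x median absolute deviation of the flattest decile of the trace.

    The flattest decile is selected by the smallest local first
    differences, which isolates baseline stretches even when the trace
    contains large peaks.
    """
    dcp = np.abs(np.diff(cp))
    n_flat = max(dcp.size // 10, 4)
    flat_idx = np.argsort(dcp)[:n_flat]
    flat = cp[flat_idx]
    mad = np.median(np.abs(flat - np.median(flat)))
    return k * max(mad, 1e-12)


def detect_transitions(
    thermogram: Thermogram,
    boundary_fraction: float = 0.02,
    noise_k: float = 5.0,
) -> list[TransitionWindow]:
    """Locate unfolding transitions as peaks of |C_p| above noise.

    Each detected window reports t_m at the |C_p| extremum, and t_ini /
    t_end where |C_p| first/last exceeds ``boundary_fraction`` of the
    baseline-corrected peak height.  Windows are returned in scan order;
    a double heat+cold transition yields two windows.  A flat trace
    returns an empty list.
    """
    t = thermogram.temperature
    cp_abs = np.abs(thermogram.cp)
    threshold = _noise_threshold(thermogram.cp, noise_k)
    peak_floor = max(threshold, 0.05 * cp_abs.max()) if cp_abs.max() > 0 else threshold

    idx, props = find_peaks(cp_abs, height=peak_floor, prominence=peak_floor / 2)
    if idx.size == 0:
        return []

    windows: list[TransitionWindow] = []
    for j, i_peak in enumerate(idx):
        height = cp_abs[i_peak]
        cut = boundary_fraction * height
        # search outward, bounded by neighbouring peaks' valleys
        left_lim = 0 if j == 0 else int(np.argmin(cp_abs[idx[j - 1]: i_peak])) + idx[j - 1]
        right_lim = (
            cp_abs.size - 1
            if j == idx.size - 1
            else int(np.argmin(cp_abs[i_peak: idx[j + 1]])) + i_peak
        )
        i_lo = i_peak
        while i_lo > left_lim and cp_abs[i_lo - 1] > cut:
            i_lo -= 1
        i_hi = i_peak
        while i_hi < right_lim and cp_abs[i_hi + 1] > cut:
            i_hi += 1
        if i_lo == i_peak or i_hi == i_peak:
            continue  # degenerate edge peak
        windows.append(
            TransitionWindow(
                t_ini=float(t[i_lo]),
                t_m=float(t[i_peak]),
                t_end=float(t[i_hi]),
                peak_height=float(thermogram.cp[i_peak]),
                width=float(abs(t[i_hi] - t[i_lo])),
            )
        )
    return windows


def rebase_profiles(
    profile: ThermoProfile, dH_shift: float, dS_shift: float
) -> ThermoProfile:
    """Shift cumulative profiles so the native state sits at zero.

    When a heating scan starts from the cold-denatured state, the raw
    cumulative enthalpy/entropy reach the native plateau at the totals of
    the low-temperature disorder-to-order transition.  Subtracting those
    totals (``dH_shift``, ``dS_shift``) places the native state at zero
    and dG is recomputed as dH - T*dS, which then shows the trapezoidal
    free-energy profile characteristic of a protein with both heat and
    cold denaturation.
    """
    dH = profile.dH - dH_shift
    dS = profile.dS - dS_shift
    dG = dH - profile.temperature * dS
    return replace(profile, dH=dH, dS=dS, dG=dG)
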