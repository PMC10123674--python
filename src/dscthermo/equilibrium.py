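"""Chemical-equilibrium two-state unfolding models.

The standard two-state model treats unfolding as a chemical equilibrium
N <=> U with van't Hoff enthalpy dH0, midpoint T_m and heat-capacity step
dCp0:

    dH_NU(T) = dH0 + dCp0 * (T - T_m)
    dS_NU(T) = dH0 / T_m + dCp0 * ln(T / T_m)
    dG_NU(T) = dH_NU - T * dS_NU
    K_NU(T)  = exp(-dG_NU / (R T)),   theta_U = K / (1 + K)

The standard model's dG_NU is parabolic and positive on the native side
of T_m, at odds with calorimetric profiles; it is nevertheless computed
and reported so it can be compared against the data.  The theta-weighted
variant multiplies dH_NU, dS_NU and dG_NU pointwise by the extent of
unfolding theta_U(T), which restores zero thermodynamics for the deep
native state.  Both variants share the same heat-capacity curve

    C_p(T) = d/dT [dH_NU * theta_U]
           = theta_U * dCp0 + dH_NU^2 * theta_U * (1 - theta_U) / (R T^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .constants import R_KCAL

__all__ = [
    "EquilibriumTwoStateParams",
    "vant_hoff_curves",
    "heat_capacity",
    "theta_weighted_curves",
]


@dataclass(frozen=True)
class EquilibriumTwoStateParams:
    """Parameters of the chemical-equilibrium two-state model.

    dH0 : van't Hoff (conformational) enthalpy, kcal/mol.  Negative for a
        cold-denaturation-only fit.
    t_m : midpoint temperature, K.
    cp_step : heat-capacity step dCp0 between native and unfolded state,
        kcal/mol/K.
    """

    dH0: float
    t_m: float
    cp_step: float = 0.0

    def __post_init__(self) -> None:
        if self.t_m <= 0:
            raise ValueError("t_m must be positive kelvin")
        if self.dH0 == 0:
            raise ValueError("dH0 must be nonzero")


def vant_hoff_curves(params: EquilibriumTwoStateParams, temperature):
    """Evaluate dH_NU, dS_NU, dG_NU, K_NU and theta_U on a kelvin grid.

    theta_U is computed in log space (a logistic in -dG/(RT)) so it stays
    finite when |dG| is large; K_NU itself can overflow to inf in the deep
    unfolded limit, which numpy handles gracefully.
    """
    t = np.asarray(temperature, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperatures must be positive kelvin")
    dH = params.dH0 + params.cp_step * (t - params.t_m)
    dS = params.dH0 / params.t_m + params.cp_step * np.log(t / params.t_m)
    dG = dH - t * dS
    x = -dG / (R_KCAL * t)
    with np.errstate(over="ignore"):
        K = np.exp(x)
    theta = expit(x)
    return dH, dS, dG, K, theta


def heat_capacity(params: EquilibriumTwoStateParams, temperature):
    """Model heat capacity C_p(T) of the two-state equilibrium.

    Analytic derivative of dH_NU(T) * theta_U(T); tends to zero in the
    deep native limit (theta_U -> 0) and to theta_U * dCp0 past the
    transition.
    """
    t = np.asarray(temperature, dtype=float)
    dH, _, _, _, theta = vant_hoff_curves(params, t)
    return theta * params.cp_step + dH**2 * theta * (1.0 - theta) / (R_KCAL * t**2)


def theta_weighted_curves(params: EquilibriumTwoStateParams, temperature):
    """dH, dS, dG of the theta_U-weighted two-state model.

    Each van't Hoff function is multiplied pointwise by the extent of
    unfolding, so all three vanish in the deep native limit and
    dG_theta(T_m) = 0 exactly.
    """
    t = np.asarray(temperature, dtype=float)
    dH, dS, dG, _, theta = vant_hoff_curves(params, t)
    return dH * theta, dS * theta, dG * theta
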