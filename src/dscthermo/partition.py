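"""Partition-function unfolding models.

Two models are driven through a common partition-function-to-
thermodynamics engine:

* a statistical-mechanical two-state model with canonical partition
  function

      Z(T) = 1 + q(T),
      q(T) = exp[-dE(T) * (1/(R T) - 1/(R T_m))],
      dE(T) = dE0 + C_v * (T - T_m),

  where dE0 is the native-to-unfolded inner-energy difference and C_v
  the heat capacity of the inner energy (which produces the heat-capacity
  step between native and unfolded baselines).  Z(T_m) = 2, so the free
  energy at the midpoint is F(T_m) = -R T_m ln 2.  Because dE(T) crosses
  zero at T_cold = T_m - dE0 / C_v, the same parameters predict cold
  denaturation with midpoint separation dT = dE0 / C_v.

* the multistate cooperative Zimm-Bragg model, evaluated through the
  largest transfer-matrix eigenvalue

      s(T)   = exp[-h(T) * (1/(R T) - 1/(R T_m))],
      h(T)   = h0 + c_v * (T - T_m),
      lam(T) = (1 + s)/2 + sqrt(((1 - s)/2)^2 + sigma * s),
      ln Z   = N * ln lam,

  with per-residue unfolding energy h0, per-residue heat capacity c_v,
  cooperativity parameter sigma (smaller sigma -> sharper transition)
  and N residues participating in the transition.  At sigma = 1 the
  eigenvalue collapses to 1 + s, so the N = 1 Zimm-Bragg chain is
  identical to the statistical two-state model.

Thermodynamics follow from ln Z by the canonical relations
E = R T^2 dlnZ/dT, F = -R T ln Z, S = (E - F)/T, C_v = dE/dT.  Since
Z >= 1 everywhere, F <= 0: the free energy of the partition-function
models is never positive, in contrast to the standard chemical
equilibrium model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import R_KCAL

__all__ = [
    "StatTwoStateParams",
    "ZimmBraggParams",
    "PartitionThermo",
    "stat_two_state_lnZ",
    "cold_denaturation_temperature",
    "zimm_bragg_lnZ",
    "thermo_from_lnZ",
    "extent_unfolded",
    "nucleation_free_energy",
]


@dataclass(frozen=True)
class StatTwoStateParams:
    """Statistical-mechanical two-state parameters.

    dE0 : inner-energy difference between unfolded and native state,
        kcal/mol (negative for cold-denaturation-only data).
    t_m : heat-unfolding midpoint, K.
    cv : heat capacity of the inner energy, kcal/mol/K; accounts for the
        heat-capacity step between the native and unfolded baselines and
        sets the cold-denaturation midpoint.
    """

    dE0: float
    t_m: float
    cv: float = 0.0

    def __post_init__(self) -> None:
        if self.t_m <= 0:
            raise ValueError("t_m must be positive kelvin")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")


@dataclass(frozen=True)
class ZimmBraggParams:
    """Zimm-Bragg multistate cooperative model parameters.

    h0 : unfolding energy per residue, kcal/mol.
    cv_res : per-residue heat capacity, kcal/mol/K (values quoted in
        cal/mol/K must be divided by 1000).
    sigma : cooperativity (nucleation) parameter in (0, 1]; typical
        protein values are 1e-3 to 1e-7.
    n_res : number of residues participating in the transition.
    t_m : midpoint temperature, K.
    """

    h0: float
    cv_res: float
    sigma: float
    n_res: int
    t_m: float

    def __post_init__(self) -> None:
        if not (0.0 < self.sigma <= 1.0):
            raise ValueError("sigma must be in (0, 1]")
        if self.n_res < 1:
            raise ValueError("n_res must be >= 1")
        if self.t_m <= 0:
            raise ValueError("t_m must be positive kelvin")


@dataclass(frozen=True)
class PartitionThermo:
    """Thermodynamic curves derived from ln Z on a temperature grid.

    E (kcal/mol), S (kcal/mol/K), F (kcal/mol) and the model heat
    capacity Cv_curve (kcal/mol/K).  F = -R T lnZ <= 0 whenever
    lnZ >= 0, and S = (E - F)/T by construction.
    """

    temperature: np.ndarray
    lnZ: np.ndarray
    E: np.ndarray
    S: np.ndarray
    F: np.ndarray
    Cv_curve: np.ndarray


def _check_grid(temperature) -> np.ndarray:
    t = np.asarray(temperature, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperatures must be positive kelvin")
    return t


def stat_two_state_lnZ(params: StatTwoStateParams, temperature) -> np.ndarray:
    """ln Z of the statistical two-state model; lnZ(T_m) = ln 2."""
    t = _check_grid(temperature)
    dE = params.dE0 + params.cv * (t - params.t_m)
    x = -dE * (1.0 / (R_KCAL * t) - 1.0 / (R_KCAL * params.t_m))
    return np.logaddexp(0.0, x)


def _stat_two_state_log_q(params: StatTwoStateParams, t: np.ndarray) -> np.ndarray:
    dE = params.dE0 + params.cv * (t - params.t_m)
    return -dE * (1.0 / (R_KCAL * t) - 1.0 / (R_KCAL * params.t_m))


def cold_denaturation_temperature(params: StatTwoStateParams) -> float | None:
    """Cold-denaturation midpoint T_cold = T_m - dE0 / C_v.

    T_cold is the second temperature at which the unfolded-state weight
    equals the native weight (the zero of dE(T)).  dE0 stabilises the
    protein and pushes T_cold down; C_v represents energy fluctuations
    and pulls T_cold up.  Returns ``None`` when cv == 0 (no cold
    denaturation at any temperature).
    """
    if params.cv == 0.0:
        return None
    return params.t_m - params.dE0 / params.cv


def zimm_bragg_lnZ(params: ZimmBraggParams, temperature) -> np.ndarray:
    """ln Z of the Zimm-Bragg chain via the largest eigenvalue."""
    t = _check_grid(temperature)
    h = params.h0 + params.cv_res * (t - params.t_m)
    s = np.exp(-h * (1.0 / (R_KCAL * t) - 1.0 / (R_KCAL * params.t_m)))
    lam = 0.5 * (1.0 + s) + np.sqrt((0.5 * (1.0 - s)) ** 2 + params.sigma * s)
    return params.n_res * np.log(lam)


def thermo_from_lnZ(lnZ, temperature) -> PartitionThermo:
    """Canonical thermodynamics from ln Z by numerical differentiation.

    E = R T^2 dlnZ/dT and Cv = dE/dT use central differences on the input
    grid (one-sided at the ends), so any partition function drops in
    unchanged; a spacing of <= 0.5 K keeps the derivatives stable.
    """
    t = _check_grid(temperature)
    lnz = np.asarray(lnZ, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 grid points for stable derivatives")
    if lnz.shape != t.shape:
        raise ValueError("lnZ and temperature must share a grid")
    E = R_KCAL * t**2 * np.gradient(lnz, t)
    F = -R_KCAL * t * lnz
    S = (E - F) / t
    Cv = np.gradient(E, t)
    return PartitionThermo(temperature=t, lnZ=lnz, E=E, S=S, F=F, Cv_curve=Cv)


def extent_unfolded(model: str, params, temperature) -> np.ndarray:
    """Fraction unfolded theta_U(T) in [0, 1]; 1/2 at the midpoint.

    For the two-state model theta_U = q / (1 + q); for the Zimm-Bragg
    chain theta_U = (s / N) dlnZ/ds, the mean fraction of unfolded
    residues, evaluated analytically from the eigenvalue.
    """
    t = _check_grid(temperature)
    if model == "stat_two_state":
        from scipy.special import expit

        return expit(_stat_two_state_log_q(params, t))
    if model == "zimm_bragg":
        h = params.h0 + params.cv_res * (t - params.t_m)
        s = np.exp(-h * (1.0 / (R_KCAL * t) - 1.0 / (R_KCAL * params.t_m)))
        root = np.sqrt((0.5 * (1.0 - s)) ** 2 + params.sigma * s)
        lam = 0.5 * (1.0 + s) + root
        dlam_ds = 0.5 + (0.5 * (s - 1.0) + params.sigma) / (2.0 * root)
        return s * dlam_ds / lam
    raise ValueError(f"unknown model {model!r}")


def nucleation_free_energy(sigma: float, temperature: float) -> float:
    """Free energy to nucleate a new folded stretch: dG_sigma = -R T ln sigma.

    A quantitative cooperativity measure: the smaller sigma, the larger
    the nucleation barrier and the more stable (more cooperative) the
    protein.
    """
    if not (0.0 < sigma <= 1.0):
        raise ValueError("sigma must be in (0, 1]")
    if temperature <= 0:
        raise ValueError("temperature must be positive kelvin")
    return -R_KCAL * temperature * float(np.log(sigma))
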