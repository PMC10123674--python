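"""Uniform access to the four unfolding models.

Maps model names to parameter records, heat-capacity curves and
thermodynamic profile curves so the synthetic generator, the fitter and
the CLI can treat all models through one surface.

Model names: ``standard``, ``theta_weighted`` (chemical-equilibrium
two-state; both share the same C_p curve but differ in their dH/dS/dG
profiles), ``stat_two_state`` and ``zimm_bragg`` (partition-function
models, profiles and C_p derived from ln Z).
"""

from __future__ import annotations

import numpy as np

from . import equilibrium, partition

__all__ = [
    "MODEL_NAMES",
    "PARAM_TYPES",
    "make_params",
    "params_to_dict",
    "model_heat_capacity",
    "model_profiles",
]

MODEL_NAMES = ("standard", "theta_weighted", "stat_two_state", "zimm_bragg")

PARAM_TYPES = {
    "standard": equilibrium.EquilibriumTwoStateParams,
    "theta_weighted": equilibrium.EquilibriumTwoStateParams,
    "stat_two_state": partition.StatTwoStateParams,
    "zimm_bragg": partition.ZimmBraggParams,
}

# flat config keys (unit suffixes explicit; cv_res accepts cal or kcal)
_CONFIG_KEYS = {
    "standard": {"dH0_kcal_mol": "dH0", "Tm_K": "t_m", "dCp0_kcal_molK": "cp_step"},
    "theta_weighted": {
        "dH0_kcal_mol": "dH0",
        "Tm_K": "t_m",
        "dCp0_kcal_molK": "cp_step",
    },
    "stat_two_state": {"dE0_kcal_mol": "dE0", "Tm_K": "t_m", "Cv_kcal_molK": "cv"},
    "zimm_bragg": {
        "h0_kcal_mol": "h0",
        "cv_res_cal_molK": "cv_res",  # converted cal -> kcal
        "cv_res_kcal_molK": "cv_res",
        "sigma": "sigma",
        "N": "n_res",
        "Tm_K": "t_m",
    },
}


def _check_model(model_name: str) -> str:
    if model_name not in MODEL_NAMES:
        raise ValueError(
            f"unknown model {model_name!r}; expected one of {MODEL_NAMES}"
        )
    return model_name


def make_params(model_name: str, config: dict):
    """Build a typed parameter record from flat config keys.

    Accepts either the documented config keys (``dH0_kcal_mol`` etc.) or
    the field names of the parameter record itself.  The Zimm-Bragg
    per-residue heat capacity given as ``cv_res_cal_molK`` is converted
    from cal to kcal.
    """
    _check_model(model_name)
    cls = PARAM_TYPES[model_name]
    keymap = _CONFIG_KEYS[model_name]
    kwargs: dict = {}
    for key, value in config.items():
        if key in keymap:
            field = keymap[key]
            if key == "cv_res_cal_molK":
                value = float(value) / 1000.0
            kwargs[field] = value
        elif key in cls.__dataclass_fields__:
            kwargs[key] = value
    if "n_res" in kwargs:
        kwargs["n_res"] = int(kwargs["n_res"])
    return cls(**kwargs)


def params_to_dict(params) -> dict:
    return {k: getattr(params, k) for k in params.__dataclass_fields__}


def model_heat_capacity(model_name: str, params, temperature) -> np.ndarray:
    """Model molar excess heat capacity C_p(T) on a kelvin grid.

    Equilibrium models use the analytic derivative of theta_U * dH_NU;
    partition models differentiate ln Z numerically on the given grid
    (keep the spacing <= 0.5 K).
    """
    _check_model(model_name)
    t = np.asarray(temperature, dtype=float)
    if model_name in ("standard", "theta_weighted"):
        return equilibrium.heat_capacity(params, t)
    if model_name == "stat_two_state":
        lnz = partition.stat_two_state_lnZ(params, t)
    else:
        lnz = partition.zimm_bragg_lnZ(params, t)
    return partition.thermo_from_lnZ(lnz, t).Cv_curve


def model_profiles(model_name: str, params, temperature):
    """Model (dH, dS, dG) profiles on a kelvin grid.

    ``standard`` returns the unweighted van't Hoff functions (linear
    dH/dS, parabolic dG); ``theta_weighted`` multiplies them by theta_U;
    the partition models return (E, S, F) from ln Z, which approximate
    (dH, dS, dG) because unfolding volume changes are small.
    """
    _check_model(model_name)
    t = np.asarray(temperature, dtype=float)
    if model_name == "standard":
        dH, dS, dG, _, _ = equilibrium.vant_hoff_curves(params, t)
        return dH, dS, dG
    if model_name == "theta_weighted":
        return equilibrium.theta_weighted_curves(params, t)
    if model_name == "stat_two_state":
        lnz = partition.stat_two_state_lnZ(params, t)
    else:
        lnz = partition.zimm_bragg_lnZ(params, t)
    thermo = partition.thermo_from_lnZ(lnz, t)
    return thermo.E, thermo.S, thermo.F
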