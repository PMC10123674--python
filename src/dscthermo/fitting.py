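"""Nonlinear least-squares fitting of unfolding models to thermograms.

The objective is the residual in heat-capacity space -- C_p(T) is what
DSC measures -- minimised with trust-region-reflective least squares
(via lmfit) from several seeded multistart initialisations.  Residuals
of the integrated dH/dS/dG profiles are computed afterwards as
diagnostics for model comparison, not as part of the objective.

Two heat-induced transitions in one scan can be fitted simultaneously as
the sum of two independent transitions (no shared parameters except an
optional common constant baseline, fixed at 0 by default since input
thermograms are baseline-corrected).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

from . import modelfree
from .models import MODEL_NAMES, PARAM_TYPES, model_heat_capacity, model_profiles
from .partition import ZimmBraggParams
from .thermogram import Thermogram, ThermogramError, TransitionWindow

__all__ = ["FitResult", "fit_model", "compare_models", "stability_report"]

DEFAULT_SEED = 0
DEFAULT_N_STARTS = 8


class FitInitializationError(RuntimeError):
    """No transition detected and no initial parameters supplied."""


@dataclass(frozen=True)
class FitResult:
    """Outcome of one model fit.

    ``params`` holds the fitted parameter record; for a simultaneous
    two-transition fit ``params2`` holds the second transition's record.
    ``rmsd_cp`` is the root-mean-square C_p residual (kcal/mol/K) and
    ``rmsd_profiles`` the per-profile residual norms against the
    integrated dH/dS/dG of the data.
    """

    model_name: str
    params: object
    rmsd_cp: float
    rmsd_profiles: dict = field(default_factory=dict)
    converged: bool = True
    n_iter: int = 0
    seed: int = DEFAULT_SEED
    params2: object | None = None
    baseline: float = 0.0

    @property
    def param_list(self) -> list:
        return [self.params] if self.params2 is None else [self.params, self.params2]


# per-model free parameter layout: (field, min, max) -- None bounds are set
# from the data span at fit time.  sigma is log10-parameterised.
_FREE_FIELDS = {
    "standard": [("dH0", -2000.0, 2000.0), ("t_m", None, None), ("cp_step", 0.0, 20.0)],
    "theta_weighted": [
        ("dH0", -2000.0, 2000.0),
        ("t_m", None, None),
        ("cp_step", 0.0, 20.0),
    ],
    "stat_two_state": [
        ("dE0", -2000.0, 2000.0),
        ("t_m", None, None),
        ("cv", 0.0, 20.0),
    ],
    "zimm_bragg": [
        ("h0", -50.0, 50.0),
        ("t_m", None, None),
        ("cv_res", 0.0, 0.5),
        ("log10_sigma", -9.0, 0.0),
    ],
}


def _params_to_lmfit(model_name, records, t_span, fit_baseline, baseline0=0.0):
    lo, hi = min(t_span), max(t_span)
    lp = lmfit.Parameters()
    for k, rec in enumerate(records):
        prefix = f"p{k}_"
        for fld, bmin, bmax in _FREE_FIELDS[model_name]:
            if fld == "log10_sigma":
                value = float(np.log10(rec.sigma))
            else:
                value = float(getattr(rec, fld))
            if fld == "t_m":
                bmin, bmax = lo - 20.0, hi + 20.0
                value = min(max(value, bmin), bmax)
            lp.add(prefix + fld, value=value, min=bmin, max=bmax)
        if model_name == "zimm_bragg":
            lp.add(prefix + "n_res", value=int(rec.n_res), vary=False)
    lp.add("baseline", value=baseline0, vary=fit_baseline)
    return lp


def _record_from_lmfit(model_name, lp, k):
    prefix = f"p{k}_"
    cls = PARAM_TYPES[model_name]
    kwargs = {}
    for fld, _, _ in _FREE_FIELDS[model_name]:
        if fld == "log10_sigma":
            kwargs["sigma"] = 10.0 ** lp[prefix + "log10_sigma"].value
        else:
            kwargs[fld] = lp[prefix + fld].value
    if model_name == "zimm_bragg":
        kwargs["n_res"] = int(lp[prefix + "n_res"].value)
    if model_name in ("standard", "theta_weighted") and kwargs["dH0"] == 0.0:
        kwargs["dH0"] = 1e-6  # keep the record constructible at the boundary
    return cls(**kwargs)


def _model_cp_sum(model_name, lp, n_transitions, t):
    cp = np.full_like(t, lp["baseline"].value)
    for k in range(n_transitions):
        cp = cp + model_heat_capacity(model_name, _record_from_lmfit(model_name, lp, k), t)
    return cp


def _auto_init(model_name: str, thermogram: Thermogram, windows):
    """Initial parameter records from detected transitions.

    T_m at the |C_p| peak, enthalpy from the peak area net of the
    heat-capacity-step triangle, and the step itself from the plateau
    difference across the window.
    """
    if windows is None:
        windows = modelfree.detect_transitions(thermogram)
    if not windows:
        raise FitInitializationError(
            "no transition detected and no initial parameters supplied"
        )
    profile = modelfree.integrate_profiles(thermogram)
    records = []
    for w in windows:
        try:
            cp_step = max(modelfree.estimate_cp_step(thermogram, w), 0.0)
        except ThermogramError:
            cp_step = 0.0
        totals = modelfree.total_changes(profile, w)
        dh0 = totals.dH_total - modelfree.cp_step_enthalpy(cp_step, w)
        if abs(dh0) < 1.0:
            dh0 = np.sign(dh0 or 1.0) * 10.0
        if model_name in ("standard", "theta_weighted"):
            records.append(PARAM_TYPES[model_name](dH0=dh0, t_m=w.t_m, cp_step=cp_step))
        elif model_name == "stat_two_state":
            records.append(PARAM_TYPES[model_name](dE0=dh0, t_m=w.t_m, cv=max(cp_step, 1e-3)))
        else:
            n_res = 100
            records.append(
                ZimmBraggParams(
                    h0=dh0 / n_res,
                    cv_res=max(cp_step / n_res, 1e-5),
                    sigma=1e-4,
                    n_res=n_res,
                    t_m=w.t_m,
                )
            )
    return records


def _perturb(lp: lmfit.Parameters, rng: np.random.Generator) -> lmfit.Parameters:
    out = lp.copy()
    for name, par in out.items():
        if not par.vary:
            continue
        if name.endswith("t_m"):
            par.value = par.value + rng.normal(0.0, 2.0)
        elif name.endswith("log10_sigma"):
            par.value = par.value + rng.normal(0.0, 1.0)
        else:
            par.value = par.value * (1.0 + rng.normal(0.0, 0.25))
        par.value = min(max(par.value, par.min + 1e-12), par.max - 1e-12)
    return out


def _profile_rmsds(model_name, records, baseline, thermogram) -> dict:
    data = modelfree.integrate_profiles(thermogram)
    t = thermogram.temperature
    dH = np.zeros_like(t)
    dS = np.zeros_like(t)
    dG = np.zeros_like(t)
    for rec in records:
        h, s, g = model_profiles(model_name, rec, t)
        dH, dS, dG = dH + h, dS + s, dG + g
    if baseline:
        dH = dH + baseline * (t - t[0])
        dS = dS + baseline * np.log(t / t[0])
    # reference both routes to the scan-start (native) point
    dH, dS = dH - dH[0], dS - dS[0]
    dG = dH - t * dS
    return {
        "dH": float(np.sqrt(np.mean((dH - data.dH) ** 2))),
        "dS": float(np.sqrt(np.mean((dS - data.dS) ** 2))),
        "dG": float(np.sqrt(np.mean((dG - data.dG) ** 2))),
    }


def fit_model(
    thermogram: Thermogram,
    model_name: str,
    init=None,
    windows: list[TransitionWindow] | None = None,
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = DEFAULT_SEED,
    fit_baseline: bool = False,
) -> FitResult:
    """Fit one model's C_p(T) to a thermogram.

    Parameters
    ----------
    init : parameter record, list of records, or None
        Starting values; a list of two records (or two detected windows)
        requests a simultaneous two-transition fit.  When None, starting
        values are derived from transition detection.
    n_starts : int
        Number of multistart initialisations (the first is the plain
        initial guess, the rest are seeded random perturbations of it).
    seed : int
        Seed of the multistart perturbations, recorded in the result.
    """
    if model_name not in MODEL_NAMES:
        raise ValueError(f"unknown model {model_name!r}")
    if init is None:
        records = _auto_init(model_name, thermogram, windows)
    else:
        records = list(init) if isinstance(init, (list, tuple)) else [init]
    if len(records) > 2:
        raise ValueError("at most two simultaneous transitions are supported")
    n_trans = len(records)

    t = thermogram.temperature
    cp = thermogram.cp
    lp0 = _params_to_lmfit(model_name, records, (t.min(), t.max()), fit_baseline)

    def residual(lp):
        return _model_cp_sum(model_name, lp, n_trans, t) - cp

    rng = np.random.default_rng(seed)
    best = None
    n_iter_total = 0
    any_converged = False
    for start in range(max(n_starts, 1)):
        lp_start = lp0 if start == 0 else _perturb(lp0, rng)
        try:
            res = lmfit.minimize(residual, lp_start, method="least_squares")
        except Exception:
            continue
        n_iter_total += int(res.nfev)
        if res.success:
            any_converged = True
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("optimizer failed in every multistart attempt")

    fitted = [_record_from_lmfit(model_name, best.params, k) for k in range(n_trans)]
    # report transitions in scan order of their midpoints
    if n_trans == 2:
        ascending = t[1] > t[0]
        fitted.sort(key=lambda r: r.t_m, reverse=not ascending)
    rmsd_cp = float(np.sqrt(np.mean(best.residual**2)))
    baseline = float(best.params["baseline"].value)
    return FitResult(
        model_name=model_name,
        params=fitted[0],
        params2=fitted[1] if n_trans == 2 else None,
        rmsd_cp=rmsd_cp,
        rmsd_profiles=_profile_rmsds(model_name, fitted, baseline, thermogram),
        converged=any_converged,
        n_iter=n_iter_total,
        seed=seed,
        baseline=baseline,
    )


def compare_models(thermogram: Thermogram, fits: list[FitResult]) -> pd.DataFrame:
    """Rank fits of the same thermogram by their thermodynamic-profile fit.

    A model that merely reproduces the C_p peak can still fail the
    integrated dH/dS/dG profiles (the standard chemical-equilibrium model
    does, with its parabolic positive dG), so ranking uses the summed
    profile residuals.  ``dG_positive_flag`` marks fits whose model dG
    goes distinctly positive where the model-free integrated dG does not.
    Ties keep the input order (stable sort).
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    data = modelfree.integrate_profiles(thermogram)
    t = thermogram.temperature
    # a model is flagged when its dG goes more positive than the
    # integrated dG ever does, by more than 0.05 kcal/mol
    positive_ceiling = max(float(np.max(data.dG)), 0.0) + 0.05

    rows = []
    for fit in fits:
        dG = np.zeros_like(t)
        dH = np.zeros_like(t)
        dS = np.zeros_like(t)
        for rec in fit.param_list:
            h, s, g = model_profiles(fit.model_name, rec, t)
            dH, dS = dH + h, dS + s
        if fit.model_name == "standard":
            # the standard model's own dG, not re-zeroed: its positive
            # native-side parabola is the reported failure mode
            for rec in fit.param_list:
                _, _, g = model_profiles(fit.model_name, rec, t)
                dG = dG + g
        else:
            dH0, dS0 = dH - dH[0], dS - dS[0]
            dG = dH0 - t * dS0
        flag = bool(np.max(dG) > positive_ceiling)
        profile_score = sum(fit.rmsd_profiles.values())
        rows.append(
            {
                "model": fit.model_name,
                "rmsd_cp": fit.rmsd_cp,
                "rmsd_dH": fit.rmsd_profiles["dH"],
                "rmsd_dS": fit.rmsd_profiles["dS"],
                "rmsd_dG": fit.rmsd_profiles["dG"],
                "profile_score": profile_score,
                "dG_positive_flag": flag,
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values("profile_score", kind="stable").reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    # preserve exact ties as equal ranks
    scores = table["profile_score"].to_numpy()
    for i in range(1, len(scores)):
        if scores[i] == scores[i - 1]:
            table.loc[i, "rank"] = table.loc[i - 1, "rank"]
    return table


def stability_report(
    thermogram: Thermogram,
    model_name: str = "stat_two_state",
    seed: int = DEFAULT_SEED,
    init=None,
) -> dict:
    """Integrate, fit and summarise protein-stability metrics.

    Returns a dict with the model-free totals and midpoint prediction,
    detected transition windows (position, height, width), the fitted
    model parameters, and -- where the model provides them -- the
    cold-denaturation temperature T_cold, the heat/cold midpoint
    separation dT, the nucleation free energy dG_sigma and the enthalpy
    decomposition into conformational and heat-capacity-step parts.
    """
    from .partition import cold_denaturation_temperature, nucleation_free_energy

    profile = modelfree.integrate_profiles(thermogram)
    windows = modelfree.detect_transitions(thermogram)
    report: dict = {
        "label": thermogram.label,
        "scan_direction": thermogram.scan_direction,
        "transitions": [
            {
                "t_ini_K": w.t_ini,
                "t_m_K": w.t_m,
                "t_end_K": w.t_end,
                "peak_height_kcal_molK": w.peak_height,
                "width_K": w.width,
            }
            for w in windows
        ],
    }
    if windows:
        main = max(windows, key=lambda w: abs(w.peak_height or 0.0))
        totals = modelfree.total_changes(profile, main)
        cp_step = modelfree.estimate_cp_step(thermogram, main)
        dh_step = modelfree.cp_step_enthalpy(cp_step, main)
        report["model_free"] = {
            "dH_total_kcal_mol": totals.dH_total,
            "dS_total_kcal_molK": totals.dS_total,
            "dG_total_kcal_mol": totals.dG_total,
            "cp_step_kcal_molK": cp_step,
            "dH_cp_step_kcal_mol": dh_step,
            "dH_conformational_kcal_mol": totals.dH_total - dh_step,
            "Tm_peak_K": main.t_m,
            "Tm_ratio_K": modelfree.midpoint_from_ratio(
                totals.dH_total, totals.dS_total
            ),
            "peak_width_K": main.width,
        }
    fit = fit_model(thermogram, model_name, init=init, windows=windows or None, seed=seed)
    from .models import params_to_dict

    report["fit"] = {
        "model": model_name,
        "params": [params_to_dict(p) for p in fit.param_list],
        "rmsd_cp_kcal_molK": fit.rmsd_cp,
        "rmsd_profiles": fit.rmsd_profiles,
        "converged": fit.converged,
        "seed": fit.seed,
    }
    p = fit.params
    if model_name == "stat_two_state":
        t_cold = cold_denaturation_temperature(p)
        report["stability"] = {
            "Tm_K": p.t_m,
            "T_cold_K": t_cold,
            "dT_K": None if t_cold is None else p.t_m - t_cold,
        }
    elif model_name == "zimm_bragg":
        report["stability"] = {
            "Tm_K": p.t_m,
            "dT_K": p.h0 / p.cv_res if p.cv_res > 0 else None,
            "dG_sigma_kcal_mol": nucleation_free_energy(p.sigma, p.t_m),
            "sigma": p.sigma,
        }
    else:
        report["stability"] = {"Tm_K": p.t_m}
    return report
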