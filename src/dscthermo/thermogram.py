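"""Thermogram containers and delimited-text I/O.

A DSC thermogram is a molar excess heat capacity trace C_p(T) recorded on
a strictly monotone temperature grid.  Heating scans are recorded with
increasing temperature, cooling scans with decreasing temperature; the
recorded order is preserved because downstream integration always starts
from the native-state end of the scan.

Temperatures are kept in kelvin internally.  Degrees Celsius appear only
at the I/O and reporting boundaries.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import CELSIUS_OFFSET

__all__ = [
    "Thermogram",
    "TransitionWindow",
    "ThermogramError",
    "read_thermogram",
    "write_thermogram",
    "crop",
    "read_params_config",
    "write_params_config",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
]


class ThermogramError(ValueError):
    """Raised for malformed thermogram files or invalid grids."""


def celsius_to_kelvin(t_celsius):
    return np.asarray(t_celsius, dtype=float) + CELSIUS_OFFSET


def kelvin_to_celsius(t_kelvin):
    return np.asarray(t_kelvin, dtype=float) - CELSIUS_OFFSET


@dataclass(frozen=True)
class Thermogram:
    """Molar excess heat capacity versus temperature.

    Parameters
    ----------
    temperature : ndarray
        Strictly monotone temperature grid in kelvin, recorded scan order.
    cp : ndarray
        Molar excess heat capacity in kcal mol^-1 K^-1, one value per
        grid point.  Zero for the native baseline by convention (input
        data are assumed baseline-corrected).
    label : str
        Free-text sample description.
    """

    temperature: np.ndarray
    cp: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        c = np.asarray(self.cp, dtype=float)
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "cp", c)
        if t.ndim != 1 or c.ndim != 1:
            raise ThermogramError("temperature and cp must be 1-D arrays")
        if t.size != c.size:
            raise ThermogramError(
                f"temperature ({t.size}) and cp ({c.size}) lengths differ"
            )
        if t.size < 3:
            raise ThermogramError("a thermogram needs at least 3 points")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(c))):
            raise ThermogramError("non-finite values in thermogram")
        if np.any(t <= 0.0):
            raise ThermogramError("temperatures must be positive kelvin")
        steps = np.diff(t)
        if not (np.all(steps > 0) or np.all(steps < 0)):
            raise ThermogramError("temperature grid must be strictly monotone")

    @property
    def scan_direction(self) -> str:
        """'heating' for an increasing grid, 'cooling' for decreasing."""
        return "heating" if self.temperature[1] > self.temperature[0] else "cooling"

    @property
    def native_index(self) -> int:
        """Index of the native-state end of the scan.

        Both heating scans and cooling scans start at the native protein,
        so the native reference is always the first recorded point.
        """
        return 0

    def __len__(self) -> int:
        return int(self.temperature.size)


@dataclass(frozen=True)
class TransitionWindow:
    """Start, midpoint and end temperature of one unfolding transition.

    For a heating transition ``t_ini < t_m < t_end``; a cooling-scan
    window is stated in scan order, so ``t_ini > t_m > t_end``.
    Optional peak metadata is filled in by transition detection.
    """

    t_ini: float
    t_m: float
    t_end: float
    peak_height: float | None = field(default=None, compare=False)
    width: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        lo, hi = min(self.t_ini, self.t_end), max(self.t_ini, self.t_end)
        if not (lo < self.t_m < hi):
            raise ThermogramError(
                f"t_m={self.t_m} must lie strictly between "
                f"t_ini={self.t_ini} and t_end={self.t_end}"
            )

    @property
    def span(self) -> float:
        """Absolute width |t_end - t_ini| in kelvin."""
        return abs(self.t_end - self.t_ini)


_DELIMITERS = [",", "\t", ";"]


def _sniff_delimiter(sample: str) -> str:
    counts = {d: sample.count(d) for d in _DELIMITERS}
    best = max(counts, key=counts.get)
    if counts[best] == 0:
        # whitespace-separated fallback
        return r"\s+"
    return best


def read_thermogram(path, units: str = "kelvin", label: str = "") -> Thermogram:
    """Read a two-column delimited thermogram file.

    Parameters
    ----------
    path : str or path-like
        Delimited text with two numeric columns (temperature, heat
        capacity) and an optional single header line.  Comma, tab,
        semicolon or whitespace delimited.
    units : {'kelvin', 'celsius'}
        Unit of the temperature column; Celsius values are converted to
        kelvin on read.
    """
    if units not in ("kelvin", "celsius"):
        raise ValueError(f"units must be 'kelvin' or 'celsius', got {units!r}")
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ThermogramError(f"{path}: empty file")
    delim = _sniff_delimiter(lines[0] if len(lines) == 1 else lines[1])

    start = 0
    first_fields = re.split(delim, lines[0].strip())
    try:
        [float(x) for x in first_fields if x != ""]
    except ValueError:
        start = 1  # header line

    temps, cps = [], []
    for lineno, ln in enumerate(lines[start:], start=start + 1):
        fields = [f for f in re.split(delim, ln.strip()) if f != ""]
        if len(fields) < 2:
            raise ThermogramError(f"{path}: line {lineno}: expected 2 columns")
        try:
            temps.append(float(fields[0]))
            cps.append(float(fields[1]))
        except ValueError as exc:
            raise ThermogramError(
                f"{path}: line {lineno}: non-numeric value ({ln.strip()!r})"
            ) from exc

    t = np.asarray(temps, dtype=float)
    if units == "celsius":
        t = celsius_to_kelvin(t)
    return Thermogram(temperature=t, cp=np.asarray(cps, dtype=float), label=label)


def write_thermogram(thermogram: Thermogram, path) -> None:
    """Write a thermogram as CSV with full float precision.

    Columns are ``temperature_K,cp_kcal_per_mol_K``; rows keep the
    recorded scan order (descending temperature for cooling scans).
    """
    df = pd.DataFrame(
        {
            "temperature_K": thermogram.temperature,
            "cp_kcal_per_mol_K": thermogram.cp,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def crop(thermogram: Thermogram, window: TransitionWindow) -> Thermogram:
    """Return the sub-thermogram with t_ini <= T <= t_end (scan order kept)."""
    lo = min(window.t_ini, window.t_end)
    hi = max(window.t_ini, window.t_end)
    mask = (thermogram.temperature >= lo) & (thermogram.temperature <= hi)
    if mask.sum() < 3:
        raise ThermogramError(
            f"window [{lo}, {hi}] K overlaps fewer than 3 grid points"
        )
    return replace(
        thermogram, temperature=thermogram.temperature[mask], cp=thermogram.cp[mask]
    )


# ---------------------------------------------------------------------------
# flat key=value model-parameter config files
# ---------------------------------------------------------------------------

def read_params_config(path) -> dict:
    """Read a flat ``key = value`` config file into a dict.

    Values are parsed as float where possible, int where exact, else kept
    as strings.  Lines starting with '#' are comments.
    """
    out: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            if "=" not in ln:
                raise ThermogramError(f"{path}: line {lineno}: expected key=value")
            key, _, val = ln.partition("=")
            key, val = key.strip(), val.strip()
            try:
                f = float(val)
                out[key] = int(f) if f.is_integer() and "." not in val and "e" not in val.lower() else f
            except ValueError:
                out[key] = val
    return out


def write_params_config(params: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in params.items():
            fh.write(f"{key} = {val!r}\n" if isinstance(val, str) else f"{key} = {val}\n")
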