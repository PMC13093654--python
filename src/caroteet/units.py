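"""Physical constants, energy-unit conversions, and the shared numeric grids.

Internally the package works in wavenumbers (cm^-1) for vibrational
energies, electronvolts for electronic energies, and femtoseconds for
time.  Everything funnels through a single set of CODATA-style constants
so that rate/efficiency arithmetic is bit-stable across modules.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DomainError

# --- constants (eV-based) ------------------------------------------------
HC_EV_NM = 1239.84193          # h*c, eV nm
HBAR_EV_FS = 0.6582119569      # hbar, eV fs
HBAR_EV_S = 6.582119569e-16    # hbar, eV s
KB_EV_K = 8.617333262e-5       # Boltzmann constant, eV / K

#: 1 cm^-1 expressed in eV (= hc with wavelength 1 cm)
CM1_TO_EV = HC_EV_NM * 1e-7
EV_TO_CM1 = 1.0 / CM1_TO_EV

#: permitted energy units
UNITS = ("cm-1", "eV", "nm", "rad/fs")


@dataclass(frozen=True)
class EnergyQuantity:
    """A scalar energy (or wavelength / angular frequency) with its unit."""

    value: float
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ConfigurationError(f"unknown energy unit {self.unit!r}; expected one of {UNITS}")
        if self.unit == "nm" and self.value <= 0:
            raise DomainError("wavelength must be positive")


def _to_ev(value: float, unit: str) -> float:
    if unit == "eV":
        return value
    if unit == "cm-1":
        return value * CM1_TO_EV
    if unit == "nm":
        if value <= 0:
            raise DomainError("wavelength must be positive")
        return HC_EV_NM / value
    if unit == "rad/fs":
        return value * HBAR_EV_FS
    raise ConfigurationError(f"unknown energy unit {unit!r}")


def _from_ev(ev: float, unit: str) -> float:
    if unit == "eV":
        return ev
    if unit == "cm-1":
        return ev * EV_TO_CM1
    if unit == "nm":
        if ev <= 0:
            raise DomainError("cannot express a non-positive energy as a wavelength")
        return HC_EV_NM / ev
    if unit == "rad/fs":
        return ev / HBAR_EV_FS
    raise ConfigurationError(f"unknown energy unit {unit!r}")


def convert_energy(q: EnergyQuantity, target_unit: str) -> EnergyQuantity:
    """Convert an :class:`EnergyQuantity` to ``target_unit``.

    nm <-> energy conversions use the single hc constant; linear energy
    units (cm^-1, eV, rad/fs) convert proportionally, so 0 maps to 0.
    """
    return EnergyQuantity(_from_ev(_to_ev(q.value, q.unit), target_unit), target_unit)


def ev(value: float, unit: str) -> float:
    """Shorthand: numeric value of ``value [unit]`` in eV."""
    return _to_ev(value, unit)


# --- grids ---------------------------------------------------------------
@dataclass(frozen=True)
class Grid:
    """A uniform 1-D grid in time (fs) or energy (eV)."""

    points: np.ndarray
    domain: str  # "time_fs" | "energy_eV"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if self.domain not in ("time_fs", "energy_eV"):
            raise ConfigurationError(f"unknown grid domain {self.domain!r}")
        if pts.ndim != 1 or pts.size < 2:
            raise DomainError("grid needs at least two points")
        steps = np.diff(pts)
        if np.any(steps <= 0):
            raise DomainError("grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=0.0):
            raise DomainError("grid must be uniform")
        if self.domain == "time_fs" and abs(pts[0]) > 1e-12:
            raise DomainError("time grids must start at 0")

    @property
    def spacing(self) -> float:
        return float(self.points[1] - self.points[0])


def time_grid(t_max_fs: float, dt_fs: float) -> Grid:
    """Uniform time grid 0..t_max (inclusive endpoint within one step)."""
    n = int(round(t_max_fs / dt_fs)) + 1
    return Grid(np.arange(n) * dt_fs, "time_fs")


def energy_grid(e_min_ev: float, e_max_ev: float, de_ev: float) -> Grid:
    """Uniform energy grid in eV."""
    n = int(round((e_max_ev - e_min_ev) / de_ev)) + 1
    return Grid(e_min_ev + np.arange(n) * de_ev, "energy_eV")
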