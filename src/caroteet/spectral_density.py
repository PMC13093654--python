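"""Pigment spectral densities in the displaced-oscillator picture.

A spectral density J(w) (here tabulated on a wavenumber grid, with J
itself carrying units of cm^-1) encodes how strongly an electronic
transition couples to nuclear motion.  Its first inverse moment gives
the reorganization energy

    lambda = (1/pi) * Integral_0^inf J(w)/w dw

which is the quantity the EET analysis cares about: it sets the Stokes
shift (2*lambda) of the donor emission and thereby the donor-acceptor
spectral overlap.  Discrete vibronic modes are broadened with Lorentzian
kernels that are renormalized numerically so the lambda integral is
kernel-independent.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError
from .units import Grid

#: default wavenumber grid: 1..20000 cm^-1 at 1 cm^-1 (lambda truncation < 0.5%)
DEFAULT_OMEGA_CM1 = (1.0, 20000.0, 1.0)


def default_energy_grid_cm1() -> np.ndarray:
    lo, hi, step = DEFAULT_OMEGA_CM1
    return lo + np.arange(int(round((hi - lo) / step)) + 1) * step


@dataclass(frozen=True)
class VibronicMode:
    """One displaced harmonic mode: frequency, reorganization share, half-width."""

    omega_cm1: float
    lambda_cm1: float
    gamma_cm1: float

    def __post_init__(self) -> None:
        if self.omega_cm1 <= 0:
            raise DomainError("mode frequency must be positive")
        if self.lambda_cm1 < 0:
            raise DomainError("mode reorganization energy must be >= 0")
        if self.gamma_cm1 <= 0:
            raise DomainError("mode broadening must be positive")


@dataclass(frozen=True)
class SpectralDensity:
    """Tabulated J(w) >= 0 on a positive wavenumber grid, with cached lambda."""

    omega_cm1: np.ndarray
    j_cm1: np.ndarray
    label: str = ""
    lambda_cm1: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        w = np.asarray(self.omega_cm1, dtype=float)
        j = np.asarray(self.j_cm1, dtype=float)
        object.__setattr__(self, "omega_cm1", w)
        object.__setattr__(self, "j_cm1", j)
        if w.shape != j.shape or w.ndim != 1:
            raise DomainError("omega and J must be 1-D arrays of equal length")
        if np.any(j < 0):
            raise DomainError("J(w) must be nonnegative")
        if np.any(w < 0):
            raise DomainError("w must be nonnegative")
        if w.size and w[0] == 0.0 and j[0] > 0.0:
            raise DomainError("J(0) > 0 makes J(w)/w non-integrable")
        if self.lambda_cm1 is None:
            object.__setattr__(self, "lambda_cm1", reorganization_energy(self))

    def __add__(self, other: "SpectralDensity") -> "SpectralDensity":
        if not np.array_equal(self.omega_cm1, other.omega_cm1):
            raise DomainError("can only add spectral densities on identical grids")
        return SpectralDensity(self.omega_cm1, self.j_cm1 + other.j_cm1,
                               label=f"{self.label}+{other.label}")


def reorganization_energy(sd: SpectralDensity) -> float:
    """(1/pi) * trapezoidal integral of J(w)/w over the stored grid, cm^-1."""
    w, j = sd.omega_cm1, sd.j_cm1
    if w.size and w[0] == 0.0:
        if j[0] > 0.0:
            raise DomainError("J(0) > 0 makes J(w)/w non-integrable")
        integrand = np.zeros_like(j)
        integrand[1:] = j[1:] / w[1:]
    else:
        integrand = j / w
    return float(np.trapezoid(integrand, w) / np.pi)


def build_from_modes(modes: Sequence[VibronicMode] | Iterable[VibronicMode],
                     omega_cm1: np.ndarray | Grid | None = None,
                     label: str = "") -> SpectralDensity:
    """Broadened sum of displaced modes with lambda enforced per mode.

    Each mode contributes a Lorentzian (half-width gamma_k) in w, weighted
    by w so that J vanishes linearly at w -> 0, and numerically rescaled
    so its (1/pi) Int J/w dw equals exactly lambda_k on the grid.
    """
    modes = list(modes)
    if not modes:
        raise DomainError("empty mode set")
    if omega_cm1 is None:
        w = default_energy_grid_cm1()
    elif isinstance(omega_cm1, Grid):
        raise DomainError("mode grids are wavenumber arrays, not eV/time Grids")
    else:
        w = np.asarray(omega_cm1, dtype=float)
    j = np.zeros_like(w)
    for m in modes:
        if not (w[0] <= m.omega_cm1 <= w[-1]):
            raise DomainError(
                f"mode at {m.omega_cm1} cm^-1 lies outside the grid span [{w[0]}, {w[-1]}]")
        shape = w * (m.gamma_cm1 / np.pi) / ((w - m.omega_cm1) ** 2 + m.gamma_cm1 ** 2)
        raw = np.trapezoid(np.where(w > 0, shape / np.maximum(w, 1e-300), 0.0), w) / np.pi
        if raw <= 0:
            raise DomainError("degenerate broadening kernel")
        j += (m.lambda_cm1 / raw) * shape
    return SpectralDensity(w, j, label=label)


def scale_to_lambda(sd: SpectralDensity, lambda_target_cm1: float) -> SpectralDensity:
    """Same spectral shape, pointwise rescaled to the target reorganization energy."""
    if lambda_target_cm1 < 0:
        raise DomainError("target reorganization energy must be >= 0")
    if sd.lambda_cm1 <= 0:
        raise DomainError("cannot rescale a zero spectral density")
    c = lambda_target_cm1 / sd.lambda_cm1
    return SpectralDensity(sd.omega_cm1, sd.j_cm1 * c, label=sd.label)


def drude_lorentz(lambda_cm1: float, gamma_cm1: float,
                  omega_cm1: np.ndarray | None = None,
                  label: str = "drude") -> SpectralDensity:
    """Overdamped Drude-Lorentz profile J(w) = 2*lambda*gamma*w / (w^2 + gamma^2)."""
    if lambda_cm1 < 0 or gamma_cm1 <= 0:
        raise DomainError("need lambda >= 0 and gamma > 0")
    w = default_energy_grid_cm1() if omega_cm1 is None else np.asarray(omega_cm1, float)
    j = 2.0 * lambda_cm1 * gamma_cm1 * w / (w ** 2 + gamma_cm1 ** 2)
    return SpectralDensity(w, j, label=label)


# --- pigment templates ---------------------------------------------------
# Three-band vibronic templates: C=C stretch, C-C stretch, low-frequency
# envelope.  Only the total lambda is constrained by upstream data; the
# band positions/weights are a documented stand-in (see docs/methods.md).
CAROTENOID_TEMPLATE = ((1550.0, 0.45, 10.0), (1150.0, 0.35, 10.0), (350.0, 0.20, 50.0))
RETINAL_TEMPLATE = ((1530.0, 0.40, 10.0), (1190.0, 0.35, 10.0), (300.0, 0.25, 50.0))


def template_sd(lambda_total_cm1: float,
                template: Sequence[tuple[float, float, float]] = CAROTENOID_TEMPLATE,
                omega_cm1: np.ndarray | None = None,
                label: str = "") -> SpectralDensity:
    """Build a template spectral density scaled so Sum lambda_k = lambda_total."""
    weights = np.array([t[1] for t in template], dtype=float)
    weights = weights / weights.sum()
    modes = [VibronicMode(t[0], lambda_total_cm1 * wgt, t[2])
             for t, wgt in zip(template, weights)]
    return build_from_modes(modes, omega_cm1, label=label)


def carotenoid_sd(lambda_total_cm1: float, omega_cm1: np.ndarray | None = None,
                  label: str = "carotenoid") -> SpectralDensity:
    return template_sd(lambda_total_cm1, CAROTENOID_TEMPLATE, omega_cm1, label)


def retinal_sd(lambda_total_cm1: float = 1500.0, omega_cm1: np.ndarray | None = None,
               label: str = "rPSB") -> SpectralDensity:
    return template_sd(lambda_total_cm1, RETINAL_TEMPLATE, omega_cm1, label)


# --- I/O -----------------------------------------------------------------
def write_sd(sd: SpectralDensity, path: str | Path) -> None:
    """Two-column TSV (w cm^-1, J cm^-1) with a comment header."""
    header = (f"# label: {sd.label}\n"
              f"# lambda_cm1: {sd.lambda_cm1:.10g}\n"
              "# omega_cm1\tJ_cm1")
    np.savetxt(path, np.column_stack([sd.omega_cm1, sd.j_cm1]),
               delimiter="\t", header=header, comments="")


def read_sd(path: str | Path) -> SpectralDensity:
    label = ""
    with open(path) as fh:
        for line in fh:
            if line.startswith("# label:"):
                label = line.split(":", 1)[1].strip()
            if not line.startswith("#"):
                break
    data = np.loadtxt(path, delimiter="\t", comments="#")
    return SpectralDensity(data[:, 0], data[:, 1], label=label)
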