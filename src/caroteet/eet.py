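"""Spectral overlap, golden-rule EET rates, efficiencies, and kinetics.

The donor-to-acceptor energy-transfer rate follows the golden rule

    k_DA = (2 pi / hbar) |V_DA|^2 J_DA

with V_DA the electronic coupling (converted to eV) and J_DA the overlap
integral of the area-normalized donor emission and acceptor absorption
(eV^-1), so k comes out in fs^-1.  Transfer competes with the donor's
intrinsic S2 internal conversion (lifetime tau_D, 140 fs reference), giving

    eta = k_DA / (k_DA + 1 / tau_D)

The three-state kinetic model (donor S2, acceptor S1, ground state) is
solved in closed form; its asymptotic transferred fraction reproduces eta
exactly when the acceptor decay is switched off, which serves as a
cross-module consistency oracle.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DomainError
from .lineshape import (Spectrum, absorption_spectrum,
                        fluorescence_spectrum, lineshape_g,
                        require_area_normalized)
from .spectral_density import SpectralDensity
from .units import CM1_TO_EV, HBAR_EV_FS

DEFAULT_TAU_D_FS = 140.0   # donor S2 lifetime with EET chemically suppressed
DEFAULT_TAU_A_FS = 1000.0  # acceptor S1 decay; unconstrained config default


@dataclass(frozen=True)
class EETResult:
    """One donor->acceptor channel: overlap, rate, time, efficiency."""

    j_overlap_ev: float
    v_cm1: float
    rate_fs: float
    eet_time_fs: float
    efficiency: float
    tau_d_fs: float


def spectral_overlap(donor_fluo: Spectrum, acceptor_abs: Spectrum) -> float:
    """J_DA = Int F_D(E) A_A(E) dE in eV^-1 (linear interpolation onto the
    finer grid over the common support; disjoint supports give 0)."""
    require_area_normalized(donor_fluo)
    require_area_normalized(acceptor_abs)
    lo = max(donor_fluo.energy_ev[0], acceptor_abs.energy_ev[0])
    hi = min(donor_fluo.energy_ev[-1], acceptor_abs.energy_ev[-1])
    if hi <= lo:
        return 0.0
    de = min(np.min(np.diff(donor_fluo.energy_ev)),
             np.min(np.diff(acceptor_abs.energy_ev)))
    grid = np.linspace(lo, hi, max(int(round((hi - lo) / de)) + 1, 2))
    f = np.interp(grid, donor_fluo.energy_ev, donor_fluo.intensity,
                  left=0.0, right=0.0)
    a = np.interp(grid, acceptor_abs.energy_ev, acceptor_abs.intensity,
                  left=0.0, right=0.0)
    return float(np.trapezoid(f * a, grid))


def forster_rate(v_cm1: float, j_ev: float) -> float:
    """Golden-rule rate k = (2 pi / hbar) V^2 J in fs^-1 (V given in cm^-1)."""
    if j_ev < 0:
        raise DomainError("spectral overlap must be >= 0")
    v_ev = v_cm1 * CM1_TO_EV
    return 2.0 * np.pi / HBAR_EV_FS * v_ev ** 2 * j_ev


def eet_efficiency(rate_fs: float, tau_d_fs: float = DEFAULT_TAU_D_FS) -> float:
    """Branching efficiency eta = k / (k + 1/tau_D)."""
    if tau_d_fs <= 0:
        raise DomainError("donor lifetime must be positive")
    if rate_fs < 0:
        raise DomainError("rate must be >= 0")
    return rate_fs / (rate_fs + 1.0 / tau_d_fs)


def eet_result(v_cm1: float, j_ev: float,
               tau_d_fs: float = DEFAULT_TAU_D_FS) -> EETResult:
    """Bundle overlap -> rate -> time -> efficiency for one channel."""
    k = forster_rate(v_cm1, j_ev)
    return EETResult(j_overlap_ev=j_ev, v_cm1=v_cm1, rate_fs=k,
                     eet_time_fs=(np.inf if k == 0 else 1.0 / k),
                     efficiency=eet_efficiency(k, tau_d_fs), tau_d_fs=tau_d_fs)


# --- kinetic model -------------------------------------------------------
@dataclass(frozen=True)
class KineticModel:
    """Three-state photocycle: donor S2 -> {acceptor S1, GS}, acceptor S1 -> GS."""

    k_eet_fs: float
    k_d_ic_fs: float                       # donor internal conversion, 1/tau_D
    k_a_decay_fs: float = 1.0 / DEFAULT_TAU_A_FS

    def __post_init__(self) -> None:
        if min(self.k_eet_fs, self.k_d_ic_fs, self.k_a_decay_fs) < 0:
            raise DomainError("rates must be >= 0")


@dataclass(frozen=True)
class PopulationTrajectory:
    """Closed-form populations of donor S2, acceptor S1 and ground state."""

    time_fs: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    ground: np.ndarray


def simulate_populations(model: KineticModel, t_max_fs: float,
                         dt_fs: float) -> PopulationTrajectory:
    """Exact solution of the sequential first-order kinetics.

    D(t) = exp(-(kE + kD) t); the acceptor follows the standard two-step
    expression (with the degenerate-rate limit handled analytically);
    the ground state closes the balance.
    """
    if dt_fs <= 0 or t_max_fs < dt_fs:
        raise DomainError("need dt > 0 and t_max >= dt")
    t = np.arange(int(round(t_max_fs / dt_fs)) + 1) * dt_fs
    k_tot = model.k_eet_fs + model.k_d_ic_fs
    d = np.exp(-k_tot * t)
    if abs(k_tot - model.k_a_decay_fs) > 1e-15:
        a = model.k_eet_fs / (k_tot - model.k_a_decay_fs) * (
            np.exp(-model.k_a_decay_fs * t) - np.exp(-k_tot * t))
    else:
        a = model.k_eet_fs * t * np.exp(-k_tot * t)
    g = 1.0 - d - a
    return PopulationTrajectory(t, d, a, np.clip(g, 0.0, 1.0))


def transferred_fraction(model: KineticModel, t_max_fs: float) -> float:
    """Integral of the acceptor influx k_EET * D(t) up to t_max (closed form)."""
    k_tot = model.k_eet_fs + model.k_d_ic_fs
    if k_tot == 0:
        return 0.0
    return model.k_eet_fs / k_tot * (1.0 - np.exp(-k_tot * t_max_fs))


# --- donor/acceptor channel from lineshape theory ------------------------
@dataclass(frozen=True)
class DimerChannel:
    """Parameters of one carotenoid->retinal EET channel.

    Site energies are the operative (calibrated) vertical energies; the
    coupling is an input from upstream electronic-structure data, never
    recomputed from dipoles.
    """

    label: str
    donor_e_ev: float
    acceptor_e_ev: float
    donor_sd: SpectralDensity
    acceptor_sd: SpectralDensity
    v_cm1: float
    tau_d_fs: float = DEFAULT_TAU_D_FS
    temperature_K: float = 300.0


def channel_overlap(channel: DimerChannel, energy_ev: np.ndarray,
                    time_fs: np.ndarray,
                    damping_fs: float | None = None) -> EETResult:
    """Compute J, rate and efficiency of a channel from its lineshapes."""
    g_d = lineshape_g(channel.donor_sd, channel.temperature_K, time_fs)
    g_a = lineshape_g(channel.acceptor_sd, channel.temperature_K, time_fs)
    fluo = fluorescence_spectrum(g_d, channel.donor_e_ev, energy_ev, damping_fs)
    ab = absorption_spectrum(g_a, channel.acceptor_e_ev, energy_ev, damping_fs)
    j = spectral_overlap(fluo, ab)
    return eet_result(channel.v_cm1, j, channel.tau_d_fs)


def counterfactual_overlap(base: DimerChannel,
                           energies_from: DimerChannel | None = None,
                           sd_from: DimerChannel | None = None,
                           *, energy_ev: np.ndarray, time_fs: np.ndarray,
                           damping_fs: float | None = None) -> EETResult:
    """Artificial-model channel: swap site energies and/or the donor
    spectral density between complexes while keeping the base coupling.

    ``energies_from`` replaces both site energies (restoring that
    complex's donor-acceptor gap); ``sd_from`` replaces the donor
    spectral density.  With no overrides this is the identity.
    """
    ch = base
    if energies_from is not None:
        ch = replace(ch, donor_e_ev=energies_from.donor_e_ev,
                     acceptor_e_ev=energies_from.acceptor_e_ev)
    if sd_from is not None:
        ch = replace(ch, donor_sd=sd_from.donor_sd)
    return channel_overlap(ch, energy_ev, time_fs, damping_fs)
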