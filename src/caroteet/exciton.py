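"""Two-pigment exciton Hamiltonian, dimer absorption/CD, binding-mode rules.

The carotenoid (S2 donor) and retinal protonated Schiff base (S1
acceptor) form an electronically coupled dimer.  Diagonalizing

    H = [[E_D, V], [V, E_A]]   (V in eV)

gives two exciton states whose dipole strengths govern absorption and
whose equal-and-opposite rotational strengths produce the bisignate CD
couplet that is diagnostic of carotenoid binding.  Each exciton line is
broadened by the coefficient-squared mixture of the site lineshape
functions, and ensembles of conformational snapshots are averaged with
their weights.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .lineshape import LineshapeFunction, Spectrum, _band, lineshape_g
from .spectral_density import SpectralDensity
from .units import CM1_TO_EV

#: point-dipole prefactor: 1 D^2 / Angstrom^3 in cm^-1 (vacuum)
DIPOLE_COUPLING_CM1 = 5034.11

BINDING_MODES = ("CL1", "CL2", "CL3")


@dataclass(frozen=True)
class Pigment:
    """One chromophore site: energy, transition dipole, geometry, bath tag."""

    label: str
    e_vert_ev: float
    mu_debye: np.ndarray          # 3-vector, Debye
    center_ang: np.ndarray        # 3-vector, Angstrom
    ring_ref_ang: np.ndarray      # terminal-ring reference point, Angstrom
    sd_label: str = ""

    def __post_init__(self) -> None:
        for name in ("mu_debye", "center_ang", "ring_ref_ang"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.e_vert_ev <= 0:
            raise DomainError("site energy must be positive")
        if np.linalg.norm(self.mu_debye) <= 0:
            raise DomainError("transition dipole must be nonzero")


@dataclass(frozen=True)
class DimerSnapshot:
    """One conformational sample of the carotenoid-retinal pair."""

    donor: Pigment
    acceptor: Pigment
    v_cm1: float                  # electronic coupling, signed
    r_cc_ang: float               # center-to-center distance
    r_rr_ang: float               # ring-to-ring distance
    theta_c6c7_deg: float         # carotenoid C6-C7 dihedral
    binding_mode: str = "CL2"
    tail_contact: str = "protein"  # protein | lipid
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.r_cc_ang <= 0 or self.r_rr_ang <= 0:
            raise DomainError("distances must be positive")
        if self.binding_mode not in BINDING_MODES:
            raise DomainError(f"unknown binding mode {self.binding_mode!r}")
        if self.weight < 0:
            raise DomainError("snapshot weight must be >= 0")


@dataclass(frozen=True)
class ExcitonStates:
    """Eigenstates of the dimer, ordered by increasing energy."""

    energies_ev: np.ndarray            # (2,)
    coefficients: np.ndarray           # (2, 2), row k = state k over (D, A)
    dipole_strengths: np.ndarray       # (2,), Debye^2
    rotational_strengths: np.ndarray   # (2,), signed (D^2 Angstrom eV scale)


def diagonalize_dimer(s: DimerSnapshot) -> ExcitonStates:
    """Exciton energies, dipole strengths and rotational strengths of a snapshot.

    Rotational strengths use the exciton (mu x mu . R) form with the mean
    exciton energy as prefactor, which keeps the couplet exactly
    conservative (R+ + R- = 0); intrinsic single-pigment CD is neglected.
    """
    e_d, e_a = s.donor.e_vert_ev, s.acceptor.e_vert_ev
    v_ev = s.v_cm1 * CM1_TO_EV
    h = np.array([[e_d, v_ev], [v_ev, e_a]])
    energies, vecs = np.linalg.eigh(h)
    coeffs = vecs.T  # row k = coefficients of state k on (donor, acceptor)
    mu = np.vstack([s.donor.mu_debye, s.acceptor.mu_debye])
    mu_exc = coeffs @ mu
    dip = np.einsum("ki,ki->k", mu_exc, mu_exc)
    chirality = float(np.dot(s.acceptor.center_ang - s.donor.center_ang,
                             np.cross(s.donor.mu_debye, s.acceptor.mu_debye)))
    e_mean = 0.5 * energies.sum()
    rot = np.array([np.pi * e_mean * coeffs[k, 0] * coeffs[k, 1] * chirality
                    for k in range(2)])
    return ExcitonStates(energies, coeffs, dip, rot)


def point_dipole_coupling(donor: Pigment, acceptor: Pigment) -> float:
    """Vacuum point-dipole coupling estimate in cm^-1 (diagnostics only).

    The transition-density couplings consumed by the rate calculation are
    inputs; this estimator exists to sanity-check their order of magnitude,
    since the dipole approximation is unreliable at contact distances.
    """
    r_vec = acceptor.center_ang - donor.center_ang
    r = float(np.linalg.norm(r_vec))
    if r <= 0:
        raise DomainError("pigment centers coincide")
    n = r_vec / r
    mu_d, mu_a = donor.mu_debye, acceptor.mu_debye
    md, ma = np.linalg.norm(mu_d), np.linalg.norm(mu_a)
    ud, ua = mu_d / md, mu_a / ma
    kappa = float(np.dot(ud, ua) - 3.0 * np.dot(ud, n) * np.dot(ua, n))
    return DIPOLE_COUPLING_CM1 * kappa * md * ma / r ** 3


def classify_binding_mode(theta_c6c7_deg: float, tail_contact: str) -> str:
    """Binding-mode label from the C6-C7 dihedral sign and tail anchoring.

    s-cis(+) twists (theta > 0) define CL1; s-cis(-) twists split into CL2
    (tail anchored to the protein) and CL3 (tail contacts the lipid).
    """
    if not (-180.0 < theta_c6c7_deg <= 180.0):
        raise DomainError("dihedral must lie in (-180, 180] degrees")
    if tail_contact not in ("protein", "lipid"):
        raise ConfigurationError(f"unknown tail contact {tail_contact!r}")
    if theta_c6c7_deg > 0:
        return "CL1"
    return "CL2" if tail_contact == "protein" else "CL3"


def ensemble_spectra(snapshots: Sequence[DimerSnapshot],
                     sds: Mapping[str, SpectralDensity],
                     temperature_K: float,
                     energy_ev: np.ndarray,
                     time_fs: np.ndarray,
                     damping_fs: float | None = None,
                     g_cache: dict | None = None,
                     ) -> tuple[Spectrum, Spectrum]:
    """Weighted ensemble-average dimer absorption and CD spectra.

    Each snapshot's exciton lines are dressed with coefficient-squared
    mixtures of the site lineshapes, weighted by dipole strength
    (absorption) or rotational strength (CD), then averaged over snapshot
    weights.  Absorption is area-normalized; CD is scaled by the same
    factor so relative signs and magnitudes are preserved.
    """
    if not snapshots:
        raise DomainError("need at least one snapshot")
    energy_ev = np.asarray(energy_ev, dtype=float)
    if g_cache is None:
        g_cache = {}

    def site_g(label: str) -> LineshapeFunction:
        if label not in g_cache:
            if label not in sds:
                raise ConfigurationError(f"no spectral density registered for {label!r}")
            g_cache[label] = lineshape_g(sds[label], temperature_K, time_fs)
        return g_cache[label]

    absorption = np.zeros_like(energy_ev)
    cd = np.zeros_like(energy_ev)
    total_w = 0.0
    for snap in snapshots:
        st = diagonalize_dimer(snap)
        g_d = site_g(snap.donor.sd_label or snap.donor.label)
        g_a = site_g(snap.acceptor.sd_label or snap.acceptor.label)
        for k in range(2):
            c2_d, c2_a = st.coefficients[k, 0] ** 2, st.coefficients[k, 1] ** 2
            g_mix = c2_d * g_d.g + c2_a * g_a.g
            corr = np.exp(-g_mix)
            if damping_fs is not None:
                corr = corr * np.exp(-time_fs / damping_fs)
            line = _band(corr, np.asarray(time_fs, float), st.energies_ev[k], energy_ev)
            area = np.trapezoid(line, energy_ev)
            if area <= 0:
                continue
            line = line / area
            absorption += snap.weight * st.dipole_strengths[k] * line
            cd += snap.weight * st.rotational_strengths[k] * line
        total_w += snap.weight
    if total_w <= 0:
        raise DomainError("total snapshot weight is zero")
    norm = np.trapezoid(absorption, energy_ev)
    if norm <= 0:
        raise DomainError("ensemble absorption has zero area on this grid")
    meta = {"T_K": temperature_K, "n_snapshots": len(snapshots)}
    return (Spectrum(energy_ev, absorption / norm, kind="absorption",
                     normalization="area", meta=meta),
            Spectrum(energy_ev, cd / norm, kind="CD",
                     normalization="matched", meta=meta))


# --- snapshot table I/O --------------------------------------------------
_VEC_COLS = {
    "mu_D": "mu_debye", "mu_A": "mu_debye",
    "cen_D": "center_ang", "cen_A": "center_ang",
    "ring_D": "ring_ref_ang", "ring_A": "ring_ref_ang",
}


def snapshots_to_frame(snapshots: Sequence[DimerSnapshot]) -> pd.DataFrame:
    rows = []
    for s in snapshots:
        row = {
            "mode": s.binding_mode, "tail_contact": s.tail_contact,
            "donor_label": s.donor.label, "acceptor_label": s.acceptor.label,
            "donor_sd": s.donor.sd_label, "acceptor_sd": s.acceptor.sd_label,
            "E_D_eV": s.donor.e_vert_ev, "E_A_eV": s.acceptor.e_vert_ev,
            "V_cm1": s.v_cm1, "R_cc_A": s.r_cc_ang, "R_rr_A": s.r_rr_ang,
            "theta_deg": s.theta_c6c7_deg, "weight": s.weight,
        }
        for tag, pig in (("D", s.donor), ("A", s.acceptor)):
            for prefix, attr in (("mu", "mu_debye"), ("cen", "center_ang"),
                                 ("ring", "ring_ref_ang")):
                vec = getattr(pig, attr)
                for ax, val in zip("xyz", vec):
                    row[f"{prefix}_{tag}_{ax}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_snapshots(df: pd.DataFrame) -> list[DimerSnapshot]:
    out = []
    for _, r in df.iterrows():
        def vec(prefix: str, tag: str) -> np.ndarray:
            return np.array([r[f"{prefix}_{tag}_{ax}"] for ax in "xyz"])

        donor = Pigment(r["donor_label"], r["E_D_eV"], vec("mu", "D"),
                        vec("cen", "D"), vec("ring", "D"), r["donor_sd"])
        acceptor = Pigment(r["acceptor_label"], r["E_A_eV"], vec("mu", "A"),
                           vec("cen", "A"), vec("ring", "A"), r["acceptor_sd"])
        out.append(DimerSnapshot(donor, acceptor, r["V_cm1"], r["R_cc_A"],
                                 r["R_rr_A"], r["theta_deg"], r["mode"],
                                 r["tail_contact"], r["weight"]))
    return out


def write_snapshots(snapshots: Sequence[DimerSnapshot], path: str | Path) -> None:
    snapshots_to_frame(snapshots).to_csv(path, sep="\t", index=False)


def read_snapshots(path: str | Path) -> list[DimerSnapshot]:
    return frame_to_snapshots(pd.read_csv(path, sep="\t"))
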