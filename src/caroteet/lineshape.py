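"""Second-order cumulant lineshapes and area-normalized spectra.

For a single electronic transition coupled to a harmonic bath described
by a spectral density J(w), the finite-temperature lineshape function is

    g(t) = (1/pi) Int_0^inf dE J(E)/E^2
           [ coth(E / 2 kB T) (1 - cos(E t / hbar))
             + i (sin(E t / hbar) - E t / hbar) ]

(all bath energies E in eV internally).  Absorption and fluorescence
follow from half-sided Fourier transforms

    A(E) ~ Re Int_0^inf dt exp(+i (E - E_vert) t / hbar - g(t))
    F(E) ~ Re Int_0^inf dt exp(+i (E - E_vert + 2 lambda) t / hbar - g*(t))

so that the first moment of absorption is the vertical energy E_vert and
emission is Stokes-shifted by 2*lambda.  Spectra are returned
area-normalized on the eV axis.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ContractError, ConvergenceError, DomainError
from .spectral_density import SpectralDensity
from .units import CM1_TO_EV, HBAR_EV_FS, KB_EV_K

DAMPING_FLOOR = 1e-6   # required decay of |exp(-g)| at t_max
CLIP_FRACTION = 1e-8   # ringing below this fraction of the max is clipped


@dataclass(frozen=True)
class LineshapeFunction:
    """g(t) on a uniform time grid starting at 0, plus its provenance."""

    time_fs: np.ndarray
    g: np.ndarray
    temperature_K: float
    lambda_cm1: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time_fs, dtype=float)
        g = np.asarray(self.g, dtype=complex)
        object.__setattr__(self, "time_fs", t)
        object.__setattr__(self, "g", g)
        if t.shape != g.shape:
            raise DomainError("time grid and g must have matching shape")


@dataclass(frozen=True)
class Spectrum:
    """Intensity on an eV grid.  CD spectra are signed; others nonnegative."""

    energy_ev: np.ndarray
    intensity: np.ndarray
    kind: str = "absorption"          # absorption | fluorescence | CD
    normalization: str = "raw"        # area | max | raw | matched
    meta: dict = None                 # type: ignore[assignment]

    def __post_init__(self) -> None:
        e = np.asarray(self.energy_ev, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "energy_ev", e)
        object.__setattr__(self, "intensity", i)
        object.__setattr__(self, "meta", dict(self.meta or {}))
        if e.shape != i.shape:
            raise DomainError("energy grid and intensity must match")
        if self.kind != "CD" and np.any(i < 0):
            raise DomainError(f"{self.kind} spectrum must be nonnegative")

    def area(self) -> float:
        return float(np.trapezoid(self.intensity, self.energy_ev))

    def moment(self, n: int = 1) -> float:
        """n-th moment of the normalized band (n=1: mean energy in eV)."""
        a = self.area()
        if a == 0:
            raise DomainError("zero-area spectrum has no moments")
        mean = np.trapezoid(self.energy_ev * self.intensity, self.energy_ev) / a
        if n == 1:
            return float(mean)
        return float(np.trapezoid((self.energy_ev - mean) ** n * self.intensity,
                                  self.energy_ev) / a)


def _trapezoid_weights(x: np.ndarray) -> np.ndarray:
    w = np.empty_like(x)
    w[1:-1] = 0.5 * (x[2:] - x[:-2])
    w[0] = 0.5 * (x[1] - x[0])
    w[-1] = 0.5 * (x[-1] - x[-2])
    return w


def _is_uniform(x: np.ndarray) -> bool:
    d = np.diff(x)
    return bool(d.size) and np.allclose(d, d[0], rtol=1e-9, atol=0.0)


def lineshape_g(sd: SpectralDensity, temperature_K: float,
                time_fs: np.ndarray) -> LineshapeFunction:
    """Second-order cumulant g(t) for a spectral density at temperature T.

    On uniform bath grids the cos/sin transforms are evaluated with a
    zero-padded FFT (a trapezoidal sum, oversampled ~4x and linearly
    interpolated onto the requested times); non-uniform grids fall back
    to direct quadrature.
    """
    if temperature_K <= 0:
        raise DomainError("temperature must be positive")
    t = np.asarray(time_fs, dtype=float)
    E = sd.omega_cm1 * CM1_TO_EV
    J = sd.j_cm1 * CM1_TO_EV
    pos = E > 0
    E, J = E[pos], J[pos]
    a = J / E ** 2 * _trapezoid_weights(E) / np.pi
    coth = 1.0 / np.tanh(E / (2.0 * KB_EV_K * temperature_K))
    lam_ev = float(np.sum(a * E))
    if _is_uniform(E) and t.size > 64:
        de = E[1] - E[0]
        n = 1 << max(int(np.ceil(np.log2(4 * E.size))), 14)
        # ensure FFT time step resolves the requested grid and span
        while 2.0 * np.pi * HBAR_EV_FS / (n * de) > max(np.min(np.diff(t)), 1e-3) \
                or 2.0 * np.pi * HBAR_EV_FS / de * (n - 1) / n < t[-1]:
            n <<= 1
            if n > 1 << 24:
                break
        tf = 2.0 * np.pi * HBAR_EV_FS / (n * de) * np.arange(n)
        phase0 = np.exp(1j * E[0] * tf / HBAR_EV_FS)
        f1 = np.zeros(n, dtype=complex)
        f1[:E.size] = a * coth
        f2 = np.zeros(n, dtype=complex)
        f2[:E.size] = a
        tr1 = phase0 * np.fft.ifft(f1) * n   # sum a*coth*exp(+iEt/hbar)
        tr2 = phase0 * np.fft.ifft(f2) * n   # sum a*exp(+iEt/hbar)
        re_f = np.sum(a * coth) - tr1.real
        im_f = tr2.imag
        keep = tf <= t[-1] + 2 * (tf[1] - tf[0])
        re = np.interp(t, tf[keep], re_f[keep])
        im = np.interp(t, tf[keep], im_f[keep]) - lam_ev * t / HBAR_EV_FS
    else:
        g = np.empty(t.shape, dtype=complex)
        for i0 in range(0, t.size, 256):
            ph = np.outer(t[i0:i0 + 256], E) / HBAR_EV_FS
            g[i0:i0 + 256] = ((1.0 - np.cos(ph)) @ (a * coth)
                              + 1j * (np.sin(ph) @ a - ph @ a))
        re, im = g.real, g.imag
    re[0], im[0] = 0.0, 0.0  # g(0) = 0 exactly
    return LineshapeFunction(t, re + 1j * im, temperature_K, sd.lambda_cm1)


def _half_fourier(corr: np.ndarray, time_fs: np.ndarray,
                  energy_ev: np.ndarray) -> np.ndarray:
    """Re Int_0^inf dt exp(i E t / hbar) corr(t), trapezoidal in t.

    Uniform time grids go through a zero-padded FFT whose output is
    linearly interpolated at the requested energies; the padding keeps
    the FFT energy step far below any physical band width.
    """
    t = np.asarray(time_fs, dtype=float)
    e = np.asarray(energy_ev, dtype=float)
    if _is_uniform(t) and t.size > 64:
        dt = t[1] - t[0]
        v = corr.astype(complex).copy()
        v[0] *= 0.5
        v[-1] *= 0.5
        n = 1 << max(int(np.ceil(np.log2(4 * t.size))), 14)
        spec = np.fft.ifft(v, n) * n * dt       # sum v exp(+2pi i kn/N) dt
        e_fft = 2.0 * np.pi * HBAR_EV_FS / (n * dt) * np.arange(n)
        half = n // 2
        e_ax = np.concatenate([e_fft[half:] - 2.0 * np.pi * HBAR_EV_FS / dt,
                               e_fft[:half]])
        re = np.concatenate([spec.real[half:], spec.real[:half]])
        return np.interp(e, e_ax, re, left=0.0, right=0.0)
    wt = _trapezoid_weights(t)
    v = corr * wt
    out = np.empty(e.shape, dtype=float)
    for i0 in range(0, e.size, 512):
        ph = np.outer(e[i0:i0 + 512], t) / HBAR_EV_FS
        out[i0:i0 + 512] = (np.exp(1j * ph) @ v).real
    return out


def _band(corr: np.ndarray, time_fs: np.ndarray, center_ev: float,
          energy_ev: np.ndarray) -> np.ndarray:
    raw = _half_fourier(corr, time_fs, energy_ev - center_ev)
    top = raw.max()
    if top <= 0:
        return np.zeros_like(raw)
    raw[raw < CLIP_FRACTION * top] = 0.0
    return raw


def _check_damped(corr: np.ndarray) -> None:
    if abs(corr[-1]) > DAMPING_FLOOR:
        raise ConvergenceError(
            f"integrand not damped at t_max (|corr|={abs(corr[-1]):.2e}); "
            "extend the time grid or add damping")


def _apply_damping(g: LineshapeFunction, damping_fs: float | None) -> np.ndarray:
    d = np.exp(-g.g)
    if damping_fs is not None:
        if damping_fs <= 0:
            raise DomainError("damping time must be positive")
        d = d * np.exp(-g.time_fs / damping_fs)
    return d


def absorption_spectrum(g: LineshapeFunction, e_vert_ev: float,
                        energy_ev: np.ndarray,
                        damping_fs: float | None = None) -> Spectrum:
    """Area-normalized absorption band centered (first moment) at E_vert."""
    corr = _apply_damping(g, damping_fs)
    _check_damped(corr)
    band = _band(corr, g.time_fs, e_vert_ev, np.asarray(energy_ev, float))
    return _normalized(band, energy_ev, "absorption", e_vert_ev, g)


def fluorescence_spectrum(g: LineshapeFunction, e_vert_ev: float,
                          energy_ev: np.ndarray,
                          damping_fs: float | None = None) -> Spectrum:
    """Area-normalized emission band, Stokes-shifted by 2*lambda from E_vert."""
    corr = np.conj(_apply_damping(g, damping_fs))
    _check_damped(corr)
    center = e_vert_ev - 2.0 * g.lambda_cm1 * CM1_TO_EV
    band = _band(corr, g.time_fs, center, np.asarray(energy_ev, float))
    return _normalized(band, energy_ev, "fluorescence", e_vert_ev, g)


def _normalized(band: np.ndarray, energy_ev: np.ndarray, kind: str,
                e_vert_ev: float, g: LineshapeFunction) -> Spectrum:
    area = np.trapezoid(band, energy_ev)
    if area <= 0:
        raise ConvergenceError("spectrum has nonpositive area on this grid")
    return Spectrum(energy_ev, band / area, kind=kind, normalization="area",
                    meta={"E_vert_eV": e_vert_ev, "lambda_cm1": g.lambda_cm1,
                          "T_K": g.temperature_K})


# --- I/O -----------------------------------------------------------------
def write_spectrum(sp: Spectrum, path: str | Path) -> None:
    meta = "\t".join(f"{k}={v:.10g}" for k, v in sp.meta.items())
    header = (f"# kind: {sp.kind}\n# normalization: {sp.normalization}\n"
              f"# {meta}\n# energy_eV\tintensity")
    np.savetxt(path, np.column_stack([sp.energy_ev, sp.intensity]),
               delimiter="\t", header=header, comments="")


def read_spectrum(path: str | Path) -> Spectrum:
    kind, norm = "absorption", "raw"
    with open(path) as fh:
        for line in fh:
            if line.startswith("# kind:"):
                kind = line.split(":", 1)[1].strip()
            elif line.startswith("# normalization:"):
                norm = line.split(":", 1)[1].strip()
            elif not line.startswith("#"):
                break
    data = np.loadtxt(path, delimiter="\t", comments="#")
    return Spectrum(data[:, 0], data[:, 1], kind=kind, normalization=norm)


def require_area_normalized(sp: Spectrum, tol: float = 1e-3) -> None:
    if sp.normalization != "area" or abs(sp.area() - 1.0) > tol:
        raise ContractError(f"{sp.kind} spectrum is not area-normalized "
                            f"(area={sp.area():.6g})")
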