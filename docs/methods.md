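# Methods

## Physical model

The system is a two-pigment complex: a carotenoid donor whose bright
S₀→S₂ transition is coupled to nuclear motion through a spectral density
J_D(ω), and the retinal protonated Schiff base (rPSB) acceptor with its
S₀→S₁ transition and bath J_A(ω). Both baths are harmonic
(displaced-oscillator picture); the reorganization energy of each pigment
is

    lambda = (1/pi) * Int_0^inf J(w)/w dw,

evaluated by trapezoidal quadrature on the stored grid (default
1–20000 cm⁻¹ at 1 cm⁻¹; truncation error < 0.5% for the mode templates
used here).

### Lineshapes

Band shapes come from the second-order cumulant expansion. For each
pigment

    g(t) = (1/pi) Int dE J(E)/E^2 [ coth(E/2kT)(1 - cos(Et/hbar))
                                    + i (sin(Et/hbar) - Et/hbar) ],

    A(E) ∝ Re Int_0^inf dt e^{ i(E-E_vert)t/hbar - g(t) },
    F(E) ∝ Re Int_0^inf dt e^{ i(E-E_vert+2lambda)t/hbar - g*(t) },

both returned area-normalized on the eV axis. In this convention the
absorption first moment is the vertical energy E_vert and the emission
first moment is E_vert − 2λ (mirror-image/Stokes theorem; verified
numerically to 3% in the tests). A full cumulant treatment would add
inter-state transfer corrections to the dimer spectra; those are not
constrained by any quantity this pipeline targets, so spectra are
computed per state at second order and inhomogeneity enters only through
explicit averaging over snapshots. Deviations of fine CD/absorption
shapes from a full-cumulant calculation are expected and accepted.

### Exciton dimer and CD

Each snapshot defines H = [[E_D, V],[V, E_A]] (V in eV). Exciton
dipoles are coefficient combinations of the site dipoles; rotational
strengths use the exciton chirality form

    R_k = pi * E_mean * c_k,D * c_k,A * (r_A - r_D) . (mu_D x mu_A),

with the *mean* exciton energy as prefactor for both states so the
couplet is exactly conservative (R₊ + R₋ = 0). Intrinsic single-pigment
CD is not parameterized and is neglected; CD is reported in units
matched to the area-normalized absorption (no Δε calibration). Each
exciton line is broadened by the coefficient-squared mixture of the site
lineshapes, g_k = c²_{k,D} g_D + c²_{k,A} g_A — the standard weak-mixing
treatment.

Note an easily-missed asymmetry: flipping the sign of V flips the CD
couplet but does *not* leave absorption invariant unless μ_D·μ_A = 0,
because the relative sign of V and μ_D·μ_A decides which exciton
carries the oscillator strength (H- vs J-aggregate).

The electronic coupling V is always an input (from upstream
transition-density calculations or the generator), never recomputed from
dipoles: at ring-to-ring contact distances of 6.5–8 Å the point-dipole
approximation is unreliable. `point_dipole_coupling` exists purely as an
order-of-magnitude diagnostic.

### EET rate, efficiency, kinetics

    J_DA = Int F_D(E) A_A(E) dE          [eV^-1]
    k_DA = (2 pi / hbar) |V|^2 J_DA      [fs^-1, V in eV]
    eta  = k_DA / (k_DA + 1/tau_D)

τ_D = 140 fs is the donor S₂ lifetime measured with retinal-mediated
transfer chemically suppressed, used for all carotenoids. The
three-state kinetics (donor S₂ → acceptor S₁ at k_DA; donor S₂ → GS at
1/τ_D; acceptor S₁ → GS at 1/τ_A) is solved in closed form, not with a
numerical integrator. The asymptotic transferred fraction with τ_A → ∞
equals η exactly, which the tests use as a cross-module oracle (1e-9).
τ_A is not constrained by any published number; default 1 ps, and all
reported bounds are insensitive to it.

An internal consistency worth recording: with the published overlap
(0.06 eV⁻¹) and coupling (248 cm⁻¹), the salinixanthin transfer time is
1/k ≈ 1.85 ps, which together with τ_D = 140 fs gives the published ~7%
efficiency. A transfer time of ~9 ps would not; this pipeline treats
the overlap/efficiency values as the binding constraints.

## Parameter provenance and defaults

Constants: hc = 1239.84193 eV·nm, ħ = 0.6582119569 eV·fs,
k_B = 8.617333262e-5 eV/K, point-dipole prefactor 5034.11 cm⁻¹·Å³/D²
(vacuum).

Per-complex inputs (couplings 248/291/270/283 cm⁻¹; dipole magnitudes
13.6/13.5/12.4/11.9 D carotenoid and 9.5 D rPSB; center distances
16.7/16.7/12.5/12.8 Å; ring distances ~7–7.5 Å; carotenoid λ
3593/3593/1458/1787 cm⁻¹; ensemble sizes 79/30 for the two
salinixanthin sets) are upstream QM/MM and MD results, taken as given.

Site energies. Carotenoid S₂ means: 2.76 eV (LUT), 2.68 eV (ZEA),
2.53 eV (SXN set-cis(−)); the set-cis(+) mean applies the reported
545-vs-535 nm offset (−0.043 eV). The rPSB S₁ means come from the
reported per-complex wavelengths (491/481/460/453 nm) with a −0.2 eV
calibration shift applied to the rPSB only, a correction traceable to
benchmark calculations on these chromophores; the shifted acceptor band
(~2.33–2.54 eV, i.e. ~490–530 nm) sits where retinal-protein absorption
is actually observed. Both shifts are per-pigment config knobs
(`calibration_donor_ev`, `calibration_acceptor_ev`). With this choice
the computed overlaps come out at the reported scale (~1.3–1.5 eV⁻¹ for
LUT/ZEA, ~0.06 eV⁻¹ for salinixanthin set-cis(−)) with no further
tuning.

Spectral-density shapes. Only the λ totals are published. Each pigment
uses a three-band vibronic template (C=C stretch ~1550, C–C stretch
~1150, low-frequency envelope ~350 cm⁻¹ at weights 0.45/0.35/0.20 for
carotenoids; 1530/1190/300 at 0.40/0.35/0.25 for the rPSB), broadened
with per-mode Lorentzians (γ = 10 cm⁻¹ high-frequency, 50 cm⁻¹
low-frequency) that are renormalized numerically so the λ integral is
exact regardless of kernel. The template is a documented stand-in for
the unpublished profiles; the acceptance-relevant conclusions depend on
λ and the site energies, not on the band positions. λ_rPSB = 1500 cm⁻¹
is likewise unpublished; the default is a typical
protonated-Schiff-base value and is a config knob.

Ensemble statistics. Binding modes: CL1 is the s-cis(+) pose
(θ_C6C7 ≈ +62°), CL2/CL3 the s-cis(−) poses (θ ≈ −47°) distinguished by
protein vs lipid tail anchoring; the aggregate mixture uses 56% CL1
with the CL2:CL3 remainder split 2:1 (the split itself is not
published). The set-cis(−)/set-cis(+) ensembles are pure
CL2+CL3 / pure CL1. Inhomogeneous widths are not published: defaults
0.05 eV (site energies), 20% (couplings), 10° (dihedrals), flagged
`paper_constrained=False` on the spec object. LUT/ZEA ensemble sizes
are likewise unpublished (default n = 50).

Synthetic geometry. The generator emits only what the pipeline
consumes: pigment centers on the x-axis at the center-to-center
distance, ring-reference points separated by the ring-to-ring distance,
and near-parallel transition dipoles with a fixed +20° mean twist
(right-handed; this pins the CD sign convention so the upper,
carotenoid-rich exciton carries the positive lobe) plus 8° orientational
jitter. It reproduces none of the atomistic structure, no real
orientation-factor distribution, and no MD time correlation (snapshots
are i.i.d.). Passing tests therefore demonstrate the statistical and
spectroscopic machinery, not agreement with any real trajectory.

## Numerical choices

- Bath integrals and half-sided Fourier transforms are evaluated as
  trapezoidal sums via zero-padded FFTs (oversampled ≥4× and linearly
  interpolated onto the requested grids); agreement with direct
  quadrature is ~4e-5 relative. Non-uniform bath grids fall back to
  direct quadrature.
- Default grids: time 0–2 ps at 0.25 fs; spectra 0.4–4.2 eV at 2 meV;
  bath 1–20000 cm⁻¹ at 1 cm⁻¹. The 2 ps window damps |e^{−g}| below
  1e-6 for every pigment here when combined with the default 500 fs
  exponential damping (a ~2 meV Lorentzian broadening, negligible
  against ≥0.2 eV bandwidths); an undamped integrand at t_max raises a
  convergence error rather than returning a ringing spectrum.
- Negative ringing below 1e-8 of the band maximum is clipped to zero
  before area normalization.
- Overdamped Drude–Lorentz profiles concentrate weight of J(E)/E² near
  E→0 and need a denser low-frequency grid than the default (the test
  suite uses 0.01 cm⁻¹ steps below 10 cm⁻¹ for its closed-form
  oracles). The vibronic-mode templates the pipeline uses are linear in
  E near zero with a small prefactor and are insensitive to this.
- Ensemble averaging of rates defaults to per-snapshot ⟨V²J⟩
  (config `averaging: per_snapshot`); `mean_field` uses ⟨V⟩² times the
  overlap of the ensemble-mean spectra. Which the original analysis
  used is not documented; the two differ by the V–J covariance.
- Reproducibility: every stochastic step draws from
  `numpy.random.default_rng` seeded from the run seed via
  `SeedSequence`; identical configs give byte-identical outputs.

## Known limitations

- Second-order cumulant per state, no inter-exciton transfer
  corrections, no Herzberg–Teller vibronic intensity borrowing: CD and
  absorption fine structure is approximate.
- The pipeline reproduces the ordering and the ≥10× overlap separation
  between the hydroxylated-xanthophyll complexes and the salinixanthin
  complexes from published means alone. It does **not** reproduce the
  reported set-cis(+) > set-cis(−) overlap sub-ordering: the published
  set-cis(+) means (donor lower, acceptor higher) both push donor
  emission further from the acceptor band, so any overlap functional of
  those means gives the opposite sub-ordering. Resolving that would
  require the unpublished per-set spectral distributions.
- No back-transfer (acceptor→donor), no multi-acceptor generalized
  Förster, no Redfield-type dynamics; the kinetic model is strictly
  sequential first-order.
- Spectral overlaps computed here depend on the unpublished bath shapes
  and widths at the ~2× level; the printed-input rate/efficiency
  arithmetic does not.
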