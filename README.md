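# caroteet

Excitonic spectroscopy and carotenoid-to-retinal excitation energy
transfer (EET) analysis for rhodopsin antenna complexes.

Some microbial rhodopsins bind a carotenoid antenna whose bright S₂
state can feed its excitation to the retinal protonated Schiff base
(rPSB) S₁ state. Whether that works is a race: EET competes with the
carotenoid's ultrafast S₂ internal conversion (τ_D ≈ 140 fs). This
package implements the pieces needed to quantify that race for a
carotenoid–retinal dimer and to explain why some carotenoids
(lutein, zeaxanthin) are good antennas while the keto-carotenoid
salinixanthin, in the same binding pocket, is not:

- **Spectral densities** J(ω) in the displaced-oscillator picture, with
  reorganization energies λ = (1/π)∫J(ω)/ω dω.
- **Second-order cumulant lineshapes** g(t) at finite temperature, and
  area-normalized absorption/fluorescence bands obtained from half-sided
  Fourier transforms (absorption first moment at the vertical energy,
  emission Stokes-shifted by 2λ).
- **Exciton absorption and circular dichroism** of the coupled dimer
  (2×2 Hamiltonian, dipole and rotational strengths, conservative
  bisignate CD couplet), ensemble-averaged over conformational
  snapshots; a point-dipole coupling estimator for sanity checks.
- **Golden-rule EET**: spectral overlap J_DA = ∫F_D(E)A_A(E)dE, rate
  k_DA = (2π/ħ)|V_DA|²J_DA, branching efficiency
  η = k_DA/(k_DA + 1/τ_D), and the closed-form three-state population
  kinetics (donor S₂, acceptor S₁, ground state).
- **A synthetic snapshot-ensemble generator** that emulates the
  statistics of MD/QM-MM ensembles (binding-mode mixture CL1/CL2/CL3,
  C6–C7 dihedral distributions, ring-to-ring distances, site-energy and
  coupling spreads) so the whole pipeline runs with no external data.
- **Counterfactual models** that swap the donor–acceptor energy gap and
  the donor spectral density independently, to separate the two
  suppression mechanisms.

## Worked example

Efficiency of one channel from its coupling and spectral overlap
(salinixanthin set-cis(−) inputs):

```
$ caroteet eet --coupling-cm1 248 --overlap-ev 0.06
{
  "V_cm1": 248.0,
  "J_eV^-1": 0.06,
  "rate_fs^-1": 0.0005415036050474988,
  "eet_time_fs": 1846.7097738200348,
  "efficiency": 0.07046826962088618
}
```

With a 248 cm⁻¹ coupling but only 0.06 eV⁻¹ of donor-emission /
acceptor-absorption overlap, transfer takes ~1.8 ps — far slower than
the 140 fs internal conversion — so only ~7% of the excitations reach
the retinal.

The full pipeline (generate ensembles → spectra → overlaps → rates →
kinetics) for the four standard complexes:

```
$ caroteet run --seed 7
      complex      V_cm1  J_eV^-1  rate_fs^-1  eet_time_fs  efficiency  max_acceptor_population
          LUT 274.928993 1.290436    0.014869    67.255953    0.675493                 0.583065
          ZEA 277.174813 1.510072    0.017667    56.603681    0.712092                 0.622241
SXN_cis_minus 246.929353 0.060435    0.000610  1640.203138    0.078643                 0.058068
 SXN_cis_plus 318.250472 0.014383    0.000212  4716.232586    0.028829                 0.021060
```

The lutein/zeaxanthin complexes overlap the retinal absorption by
~1.3–1.5 eV⁻¹ and transfer in ~60 fs at ~70% efficiency; the
salinixanthin complexes — same pocket, comparable coupling — have >20×
smaller overlap, because salinixanthin's S₂ energy is red-shifted and
its reorganization energy (3593 cm⁻¹) is more than twice that of
lutein/zeaxanthin, which pushes its Stokes-shifted emission far below
the acceptor band. After selective donor excitation, the retinal S₁
population of the salinixanthin complex stays below 0.06.

Other CLI verbs: `generate` (write a snapshot ensemble), `spectra`
(per-complex exciton absorption/CD), `kinetics` (population
trajectories), `fixtures` (deterministic test bundles). Everything is
also available as a library; see `caroteet.pipeline.RunConfig` for the
knobs (temperature, τ_D, grids, averaging mode, per-complex overrides).

## Layout

```
src/caroteet/
  units.py             constants, unit conversions, grids
  spectral_density.py  J(omega) construction, lambda integrals, templates
  lineshape.py         cumulant g(t), absorption/fluorescence spectra
  exciton.py           dimer Hamiltonian, ensemble absorption + CD
  eet.py               overlap, golden-rule rate, efficiency, kinetics
  ensemble.py          synthetic snapshot-ensemble generator
  pipeline.py, cli.py  orchestration and command-line interface
docs/methods.md        model assumptions, parameter provenance, limitations
```
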