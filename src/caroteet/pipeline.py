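"""End-to-end orchestration: generate -> spectra -> overlap -> rates -> kinetics.

A single :class:`RunConfig` drives the whole analysis for a list of
complexes and writes plain tab-separated outputs plus a machine-readable
JSON summary, so every number is diffable and every stage can be re-run
from its saved intermediates.
"""
from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .eet import (DEFAULT_TAU_A_FS, DEFAULT_TAU_D_FS, KineticModel,
                  forster_rate, simulate_populations, spectral_overlap)
from .ensemble import default_spec, sample_ensemble, sd_registry
from .errors import ConfigurationError
from .exciton import ensemble_spectra, write_snapshots
from .lineshape import (Spectrum, absorption_spectrum, fluorescence_spectrum,
                        lineshape_g, write_spectrum)
from .spectral_density import write_sd
from .units import CM1_TO_EV, HBAR_EV_FS

log = logging.getLogger("caroteet")

DEFAULT_COMPLEXES = ("LUT", "ZEA", "SXN_cis_minus", "SXN_cis_plus")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (all knobs in one place)."""

    complexes: list = field(default_factory=lambda: list(DEFAULT_COMPLEXES))
    output_dir: str = "caroteet_out"
    seed: int = 0
    temperature_K: float = 300.0
    tau_d_fs: float = DEFAULT_TAU_D_FS
    tau_a_fs: float = DEFAULT_TAU_A_FS
    averaging: str = "per_snapshot"       # per_snapshot | mean_field
    n_snapshots: dict = field(default_factory=dict)   # per-complex override
    spec_overrides: dict = field(default_factory=dict)
    energy_min_ev: float = 0.4
    energy_max_ev: float = 4.2
    energy_step_ev: float = 0.002
    t_max_fs: float = 2000.0
    dt_fs: float = 0.25
    damping_fs: float = 500.0
    kinetics_t_max_fs: float = 2000.0
    kinetics_dt_fs: float = 2.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def energy_grid(self) -> np.ndarray:
        n = int(round((self.energy_max_ev - self.energy_min_ev) / self.energy_step_ev)) + 1
        return self.energy_min_ev + np.arange(n) * self.energy_step_ev

    def time_grid(self) -> np.ndarray:
        return np.arange(int(round(self.t_max_fs / self.dt_fs)) + 1) * self.dt_fs


def _mean_spectrum(spectra: list[Spectrum], energy: np.ndarray,
                   kind: str) -> Spectrum:
    mean = np.mean([sp.intensity for sp in spectra], axis=0)
    area = np.trapezoid(mean, energy)
    return Spectrum(energy, mean / area, kind=kind, normalization="area")


def run_complex(complex_id: str, config: RunConfig, seed: int) -> dict:
    """Run every stage for one complex; returns results and artifacts."""
    overrides = dict(config.spec_overrides.get(complex_id, {}))
    if complex_id in config.n_snapshots:
        overrides["n_snapshots"] = int(config.n_snapshots[complex_id])
    spec = default_spec(complex_id, seed=seed, **overrides)
    log.info("[generate] %s: n=%d seed=%d", complex_id, spec.n_snapshots, seed)
    snaps = sample_ensemble(spec)
    sds = sd_registry(spec)
    energy = config.energy_grid()
    t = config.time_grid()

    log.info("[spectra] %s: site lineshape functions", complex_id)
    g_cache = {label: lineshape_g(sd, config.temperature_K, t)
               for label, sd in sds.items()}
    log.info("[spectra] %s: exciton absorption + CD", complex_id)
    abs_spec, cd_spec = ensemble_spectra(snaps, sds, config.temperature_K,
                                         energy, t, damping_fs=config.damping_fs,
                                         g_cache=g_cache)

    log.info("[overlap] %s: donor emission vs acceptor absorption", complex_id)
    g_d = g_cache[spec.car_label]
    g_a = g_cache["rPSB"]
    fluos, abss, j_each, v2j = [], [], [], []
    for s in snaps:
        fl = fluorescence_spectrum(g_d, s.donor.e_vert_ev, energy, config.damping_fs)
        ab = absorption_spectrum(g_a, s.acceptor.e_vert_ev, energy, config.damping_fs)
        j = spectral_overlap(fl, ab)
        fluos.append(fl)
        abss.append(ab)
        j_each.append(j)
        v2j.append((s.v_cm1 * CM1_TO_EV) ** 2 * j)
    mean_fluo = _mean_spectrum(fluos, energy, "fluorescence")
    mean_abs = _mean_spectrum(abss, energy, "absorption")
    v_mean = float(np.mean([s.v_cm1 for s in snaps]))
    if config.averaging == "per_snapshot":
        rate = 2.0 * np.pi / HBAR_EV_FS * float(np.mean(v2j))
        j_report = float(np.mean(j_each))
    elif config.averaging == "mean_field":
        j_report = spectral_overlap(mean_fluo, mean_abs)
        rate = forster_rate(v_mean, j_report)
    else:
        raise ConfigurationError(f"unknown averaging mode {config.averaging!r}")
    eff = rate / (rate + 1.0 / config.tau_d_fs)

    log.info("[kinetics] %s: three-state populations", complex_id)
    model = KineticModel(rate, 1.0 / config.tau_d_fs, 1.0 / config.tau_a_fs)
    traj = simulate_populations(model, config.kinetics_t_max_fs, config.kinetics_dt_fs)

    return {
        "spec": spec, "snapshots": snaps, "sds": sds,
        "absorption": abs_spec, "cd": cd_spec,
        "donor_fluorescence": mean_fluo, "acceptor_absorption": mean_abs,
        "J_eV": j_report, "V_cm1": v_mean, "rate_fs": rate,
        "eet_time_fs": (float("inf") if rate == 0 else 1.0 / rate),
        "efficiency": eff, "trajectory": traj,
        "max_acceptor_population": float(traj.acceptor.max()),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run all configured complexes and write the report bundle."""
    if not config.complexes:
        raise ConfigurationError("empty complex list: nothing to run")
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(name)s %(message)s")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(len(config.complexes))
    results, summary_rows = {}, []
    for cid, s in zip(config.complexes, seeds):
        res = run_complex(cid, config, int(s) % (2 ** 31))
        results[cid] = res
        cdir = out / cid
        cdir.mkdir(exist_ok=True)
        write_snapshots(res["snapshots"], cdir / "ensemble.tsv")
        for key in ("absorption", "cd", "donor_fluorescence", "acceptor_absorption"):
            write_spectrum(res[key], cdir / f"{key}.tsv")
        for label, sd in res["sds"].items():
            write_sd(sd, cdir / f"sd_{label}.tsv")
        traj = res["trajectory"]
        np.savetxt(cdir / "populations.tsv",
                   np.column_stack([traj.time_fs, traj.donor, traj.acceptor,
                                    traj.ground]),
                   delimiter="\t", comments="",
                   header="time_fs\tdonor_S2\tacceptor_S1\tground")
        summary_rows.append({
            "complex": cid, "V_cm1": res["V_cm1"], "J_eV^-1": res["J_eV"],
            "rate_fs^-1": res["rate_fs"], "eet_time_fs": res["eet_time_fs"],
            "efficiency": res["efficiency"],
            "max_acceptor_population": res["max_acceptor_population"],
        })
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out / "eet_summary.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump({r["complex"]: {k: v for k, v in r.items() if k != "complex"}
                   for r in summary_rows}, fh, indent=2)
    results["summary"] = summary
    return results


def make_fixtures(size: str = "tiny", output_dir: str | Path = "fixtures",
                  seed: int = 0) -> dict:
    """Small deterministic ensembles + spectral densities for tests.

    ``tiny`` caps every complex at 8 snapshots; ``standard`` keeps the
    published ensemble sizes.
    """
    if size not in ("tiny", "standard"):
        raise ConfigurationError("size must be 'tiny' or 'standard'")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = {}
    seeds = np.random.SeedSequence(seed).generate_state(len(DEFAULT_COMPLEXES))
    for cid, s in zip(DEFAULT_COMPLEXES, seeds):
        overrides = {"n_snapshots": 8} if size == "tiny" else {}
        spec = default_spec(cid, seed=int(s) % (2 ** 31), **overrides)
        snaps = sample_ensemble(spec)
        write_snapshots(snaps, out / f"{cid}_ensemble.tsv")
        for label, sd in sd_registry(spec).items():
            write_sd(sd, out / f"{cid}_sd_{label}.tsv")
        bundle[cid] = {"spec": spec, "snapshots": snaps}
    return bundle
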