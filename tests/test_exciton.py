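"""Exciton dimer: sum rules, closed-form eigenvalues, CD conventions."""
import numpy as np
import pytest

from caroteet.errors import ConfigurationError, DomainError
from caroteet.exciton import (DimerSnapshot, Pigment, classify_binding_mode,
                              diagonalize_dimer, ensemble_spectra,
                              point_dipole_coupling, read_snapshots,
                              write_snapshots)
from caroteet.lineshape import absorption_spectrum, lineshape_g
from caroteet.spectral_density import carotenoid_sd
from caroteet.units import CM1_TO_EV


def _pigment(label, e, mu, center, sd_label=""):
    return Pigment(label, e, np.asarray(mu, float), np.asarray(center, float),
                   np.asarray(center, float), sd_label)


def _random_snapshot(rng):
    donor = _pigment("D", rng.uniform(1, 4), rng.normal(size=3) + 0.5,
                     rng.normal(size=3))
    acceptor = _pigment("A", rng.uniform(1, 4), rng.normal(size=3) + 0.5,
                        rng.normal(size=3) + 5.0)
    return DimerSnapshot(donor, acceptor, rng.normal(0, 400),
                         rng.uniform(5, 20), rng.uniform(5, 10),
                         rng.uniform(-170, 170))


def test_sum_rules_on_random_geometries():
    """Trace, dipole-strength and rotational-strength sum rules, 1000 draws."""
    rng = np.random.default_rng(7)
    for _ in range(1000):
        s = _random_snapshot(rng)
        st = diagonalize_dimer(s)
        e_d, e_a = s.donor.e_vert_ev, s.acceptor.e_vert_ev
        assert st.energies_ev.sum() == pytest.approx(e_d + e_a, abs=1e-10)
        mu2 = (np.dot(s.donor.mu_debye, s.donor.mu_debye)
               + np.dot(s.acceptor.mu_debye, s.acceptor.mu_debye))
        assert st.dipole_strengths.sum() == pytest.approx(mu2, abs=1e-8)
        assert st.rotational_strengths.sum() == pytest.approx(0.0, abs=1e-10)
        # closed-form 2x2 eigenvalues
        v_ev = s.v_cm1 * CM1_TO_EV
        mid, half = 0.5 * (e_d + e_a), 0.5 * (e_d - e_a)
        root = np.hypot(half, v_ev)
        assert st.energies_ev[0] == pytest.approx(mid - root, abs=1e-12)
        assert st.energies_ev[1] == pytest.approx(mid + root, abs=1e-12)


def test_uncoupled_limit():
    donor = _pigment("D", 2.0, [1, 0, 0], [0, 0, 0])
    acceptor = _pigment("A", 3.0, [0, 1, 0], [10, 0, 0])
    st = diagonalize_dimer(DimerSnapshot(donor, acceptor, 0.0, 10, 7, -47))
    np.testing.assert_allclose(st.energies_ev, [2.0, 3.0], atol=1e-14)
    np.testing.assert_allclose(np.abs(st.coefficients), np.eye(2), atol=1e-12)
    np.testing.assert_allclose(st.rotational_strengths, 0.0, atol=1e-14)


def test_resonant_splitting_is_2v():
    donor = _pigment("D", 2.5, [1, 0, 0], [0, 0, 0])
    acceptor = _pigment("A", 2.5, [0, 1, 0], [10, 0, 0])
    st = diagonalize_dimer(DimerSnapshot(donor, acceptor, 248.0, 10, 7, -47))
    split = (st.energies_ev[1] - st.energies_ev[0]) / CM1_TO_EV
    assert split == pytest.approx(2 * 248.0, rel=1e-12)


def test_collinear_dipoles_have_no_rotational_strength():
    donor = _pigment("D", 2.4, [0, 2, 0], [0, 0, 0])
    acceptor = _pigment("A", 2.6, [0, 5, 0], [8, 3, 1])
    st = diagonalize_dimer(DimerSnapshot(donor, acceptor, 300.0, 10, 7, -47))
    np.testing.assert_allclose(st.rotational_strengths, 0.0, atol=1e-12)


def test_point_dipole_coupling_reference_values():
    # parallel unit dipoles perpendicular to the separation: kappa = 1
    d = _pigment("D", 2.5, [0, 1, 0], [0, 0, 0])
    a = _pigment("A", 2.5, [0, 1, 0], [10, 0, 0])
    assert point_dipole_coupling(d, a) == pytest.approx(5.03411, rel=1e-5)
    # kappa = 0 geometry
    a_par = _pigment("A", 2.5, [1, 0, 0], [10, 0, 0])
    d_perp = _pigment("D", 2.5, [0, 0, 1], [0, 0, 0])
    assert point_dipole_coupling(d_perp, a_par) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(DomainError):
        point_dipole_coupling(d, _pigment("A", 2.5, [0, 1, 0], [0, 0, 0]))


def test_point_dipole_order_of_magnitude_for_table_geometry():
    """Best-case oriented dipoles at the real center distance give a coupling
    of the same order as the transition-density value (~248 cm^-1)."""
    d = _pigment("D", 2.53, [0, 0, 13.6], [0, 0, 0])
    a = _pigment("A", 2.33, [0, 0, 9.5], [16.7, 0, 0])
    v = abs(point_dipole_coupling(d, a))   # kappa = 1 here; 2 is the max
    assert 24.8 < 2 * v < 2480.0


@pytest.mark.parametrize("theta,tail,expected", [
    (62.0, "protein", "CL1"),
    (-47.0, "protein", "CL2"),
    (-47.0, "lipid", "CL3"),
    (0.0, "protein", "CL2"),
])
def test_classify_binding_mode(theta, tail, expected):
    assert classify_binding_mode(theta, tail) == expected


def test_classify_binding_mode_errors():
    with pytest.raises(DomainError):
        classify_binding_mode(-180.0, "protein")
    with pytest.raises(DomainError):
        classify_binding_mode(200.0, "protein")
    with pytest.raises(ConfigurationError):
        classify_binding_mode(10.0, "water")


@pytest.fixture(scope="module")
def cd_setup(time_grid_fs, energy_grid_ev):
    sd = carotenoid_sd(1787.0, label="site")
    sds = {"site": sd}
    donor = _pigment("D", 2.6, [0, 3, 0], [0, 0, 0], "site")
    # acceptor dipole orthogonal to the donor's: the absorption spectrum is
    # then invariant under V -> -V (for non-orthogonal dipoles the sign of V
    # relative to mu_D.mu_A redistributes oscillator strength between the
    # excitons, the H- vs J-aggregate distinction)
    acceptor = Pigment("A", 2.4, np.array([0.0, 0.0, 2.7]),
                       np.array([12.0, 0, 0]), np.array([7.0, 0, 0]), "site")
    snap = DimerSnapshot(donor, acceptor, 250.0, 12, 7, -47)
    return sds, donor, acceptor, snap


def test_single_uncoupled_snapshot_reduces_to_site_spectrum(
        cd_setup, time_grid_fs, energy_grid_ev):
    sds, donor, _, _ = cd_setup
    twin = Pigment("A", donor.e_vert_ev, donor.mu_debye,
                   np.array([10.0, 0, 0]), np.array([7.0, 0, 0]), "site")
    snap = DimerSnapshot(donor, twin, 0.0, 10, 7, -47)
    ab, cd = ensemble_spectra([snap], sds, 300.0, energy_grid_ev, time_grid_fs,
                              damping_fs=500.0)
    g = lineshape_g(sds["site"], 300.0, time_grid_fs)
    site = absorption_spectrum(g, donor.e_vert_ev, energy_grid_ev,
                               damping_fs=500.0)
    np.testing.assert_allclose(ab.intensity, site.intensity, atol=1e-3)
    np.testing.assert_allclose(cd.intensity, 0.0, atol=1e-12)


def test_cd_is_bisignate_and_flips_with_coupling_sign(
        cd_setup, time_grid_fs, energy_grid_ev):
    sds, donor, acceptor, snap = cd_setup
    ab1, cd1 = ensemble_spectra([snap], sds, 300.0, energy_grid_ev,
                                time_grid_fs, damping_fs=500.0)
    assert cd1.intensity.max() > 0 and cd1.intensity.min() < 0
    flipped = DimerSnapshot(donor, acceptor, -snap.v_cm1, 12, 7, -47)
    ab2, cd2 = ensemble_spectra([flipped], sds, 300.0, energy_grid_ev,
                                time_grid_fs, damping_fs=500.0)
    np.testing.assert_allclose(ab2.intensity, ab1.intensity, atol=1e-9)
    np.testing.assert_allclose(cd2.intensity, -cd1.intensity, atol=1e-9)


def test_cd_sign_convention_regression(cd_setup):
    """Right-handed reference geometry (positive chirality triple product,
    donor above acceptor, V>0): the upper, donor-rich exciton carries the
    positive rotational strength."""
    _, _, _, snap = cd_setup
    st = diagonalize_dimer(snap)
    chirality = np.dot(snap.acceptor.center_ang - snap.donor.center_ang,
                       np.cross(snap.donor.mu_debye, snap.acceptor.mu_debye))
    assert chirality > 0
    assert st.rotational_strengths[1] > 0 > st.rotational_strengths[0]


def test_missing_sd_raises(cd_setup, time_grid_fs, energy_grid_ev):
    _, donor, acceptor, snap = cd_setup
    with pytest.raises(ConfigurationError):
        ensemble_spectra([snap], {}, 300.0, energy_grid_ev, time_grid_fs)


def test_snapshot_io_round_trip(tmp_path, cd_setup):
    _, _, _, snap = cd_setup
    path = tmp_path / "snaps.tsv"
    write_snapshots([snap, snap], path)
    back = read_snapshots(path)
    assert len(back) == 2
    assert back[0].v_cm1 == pytest.approx(snap.v_cm1)
    assert back[0].binding_mode == snap.binding_mode
    np.testing.assert_allclose(back[0].donor.mu_debye, snap.donor.mu_debye)
    np.testing.assert_allclose(back[0].acceptor.center_ang,
                               snap.acceptor.center_ang)
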