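"""Exciton states and CD/LD/ACD band shapes.

The brute-force oracle below re-derives state properties from scratch
(explicit Hamiltonian assembly, per-pair chirality terms) independently
of the production code path.
"""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from baseplate.errors import SpectraError
from baseplate.spectra import (AxisSpec, Spectrum, compare_spectra,
                               exciton_states, point_dipole_coupling,
                               simulate_spectra)
from baseplate.structure_io import PigmentSite


def site(mg, dipole, normal=None, energy=12500.0, strength=37.0):
    d = np.asarray(dipole, float)
    d = d / np.linalg.norm(d)
    if normal is None:
        # any unit vector orthogonal to the dipole works as a ring normal
        trial = np.array([0.0, 0.0, 1.0])
        if abs(d @ trial) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        n = np.cross(d, trial)
        n /= np.linalg.norm(n)
    else:
        n = np.asarray(normal, float)
        n /= np.linalg.norm(n)
    return PigmentSite(np.asarray(mg, float), n, d, energy, strength)


def random_sites(rng, n=3, spread=25.0):
    sites = []
    while len(sites) < n:
        mg = rng.uniform(-spread, spread, 3)
        if any(np.linalg.norm(mg - s.mg_position) < 12.0 for s in sites):
            continue
        sites.append(site(mg, rng.normal(size=3),
                          energy=rng.uniform(12000, 13000),
                          strength=rng.uniform(20, 45)))
    return sites


class TestCoupling:
    def test_parallel_dipoles_perpendicular_to_r(self):
        a = site([0, 0, 0], [0, 0, 1])
        b = site([20, 0, 0], [0, 0, 1])
        v = point_dipole_coupling(a, b)
        # kappa = 1: V = 5.04 * 37 / 2^3
        assert v == pytest.approx(5.04 * 37.0 / 8.0, rel=1e-12)

    def test_head_to_tail_kappa_minus_two(self):
        a = site([0, 0, 0], [1, 0, 0])
        b = site([20, 0, 0], [1, 0, 0])
        v = point_dipole_coupling(a, b)
        assert v == pytest.approx(-2 * 5.04 * 37.0 / 8.0, rel=1e-12)

    def test_orthogonal_arrangement_zero(self):
        a = site([0, 0, 0], [1, 0, 0])   # along r
        b = site([20, 0, 0], [0, 0, 1])  # perpendicular to r
        assert point_dipole_coupling(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_coincident_sites_rejected(self):
        a = site([0, 0, 0], [0, 0, 1])
        b = site([1.0, 0, 0], [0, 0, 1])
        with pytest.raises(SpectraError):
            point_dipole_coupling(a, b)

    def test_r_cubed_decay(self, rng):
        sites = random_sites(rng, 3)
        h1 = exciton_states(sites)
        doubled = [site(2.0 * s.mg_position, s.qy_dipole_direction,
                        s.ring_normal, s.site_energy, s.dipole_strength)
                   for s in sites]
        for i in range(3):
            for j in range(i + 1, 3):
                v1 = point_dipole_coupling(sites[i], sites[j])
                v2 = point_dipole_coupling(doubled[i], doubled[j])
                assert v2 == pytest.approx(v1 / 8.0, rel=1e-12)


class TestExcitonStates:
    def test_degenerate_dimer_splitting(self):
        a = site([0, 0, 0], [0, 0, 1])
        b = site([15, 0, 0], [0, 0, 1])
        v = point_dipole_coupling(a, b)
        res = exciton_states([a, b])
        assert res.energies[1] - res.energies[0] == pytest.approx(2 * abs(v), rel=1e-10)
        assert res.energies[0] == pytest.approx(12500.0 - abs(v), rel=1e-10)

    def test_rotational_strength_sum_rule(self, rng):
        res = exciton_states(random_sites(rng, 5))
        total = res.rotational_strengths.sum()
        scale = np.abs(res.rotational_strengths).max()
        assert abs(total) < 1e-9 * max(scale, 1.0)

    def test_dipole_strength_conservation(self, rng):
        sites = random_sites(rng, 4)
        res = exciton_states(sites)
        assert res.dipole_strengths.sum() == pytest.approx(
            sum(s.dipole_strength for s in sites), rel=1e-9)
        # orthonormal coefficients
        np.testing.assert_allclose(res.coefficients @ res.coefficients.T,
                                   np.eye(4), atol=1e-9)

    def test_against_independent_brute_force(self, rng):
        """Energies/strengths re-derived with a from-scratch implementation."""
        sites = random_sites(rng, 3)
        res = exciton_states(sites)
        # oracle: build everything with explicit loops
        n = len(sites)
        H = np.zeros((n, n))
        for i in range(n):
            H[i, i] = sites[i].site_energy
            for j in range(n):
                if i != j:
                    ri, rj = sites[i].mg_position, sites[j].mg_position
                    r = rj - ri
                    dist = np.linalg.norm(r)
                    rh = r / dist
                    mi, mj = sites[i].qy_dipole_direction, sites[j].qy_dipole_direction
                    kappa = mi @ mj - 3 * (mi @ rh) * (mj @ rh)
                    H[i, j] = (5.04 * kappa
                               * np.sqrt(sites[i].dipole_strength
                                         * sites[j].dipole_strength)
                               / (dist / 10.0) ** 3)
        evals, evecs = np.linalg.eigh(H)
        np.testing.assert_allclose(res.energies, evals, rtol=1e-12)
        for k in range(n):
            c = evecs[:, k]
            mu = sum(c[i] * np.sqrt(sites[i].dipole_strength)
                     * sites[i].qy_dipole_direction for i in range(n))
            assert res.dipole_strengths[k] == pytest.approx(mu @ mu, abs=1e-9)
            rk = 0.0
            for i in range(n):
                for j in range(i + 1, n):
                    rij = sites[j].mg_position - sites[i].mg_position
                    mi = np.sqrt(sites[i].dipole_strength) * sites[i].qy_dipole_direction
                    mj = np.sqrt(sites[j].dipole_strength) * sites[j].qy_dipole_direction
                    rk += c[i] * c[j] * rij @ np.cross(mi, mj)
            rk *= np.pi * np.mean([s.site_energy for s in sites]) * 1e-8
            assert res.rotational_strengths[k] == pytest.approx(rk, abs=1e-12)

    def test_rotation_invariance_and_covariance(self, rng):
        sites = random_sites(rng, 4)
        rot = Rotation.from_rotvec(rng.normal(size=3))
        shift = np.array([7.0, -3.0, 11.0])
        moved = [site(rot.apply(s.mg_position) + shift,
                      rot.apply(s.qy_dipole_direction),
                      rot.apply(s.ring_normal), s.site_energy, s.dipole_strength)
                 for s in sites]
        r0 = exciton_states(sites)
        r1 = exciton_states(moved)
        np.testing.assert_allclose(r1.rotational_strengths,
                                   r0.rotational_strengths, atol=1e-9)
        # oriented strength is covariant: rotate the axis along
        axis = np.array([0.0, 0.0, 1.0])
        np.testing.assert_allclose(
            r1.oriented_rotational_strengths(rot.apply(axis)),
            r0.oriented_rotational_strengths(axis), atol=1e-9)

    def test_sphere_average_equals_isotropic(self, rng):
        """Lebedev-free check: average R(n) over a dense Fibonacci sphere."""
        res = exciton_states(random_sites(rng, 4))
        n_dir = 4000
        k = np.arange(n_dir)
        phi = np.pi * (3.0 - np.sqrt(5.0)) * k
        z = 1.0 - 2.0 * (k + 0.5) / n_dir
        r = np.sqrt(1 - z ** 2)
        dirs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
        avg = np.mean([res.oriented_rotational_strengths(d) for d in dirs], axis=0)
        np.testing.assert_allclose(avg, res.rotational_strengths,
                                   atol=1e-6 * max(np.abs(res.rotational_strengths).max(), 1.0))

    def test_enantiomer_negates_cd(self, rng):
        sites = random_sites(rng, 4)
        M = np.diag([-1.0, 1.0, 1.0])
        mirrored = [site(M @ s.mg_position, M @ s.qy_dipole_direction,
                         M @ s.ring_normal, s.site_energy, s.dipole_strength)
                    for s in sites]
        r0 = exciton_states(sites)
        r1 = exciton_states(mirrored)
        np.testing.assert_allclose(r1.energies, r0.energies, atol=1e-9)
        np.testing.assert_allclose(r1.rotational_strengths,
                                   -r0.rotational_strengths, atol=1e-9)
        np.testing.assert_allclose(r1.dipole_strengths, r0.dipole_strengths,
                                   atol=1e-9)


class TestSimulateSpectra:
    def test_single_site_absorption_peak_no_cd(self):
        s = site([0, 0, 0], [1, 0, 0], energy=12500.0)
        res = exciton_states([s])
        specs = simulate_spectra(res, fwhm_cm=200.0,
                                 axis=AxisSpec(750.0, 850.0, 501, "nm"))
        ab = specs["absorption"]
        peak_nm = ab.axis[np.argmax(ab.values)]
        assert abs(peak_nm - 1e7 / 12500.0) < 0.5
        assert np.allclose(specs["CD"].values, 0.0, atol=1e-12)

    def test_ld_weight_in_plane_dipole(self):
        # dipole perpendicular to the orientation axis: weight -D/2
        s = site([0, 0, 0], [1, 0, 0])
        res = exciton_states([s])
        specs = simulate_spectra(res, fwhm_cm=200.0,
                                 axis=AxisSpec(11500, 13500, 801, "cm-1"),
                                 order_parameter=1.0)
        ab = specs["absorption"].values
        mask = ab > 1e-6 * ab.max()
        ratio = specs["LD"].values[mask] / ab[mask]
        assert np.allclose(ratio, -0.5, atol=1e-6)

    def test_band_areas_match_strengths(self, rng):
        sites = random_sites(rng, 3)
        res = exciton_states(sites)
        specs = simulate_spectra(res, fwhm_cm=150.0,
                                 axis=AxisSpec(10500, 14500, 4001, "cm-1"))
        area = np.trapezoid(specs["absorption"].values, specs["absorption"].axis)
        assert area == pytest.approx(res.dipole_strengths.sum(), rel=1e-3)
        cd_area = np.trapezoid(specs["CD"].values, specs["CD"].axis)
        assert cd_area == pytest.approx(res.rotational_strengths.sum(),
                                        abs=1e-3 * np.abs(res.rotational_strengths).max())

    def test_spectrum_file_round_trip(self, tmp_path):
        spec = Spectrum(np.linspace(750, 850, 11), np.sin(np.linspace(0, 3, 11)),
                        "CD", "nm")
        spec.write(tmp_path / "cd.txt")
        back = Spectrum.read(tmp_path / "cd.txt")
        assert back.kind == "CD" and back.axis_unit == "nm"
        np.testing.assert_allclose(back.values, spec.values, rtol=1e-6)


class TestCompareSpectra:
    def _bisignate(self, flip=False, shift=0.0):
        ax = np.linspace(750.0, 850.0, 401)
        v = np.exp(-((ax - 790 - shift) / 12) ** 2) - np.exp(-((ax - 815 - shift) / 12) ** 2)
        return Spectrum(ax, -v if flip else v, "CD", "nm")

    def test_self_comparison(self):
        s = self._bisignate()
        m = compare_spectra(s, s)
        assert m.signs_match and m.zero_crossing_delta == 0.0 and m.rms_normalized == 0.0
        assert m.passes

    def test_negation_fails_sign_check(self):
        m = compare_spectra(self._bisignate(), self._bisignate(flip=True))
        assert not m.signs_match
        assert not m.passes

    def test_shifted_crossing_detected(self):
        m = compare_spectra(self._bisignate(), self._bisignate(shift=6.0))
        assert m.signs_match
        assert m.zero_crossing_delta == pytest.approx(6.0, abs=0.5)
        assert m.passes  # within the default 10 nm tolerance
        m2 = compare_spectra(self._bisignate(), self._bisignate(shift=15.0),
                             tolerance_nm=10.0)
        assert not m2.passes

    def test_no_overlap_raises(self):
        a = Spectrum(np.linspace(700, 750, 50), np.ones(50), "CD", "nm")
        b = Spectrum(np.linspace(800, 850, 50), np.ones(50), "CD", "nm")
        with pytest.raises(SpectraError):
            compare_spectra(a, b)
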