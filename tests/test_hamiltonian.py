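import numpy as np
import pytest

from amide2d.hamiltonian import (
    HamiltonianParams,
    NNCouplingMap,
    build_hamiltonian,
    load_default_nn_map,
    load_hamiltonian,
    nn_coupling,
    save_hamiltonian,
    site_energies,
    tdc_coupling,
    transition_dipole,
    two_exciton_block,
)
from amide2d.structures import AmideUnit, StructureError, backbone_dihedrals, extract_amide_units

from conftest import random_rotation


def unit_at(c, o, n, ca=None) -> AmideUnit:
    c, o, n = map(np.asarray, (c, o, n))
    ca = np.array([-1.5, 0.0, 0.0]) if ca is None else np.asarray(ca)
    h = n + np.array([0.0, -1.02, 0.0])
    return AmideUnit(index=1, c=c.astype(float), o=o.astype(float),
                     n=n.astype(float), h=h, ca=ca.astype(float),
                     label_index=2, label_name="ALA")


class TestSiteEnergies:
    def test_uniform_without_labels(self, conformers):
        units = extract_amide_units(conformers["Native"])
        eps = site_energies(units, HamiltonianParams())
        assert np.all(eps == 1660.0)

    def test_isotope_label_red_shift(self, conformers):
        units = extract_amide_units(conformers["Native"])
        params = HamiltonianParams(labeled_residues=frozenset({4}))
        eps = site_energies(units, params)
        labelled = [k for k, u in enumerate(units) if u.label_index == 4]
        assert len(labelled) == 1
        assert eps[labelled[0]] == 1660.0 - 65.0
        assert np.all(np.delete(eps, labelled[0]) == 1660.0)

    def test_label_outside_sequence_rejected(self, conformers):
        units = extract_amide_units(conformers["Native"])
        with pytest.raises(StructureError):
            site_energies(units, HamiltonianParams(labeled_residues=frozenset({25})))

    def test_disorder_statistics(self, conformers):
        units = extract_amide_units(conformers["Native"])
        params = HamiltonianParams(sigma_eps=5.0)
        rng = np.random.default_rng(42)
        draws = np.concatenate([site_energies(units, params, rng=rng) - 1660.0
                                for _ in range(600)])
        assert draws.size > 10000
        assert abs(draws.std() - 5.0) / 5.0 < 0.05

    def test_disorder_deterministic_per_seed(self, conformers):
        units = extract_amide_units(conformers["Native"])
        params = HamiltonianParams(sigma_eps=5.0, seed=9)
        assert np.array_equal(site_energies(units, params), site_energies(units, params))


class TestTransitionDipole:
    def test_zero_tilt_parallel_to_co(self):
        u = unit_at([0, 0, 0], [1.231, 0, 0], [0.8, -1.0, 0])
        mu, origin = transition_dipole(u, HamiltonianParams(dipole_tilt_deg=0.0))
        assert np.allclose(np.cross(mu, [1.0, 0, 0]), 0, atol=1e-10)
        assert np.allclose(origin, [0.868, 0, 0])

    def test_tilt_angle_exact(self):
        u = unit_at([0, 0, 0], [1.231, 0, 0], [0.8, -1.0, 0])
        mu, _ = transition_dipole(u, HamiltonianParams(dipole_tilt_deg=20.0))
        cosang = mu @ np.array([1.0, 0, 0]) / np.linalg.norm(mu)
        assert np.degrees(np.arccos(cosang)) == pytest.approx(20.0, abs=1e-6)
        # tilt is toward N (negative y half-plane here)
        assert mu[1] < 0

    def test_rigid_covariance(self, rng):
        u = unit_at([0, 0, 0], [1.231, 0, 0], [0.8, -1.0, 0])
        mu0, org0 = transition_dipole(u, HamiltonianParams())
        rot, t = random_rotation(rng)
        moved = AmideUnit(index=1, c=rot @ u.c + t, o=rot @ u.o + t,
                          n=rot @ u.n + t, h=rot @ u.h + t, ca=rot @ u.ca + t,
                          label_index=2, label_name="ALA")
        mu1, org1 = transition_dipole(moved, HamiltonianParams())
        assert np.allclose(mu1, rot @ mu0, atol=1e-10)
        assert np.allclose(org1, rot @ org0 + t, atol=1e-10)

    def test_collinear_geometry_rejected(self):
        u = unit_at([0, 0, 0], [1.231, 0, 0], [1.4, 0, 0])
        with pytest.raises(StructureError, match="degenerate"):
            transition_dipole(u, HamiltonianParams())


class TestTdc:
    def test_head_to_tail_closed_form(self):
        params = HamiltonianParams(dipole_tilt_deg=0.0)
        r = 10.0
        a = unit_at([0, 0, 0], [1.231, 0, 0], [0.8, -1.0, 0])
        b = unit_at([r, 0, 0], [r + 1.231, 0, 0], [r + 0.8, -1.0, 0])
        j = tdc_coupling(a, b, params)
        mu = params.dipole_magnitude
        expected = -2.0 * params.tdc_prefactor * mu ** 2 / r ** 3
        assert j == pytest.approx(expected, rel=1e-12)

    def test_perpendicular_zero(self):
        params = HamiltonianParams(dipole_tilt_deg=0.0)
        a = unit_at([0, 0, 0], [1.231, 0, 0], [0.8, -1.0, 0])
        # second dipole along y with its origin exactly 10 Å along z from
        # the first origin: both dipoles ⊥ r and mutually ⊥
        c_b = np.array([0.868, -0.868, 10.0])
        b = unit_at(c_b, c_b + [0, 1.231, 0], c_b + [-1.0, 0.8, 0])
        assert tdc_coupling(a, b, params) == pytest.approx(0.0, abs=1e-10)

    def test_inverse_cube_decay(self):
        params = HamiltonianParams(dipole_tilt_deg=0.0)
        a = unit_at([0, 0, 0], [1.231, 0, 0], [0.8, -1.0, 0])
        b1 = unit_at([10, 0, 0], [11.231, 0, 0], [10.8, -1.0, 0])
        # origins sit at c + 0.868 along x, so c at 20 doubles the separation
        far = 20.0
        b2 = unit_at([far, 0, 0], [far + 1.231, 0, 0], [far + 0.8, -1.0, 0])
        j1 = tdc_coupling(a, b1, params)
        j2 = tdc_coupling(a, b2, params)
        assert abs(j1 / j2) == pytest.approx(8.0, rel=1e-10)


class TestNNCoupling:
    def test_node_identity(self):
        m = load_default_nn_map()
        i, j = 4, 7
        assert nn_coupling(m.phi_grid[i], m.psi_grid[j], m) == pytest.approx(
            m.values[i, j], abs=1e-12)

    def test_midpoint_is_mean_of_four_nodes(self):
        m = load_default_nn_map()
        phi = 0.5 * (m.phi_grid[2] + m.phi_grid[3])
        psi = 0.5 * (m.psi_grid[5] + m.psi_grid[6])
        expected = np.mean([m.values[2, 5], m.values[3, 5], m.values[2, 6], m.values[3, 6]])
        assert nn_coupling(phi, psi, m) == pytest.approx(expected, abs=1e-12)

    def test_periodic_seam(self):
        m = load_default_nn_map()
        a = nn_coupling(179.9, 20.0, m)
        b = nn_coupling(-179.9, 20.0, m)
        assert a == pytest.approx(b, abs=0.1)

    def test_malformed_table_rejected(self):
        with pytest.raises(ValueError):
            NNCouplingMap(np.array([0.0, 30.0, 90.0]), np.array([0.0, 30.0]),
                          np.zeros((3, 2)))


class TestBuildHamiltonian:
    def test_tripeptide_manual_assembly(self):
        from amide2d.synthetic import MotifSpec, build_backbone
        phi = np.array([-100.0, -80.0, -60.0])
        psi = np.array([120.0, 100.0, 80.0])
        st = build_backbone(MotifSpec("custom", phi, psi, sequence="AAA"))
        m = load_default_nn_map()
        h = build_hamiltonian(st, HamiltonianParams(), map_table=m)
        assert h.matrix.shape == (2, 2)
        d = backbone_dihedrals(st)
        expected = nn_coupling(d.phi[1], d.psi[1], m)
        assert h.matrix[0, 1] == pytest.approx(expected, abs=1e-9)

    def test_19x19_for_beta3s(self, conformers):
        h = build_hamiltonian(conformers["Native"])
        assert h.matrix.shape == (19, 19)
        assert np.allclose(h.matrix, h.matrix.T)
        assert np.all((h.matrix.diagonal() > 1500) & (h.matrix.diagonal() < 1800))
        assert h.labels[0] == "Trp2" and h.labels[-1] == "Thr20"

    def test_rigid_motion_invariance(self, conformers, rng):
        nat = conformers["Native"]
        h0 = build_hamiltonian(nat)
        rot, t = random_rotation(rng)
        h1 = build_hamiltonian(nat.transformed(rot, t))
        assert np.max(np.abs(h1.matrix - h0.matrix)) < 1e-8

    def test_tdc_decay_beyond_15A(self, conformers):
        h = build_hamiltonian(conformers["Native"])
        n = h.n_sites
        far = []
        for a in range(n):
            for b in range(a + 2, n):
                if np.linalg.norm(h.origins[a] - h.origins[b]) > 15.0:
                    far.append(abs(h.matrix[a, b]))
        assert far and max(far) < 1.0

    def test_round_trip_text_format(self, conformers, tmp_path):
        h = build_hamiltonian(conformers["Native"])
        path = tmp_path / "h.txt"
        save_hamiltonian(h, path)
        back = load_hamiltonian(path)
        assert np.allclose(back.matrix, h.matrix, atol=1e-6)
        assert back.labels == h.labels


class TestTwoExciton:
    def test_single_site(self):
        h2 = two_exciton_block(np.array([[1650.0]]), 16.0)
        assert h2.matrix.shape == (1, 1)
        assert h2.matrix[0, 0] == pytest.approx(2 * 1650 - 16)

    def test_uncoupled_two_sites(self):
        h2 = two_exciton_block(np.diag([1650.0, 1660.0]), 16.0)
        assert sorted(np.diag(h2.matrix)) == pytest.approx([3284.0, 3304.0, 3310.0])
        assert np.allclose(h2.matrix, np.diag(np.diag(h2.matrix)))

    def test_symmetric_dimer_harmonic_eigenvalues(self):
        # brute-force diagonalization of the 3×3 block: eigenvalues must be
        # all pairwise sums of the one-exciton energies ε ± J
        eps, j = 1650.0, 8.0
        h1 = np.array([[eps, j], [j, eps]])
        e2 = np.sort(np.linalg.eigvalsh(two_exciton_block(h1, 0.0).matrix))
        assert e2 == pytest.approx([2 * eps - 2 * j, 2 * eps, 2 * eps + 2 * j])

    def test_harmonic_sum_rule_random(self, rng):
        for n in (2, 3, 5):
            h = rng.normal(1650, 12, size=(n, n))
            h = 0.5 * (h + h.T)
            e1 = np.linalg.eigvalsh(h)
            e2 = np.sort(np.linalg.eigvalsh(two_exciton_block(h, 0.0).matrix))
            sums = np.sort([e1[i] + e1[j] for i in range(n) for j in range(i, n)])
            assert np.allclose(e2, sums, atol=1e-8)

    def test_trace_identity(self, rng):
        h = rng.normal(1650, 10, size=(4, 4))
        h = 0.5 * (h + h.T)
        h2 = two_exciton_block(h, 12.0)
        assert np.trace(h2.matrix) == pytest.approx(np.sum(np.linalg.eigvalsh(h2.matrix)))

    def test_negative_anharmonicity_rejected(self):
        with pytest.raises(ValueError):
            two_exciton_block(np.array([[1650.0]]), -1.0)
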