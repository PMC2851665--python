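import numpy as np
import pytest

from amide2d.metrics import (
    ContactMap,
    backbone_rmsd,
    contact_map,
    dssp_string,
    kabsch_sander_hbonds,
    match_conformation,
    q_score,
    quintile_representatives,
    radius_of_gyration,
    sasa,
)
from amide2d.structures import Residue, Structure, StructureEnsemble, StructureError
from amide2d.synthetic import (
    REFERENCE_DSSP,
    EnsembleNoiseModel,
    MotifSpec,
    build_backbone,
    perturb_ensemble,
)

from conftest import random_rotation


class TestHydrogenBonds:
    def test_helix_has_i4_to_i_bonds(self, helix12):
        hb = kabsch_sander_hbonds(helix12)
        for i in range(2, 8):
            assert (i + 4, i) in hb

    def test_extended_chain_unbonded(self, extended20):
        assert kabsch_sander_hbonds(extended20) == set()

    def test_energy_vanishes_at_20A(self):
        # direct evaluation of the electrostatic model for a donor/acceptor
        # pair separated by 20 Å: far above the -0.5 kcal/mol threshold
        n = np.array([20.0, 0, 0])
        h = np.array([19.0, 0, 0])
        c = np.array([1.2, 0, 0])
        o = np.zeros(3)
        e = 0.084 * 332 * (1 / np.linalg.norm(o - n) + 1 / np.linalg.norm(c - h)
                           - 1 / np.linalg.norm(o - h) - 1 / np.linalg.norm(c - n))
        assert e > -0.5

    def test_hairpin_has_cross_strand_bonds(self, conformers):
        hb = kabsch_sander_hbonds(conformers["Native"])
        # designed antiparallel ladder: mutual bonds across both hairpins
        for pair in [(3, 10), (10, 3), (5, 8), (8, 5), (13, 16), (16, 13)]:
            assert pair in hb


class TestDssp:
    def test_helix_interior_is_H(self, helix12):
        ds = dssp_string(helix12)
        assert set(ds[2:-2]) == {"H"}

    def test_extended_chain_is_coil(self, extended20):
        assert set(dssp_string(extended20)) <= {"~"}

    def test_string_length_and_alphabet(self, conformers):
        for st in conformers.values():
            ds = dssp_string(st)
            assert len(ds) == 18
            assert set(ds) <= set("HGETS~")

    def test_native_string_matches_published(self, conformers):
        ds = dssp_string(conformers["Native"])
        ref = REFERENCE_DSSP["Native"]
        assert sum(a == b for a, b in zip(ds, ref)) >= 0.8 * len(ref)


class TestMatchConformation:
    def test_exact_native(self):
        assert match_conformation("EEEESSEEEEEESSEEEE", REFERENCE_DSSP, 0) == "Native"

    def test_helix_string(self):
        assert match_conformation("~HHHHHHHHHHHS~~~~~", REFERENCE_DSSP, 0) == "612 Helix"

    def test_no_match(self):
        assert match_conformation("~" * 18, REFERENCE_DSSP, 0) is None

    def test_ambiguous_match_is_error(self):
        refs = {"A": "EEEE", "B": "EESS"}
        with pytest.raises(StructureError, match="ambiguous"):
            match_conformation("EEES", refs, 2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(StructureError):
            match_conformation("EE", REFERENCE_DSSP, 0)


class TestContactsAndQ:
    def test_extended_chain_has_no_contacts(self, extended20):
        assert contact_map(extended20).n_contacts == 0

    def test_symmetry_and_separation(self, conformers):
        cm = contact_map(conformers["Native"])
        m = cm.matrix
        assert np.array_equal(m, m.T)
        assert not m.diagonal().any()
        n = m.shape[0]
        for i in range(n):
            for j in range(n):
                if abs(i - j) < 3:
                    assert not m[i, j]

    def test_hairpin_band_of_cross_strand_contacts(self, conformers):
        cm = contact_map(conformers["Native"]).matrix
        # residues paired across the first hairpin are in contact
        assert cm[4, 7] and cm[2, 9]   # (5,8) and (3,10), 0-based
        assert cm.sum() > 0

    def test_invalid_cutoff(self, extended20):
        with pytest.raises(StructureError):
            contact_map(extended20, cutoff=0.0)

    def test_native_self_q_is_one(self, conformers):
        nat = conformers["Native"]
        assert q_score(nat, contact_map(nat)) == pytest.approx(1.0)

    def test_extended_q_is_zero(self, conformers, extended20):
        nmap = contact_map(conformers["Native"])
        assert q_score(extended20, nmap) == 0.0

    def test_partial_q_matches_direct_count(self, conformers):
        nat = conformers["Native"]
        nmap = contact_map(nat)
        # move the C-terminal strand far away: only contacts not involving
        # residues 16-20 survive
        broken = nat.copy()
        for res in broken.residues[15:]:
            for name in res.atoms:
                res.atoms[name] = res.atoms[name] + np.array([50.0, 0, 0])
        # independent oracle: count surviving native CA-CA pairs directly
        ca = [r.atoms["CA"] for r in broken.residues]
        kept = 0
        total = 0
        for i in range(20):
            for j in range(i + 3, 20):
                if nmap.matrix[i, j]:
                    total += 1
                    if np.linalg.norm(ca[i] - ca[j]) <= 6.7:
                        kept += 1
        assert 0 < kept < total
        assert q_score(broken, nmap) == pytest.approx(kept / total)

    def test_empty_native_map_is_error(self, extended20):
        empty = contact_map(extended20)
        with pytest.raises(StructureError):
            q_score(extended20, empty)


def _bare_structure(atom_sets: list[dict[str, np.ndarray]]) -> Structure:
    residues = []
    for k, atoms in enumerate(atom_sets):
        residues.append(Residue("GLY", k + 1, {n: np.asarray(x, dtype=float)
                                               for n, x in atoms.items()}))
    return Structure(residues)


class TestRgAndSasa:
    def test_rg_unit_square(self):
        st = _bare_structure([{
            "N": [0, 0, 0], "CA": [1, 0, 0], "C": [1, 1, 0], "O": [0, 1, 0]}])
        assert radius_of_gyration(st) == pytest.approx(np.sqrt(2) / 2, abs=1e-12)

    def test_rg_rigid_motion_invariant(self, conformers, rng):
        nat = conformers["Native"]
        rot, t = random_rotation(rng)
        assert radius_of_gyration(nat.transformed(rot, t)) == pytest.approx(
            radius_of_gyration(nat), abs=1e-9)

    def test_sasa_isolated_spheres(self):
        st = _bare_structure([{
            "N": [0, 0, 0], "CA": [20, 0, 0], "C": [40, 0, 0], "O": [60, 0, 0]}])
        expected = sum(4 * np.pi * (r + 1.4) ** 2 for r in (1.55, 1.70, 1.70, 1.52))
        assert sasa(st) == pytest.approx(expected, rel=0.01)

    def test_sasa_two_sphere_overlap_analytic(self):
        # two equal carbon spheres (R = 1.7 + 1.4) at centre distance 3 Å;
        # exposed area each = 4πR² − 2πR(R − d/2)
        st = _bare_structure([{
            "N": [0, 0, 300], "CA": [0, 0, 0], "C": [3.0, 0, 0], "O": [0, 0, 600]}])
        r = 1.70 + 1.4
        pair = 2 * (4 * np.pi * r ** 2 - 2 * np.pi * r * (r - 1.5))
        singles = 4 * np.pi * (1.55 + 1.4) ** 2 + 4 * np.pi * (1.52 + 1.4) ** 2
        assert sasa(st) == pytest.approx(pair + singles, rel=0.02)

    def test_sasa_unknown_element(self):
        st = _bare_structure([{
            "N": [0, 0, 0], "CA": [2, 0, 0], "C": [4, 0, 0], "O": [6, 0, 0],
            "XX": [8, 0, 0]}])
        with pytest.raises(StructureError, match="unknown element"):
            sasa(st)


class TestRmsdAndQuintiles:
    def test_identity_and_rigid_motion(self, conformers, rng):
        nat = conformers["Native"]
        assert backbone_rmsd(nat, nat) == pytest.approx(0.0, abs=1e-10)
        rot, t = random_rotation(rng)
        assert backbone_rmsd(nat, nat.transformed(rot, t)) < 1e-8

    def test_symmetric(self, conformers):
        a, b = conformers["Native"], conformers["612 Helix"]
        assert backbone_rmsd(a, b) == pytest.approx(backbone_rmsd(b, a), abs=1e-9)

    def test_length_mismatch(self, conformers, helix12):
        with pytest.raises(StructureError):
            backbone_rmsd(conformers["Native"], helix12)

    def test_three_atom_toy_matches_brute_force(self):
        # structures differing by a single displaced atom: compare against a
        # brute-force minimization over rotations
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation
        a = _bare_structure([{
            "N": [0, 0, 0], "CA": [1.5, 0, 0], "C": [1.5, 1.5, 0], "O": [0, 1.5, 0]}])
        b = _bare_structure([{
            "N": [5, 2, 1], "CA": [6.5, 2, 1], "C": [6.5, 3.5, 1], "O": [5, 3.5, 2.0]}])

        xa = a.atom_coords() - a.atom_coords().mean(axis=0)
        xb = b.atom_coords() - b.atom_coords().mean(axis=0)

        def cost(v):
            diff = Rotation.from_rotvec(v).apply(xa) - xb
            return np.sqrt(np.mean(np.sum(diff ** 2, axis=1)))

        best = min(minimize(cost, x0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12}).fun
                   for x0 in ([0.1, 0, 0], [0, 0.1, 0], [1.0, 1.0, 1.0]))
        assert backbone_rmsd(a, b) == pytest.approx(best, abs=1e-5)

    def test_quintiles_of_five(self, helix12):
        ens = perturb_ensemble(helix12, EnsembleNoiseModel(sigma_coord=0.05, n=5, seed=3))
        reps = quintile_representatives(ens)
        assert len(reps) == 5

    def test_quintiles_of_ten_select_sorted_positions(self, helix12):
        ens = perturb_ensemble(helix12, EnsembleNoiseModel(sigma_coord=0.08, n=10, seed=5))
        m = len(ens)
        rmsd = np.zeros((m, m))
        for i in range(m):
            for j in range(m):
                if i != j:
                    rmsd[i, j] = backbone_rmsd(ens.members[i], ens.members[j])
        centroid = int(np.argmin(rmsd.sum(axis=1)))
        order = sorted(range(m), key=lambda i: (rmsd[centroid, i], i))
        expected = [ens.members[order[p]] for p in (0, 2, 4, 6, 8)]
        reps = quintile_representatives(ens)
        for want, got in zip(expected, reps):
            assert want is got

    def test_too_small_ensemble(self, helix12):
        ens = perturb_ensemble(helix12, EnsembleNoiseModel(sigma_coord=0.02, n=4, seed=0))
        with pytest.raises(StructureError):
            quintile_representatives(ens)


class TestRigidMotionInvariance:
    def test_fingerprint_invariant(self, conformers, rng):
        nat = conformers["Native"]
        nmap = contact_map(nat)
        ds0 = dssp_string(nat)
        sasa0 = sasa(nat)
        for _ in range(3):
            rot, t = random_rotation(rng)
            moved = nat.transformed(rot, t)
            assert dssp_string(moved) == ds0
            assert q_score(moved, nmap) == pytest.approx(1.0)
            assert abs(sasa(moved) - sasa0) / sasa0 < 0.01
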