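"""Synthetic peptide ensembles for the Beta3s folding-intermediate study.

This module builds idealized 20-residue backbones for the five Beta3s
conformations (native three-stranded antiparallel β-sheet, the two
out-of-register intermediates Ns-or and Cs-or, the Ch-curl state and the
6-12 helix) and turns a single conformer into a heterogeneous ensemble by
Gaussian coordinate jitter.  The jitter, together with optional site-energy
disorder applied later in the Hamiltonian stage, stands in for the
solvent/MD heterogeneity of fully solvated trajectories, which are not
modelled here.

Backbones are constructed residue by residue from internal coordinates
(fixed bond lengths/angles, caller-supplied φ/ψ/ω) and, for the folded
conformers, refined by a deterministic least-squares adjustment of the
dihedrals that pulls designated backbone hydrogen bonds to their canonical
N···O distance.  This is what makes the idealized sheets actually satisfy
Kabsch–Sander hydrogen-bond criteria and hence receive strand (E) secondary
structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize

from .structures import (
    ONE_TO_THREE,
    Residue,
    Structure,
    StructureEnsemble,
    StructureError,
    reconstruct_amide_h,
)

__all__ = [
    "BETA3S_SEQUENCE",
    "REFERENCE_DSSP",
    "MotifSpec",
    "EnsembleNoiseModel",
    "build_backbone",
    "make_beta3s_conformers",
    "perturb_ensemble",
]

#: The Beta3s sequence (Thr1 ... Thr20).
BETA3S_SEQUENCE = "TWIQNGSTKWYQNGSTKIYT"

#: Published per-conformation backbone secondary-structure strings
#: (18 characters, residues 2-19 of the 20-mer), used as matching references.
REFERENCE_DSSP = {
    "612 Helix": "~HHHHHHHHHHHS~~~~~",
    "Ns-or": "EEEESTTEEEEESSEEEE",
    "Cs-or": "EEEESSEEEEESSSEEEE",
    "Ch-Curl": "~~SSGGG~~~EESSEETT",
    "Native": "EEEESSEEEEEESSEEEE",
}

# Fixed internal geometry (Å / degrees) of the idealized backbone.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

# Canonical (φ, ψ) templates, degrees.
HELIX = (-57.0, -47.0)
STRAND = (-139.0, 135.0)
THREE_TEN = (-49.0, -26.0)
TURN_I_PRIME = [(60.0, 30.0), (90.0, 0.0)]   # 2-residue type-I' turn
TURN_I = [(-60.0, -30.0), (-90.0, 0.0)]      # 2-residue type-I turn


@dataclass
class MotifSpec:
    """Target dihedrals and sequence for one synthetic conformer."""

    kind: str
    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray | None = None
    sequence: str = BETA3S_SEQUENCE

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        n = len(self.sequence)
        if self.phi.shape != (n,) or self.psi.shape != (n,):
            raise StructureError(
                f"dihedral lists must match sequence length {n}")
        if self.omega is None:
            self.omega = np.full(n, 180.0)
        else:
            self.omega = np.asarray(self.omega, dtype=float)
            if self.omega.shape != (n,):
                raise StructureError("omega list length mismatch")


@dataclass
class EnsembleNoiseModel:
    """Coordinate jitter + (downstream) site-energy disorder settings.

    ``sigma_coord`` is the i.i.d. Gaussian standard deviation in Å applied
    to every Cartesian coordinate; ``sigma_eps`` (cm⁻¹) is carried along for
    the Hamiltonian stage; ``n`` is the ensemble size (the study condition
    is 500 structures per conformation).
    """

    sigma_coord: float = 0.05
    sigma_eps: float = 0.0
    n: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_coord < 0 or self.sigma_eps < 0:
            raise StructureError("noise std must be non-negative")
        if self.n < 1:
            raise StructureError("ensemble size must be >= 1")


def _place_atom_f(a, b, c, bond, angle_deg, torsion_deg):
    """Scalar-math NeRF step (hot path of the refinement objective)."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bcx, bcy, bcz = c[0] - b[0], c[1] - b[1], c[2] - b[2]
    r = math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx / r, bcy / r, bcz / r
    abx, aby, abz = b[0] - a[0], b[1] - a[1], b[2] - a[2]
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    r = math.sqrt(nx * nx + ny * ny + nz * nz)
    nx, ny, nz = nx / r, ny / r, nz / r
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    d0 = -bond * math.cos(angle)
    sa = bond * math.sin(angle)
    d1 = sa * math.cos(torsion)
    d2 = -sa * math.sin(torsion)
    return (c[0] + d0 * bcx + d1 * mx + d2 * nx,
            c[1] + d0 * bcy + d1 * my + d2 * ny,
            c[2] + d0 * bcz + d1 * mz + d2 * nz)


def _build_coords(phi: np.ndarray, psi: np.ndarray, omega: np.ndarray) -> dict[str, np.ndarray]:
    """Backbone N/CA/C/O coordinate arrays from dihedrals (termini φ/ψ that
    are geometrically undefined are simply not used)."""
    n_res = len(phi)
    N = [(0.0, 0.0, 0.0)] * n_res
    CA = [(0.0, 0.0, 0.0)] * n_res
    C = [(0.0, 0.0, 0.0)] * n_res
    O = [(0.0, 0.0, 0.0)] * n_res
    ang = math.radians(ANGLE_N_CA_C)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    C[0] = (BOND_N_CA - BOND_CA_C * math.cos(ang), BOND_CA_C * math.sin(ang), 0.0)
    for i in range(n_res - 1):
        N[i + 1] = _place_atom_f(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, psi[i])
        CA[i + 1] = _place_atom_f(CA[i], C[i], N[i + 1], BOND_N_CA, ANGLE_C_N_CA, omega[i])
        C[i + 1] = _place_atom_f(C[i], N[i + 1], CA[i + 1], BOND_CA_C, ANGLE_N_CA_C, phi[i + 1])
        O[i] = _place_atom_f(N[i + 1], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, 180.0)
    # last carbonyl O: anti to the ψ direction of the (virtual) next N
    O[-1] = _place_atom_f(N[-1], CA[-1], C[-1], BOND_C_O, ANGLE_CA_C_O, psi[-1] + 180.0)
    return {"N": np.array(N), "CA": np.array(CA), "C": np.array(C), "O": np.array(O)}


def _coords_to_structure(coords: dict[str, np.ndarray], sequence: str) -> Structure:
    n_res = len(sequence)
    residues = []
    for i in range(n_res):
        atoms = {k: coords[k][i].copy() for k in ("N", "CA", "C", "O")}
        if i > 0:
            atoms["H"] = reconstruct_amide_h(coords["C"][i - 1], coords["N"][i],
                                             coords["CA"][i])
        residues.append(Residue(name=ONE_TO_THREE[sequence[i]], index=i + 1, atoms=atoms))
    return Structure(residues)


def build_backbone(spec: MotifSpec) -> Structure:
    """Construct an idealized backbone realizing the spec's dihedrals.

    Recomputing φ/ψ from the returned coordinates reproduces the spec's
    values (interior residues) to well below 1e-4°.
    """
    coords = _build_coords(spec.phi, spec.psi, spec.omega)
    return _coords_to_structure(coords, spec.sequence)


# ---------------------------------------------------------------------------
# Beta3s conformer templates

def _template(n: int, assignments: dict[int, tuple[float, float]],
              default: tuple[float, float] = STRAND) -> tuple[np.ndarray, np.ndarray]:
    phi = np.full(n, default[0])
    psi = np.full(n, default[1])
    for i, (p, s) in assignments.items():   # 1-based residue numbers
        phi[i - 1] = p
        psi[i - 1] = s
    return phi, psi


def _turn(at: int, kind=TURN_I_PRIME) -> dict[int, tuple[float, float]]:
    """Two-residue turn occupying residues ``at`` and ``at+1``."""
    return {at: kind[0], at + 1: kind[1]}


def _hbond_objective(x: np.ndarray, spec: MotifSpec, donors: np.ndarray,
                     acceptors: np.ndarray, x0: np.ndarray, free: np.ndarray,
                     sep_mask: np.ndarray) -> float:
    n = len(spec.sequence)
    angles = x0.copy()
    angles[free] = x
    coords = _build_coords(angles[:n], angles[n:], spec.omega)
    # designated H-bonds pulled to the canonical N···O distance, with the
    # reconstructed amide H facing the acceptor (H···O near 1.9 Å)
    d = np.linalg.norm(coords["N"][donors] - coords["O"][acceptors], axis=-1)
    cost = float(np.sum((d - 2.9) ** 2))
    for k, dres in enumerate(donors):
        if dres == 0:
            continue
        u1 = coords["N"][dres] - coords["C"][dres - 1]
        u1 /= np.linalg.norm(u1)
        u2 = coords["N"][dres] - coords["CA"][dres]
        u2 /= np.linalg.norm(u2)
        bis = u1 + u2
        h = coords["N"][dres] + 1.02 * bis / np.linalg.norm(bis)
        dho = np.linalg.norm(h - coords["O"][acceptors[k]])
        cost += (dho - 1.9) ** 2
    # soft steric guard on non-local CA pairs
    ca = coords["CA"]
    dca = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    clash = np.clip(4.0 - dca[sep_mask], 0.0, None)
    cost += 0.5 * float(np.sum(clash ** 2))
    # keep dihedrals near their motif template
    cost += 1e-5 * float(np.sum((x - x0[free]) ** 2))
    return cost


def _refine(spec: MotifSpec, pair_bonds: list[tuple[int, int]],
            directed_bonds: tuple[tuple[int, int], ...] = (),
            frozen: set[int] = frozenset(), maxiter: int = 300) -> Structure:
    """Adjust φ/ψ so that the designated hydrogen bonds form.

    ``pair_bonds`` lists mutually H-bonded residue pairs (a, b) of an
    antiparallel ladder (N_a···O_b and N_b···O_a); ``directed_bonds`` lists
    single (donor, acceptor) bonds.  Residues in ``frozen`` keep their
    template dihedrals.  The optimization is deterministic.
    """
    bonds = list(directed_bonds)
    for a, b in pair_bonds:
        bonds.append((a, b))
        bonds.append((b, a))
    donors = np.array([d - 1 for d, _ in bonds], dtype=int)
    acceptors = np.array([a - 1 for _, a in bonds], dtype=int)
    n = len(spec.sequence)
    idx = np.arange(n)
    sep_mask = (idx[None, :] - idx[:, None]) >= 3
    x0 = np.concatenate([spec.phi, spec.psi])
    free_mask = np.ones(2 * n, dtype=bool)
    for r in frozen:
        free_mask[r - 1] = False
        free_mask[n + r - 1] = False
    free = np.where(free_mask)[0]
    res = minimize(_hbond_objective, x0[free],
                   args=(spec, donors, acceptors, x0, free, sep_mask),
                   method="L-BFGS-B", options={"maxiter": maxiter})
    angles = x0.copy()
    angles[free] = res.x
    refined = MotifSpec(kind=spec.kind, phi=angles[:n], psi=angles[n:],
                        omega=spec.omega, sequence=spec.sequence)
    return build_backbone(refined)


def _coil(rng: np.random.Generator, n: int) -> list[tuple[float, float]]:
    """Coil dihedrals drawn from a broad extended/polyproline-like basin."""
    phi = rng.uniform(-150.0, -60.0, size=n)
    psi = rng.uniform(100.0, 170.0, size=n)
    return list(zip(phi, psi))


@lru_cache(maxsize=8)
def make_beta3s_conformers(seed: int = 0) -> dict[str, Structure]:
    """Build the five synthetic Beta3s conformers.

    Native is a three-stranded antiparallel sheet (strands 1-5 / 8-13 /
    16-20 with turns at 6-7 and 14-15); Ns-or and Cs-or shift the pairing
    of the N-/C-terminal strand by two residues; Ch-curl keeps only the
    C-terminal hairpin with a curled (3₁₀-like) N-terminus; the 6-12 helix
    is helical at residues 6-12 and coil elsewhere.  Deterministic for a
    given seed; results are cached.
    """
    rng = np.random.default_rng(seed)
    n = len(BETA3S_SEQUENCE)
    out: dict[str, Structure] = {}

    # Native: turns at 6-7 and 14-15, antiparallel H-bond ladders.  Residue 1
    # has no amide H, so its pairing with 12 enters as the single 12→1 bond.
    phi, psi = _template(n, {**_turn(6), **_turn(14)})
    spec = MotifSpec("three_stranded_sheet", phi, psi)
    out["Native"] = _refine(
        spec, [(3, 10), (5, 8), (9, 20), (11, 18), (13, 16)],
        directed_bonds=((12, 1),))

    # Ns-or: N-terminal strand pairing slides by two; wider first loop
    # (residues 6-9) with a turn template at 7-8.
    phi, psi = _template(n, {**_turn(7), **_turn(14)})
    spec = MotifSpec("three_stranded_sheet", phi, psi)
    out["Ns-or"] = _refine(
        spec, [(3, 12), (5, 10), (9, 20), (11, 18), (13, 16)],
        directed_bonds=((14, 1),))

    # Cs-or: C-terminal strand pairing slides by two; wider second loop
    # (residues 14-17) with a type-I turn template at 15-16.
    phi, psi = _template(n, {**_turn(6), **_turn(15, TURN_I)})
    spec = MotifSpec("three_stranded_sheet", phi, psi)
    out["Cs-or"] = _refine(
        spec, [(3, 10), (5, 8), (11, 20), (13, 18)],
        directed_bonds=((12, 1),))

    # Ch-curl: curled 3₁₀-like N-terminus (consecutive i+3 turn bonds at
    # 5 and 6), C-terminal hairpin with inverted turn, trailing isolated turn.
    assign: dict[int, tuple[float, float]] = {i: THREE_TEN for i in range(5, 9)}
    assign.update(_turn(14, TURN_I))
    for i, d in zip((1, 2, 3, 4, 10, 11), _coil(rng, 6)):
        assign[i] = d
    phi, psi = _template(n, assign)
    spec = MotifSpec("curl", phi, psi)
    out["Ch-Curl"] = _refine(
        spec, [(13, 16)],
        directed_bonds=((8, 5), (9, 6), (18, 11), (20, 17)),
        frozen=set(range(5, 9)))

    # 6-12 helix: helical core, coil elsewhere.
    assign = {i: HELIX for i in range(6, 13)}
    for i, d in zip(list(range(1, 6)) + list(range(13, 21)), _coil(rng, 13)):
        assign[i] = d
    phi, psi = _template(n, assign)
    spec = MotifSpec("helix", phi, psi)
    out["612 Helix"] = build_backbone(spec)
    return out


def perturb_ensemble(structure: Structure, noise: EnsembleNoiseModel,
                     label: str = "") -> StructureEnsemble:
    """Gaussian-jittered copies of one conformer (seeded, reproducible)."""
    rng = np.random.default_rng(noise.seed)
    members = []
    for _ in range(noise.n):
        # rare multi-σ draws can push a peptide-bond length outside the
        # amide-unit validity window; those members are redrawn from the
        # same seeded stream so the ensemble stays reproducible
        for _attempt in range(100):
            m = structure.copy()
            if noise.sigma_coord > 0:
                for res in m.residues:
                    for name in res.atoms:
                        res.atoms[name] = res.atoms[name] + rng.normal(
                            0.0, noise.sigma_coord, size=3)
            if _amide_bonds_ok(m):
                break
        members.append(m)
    return StructureEnsemble(members=members, label=label)


def _amide_bonds_ok(structure: Structure) -> bool:
    res = structure.residues
    for i in range(len(res) - 1):
        d_co = np.linalg.norm(res[i].atoms["O"] - res[i].atoms["C"])
        d_cn = np.linalg.norm(res[i + 1].atoms["N"] - res[i].atoms["C"])
        if not (0.95 <= d_co <= 1.55 and 1.15 <= d_cn <= 1.55):
            return False
    return True
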