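"""Conformational fingerprinting of peptide structures.

Secondary structure is assigned with a reduced Kabsch–Sander scheme:
backbone hydrogen bonds are detected with the classic electrostatic energy
criterion, n-turns and bridge ladders are derived from them, and each
residue receives one letter from {H, G, E, T, S, ~} with priority
H > G > E > T > S.  The first and last residues are excluded from the
string (their φ/ψ are undefined), so a 20-mer yields an 18-character
string.  Isolated bridges are folded into E and π-helices are not
assigned.

The folding order parameter Q is the fraction of native CA-CA contacts
(default 6.7 Å cutoff, sequence separation ≥ 3) present in a query
structure.  Radius of gyration, Shrake–Rupley solvent-accessible surface
area, Kabsch-superposition backbone RMSD and quintile representative
selection complete the Table-style per-ensemble fingerprint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import Structure, StructureEnsemble, StructureError, extract_amide_units

__all__ = [
    "DSSP_ALPHABET",
    "ContactMap",
    "ConformationRecord",
    "kabsch_sander_hbonds",
    "dssp_string",
    "match_conformation",
    "contact_map",
    "q_score",
    "radius_of_gyration",
    "sasa",
    "backbone_rmsd",
    "quintile_representatives",
]

DSSP_ALPHABET = "HGETS~"

#: Kabsch–Sander electrostatic H-bond model: q1*q2*332 kcal/mol prefactor
#: and the -0.5 kcal/mol acceptance threshold.
_KS_PREFACTOR = 0.084 * 332.0
_KS_CUTOFF = -0.5

_VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}


@dataclass
class ContactMap:
    """Symmetric boolean residue-contact matrix with its defining cutoff."""

    matrix: np.ndarray
    cutoff: float
    min_sep: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=bool)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise StructureError("contact map must be square")
        if not np.array_equal(m, m.T) or m.diagonal().any():
            raise StructureError("contact map must be symmetric with empty diagonal")
        self.matrix = m

    @property
    def n_contacts(self) -> int:
        return int(self.matrix.sum()) // 2


@dataclass
class ConformationRecord:
    """Per-member fingerprint of one labelled ensemble."""

    label: str
    dssp: list[str]
    q: np.ndarray
    rg: np.ndarray
    sasa: np.ndarray
    matched: list[str | None]


# ---------------------------------------------------------------------------
# Hydrogen bonds and secondary structure

def _backbone_with_h(structure: Structure):
    """N, H, C, O coordinate arrays; H is NaN for residue 1 (no donor)."""
    units = extract_amide_units(structure)
    n = structure.n_residues
    N = np.array([r.atoms["N"] for r in structure.residues])
    C = np.array([r.atoms["C"] for r in structure.residues])
    O = np.array([r.atoms["O"] for r in structure.residues])
    H = np.full((n, 3), np.nan)
    for u in units:     # unit i carries N/H of residue i+1
        H[u.index] = u.h
    return N, H, C, O


def kabsch_sander_hbonds(structure: Structure) -> set[tuple[int, int]]:
    """Backbone H-bonds as (donor, acceptor) 1-based residue pairs.

    Donor i contributes its N-H, acceptor j its C=O; the pair is bonded iff
    the Kabsch–Sander electrostatic energy is below -0.5 kcal/mol.  The
    trivially covalent pairs j == i and j == i-1 are excluded, as is
    residue 1 as a donor (it has no amide hydrogen).
    """
    N, H, C, O = _backbone_with_h(structure)
    n = structure.n_residues
    bonds: set[tuple[int, int]] = set()
    for i in range(1, n):           # donor residue i+1 in 1-based terms
        for j in range(n):
            if j == i or j == i - 1:
                continue
            r_on = np.linalg.norm(O[j] - N[i])
            r_ch = np.linalg.norm(C[j] - H[i])
            r_oh = np.linalg.norm(O[j] - H[i])
            r_cn = np.linalg.norm(C[j] - N[i])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue            # clashing geometry, not a hydrogen bond
            energy = _KS_PREFACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            if energy < _KS_CUTOFF:
                bonds.add((i + 1, j + 1))
    return bonds


def _bend_flags(structure: Structure) -> np.ndarray:
    ca = np.array([r.atoms["CA"] for r in structure.residues])
    n = len(ca)
    bend = np.zeros(n, dtype=bool)
    for i in range(2, n - 2):
        u = ca[i] - ca[i - 2]
        v = ca[i + 2] - ca[i]
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        if np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))) > 70.0:
            bend[i] = True
    return bend


def dssp_string(structure: Structure) -> str:
    """Reduced DSSP assignment for residues 2..n-1 (termini excluded)."""
    n = structure.n_residues
    if n < 5:
        raise StructureError("need at least 5 residues for secondary structure")
    kabbonds = kabsch_sander_hbonds(structure)

    def bonded(donor: int, acceptor: int) -> bool:
        return (donor, acceptor) in kabbonds

    turns = {k: np.zeros(n + 1, dtype=bool) for k in (3, 4, 5)}
    for k in turns:
        for i in range(1, n - k + 1):
            if bonded(i + k, i):
                turns[k][i] = True

    letters = np.full(n, "~", dtype="<U1")

    # S: bends (lowest priority above coil)
    bend = _bend_flags(structure)
    letters[bend] = "S"

    # bridges first, so that turns can be tested for isolation below;
    # bridge_bonds collects the H-bonds realizing accepted ladders
    bridge = np.zeros(n + 1, dtype=bool)
    bridge_bonds: set[tuple[int, int]] = set()
    for i in range(1, n):
        for j in range(i + 3, n + 1):
            clauses = [
                ((i, j), (j, i)),              # antiparallel, narrow
                ((i + 1, j - 1), (j + 1, i - 1)),  # antiparallel, wide
                ((j, i - 1), (i + 1, j)),      # parallel
                ((i, j - 1), (j + 1, i)),      # parallel
            ]
            for b1, b2 in clauses:
                if bonded(*b1) and bonded(*b2):
                    bridge[i] = True
                    bridge[j] = True
                    bridge_bonds.add(b1)
                    bridge_bonds.add(b2)

    # T: isolated turns only — a turn whose H-bond doubles as a sheet-ladder
    # bond is part of the bridge, not an isolated turn
    for k in (3, 4, 5):
        for i in range(1, n - k + 1):
            if turns[k][i] and (i + k, i) not in bridge_bonds:
                for r in range(i + 1, i + k):
                    letters[r - 1] = "T"

    # E: parallel/antiparallel bridge ladders ('B' folded into 'E')
    letters[np.where(bridge[1:])[0]] = "E"

    # G then H override (priority H > G > E)
    for k, letter in ((3, "G"), (4, "H")):
        for i in range(1, n - k):
            if turns[k][i] and turns[k][i + 1]:
                for r in range(i + 1, i + k + 1):
                    letters[r - 1] = letter

    return "".join(letters[1:n - 1])


def match_conformation(dssp: str, references: dict[str, str],
                       max_mismatch: int = 3) -> str | None:
    """Label of the unique reference within Hamming distance max_mismatch."""
    lengths = {len(s) for s in references.values()}
    if lengths != {len(dssp)}:
        raise StructureError("reference strings must match the query length")
    dists = {label: sum(a != b for a, b in zip(dssp, ref))
             for label, ref in references.items()}
    qualifying = {lab: d for lab, d in dists.items() if d <= max_mismatch}
    if not qualifying:
        return None
    best = min(qualifying.values())
    winners = sorted(lab for lab, d in qualifying.items() if d == best)
    if len(winners) > 1:
        raise StructureError(
            f"ambiguous conformation match: {', '.join(winners)} at distance {best}")
    return winners[0]


# ---------------------------------------------------------------------------
# Contacts, Q, Rg, SASA

def contact_map(structure: Structure, cutoff: float = 6.7, min_sep: int = 3) -> ContactMap:
    """CA-CA contacts at the given distance cutoff and sequence separation."""
    if cutoff <= 0:
        raise StructureError("contact cutoff must be positive")
    ca = np.array([r.atoms["CA"] for r in structure.residues])
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    n = len(ca)
    sep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    m = (d <= cutoff) & (sep >= min_sep)
    return ContactMap(matrix=m, cutoff=cutoff, min_sep=min_sep)


def q_score(structure: Structure, native_map: ContactMap) -> float:
    """Fraction of native contacts present in the structure."""
    if native_map.n_contacts == 0:
        raise StructureError("native contact map is empty: Q undefined")
    if native_map.matrix.shape[0] != structure.n_residues:
        raise StructureError("native map size does not match structure")
    current = contact_map(structure, cutoff=native_map.cutoff,
                          min_sep=native_map.min_sep)
    shared = int(np.sum(current.matrix & native_map.matrix)) // 2
    return shared / native_map.n_contacts


def radius_of_gyration(structure: Structure) -> float:
    """Mass-unweighted RMS distance of the backbone atoms from their centroid (Å)."""
    coords = structure.atom_coords()
    centroid = coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((coords - centroid) ** 2, axis=-1))))


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=-1)


def sasa(structure: Structure, probe: float = 1.4, n_points: int = 960) -> float:
    """Shrake–Rupley solvent-accessible surface area (Å²) over all atoms."""
    atoms = structure.all_atoms()
    coords = np.array([xyz for _, _, xyz in atoms])
    radii = np.empty(len(atoms))
    for k, (res, name, _) in enumerate(atoms):
        element = name[0]
        if element not in _VDW_RADII:
            raise StructureError(
                f"unknown element {element!r} for atom {name} in residue "
                f"{res.name}{res.index}")
        radii[k] = _VDW_RADII[element] + probe
    pts = _sphere_points(n_points)
    total = 0.0
    for k in range(len(atoms)):
        shell = coords[k] + radii[k] * pts
        exposed = np.ones(n_points, dtype=bool)
        for j in range(len(atoms)):
            if j == k:
                continue
            if np.linalg.norm(coords[j] - coords[k]) > radii[k] + radii[j]:
                continue
            d2 = np.sum((shell - coords[j]) ** 2, axis=-1)
            exposed &= d2 > radii[j] ** 2
        total += exposed.mean() * 4.0 * np.pi * radii[k] ** 2
    return float(total)


# ---------------------------------------------------------------------------
# Superposition, clustering

def backbone_rmsd(a: Structure, b: Structure) -> float:
    """Backbone (N, CA, C, O) RMSD after optimal Kabsch superposition (Å)."""
    if a.n_residues != b.n_residues:
        raise StructureError("structures must have the same residue count")
    xa = a.atom_coords()
    xb = b.atom_coords()
    xa = xa - xa.mean(axis=0)
    xb = xb - xb.mean(axis=0)
    rot, _ = Rotation.align_vectors(xb, xa)
    diff = rot.apply(xa) - xb
    return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=-1))))


def quintile_representatives(ensemble: StructureEnsemble) -> list[Structure]:
    """The floor-median member of each RMSD-to-centroid quintile.

    The centroid is the member minimizing its summed RMSD to all others;
    members are sorted ascending by RMSD to it (ties broken by member
    index) and split into five index-contiguous quintiles whose sizes
    differ by at most one.
    """
    m = len(ensemble)
    if m < 5:
        raise StructureError("need at least 5 members for quintile selection")
    rmsd = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            rmsd[i, j] = rmsd[j, i] = backbone_rmsd(ensemble.members[i],
                                                    ensemble.members[j])
    centroid = int(np.argmin(rmsd.sum(axis=1)))
    order = sorted(range(m), key=lambda i: (rmsd[centroid, i], i))
    chunks = np.array_split(np.array(order), 5)
    return [ensemble.members[int(ch[(len(ch) - 1) // 2])] for ch in chunks]
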