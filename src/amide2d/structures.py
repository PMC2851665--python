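"""Peptide structure data model, PDB I/O and backbone geometry.

The central objects are :class:`Structure` (a single-chain peptide backbone),
:class:`StructureEnsemble` (an ordered conformational ensemble sharing one
sequence) and :class:`AmideUnit` (one peptide bond's C=O/N-H group, the local
site of the amide-I exciton model).  A chain of N residues carries exactly
N - 1 amide units; following the convention used throughout the package, the
unit between residues i and i+1 is labelled by residue i+1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "Residue",
    "Structure",
    "StructureEnsemble",
    "AmideUnit",
    "BackboneDihedrals",
    "StructureError",
    "read_pdb",
    "write_pdb",
    "extract_amide_units",
    "backbone_dihedrals",
    "dihedral_angle",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class StructureError(ValueError):
    """Raised for malformed or inconsistent structural input."""


@dataclass
class Residue:
    """One residue: a name, an index and a dict of atom coordinates (Å)."""

    name: str
    index: int
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    def copy(self) -> "Residue":
        return Residue(self.name, self.index,
                       {k: np.array(v, dtype=float) for k, v in self.atoms.items()})


@dataclass
class Structure:
    """A single-chain peptide backbone.

    Every residue must carry the backbone atoms N, CA, C and O; the amide
    hydrogen H is optional and is reconstructed geometrically where needed.
    """

    residues: list[Residue]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.residues:
            raise StructureError("structure has no residues")
        prev = None
        for res in self.residues:
            for name in BACKBONE_ATOMS:
                if name not in res.atoms:
                    raise StructureError(
                        f"residue {res.name}{res.index} is missing backbone atom {name}")
            for name, xyz in res.atoms.items():
                xyz = np.asarray(xyz, dtype=float)
                if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
                    raise StructureError(
                        f"residue {res.name}{res.index} atom {name} has invalid coordinates")
                res.atoms[name] = xyz
            if prev is not None and res.index <= prev:
                raise StructureError("residue indices must be strictly increasing")
            prev = res.index

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(THREE_TO_ONE.get(r.name, "X") for r in self.residues)

    def atom_coords(self, names: tuple[str, ...] = BACKBONE_ATOMS) -> np.ndarray:
        """Stacked coordinates of the given atom names, chain order."""
        return np.array([r.atoms[n] for r in self.residues for n in names if n in r.atoms])

    def all_atoms(self) -> list[tuple[Residue, str, np.ndarray]]:
        return [(r, n, xyz) for r in self.residues for n, xyz in r.atoms.items()]

    def copy(self) -> "Structure":
        return Structure([r.copy() for r in self.residues])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigidly moved copy (x -> R x + t)."""
        out = self.copy()
        for res in out.residues:
            for name in res.atoms:
                res.atoms[name] = rotation @ res.atoms[name] + translation
        return out


@dataclass
class StructureEnsemble:
    """Ordered list of conformers of one peptide."""

    members: list[Structure]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise StructureError("ensemble must be non-empty")
        seq = self.members[0].sequence
        for i, m in enumerate(self.members):
            if m.sequence != seq:
                raise StructureError(
                    f"ensemble member {i} sequence differs from member 0")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


@dataclass
class AmideUnit:
    """One peptide-bond amide group and its geometry.

    ``index`` runs 1..N-1 for an N-residue chain; ``label_index`` /
    ``label_name`` identify the C-terminal-side residue i+1 that labels the
    unit.  Coordinates are in Å: the carbonyl C and O belong to residue i,
    the amide N and H to residue i+1; ``ca`` is the CA of residue i.
    """

    index: int
    c: np.ndarray
    o: np.ndarray
    n: np.ndarray
    h: np.ndarray
    ca: np.ndarray
    label_index: int
    label_name: str

    def __post_init__(self) -> None:
        d_co = float(np.linalg.norm(self.o - self.c))
        d_cn = float(np.linalg.norm(self.n - self.c))
        if not (0.9 <= d_co <= 1.6):
            raise StructureError(
                f"amide unit {self.index}: C-O distance {d_co:.3f} Å outside 0.9-1.6 Å")
        if not (1.1 <= d_cn <= 1.6):
            raise StructureError(
                f"amide unit {self.index}: C-N distance {d_cn:.3f} Å outside 1.1-1.6 Å")


@dataclass
class BackboneDihedrals:
    """Per-residue φ/ψ in degrees, NaN where undefined (chain termini)."""

    phi: np.ndarray
    psi: np.ndarray


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, IUPAC convention, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def reconstruct_amide_h(c_prev: np.ndarray, n: np.ndarray, ca: np.ndarray,
                        bond: float = 1.02) -> np.ndarray:
    """Place the amide hydrogen on N, in the C-N-CA plane opposite both
    heavy-atom neighbours (external bisector), at the given N-H bond length."""
    u1 = n - c_prev
    u1 = u1 / np.linalg.norm(u1)
    u2 = n - ca
    u2 = u2 / np.linalg.norm(u2)
    d = u1 + u2
    nrm = np.linalg.norm(d)
    if nrm < 1e-8:
        raise StructureError("degenerate geometry: cannot place amide H")
    return n + bond * d / nrm


def extract_amide_units(structure: Structure) -> list[AmideUnit]:
    """Extract the N-1 amide units of an N-residue chain, in chain order.

    The amide H of residue i+1 is taken from the input when present and
    reconstructed geometrically otherwise.
    """
    if structure.n_residues < 2:
        raise StructureError("need at least 2 residues to form an amide unit")
    units = []
    for i in range(structure.n_residues - 1):
        ri, rj = structure.residues[i], structure.residues[i + 1]
        if "H" in rj.atoms:
            h = rj.atoms["H"]
        else:
            h = reconstruct_amide_h(ri.atoms["C"], rj.atoms["N"], rj.atoms["CA"])
        units.append(AmideUnit(
            index=i + 1,
            c=ri.atoms["C"], o=ri.atoms["O"],
            n=rj.atoms["N"], h=h, ca=ri.atoms["CA"],
            label_index=rj.index, label_name=rj.name,
        ))
    return units


def backbone_dihedrals(structure: Structure) -> BackboneDihedrals:
    """φ_i from C_{i-1},N_i,CA_i,C_i and ψ_i from N_i,CA_i,C_i,N_{i+1};
    NaN at the termini where the flanking atom does not exist."""
    n = structure.n_residues
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    res = structure.residues
    for i in range(n):
        if i > 0:
            phi[i] = dihedral_angle(res[i - 1].atoms["C"], res[i].atoms["N"],
                                    res[i].atoms["CA"], res[i].atoms["C"])
        if i < n - 1:
            psi[i] = dihedral_angle(res[i].atoms["N"], res[i].atoms["CA"],
                                    res[i].atoms["C"], res[i + 1].atoms["N"])
    return BackboneDihedrals(phi=phi, psi=psi)


# ---------------------------------------------------------------------------
# PDB I/O (via gemmi)

def _structure_from_gemmi_model(model: gemmi.Model, path: str) -> Structure:
    chains = [ch for ch in model if len(ch) > 0]
    if len(chains) != 1:
        raise StructureError(
            f"{path}: expected a single chain, found {len(chains)}")
    residues = []
    for gres in chains[0]:
        atoms: dict[str, np.ndarray] = {}
        best_occ: dict[str, float] = {}
        for atom in gres:
            # alternate locations resolved to the highest-occupancy conformer
            if atom.name in atoms and atom.occ <= best_occ.get(atom.name, -1.0):
                continue
            atoms[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            best_occ[atom.name] = atom.occ
        residues.append(Residue(name=gres.name, index=gres.seqid.num, atoms=atoms))
    return Structure(residues)


def read_pdb(path: str) -> StructureEnsemble:
    """Read a (possibly multi-MODEL) PDB file into a StructureEnsemble.

    One ensemble member is produced per MODEL block; a file without MODEL
    records yields a single member.  Raises :class:`StructureError` naming
    the offending residue if any backbone atom is absent.
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no ATOM records found")
    members = [_structure_from_gemmi_model(model, str(path)) for model in st]
    if not any(m.n_residues for m in members):
        raise StructureError(f"{path}: no residues found")
    return StructureEnsemble(members=members, label=st.name or "")


def write_pdb(ensemble: StructureEnsemble | Structure, path: str) -> None:
    """Write an ensemble as a standard PDB with one MODEL block per member."""
    if isinstance(ensemble, Structure):
        ensemble = StructureEnsemble(members=[ensemble])
    st = gemmi.Structure()
    st.name = ensemble.label or "amide2d"
    for k, member in enumerate(ensemble.members, start=1):
        model = gemmi.Model(k)
        chain = gemmi.Chain("A")
        for res in member.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.index, " ")
            for name, xyz in res.atoms.items():
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(name[0])
                atom.pos = gemmi.Position(*map(float, xyz))
                atom.occ = 1.0
                gres.add_atom(atom)
            chain.add_residue(gres)
        model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)
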