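"""3D structure handling: I/O, partial charges, and rigid alignment.

Molecules are lightweight containers (elements, coordinates in angstrom,
partial charges in e, van der Waals parameters in kcal/mol) living in a
shared alignment frame. RDKit backs file parsing, substructure matching and
conformer embedding; the PEOE (Gasteiger) charge model and the Kabsch
superposition operate on the container directly.

Flexible-ligand docking is out of scope here: this module either accepts
externally aligned poses as-is or produces a rigid common-scaffold
superposition as a stand-in alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.spatial.transform import Rotation

__all__ = [
    "Atom",
    "Molecule",
    "StructureParseError",
    "ChargeParameterError",
    "GeometryError",
    "ScaffoldMatchError",
    "VDW_TABLE",
    "BENZIMIDAZOLE_SCAFFOLD_SMARTS",
    "read_structures",
    "write_sdf",
    "molecule_from_rdkit",
    "molecule_to_rdkit",
    "assign_gasteiger_charges",
    "kabsch_align",
    "common_scaffold_map",
    "embed_series",
    "align_to_reference",
]


class StructureParseError(ValueError):
    """A structure file record could not be parsed."""


class ChargeParameterError(KeyError):
    """An element lacks electronegativity parameters for PEOE."""


class GeometryError(ValueError):
    """Degenerate geometry for a superposition."""


class ScaffoldMatchError(ValueError):
    """A scaffold query matched zero times or ambiguously."""


#: Tripos-force-field-like vdW parameters: element -> (radius angstrom,
#: well depth kcal/mol). Overridable per atom or via ``vdw_table`` arguments.
VDW_TABLE = {
    "C": (1.70, 0.107),
    "H": (1.50, 0.042),
    "N": (1.55, 0.095),
    "O": (1.52, 0.116),
    "F": (1.47, 0.109),
    "S": (1.80, 0.314),
    "Cl": (1.75, 0.266),
}

#: N1-substituted 2-aryl benzimidazole core; matches every member of the
#: series exactly once (the substituted N1 breaks the ring symmetry).
BENZIMIDAZOLE_SCAFFOLD_SMARTS = "[#6]n1c(-[c])nc2ccccc21"


@dataclass
class Atom:
    element: str
    position: np.ndarray  # (3,) angstrom
    partial_charge: float = 0.0
    formal_charge: int = 0
    vdw_radius: float = 0.0
    vdw_epsilon: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be a finite 3-vector")
        if self.vdw_radius == 0.0 and self.element in VDW_TABLE:
            self.vdw_radius, self.vdw_epsilon = VDW_TABLE[self.element]


@dataclass
class Molecule:
    """Named atom set with bonds, in a shared cartesian frame."""

    name: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, float]] = field(default_factory=list)  # (i, j, order)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("molecule needs at least one atom")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @coords.setter
    def coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, float)
        for atom, pos in zip(self.atoms, xyz):
            atom.position = pos

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms])

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def total_formal_charge(self) -> int:
        return sum(a.formal_charge for a in self.atoms)

    def copy(self) -> "Molecule":
        return Molecule(
            self.name,
            [replace(a, position=a.position.copy()) for a in self.atoms],
            list(self.bonds),
        )


# --------------------------------------------------------------------------
# RDKit conversion and file I/O
# --------------------------------------------------------------------------

_BOND_ORDER = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
    Chem.BondType.AROMATIC: 1.5,
}


def molecule_from_rdkit(mol: Chem.Mol, name: str = "", conf_id: int = -1) -> Molecule:
    if mol.GetNumConformers() == 0:
        raise StructureParseError(f"molecule {name!r} has no 3D conformer")
    conf = mol.GetConformer(conf_id)
    atoms = []
    for atom in mol.GetAtoms():
        pos = conf.GetAtomPosition(atom.GetIdx())
        charge = 0.0
        if atom.HasProp("_TriposPartialCharge"):
            charge = atom.GetDoubleProp("_TriposPartialCharge")
        atoms.append(
            Atom(
                element=atom.GetSymbol(),
                position=np.array([pos.x, pos.y, pos.z]),
                partial_charge=charge,
                formal_charge=atom.GetFormalCharge(),
            )
        )
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _BOND_ORDER.get(b.GetBondType(), 1.0))
        for b in mol.GetBonds()
    ]
    return Molecule(name or (mol.GetProp("_Name") if mol.HasProp("_Name") else ""), atoms, bonds)


def molecule_to_rdkit(molecule: Molecule, sanitize: bool = True) -> Chem.Mol:
    rw = Chem.RWMol()
    for atom in molecule.atoms:
        a = Chem.Atom(atom.element)
        a.SetFormalCharge(atom.formal_charge)
        a.SetNoImplicit(True)
        rw.AddAtom(a)
    order_map = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
                 3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}
    for i, j, order in molecule.bonds:
        rw.AddBond(int(i), int(j), order_map.get(order, Chem.BondType.SINGLE))
    mol = rw.GetMol()
    mol.SetProp("_Name", molecule.name)
    if sanitize:
        Chem.SanitizeMol(mol)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for idx, atom in enumerate(molecule.atoms):
        conf.SetAtomPosition(idx, atom.position.tolist())
    mol.AddConformer(conf)
    return mol


def read_structures(path, fmt: Optional[str] = None) -> list[Molecule]:
    """Read a multi-record V2000 SDF or Tripos MOL2 file.

    MOL2 partial charges are preserved on ``partial_charge``. A malformed
    record raises :class:`StructureParseError` naming its index.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        molecules = []
        for idx, mol in enumerate(supplier):
            if mol is None:
                raise StructureParseError(f"unparseable SDF record at index {idx} in {path}")
            molecules.append(molecule_from_rdkit(mol))
        if not molecules:
            raise StructureParseError(f"no records found in {path}")
        return molecules
    if fmt == "mol2":
        return _read_mol2(path)
    raise ValueError(f"unsupported structure format: {fmt!r}")


def _read_mol2(path: Path) -> list[Molecule]:
    text = path.read_text()
    blocks = ["@<TRIPOS>MOLECULE" + b for b in text.split("@<TRIPOS>MOLECULE")[1:]]
    if not blocks:
        raise StructureParseError(f"no MOL2 records found in {path}")
    molecules = []
    for idx, block in enumerate(blocks):
        mol = Chem.MolFromMol2Block(block, removeHs=False, sanitize=False)
        if mol is None:
            raise StructureParseError(f"unparseable MOL2 record at index {idx} in {path}")
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            pass  # keep unsanitized geometry; charges/coords are still valid
        molecules.append(molecule_from_rdkit(mol))
    return molecules


def write_sdf(molecules: Sequence[Molecule], path) -> None:
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    for molecule in molecules:
        writer.write(molecule_to_rdkit(molecule))
    writer.close()


# --------------------------------------------------------------------------
# PEOE partial charges
# --------------------------------------------------------------------------

#: Electronegativity polynomial chi(q) = a + b q + c q^2 per (element,
#: sigma hybridisation): standard PEOE parameterisation, kcal-free units.
_PEOE_PARAMS = {
    ("H", "sp3"): (7.17, 6.24, -0.56),
    ("C", "sp3"): (7.98, 9.18, 1.88),
    ("C", "sp2"): (8.79, 9.32, 1.51),
    ("C", "sp"): (10.39, 9.45, 0.73),
    ("N", "sp3"): (11.54, 10.82, 1.36),
    ("N", "sp2"): (12.87, 11.15, 0.85),
    ("N", "sp"): (15.68, 11.70, -0.27),
    ("O", "sp3"): (14.18, 12.92, 1.39),
    ("O", "sp2"): (17.07, 13.79, 0.47),
    ("F", "sp3"): (14.66, 13.85, 2.31),
}
_H_CHI_PLUS = 20.02


def _hybridisations(molecule: Molecule) -> list[str]:
    max_order = [0.0] * len(molecule.atoms)
    n_double = [0] * len(molecule.atoms)
    for i, j, order in molecule.bonds:
        for k in (i, j):
            max_order[k] = max(max_order[k], order)
            if order >= 2.0:
                n_double[k] += 1
    hyb = []
    for k, atom in enumerate(molecule.atoms):
        if max_order[k] >= 3.0 or n_double[k] >= 2:
            hyb.append("sp")
        elif max_order[k] >= 1.5:
            hyb.append("sp2")
        else:
            hyb.append("sp3")
    return hyb


def assign_gasteiger_charges(
    molecule: Molecule, n_iter: int = 6, damping: float = 0.5
) -> Molecule:
    """PEOE iterative partial equalisation of orbital electronegativity.

    Seeds atomic charges with formal charges, then per iteration ``k``
    transfers charge across each bond from the less to the more
    electronegative atom, proportional to the electronegativity difference
    and attenuated by ``damping**k``. Total charge is conserved by
    construction. Returns a new molecule; the input is untouched.
    """
    if not molecule.bonds and len(molecule.atoms) > 1:
        raise ValueError("charge assignment requires bonds")
    out = molecule.copy()
    hyb = _hybridisations(out)
    abc = np.empty((len(out.atoms), 3))
    chi_plus = np.empty(len(out.atoms))
    for k, atom in enumerate(out.atoms):
        key = (atom.element, "sp3" if atom.element in ("H", "F") else hyb[k])
        if key not in _PEOE_PARAMS:
            raise ChargeParameterError(
                f"no PEOE parameters for element {atom.element!r} ({hyb[k]})"
            )
        abc[k] = _PEOE_PARAMS[key]
        chi_plus[k] = _H_CHI_PLUS if atom.element == "H" else abc[k].sum()
    q = np.array([float(a.formal_charge) for a in out.atoms])
    for it in range(1, n_iter + 1):
        chi = abc[:, 0] + abc[:, 1] * q + abc[:, 2] * q * q
        dq = np.zeros_like(q)
        f = damping**it
        for i, j, _order in out.bonds:
            if chi[j] > chi[i]:
                t = (chi[j] - chi[i]) / chi_plus[i] * f
                dq[i] += t
                dq[j] -= t
            else:
                t = (chi[i] - chi[j]) / chi_plus[j] * f
                dq[j] += t
                dq[i] -= t
        q += dq
    for atom, charge in zip(out.atoms, q):
        atom.partial_charge = float(charge)
    return out


# --------------------------------------------------------------------------
# Rigid superposition
# --------------------------------------------------------------------------

def kabsch_align(
    mobile: Molecule, reference: Molecule, atom_map: Sequence[tuple[int, int]]
) -> tuple[Molecule, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    ``atom_map`` pairs (mobile index, reference index). The optimal proper
    rotation (no reflection) and translation over the mapped pairs are
    applied to every atom of ``mobile``. Returns the moved copy and the
    RMSD over the mapped pairs.
    """
    pairs = list(atom_map)
    if len(pairs) < 3:
        raise GeometryError("need at least 3 mapped atom pairs")
    mob = np.array([mobile.atoms[i].position for i, _ in pairs])
    ref = np.array([reference.atoms[j].position for _, j in pairs])
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2 or np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise GeometryError("mapped atoms are collinear")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    moved = mobile.copy()
    moved.coords = rot.apply(moved.coords - mob.mean(axis=0)) + ref.mean(axis=0)
    rmsd = float(np.sqrt(((rot.apply(mob_c) - ref_c) ** 2).sum(axis=1).mean()))
    return moved, rmsd


def common_scaffold_map(
    molecules: Sequence[Molecule], scaffold_smarts: str
) -> list[list[int]]:
    """Atom indices of a shared scaffold, in consistent query order.

    Every molecule must match the SMARTS exactly once; zero or multiple
    matches raise :class:`ScaffoldMatchError` listing the offenders.
    """
    query = Chem.MolFromSmarts(scaffold_smarts)
    if query is None:
        raise ValueError(f"invalid SMARTS: {scaffold_smarts!r}")
    maps = []
    offenders = []
    for molecule in molecules:
        rdmol = molecule_to_rdkit(molecule)
        matches = rdmol.GetSubstructMatches(query, uniquify=True)
        if len(matches) != 1:
            offenders.append((molecule.name, len(matches)))
            maps.append(None)
        else:
            maps.append(list(matches[0]))
    if offenders:
        detail = ", ".join(f"{name}: {n} matches" for name, n in offenders)
        raise ScaffoldMatchError(f"scaffold must match exactly once ({detail})")
    return maps


# --------------------------------------------------------------------------
# Conformer embedding and series alignment (input-producing conveniences)
# --------------------------------------------------------------------------

def embed_series(smiles_by_id: dict[str, str], seed: int = 2023) -> list[Molecule]:
    """Deterministic 3D conformers for a SMILES series (ETKDG + MMFF).

    Used to manufacture aligned-pose inputs when no externally docked poses
    are supplied; coordinates are reproducible for a given seed.
    """
    molecules = []
    for cid, smiles in smiles_by_id.items():
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise StructureParseError(f"bad SMILES for compound {cid}: {smiles!r}")
        mol = Chem.AddHs(mol)
        params = AllChem.ETKDGv3()
        params.randomSeed = seed
        if AllChem.EmbedMolecule(mol, params) != 0:
            raise StructureParseError(f"embedding failed for compound {cid}")
        AllChem.MMFFOptimizeMolecule(mol, maxIters=500)
        molecules.append(molecule_from_rdkit(mol, name=cid))
    return molecules


def align_to_reference(
    molecules: Sequence[Molecule],
    scaffold_smarts: str = BENZIMIDAZOLE_SCAFFOLD_SMARTS,
    reference_name: Optional[str] = None,
) -> tuple[list[Molecule], dict[str, float]]:
    """Superpose all molecules onto one reference via the common scaffold.

    The reference defaults to the first molecule; for the benzimidazole
    series the most active compound (39) is the conventional choice.
    """
    maps = common_scaffold_map(molecules, scaffold_smarts)
    names = [m.name for m in molecules]
    ref_idx = 0 if reference_name is None else names.index(reference_name)
    reference = molecules[ref_idx]
    ref_map = maps[ref_idx]
    aligned = []
    rmsds = {}
    for molecule, mol_map in zip(molecules, maps):
        pairs = list(zip(mol_map, ref_map))
        moved, rmsd = kabsch_align(molecule, reference, pairs)
        aligned.append(moved)
        rmsds[molecule.name] = rmsd
    return aligned, rmsds
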