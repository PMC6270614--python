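import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.spatial.transform import Rotation

from comfa.registry import load_benzimidazole_dataset
from comfa.structures import (
    BENZIMIDAZOLE_SCAFFOLD_SMARTS,
    Atom,
    GeometryError,
    Molecule,
    ScaffoldMatchError,
    StructureParseError,
    align_to_reference,
    assign_gasteiger_charges,
    common_scaffold_map,
    embed_series,
    kabsch_align,
    molecule_from_rdkit,
    read_structures,
    write_sdf,
)


def _rdkit_3d(smiles: str, name: str = "m", seed: int = 7) -> Molecule:
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    assert AllChem.EmbedMolecule(mol, params) == 0
    return molecule_from_rdkit(mol, name=name)


ETHANOL = "CCO"


# ----------------------------------------------------------------- charges

def test_peoe_matches_rdkit_oracle_on_ethanol():
    mol = _rdkit_3d(ETHANOL)
    ours = assign_gasteiger_charges(mol)
    rd = Chem.AddHs(Chem.MolFromSmiles(ETHANOL))
    AllChem.ComputeGasteigerCharges(rd)
    theirs = np.array([a.GetDoubleProp("_GasteigerCharge") for a in rd.GetAtoms()])
    assert np.max(np.abs(ours.charges - theirs)) < 0.01


def test_peoe_charge_conservation_on_series_member():
    _, _records = load_benzimidazole_dataset()
    mol = _rdkit_3d("Cc1ccc2nc(-c3cccnc3)n(Cc4cccc5ccccc45)c2c1")
    charged = assign_gasteiger_charges(mol)
    assert charged.charges.sum() == pytest.approx(mol.total_formal_charge(), abs=1e-10)
    # electronegative atoms pull density: every N and F ends up negative
    for atom in charged.atoms:
        if atom.element in ("N", "F"):
            assert atom.partial_charge < 0


def test_peoe_permutation_equivariance():
    mol = _rdkit_3d(ETHANOL)
    n = len(mol.atoms)
    perm = list(reversed(range(n)))
    inv = np.argsort(perm)
    permuted = Molecule(
        "perm",
        [Atom(mol.atoms[p].element, mol.atoms[p].position.copy(),
              formal_charge=mol.atoms[p].formal_charge) for p in perm],
        [(int(inv[i]), int(inv[j]), o) for i, j, o in mol.bonds],
    )
    q_direct = assign_gasteiger_charges(mol).charges
    q_perm = assign_gasteiger_charges(permuted).charges
    assert np.allclose(q_perm, q_direct[perm], atol=1e-12)


def test_peoe_leaves_input_untouched_and_requires_bonds():
    mol = _rdkit_3d(ETHANOL)
    before = mol.charges.copy()
    assign_gasteiger_charges(mol)
    assert np.array_equal(mol.charges, before)
    two_atoms = Molecule("x", [Atom("C", [0, 0, 0]), Atom("C", [1.5, 0, 0])])
    with pytest.raises(ValueError, match="bonds"):
        assign_gasteiger_charges(two_atoms)


# ----------------------------------------------------------------- alignment

@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_kabsch_recovers_rigid_motion(seed):
    rng = np.random.default_rng(seed)
    coords = rng.normal(size=(6, 3))
    ref = Molecule("ref", [Atom("C", c) for c in coords])
    rot = Rotation.random(rng=rng)
    shift = rng.normal(size=3) * 5
    mob = Molecule("mob", [Atom("C", c) for c in rot.apply(coords) + shift])
    moved, rmsd = kabsch_align(mob, ref, [(i, i) for i in range(6)])
    assert rmsd < 1e-8
    assert np.allclose(moved.coords, ref.coords, atol=1e-7)


def test_kabsch_is_idempotent():
    rng = np.random.default_rng(3)
    ref = Molecule("ref", [Atom("C", c) for c in rng.normal(size=(5, 3))])
    mob = Molecule("mob", [Atom("C", c) for c in rng.normal(size=(5, 3))])
    pairs = [(i, i) for i in range(5)]
    once, r1 = kabsch_align(mob, ref, pairs)
    twice, r2 = kabsch_align(once, ref, pairs)
    assert r2 == pytest.approx(r1, abs=1e-10)
    assert np.allclose(twice.coords, once.coords, atol=1e-9)


def test_kabsch_no_reflection():
    # a chiral 4-point set and its mirror image cannot be superposed exactly
    coords = np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 1.5, 0], [0, 0, 1.5]])
    ref = Molecule("ref", [Atom("C", c) for c in coords])
    mirrored = coords * np.array([1.0, 1.0, -1.0])
    mob = Molecule("mob", [Atom("C", c) for c in mirrored])
    _moved, rmsd = kabsch_align(mob, ref, [(i, i) for i in range(4)])
    assert rmsd > 0.5


def test_kabsch_input_validation():
    ref = Molecule("ref", [Atom("C", [float(i), 0, 0]) for i in range(4)])
    with pytest.raises(GeometryError, match="3 mapped"):
        kabsch_align(ref, ref, [(0, 0), (1, 1)])
    with pytest.raises(GeometryError, match="collinear"):
        kabsch_align(ref, ref, [(i, i) for i in range(4)])


def test_scaffold_unique_on_series_and_alignment(series):
    compounds, _ = series
    smiles = {c.id: c.smiles for c in compounds if c.id in ("39", "14", "23")}
    molecules = embed_series(smiles, seed=11)
    maps = common_scaffold_map(molecules, BENZIMIDAZOLE_SCAFFOLD_SMARTS)
    assert all(len(m) == 11 for m in maps)  # the SMARTS covers 11 core atoms
    aligned, rmsds = align_to_reference(
        molecules, BENZIMIDAZOLE_SCAFFOLD_SMARTS, reference_name="39"
    )
    assert rmsds["39"] == pytest.approx(0.0, abs=1e-8)
    assert max(rmsds.values()) < 1.0  # rigid core superposes closely
    # idempotence: re-aligning the aligned set is a no-op
    again, rmsds2 = align_to_reference(
        aligned, BENZIMIDAZOLE_SCAFFOLD_SMARTS, reference_name="39"
    )
    for a, b in zip(again, aligned):
        assert np.allclose(a.coords, b.coords, atol=1e-6)


def test_scaffold_mismatch_reports_offender():
    benzene = _rdkit_3d("c1ccccc1", name="benzene")
    with pytest.raises(ScaffoldMatchError, match="benzene: 0 matches"):
        common_scaffold_map([benzene], BENZIMIDAZOLE_SCAFFOLD_SMARTS)


def test_embed_series_deterministic():
    a = embed_series({"x": ETHANOL}, seed=5)[0]
    b = embed_series({"x": ETHANOL}, seed=5)[0]
    assert np.array_equal(a.coords, b.coords)


# ----------------------------------------------------------------- file I/O

def test_sdf_round_trip(tmp_path):
    molecules = [_rdkit_3d(ETHANOL, "eth"), _rdkit_3d("CC(=O)N", "acet")]
    path = tmp_path / "set.sdf"
    write_sdf(molecules, path)
    back = read_structures(path)
    assert [m.name for m in back] == ["eth", "acet"]
    for a, b in zip(molecules, back):
        assert a.elements == b.elements
        # V2000 stores coordinates to 4 decimal places
        assert np.allclose(a.coords, b.coords, atol=5e-5)
        assert sorted((i, j) for i, j, _ in a.bonds) == sorted(
            (i, j) for i, j, _ in b.bonds
        )


def test_mol2_read_preserves_charges(tmp_path):
    block = """@<TRIPOS>MOLECULE
methane
5 4 1
SMALL
USER_CHARGES
@<TRIPOS>ATOM
1 C1 0.0000 0.0000 0.0000 C.3 1 MOL -0.4000
2 H1 1.0900 0.0000 0.0000 H 1 MOL 0.1000
3 H2 -0.3633 1.0277 0.0000 H 1 MOL 0.1000
4 H3 -0.3633 -0.5138 0.8900 H 1 MOL 0.1000
5 H4 -0.3633 -0.5138 -0.8900 H 1 MOL 0.1000
@<TRIPOS>BOND
1 1 2 1
2 1 3 1
3 1 4 1
4 1 5 1
"""
    path = tmp_path / "methane.mol2"
    path.write_text(block)
    (mol,) = read_structures(path)
    assert mol.elements == ["C", "H", "H", "H", "H"]
    assert np.allclose(mol.charges, [-0.4, 0.1, 0.1, 0.1, 0.1])
    assert mol.charges.sum() == pytest.approx(0.0)


def test_read_structures_errors(tmp_path):
    bad = tmp_path / "bad.sdf"
    bad.write_text("not an sdf\n")
    with pytest.raises(StructureParseError):
        read_structures(bad)
    with pytest.raises(ValueError, match="unsupported"):
        read_structures(tmp_path / "x.pdbqt")


def test_atom_defaults_and_validation():
    a = Atom("C", [0, 0, 0])
    assert a.vdw_radius == pytest.approx(1.70)
    assert a.vdw_epsilon == pytest.approx(0.107)
    with pytest.raises(ValueError):
        Atom("C", [0, 0])
    with pytest.raises(ValueError):
        Atom("C", [0, 0, float("nan")])
    with pytest.raises(ValueError, match="at least one atom"):
        Molecule("empty", [])
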