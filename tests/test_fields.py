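import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comfa.fields import (
    COULOMB_CONSTANT,
    FieldSettings,
    GridSpec,
    ProbeSpec,
    assemble_matrix,
    build_lattice,
    column_filter,
    compute_field_block,
    electrostatic_field,
    steric_field,
)
from tests.conftest import make_molecule

PROBE = ProbeSpec()  # sp3 carbon, +1 e
SETTINGS = FieldSettings()


def single_point_grid(xyz):
    return GridSpec(origin=tuple(float(v) for v in xyz), spacing=1.0, dims=(1, 1, 1))


# --------------------------------------------------------------- closed forms

def test_steric_minimum_at_contact_distance():
    # single C atom: at r = r_C + r_probe the LJ term is exactly -eps_ij
    r_m = 1.70 + 1.52
    mol = make_molecule([[0.0, 0.0, 0.0]])
    energies, excluded = steric_field(mol, single_point_grid([r_m, 0, 0]), PROBE, SETTINGS)
    assert energies[0] == pytest.approx(-np.sqrt(0.107 * 0.107), rel=1e-12)
    assert not excluded[0]


def test_steric_cutoff_truncates_and_flags():
    mol = make_molecule([[0.0, 0.0, 0.0]])
    energies, excluded = steric_field(mol, single_point_grid([0.1, 0, 0]), PROBE, SETTINGS)
    assert energies[0] == pytest.approx(SETTINGS.energy_cutoff)
    assert SETTINGS.energy_cutoff == 30.0  # 125.46 kJ/mol in kcal/mol

    assert excluded[0]


def test_electrostatic_closed_form_distance_dependent():
    # q = +0.5 e at 4 angstrom, eps = r: E = 332.0716 * 0.5 / 16
    mol = make_molecule([[0.0, 0.0, 0.0]], charges=[0.5])
    e = electrostatic_field(mol, single_point_grid([4.0, 0, 0]), PROBE, SETTINGS)
    assert e[0] == pytest.approx(COULOMB_CONSTANT * 0.5 / 16.0, rel=1e-12)


def test_electrostatic_constant_dielectric():
    mol = make_molecule([[0.0, 0.0, 0.0]], charges=[-0.25])
    settings = FieldSettings(dielectric_model="constant", dielectric_constant=2.0)
    e = electrostatic_field(mol, single_point_grid([4.0, 0, 0]), PROBE, settings)
    assert e[0] == pytest.approx(COULOMB_CONSTANT * -0.25 / (2.0 * 4.0), rel=1e-12)


def test_electrostatic_clamped_to_cutoff_both_signs():
    grid = single_point_grid([0.05, 0, 0])
    for q in (2.0, -2.0):
        mol = make_molecule([[0.0, 0.0, 0.0]], charges=[q])
        e = electrostatic_field(mol, grid, PROBE, SETTINGS)
        assert abs(e[0]) == pytest.approx(SETTINGS.energy_cutoff)
        assert np.sign(e[0]) == np.sign(q)


def test_fields_additive_over_atoms():
    grid = GridSpec(origin=(-4.0, -4.0, -4.0), spacing=2.0, dims=(5, 5, 5))
    a = make_molecule([[0.9, 0.2, -0.3]], charges=[0.4])
    b = make_molecule([[-1.1, 0.7, 0.5]], charges=[-0.2])
    both = make_molecule([[0.9, 0.2, -0.3], [-1.1, 0.7, 0.5]], charges=[0.4, -0.2])
    loose = FieldSettings(energy_cutoff=1e9)  # disable clamping: pure superposition
    ea = electrostatic_field(a, grid, PROBE, loose)
    eb = electrostatic_field(b, grid, PROBE, loose)
    eab = electrostatic_field(both, grid, PROBE, loose)
    assert np.allclose(eab, ea + eb, rtol=1e-10)
    sa, _ = steric_field(a, grid, PROBE, loose)
    sb, _ = steric_field(b, grid, PROBE, loose)
    sab, _ = steric_field(both, grid, PROBE, loose)
    assert np.allclose(sab, sa + sb, rtol=1e-10)


@settings(max_examples=20, deadline=None)
@given(
    st.tuples(
        st.floats(-50, 50, allow_nan=False),
        st.floats(-50, 50, allow_nan=False),
        st.floats(-50, 50, allow_nan=False),
    )
)
def test_translation_equivariance(shift):
    shift = np.array(shift)
    mol = make_molecule([[0.3, -0.2, 0.9], [1.4, 0.8, -0.5]], charges=[0.3, -0.3])
    moved = make_molecule(mol.coords + shift, charges=[0.3, -0.3])
    grid = GridSpec(origin=(-3.0, -3.0, -3.0), spacing=2.0, dims=(4, 4, 4))
    grid_moved = GridSpec(
        origin=tuple(np.array(grid.origin) + shift), spacing=2.0, dims=(4, 4, 4)
    )
    s0, m0 = steric_field(mol, grid, PROBE, SETTINGS)
    s1, m1 = steric_field(moved, grid_moved, PROBE, SETTINGS)
    assert np.allclose(s0, s1, rtol=1e-9, atol=1e-12)
    assert np.array_equal(m0, m1)
    e0 = electrostatic_field(mol, grid, PROBE, SETTINGS)
    e1 = electrostatic_field(moved, grid_moved, PROBE, SETTINGS)
    assert np.allclose(e0, e1, rtol=1e-9, atol=1e-12)


# --------------------------------------------------------------- lattice

def test_lattice_encloses_atoms_with_margin():
    mol = make_molecule([[0.0, 0.0, 0.0], [7.3, 2.1, -3.8]])
    grid = build_lattice([mol], margin=4.0, spacing=2.0)
    lo = np.array(grid.origin)
    hi = lo + grid.spacing * (np.array(grid.dims) - 1)
    # margin sits exactly at the low edge; the high edge covers max + margin
    assert np.allclose(lo, mol.coords.min(axis=0) - 4.0)
    assert np.all(hi >= mol.coords.max(axis=0) + 4.0 - 1e-9)
    assert np.all(mol.coords >= lo) and np.all(mol.coords <= hi)


def test_grid_flat_ordering_is_x_major():
    grid = GridSpec(origin=(1.0, 2.0, 3.0), spacing=0.5, dims=(2, 3, 4))
    pts = grid.points()
    assert pts.shape == (24, 3)
    nx, ny, nz = grid.dims
    for ix, iy, iz in [(0, 0, 0), (1, 2, 3), (1, 0, 2)]:
        flat = ix * ny * nz + iy * nz + iz
        expected = np.array(grid.origin) + grid.spacing * np.array([ix, iy, iz])
        assert np.allclose(pts[flat], expected)


def test_grid_validation():
    with pytest.raises(ValueError):
        GridSpec(origin=(0, 0, 0), spacing=0.0, dims=(2, 2, 2))
    with pytest.raises(ValueError):
        GridSpec(origin=(0, 0, 0), spacing=1.0, dims=(2, 0, 2))
    with pytest.raises(ValueError, match="at least one molecule"):
        build_lattice([], margin=4.0)


# --------------------------------------------------------------- assembly

def _two_molecule_blocks():
    mols = [
        make_molecule([[0.0, 0.0, 0.0]], charges=[0.5], name="a"),
        make_molecule([[2.0, 0.0, 0.0]], charges=[-0.5], name="b"),
    ]
    grid = build_lattice(mols, margin=4.0, spacing=2.0)
    steric = compute_field_block(mols, grid, "steric", PROBE, SETTINGS)
    elec = compute_field_block(mols, grid, "electrostatic", PROBE, SETTINGS)
    return mols, grid, steric, elec


def test_assemble_matrix_ordering_and_labels():
    _mols, grid, steric, elec = _two_molecule_blocks()
    X, columns = assemble_matrix([elec, steric], SETTINGS)  # order-insensitive input
    n = grid.n_points
    assert X.shape == (2, 2 * n)
    assert columns[:n] == [("steric", j) for j in range(n)]
    assert columns[n:] == [("electrostatic", j) for j in range(n)]
    assert np.array_equal(X[:, :n], steric.matrix)


def test_excluded_points_take_column_mean():
    _mols, grid, steric, elec = _two_molecule_blocks()
    X, _ = assemble_matrix([steric, elec], SETTINGS)
    n = grid.n_points
    mask = steric.excluded_mask
    # at points excluded for one molecule only, its electrostatic entry
    # becomes the mean of the remaining (non-excluded) values in the column
    partial = mask.any(axis=0) & ~mask.all(axis=0)
    assert partial.any()
    j = int(np.nonzero(partial)[0][0])
    col_mask = mask[:, j]
    expected = elec.matrix[~col_mask, j].mean()
    assert np.allclose(X[col_mask, n + j], expected)
    # fully included columns pass through untouched
    clean = ~mask.any(axis=0)
    assert np.array_equal(X[:, n:][:, clean], elec.matrix[:, clean])


def test_assemble_matrix_rejects_mismatched_grids():
    mols = [make_molecule([[0.0, 0.0, 0.0]])]
    g1 = build_lattice(mols, margin=4.0, spacing=2.0)
    g2 = build_lattice(mols, margin=4.0, spacing=1.0)
    b1 = compute_field_block(mols, g1, "steric", PROBE, SETTINGS)
    b2 = compute_field_block(mols, g2, "electrostatic", PROBE, SETTINGS)
    with pytest.raises(ValueError, match="share one lattice"):
        assemble_matrix([b1, b2], SETTINGS)


def test_compute_field_block_unknown_type():
    mols = [make_molecule([[0.0, 0.0, 0.0]])]
    grid = build_lattice(mols)
    with pytest.raises(ValueError, match="unknown block"):
        compute_field_block(mols, grid, "hydrophobic", PROBE, SETTINGS)


def test_column_filter_threshold_semantics():
    # column {+10, -10} has population std exactly 10 and must survive sigma=2
    X = np.array([[10.0, 1.0, 0.0], [-10.0, 1.0, 2.0]])
    cols = [("steric", 0), ("steric", 1), ("steric", 2)]
    Xf, kept_cols, kept = column_filter(X, cols, 2.0)
    assert kept.tolist() == [0]
    assert kept_cols == [("steric", 0)]
    # sigma_min = 0 keeps everything, including constant columns
    Xf0, cols0, kept0 = column_filter(X, cols, 0.0)
    assert Xf0.shape == X.shape and len(cols0) == 3
    with pytest.raises(ValueError):
        column_filter(X, cols, -1.0)


def test_field_settings_validation():
    with pytest.raises(ValueError):
        FieldSettings(energy_cutoff=0.0)
    with pytest.raises(ValueError):
        FieldSettings(dielectric_model="vacuum")
    with pytest.raises(ValueError):
        FieldSettings(excluded_point_policy="drop")
    with pytest.raises(ValueError):
        ProbeSpec(vdw_radius=-1.0)
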