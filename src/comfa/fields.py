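"""Molecular interaction fields on a shared lattice.

Steric (Lennard-Jones) and electrostatic (Coulomb) probe energies are
evaluated at every point of a rectangular lattice enclosing an aligned
molecule set, then assembled into the molecules x (2 x lattice points)
descriptor matrix that feeds the PLS stage.

Units: angstrom and kcal/mol throughout. The conventional cutoff of
125.46 kJ/mol converts to 30.0 kcal/mol (at 4.184 kJ/kcal, to the three
significant figures both values carry) and is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .structures import Molecule

__all__ = [
    "ProbeSpec",
    "GridSpec",
    "FieldSettings",
    "FieldBlock",
    "build_lattice",
    "steric_field",
    "electrostatic_field",
    "compute_field_block",
    "assemble_matrix",
    "column_filter",
    "KJ_PER_KCAL",
]

KJ_PER_KCAL = 4.184

#: Coulomb constant in kcal angstrom mol^-1 e^-2.
COULOMB_CONSTANT = 332.0716


@dataclass(frozen=True)
class ProbeSpec:
    """The probe atom: sp3 carbon, +1 charge by default."""

    vdw_radius: float = 1.52
    vdw_epsilon: float = 0.107
    charge: float = 1.0

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0 or self.vdw_epsilon < 0:
            raise ValueError("probe radius must be positive and epsilon nonnegative")


@dataclass(frozen=True)
class GridSpec:
    """Rectangular lattice; flattened ordering is x-major, then y, then z
    (flat index = ix*ny*nz + iy*nz + iz)."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("dims must be positive")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """(n_points, 3) lattice coordinates in flat order."""
        axes = [
            self.origin[i] + self.spacing * np.arange(self.dims[i]) for i in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)


@dataclass(frozen=True)
class FieldSettings:
    energy_cutoff: float = 30.0  # kcal/mol (125.46 kJ/mol)
    dielectric_model: str = "distance_dependent"  # or "constant"
    dielectric_constant: float = 1.0
    coulomb_constant: float = COULOMB_CONSTANT
    margin: float = 4.0
    excluded_point_policy: str = "column_mean"  # or "cutoff_value"
    column_filter_sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.energy_cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.column_filter_sigma < 0:
            raise ValueError("column filter must be nonnegative")
        if self.dielectric_model not in ("distance_dependent", "constant"):
            raise ValueError(f"unknown dielectric model {self.dielectric_model!r}")
        if self.excluded_point_policy not in ("column_mean", "cutoff_value"):
            raise ValueError(f"unknown excluded-point policy {self.excluded_point_policy!r}")


@dataclass
class FieldBlock:
    """Per-probe-type energy matrix: molecules x lattice points, kcal/mol."""

    block: str  # "steric" | "electrostatic"
    matrix: np.ndarray
    excluded_mask: np.ndarray
    grid: GridSpec


def build_lattice(
    molecules: Sequence[Molecule], margin: float = 4.0, spacing: float = 2.0
) -> GridSpec:
    """Bounding-box lattice over all molecules, grown by ``margin`` per side.

    Per axis the range is [min - margin, max + margin] and the point count
    is ceil(range / spacing) + 1, so every atom lies inside the lattice hull.
    """
    if not molecules:
        raise ValueError("need at least one molecule")
    if margin < 0:
        raise ValueError("margin must be nonnegative")
    all_coords = np.vstack([m.coords for m in molecules])
    lo = all_coords.min(axis=0) - margin
    hi = all_coords.max(axis=0) + margin
    dims = tuple(int(np.ceil((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
    return GridSpec(origin=tuple(float(v) for v in lo), spacing=float(spacing), dims=dims)


def _distances(molecule: Molecule, grid: GridSpec) -> np.ndarray:
    pts = grid.points()
    d = np.linalg.norm(pts[None, :, :] - molecule.coords[:, None, :], axis=2)
    return np.maximum(d, 1e-9)  # probe on an atom center: maximal repulsion


def steric_field(
    molecule: Molecule,
    grid: GridSpec,
    probe: ProbeSpec = ProbeSpec(),
    settings: FieldSettings = FieldSettings(),
) -> tuple[np.ndarray, np.ndarray]:
    """Lennard-Jones probe energy per lattice point.

    E = sum_atoms eps_ij [ (r_m/r)^12 - 2 (r_m/r)^6 ] with r_m the sum of
    atom and probe vdW radii and eps_ij their geometric-mean well depth.
    Values above the cutoff are truncated to it and flagged excluded.
    Returns (energies, excluded_mask), each of length n_points.
    """
    d = _distances(molecule, grid)
    radii = np.array([a.vdw_radius for a in molecule.atoms])
    eps = np.array([a.vdw_epsilon for a in molecule.atoms])
    if np.any(radii <= 0):
        raise ValueError("atoms must carry positive vdW radii")
    r_m = (radii + probe.vdw_radius)[:, None]
    eps_ij = np.sqrt(eps * probe.vdw_epsilon)[:, None]
    x6 = (r_m / d) ** 6
    raw = (eps_ij * (x6 * x6 - 2.0 * x6)).sum(axis=0)
    excluded = raw > settings.energy_cutoff
    return np.minimum(raw, settings.energy_cutoff), excluded


def electrostatic_field(
    molecule: Molecule,
    grid: GridSpec,
    probe: ProbeSpec = ProbeSpec(),
    settings: FieldSettings = FieldSettings(),
) -> np.ndarray:
    """Coulomb probe energy per lattice point, clamped to +/- cutoff.

    E = k sum_i q_i q_probe / (eps(r_i) r_i); the dielectric is either
    distance-dependent (eps = r, the SYBYL-style default) or a constant.
    Substitution of values at sterically excluded points happens at matrix
    assembly, where the cross-molecule column context is available.
    """
    d = _distances(molecule, grid)
    q = molecule.charges[:, None]
    if settings.dielectric_model == "distance_dependent":
        denom = d * d
    else:
        denom = settings.dielectric_constant * d
    raw = settings.coulomb_constant * probe.charge * (q / denom).sum(axis=0)
    return np.clip(raw, -settings.energy_cutoff, settings.energy_cutoff)


def compute_field_block(
    molecules: Sequence[Molecule],
    grid: GridSpec,
    block: str,
    probe: ProbeSpec = ProbeSpec(),
    settings: FieldSettings = FieldSettings(),
) -> FieldBlock:
    """Stack one probe interaction type over a molecule set."""
    rows = []
    masks = []
    for molecule in molecules:
        st, excl = steric_field(molecule, grid, probe, settings)
        if block == "steric":
            rows.append(st)
        elif block == "electrostatic":
            rows.append(electrostatic_field(molecule, grid, probe, settings))
        else:
            raise ValueError(f"unknown block {block!r}")
        masks.append(excl)
    return FieldBlock(
        block=block,
        matrix=np.array(rows),
        excluded_mask=np.array(masks),
        grid=grid,
    )


def assemble_matrix(
    blocks: Sequence[FieldBlock],
    settings: FieldSettings = FieldSettings(),
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Concatenate field blocks into the descriptor matrix.

    Columns are ordered [steric | electrostatic], each labelled
    (block name, lattice index). In the electrostatic block, entries at
    sterically excluded points are replaced per the excluded-point policy:
    ``column_mean`` (mean of the non-excluded values in that column, the
    classic convention) or ``cutoff_value`` (keep the clamped value).
    """
    grids = {id(b.grid) for b in blocks}
    if len({(b.grid.origin, b.grid.spacing, b.grid.dims) for b in blocks}) != 1:
        raise ValueError("all field blocks must share one lattice")
    ordered = sorted(blocks, key=lambda b: 0 if b.block == "steric" else 1)
    pieces = []
    columns: list[tuple[str, int]] = []
    for fb in ordered:
        mat = fb.matrix.copy()
        if fb.block == "electrostatic" and settings.excluded_point_policy == "column_mean":
            mask = fb.excluded_mask
            for j in np.nonzero(mask.any(axis=0))[0]:
                col_mask = mask[:, j]
                if not col_mask.all():
                    mat[col_mask, j] = mat[~col_mask, j].mean()
        pieces.append(mat)
        columns.extend((fb.block, j) for j in range(mat.shape[1]))
    return np.hstack(pieces), columns


def column_filter(
    matrix: np.ndarray,
    columns: Sequence[tuple[str, int]],
    sigma_min: float = 2.0,
) -> tuple[np.ndarray, list[tuple[str, int]], np.ndarray]:
    """Drop lattice columns with energy standard deviation below sigma_min.

    Standard deviations are population values (ddof=0), in kcal/mol.
    Returns (filtered matrix, surviving column metadata, kept indices).
    """
    if sigma_min < 0:
        raise ValueError("sigma_min must be nonnegative")
    sd = matrix.std(axis=0, ddof=0)
    kept = np.nonzero(sd >= sigma_min)[0] if sigma_min > 0 else np.arange(matrix.shape[1])
    return matrix[:, kept], [columns[j] for j in kept], kept
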