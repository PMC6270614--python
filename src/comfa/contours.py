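"""Contour maps: stdev-times-coefficient fields and volumetric export.

A fitted PLS model is mapped back onto the lattice as beta_j * s_j per
point (s_j the training-data column standard deviation); iso-levels at
chosen percentiles of the nonzero value distribution mark regions where
bulk (steric, green/yellow by convention) or charge (electrostatic,
blue/red) favours or disfavours activity. Grids export as OpenDX or
Gaussian cube volumes readable by standard molecular viewers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .fields import GridSpec
from .pls import PlsModel

__all__ = [
    "ContourSet",
    "stdev_coeff_grid",
    "contour_levels",
    "export_grid",
    "read_dx",
    "BOHR_PER_ANGSTROM",
]

BOHR_PER_ANGSTROM = 1.8897259886


@dataclass
class ContourSet:
    block: str
    values: np.ndarray  # (nx, ny, nz)
    grid: GridSpec
    favored_level: float
    disfavored_level: float
    favored_pct: float
    disfavored_pct: float

    def __post_init__(self) -> None:
        if self.favored_level < self.disfavored_level:
            raise ValueError("favored level must be >= disfavored level")


def stdev_coeff_grid(
    model: PlsModel,
    X: np.ndarray,
    columns: Sequence[tuple[str, int]],
    grid: GridSpec,
    block: str,
) -> np.ndarray:
    """beta_j * s_j per lattice point for one field block, as (nx, ny, nz).

    Columns dropped by filtering (hence absent from ``columns``) contribute
    zero at their lattice points.
    """
    if len(columns) != len(model.coefficients):
        raise ValueError("column metadata does not match the model coefficients")
    s = np.asarray(X, float).std(axis=0, ddof=0)
    if np.asarray(X).shape[1] != len(columns):
        raise ValueError("descriptor matrix does not match the column metadata")
    flat = np.zeros(grid.n_points)
    for (blk, lattice_idx), beta, sj in zip(columns, model.coefficients, s):
        if blk != block:
            continue
        if lattice_idx >= grid.n_points:
            raise ValueError("column lattice index outside the grid")
        flat[lattice_idx] = beta * sj
    return flat.reshape(grid.dims)


def contour_levels(
    values: np.ndarray, favored_pct: float = 80.0, disfavored_pct: float = 20.0
) -> tuple[float, float]:
    """Iso-levels at percentiles of the nonzero value distribution.

    Percentiles use linear interpolation between order statistics. An
    all-zero grid yields (0, 0) with a degenerate-level warning.
    """
    flat = np.asarray(values, float).ravel()
    nonzero = flat[flat != 0.0]
    if nonzero.size == 0:
        warnings.warn("all-zero grid: contour levels degenerate", stacklevel=2)
        return 0.0, 0.0
    favored = float(np.percentile(nonzero, favored_pct))
    disfavored = float(np.percentile(nonzero, disfavored_pct))
    return favored, disfavored


def export_grid(values: np.ndarray, grid: GridSpec, path, fmt: str = "dx") -> None:
    """Write a volumetric grid as OpenDX (.dx, angstrom) or Gaussian cube
    (.cube, Bohr)."""
    values = np.asarray(values, float)
    if values.shape != tuple(grid.dims):
        raise ValueError(f"grid shape {values.shape} != dims {grid.dims}")
    if not np.all(np.isfinite(values)):
        raise ValueError("grid contains non-finite values")
    if fmt == "dx":
        _write_dx(values, grid, Path(path))
    elif fmt == "cube":
        _write_cube(values, grid, Path(path))
    else:
        raise ValueError(f"unsupported export format {fmt!r}")


def _write_dx(values: np.ndarray, grid: GridSpec, path: Path) -> None:
    nx, ny, nz = grid.dims
    ox, oy, oz = grid.origin
    h = grid.spacing
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {ox:.6f} {oy:.6f} {oz:.6f}",
        f"delta {h:.6f} 0.000000 0.000000",
        f"delta 0.000000 {h:.6f} 0.000000",
        f"delta 0.000000 0.000000 {h:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {values.size} data follows",
    ]
    flat = values.ravel()  # x-major, matching the lattice convention
    for start in range(0, flat.size, 3):
        chunk = flat[start : start + 3]
        lines.append(" ".join(f"{v:.6e}" for v in chunk))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "regular positions regular connections" class field')
    path.write_text("\n".join(lines) + "\n")


def read_dx(path) -> tuple[np.ndarray, GridSpec]:
    """Read back an OpenDX grid written by :func:`export_grid`."""
    lines = Path(path).read_text().splitlines()
    dims = tuple(int(v) for v in lines[0].split()[-3:])
    origin = tuple(float(v) for v in lines[1].split()[1:])
    spacing = float(lines[2].split()[1])
    data: list[float] = []
    reading = False
    for line in lines:
        if line.startswith("object 3"):
            reading = True
            continue
        if reading:
            if line.startswith("attribute") or line.startswith("object"):
                break
            data.extend(float(v) for v in line.split())
    grid = GridSpec(origin=origin, spacing=spacing, dims=dims)
    return np.array(data).reshape(dims), grid


def _write_cube(values: np.ndarray, grid: GridSpec, path: Path) -> None:
    nx, ny, nz = grid.dims
    b = BOHR_PER_ANGSTROM
    ox, oy, oz = (c * b for c in grid.origin)
    h = grid.spacing * b
    lines = [
        "comfa stdev*coeff grid",
        "volumetric field",
        # one dummy atom: cube files require at least the atom-count header
        f"{1:5d}{ox:12.6f}{oy:12.6f}{oz:12.6f}",
        f"{nx:5d}{h:12.6f}{0.0:12.6f}{0.0:12.6f}",
        f"{ny:5d}{0.0:12.6f}{h:12.6f}{0.0:12.6f}",
        f"{nz:5d}{0.0:12.6f}{0.0:12.6f}{h:12.6f}",
        f"{6:5d}{0.0:12.6f}{ox:12.6f}{oy:12.6f}{oz:12.6f}",
    ]
    flat = values.ravel()
    for start in range(0, flat.size, 6):
        chunk = flat[start : start + 6]
        lines.append("".join(f"{v:13.5e}" for v in chunk))
    path.write_text("\n".join(lines) + "\n")
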