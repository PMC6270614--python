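"""Synthetic aligned pseudo-molecule sets with a planted field-activity model.

The generator emulates the statistical structure the 3D-QSAR pipeline
assumes: a congeneric series sharing a rigid scaffold, varying only in a
few substituent-like atoms, whose activity is exactly linear in a sparse
set of field-descriptor columns plus Gaussian noise. Every pipeline stage
(field computation, matrix assembly, filtering, PLS, validation) is thereby
testable against a known ground truth without external structure data.

The planted support is restricted to steric columns with low mutual
correlation: the long-range electrostatic columns form a near-collinear
block on which a sparse planted direction would not be identifiable by any
regression, steric lattice columns decorrelate over a couple of grid
spacings. See the methods note for the reasoning behind the defaults.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .fields import (
    FieldSettings,
    ProbeSpec,
    assemble_matrix,
    build_lattice,
    column_filter,
    compute_field_block,
)
from .structures import Atom, Molecule

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "make_train_test_split"]

#: Rigid five-carbon scaffold shared by every generated pseudo-molecule.
_SCAFFOLD_COORDS = np.array(
    [[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [-1.5, 0.0, 0.0], [0.0, 1.5, 0.0], [0.0, 0.0, 1.5]]
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator conditions (defaults are the package's study conditions)."""

    n_molecules: int = 30
    n_variable_atoms: int = 4
    displacement_scale: float = 2.0  # angstrom, uniform box around the scaffold
    charge_range: float = 0.3  # e, uniform perturbation on variable atoms
    n_planted: int = 5  # planted support size (used when coefficients is None)
    planted_coefficients: Optional[dict[int, float]] = None  # filtered-column -> weight
    signal_sd: float = 1.5  # activity units, scale of the noiseless signal
    noise_sigma: float = 0.3  # activity units
    max_planted_corr: float = 0.4  # identifiability bound on planted columns
    spacing: float = 2.0
    margin: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 3:
            raise ValueError("need at least 3 molecules")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


@dataclass
class GroundTruth:
    """Planted model returned alongside the generated data."""

    coefficients: np.ndarray  # dense, over the filtered descriptor columns
    planted_columns: list[int]
    noiseless_activity: np.ndarray
    matrix: np.ndarray  # filtered descriptor matrix
    columns: list
    grid: object


def generate(
    spec: SyntheticSpec, settings: FieldSettings = FieldSettings()
) -> tuple[list[Molecule], np.ndarray, GroundTruth]:
    """Draw a pseudo-molecule series and activities from the planted model.

    Molecules share the scaffold (pre-aligned by construction); variable
    atoms get uniform positions within the displacement box, elements from
    {C, N, O, F} and partial charges uniform in +/- charge_range. Fields are
    computed with the standard engine, the descriptor matrix filtered at the
    configured sigma, and activity y = X w + N(0, sigma^2) with w supported
    on well-separated steric columns (or on ``planted_coefficients`` when
    given). All randomness flows through one seeded generator.
    """
    rng = np.random.default_rng(spec.seed)
    molecules = []
    for m in range(spec.n_molecules):
        atoms = [Atom("C", xyz.copy()) for xyz in _SCAFFOLD_COORDS]
        positions = rng.uniform(
            -spec.displacement_scale, spec.displacement_scale, size=(spec.n_variable_atoms, 3)
        )
        elements = rng.choice(["C", "N", "O", "F"], size=spec.n_variable_atoms)
        charges = rng.uniform(-spec.charge_range, spec.charge_range, size=spec.n_variable_atoms)
        for pos, el, q in zip(positions, elements, charges):
            atoms.append(Atom(str(el), pos, partial_charge=float(q)))
        molecules.append(Molecule(name=f"synth-{m:03d}", atoms=atoms))

    grid = build_lattice(molecules, margin=spec.margin, spacing=spec.spacing)
    steric = compute_field_block(molecules, grid, "steric", ProbeSpec(), settings)
    elec = compute_field_block(molecules, grid, "electrostatic", ProbeSpec(), settings)
    X_full, columns_full = assemble_matrix([steric, elec], settings)
    X, columns, _kept = column_filter(X_full, columns_full, settings.column_filter_sigma)

    w = np.zeros(X.shape[1])
    if spec.planted_coefficients is not None:
        for j, weight in spec.planted_coefficients.items():
            if not 0 <= j < X.shape[1]:
                raise ValueError(f"planted column {j} outside the filtered matrix")
            w[j] = weight
        planted = sorted(spec.planted_coefficients)
    else:
        planted = _pick_planted_columns(X, columns, spec)
        signs = np.array([1.0 if k % 2 == 0 else -1.0 for k in range(len(planted))])
        w[planted] = signs
    signal = X @ w
    sd = signal.std()
    if sd == 0:
        raise ValueError("planted signal has zero variance")
    scale = spec.signal_sd / sd
    w *= scale
    noiseless = signal * scale
    y = noiseless + rng.normal(0.0, spec.noise_sigma, size=spec.n_molecules)
    truth = GroundTruth(
        coefficients=w,
        planted_columns=list(planted),
        noiseless_activity=noiseless,
        matrix=X,
        columns=columns,
        grid=grid,
    )
    return molecules, y, truth


def _pick_planted_columns(X: np.ndarray, columns: list, spec: SyntheticSpec) -> list[int]:
    """Highest-variance steric columns subject to pairwise |r| < bound.

    Small molecule sets may not offer ``n_planted`` columns meeting the
    correlation bound; the support then shrinks to what is available (with a
    warning) rather than failing, and ``GroundTruth.planted_columns`` records
    the actual support.
    """
    steric_idx = [j for j, (block, _i) in enumerate(columns) if block == "steric"]
    order = sorted(steric_idx, key=lambda j: -X[:, j].std())
    picked: list[int] = []
    for j in order:
        ok = all(
            abs(np.corrcoef(X[:, j], X[:, k])[0, 1]) < spec.max_planted_corr for k in picked
        )
        if ok:
            picked.append(j)
        if len(picked) == spec.n_planted:
            break
    if not picked:
        raise ValueError("no steric columns survive filtering; enlarge the series")
    if len(picked) < spec.n_planted:
        warnings.warn(
            f"only {len(picked)} of {spec.n_planted} requested planted columns are "
            "available at the correlation bound; planting on those",
            stacklevel=2,
        )
    return picked


def make_train_test_split(
    ids: list,
    test_fraction: float,
    seed: int,
    activities: Optional[np.ndarray] = None,
) -> dict:
    """Deterministic seeded train/test partition, stratified by activity
    tertile when activities are supplied.

    Returns {id: "train" | "test"}.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(ids)
    n_test = max(1, round(n * test_fraction))
    if n_test >= n:
        raise ValueError("split leaves no training compounds")
    rng = np.random.default_rng(seed)
    if activities is None:
        test_idx = set(rng.choice(n, size=n_test, replace=False).tolist())
    else:
        activities = np.asarray(activities, float)
        order = np.argsort(activities)
        tertiles = np.array_split(order, 3)
        # allocate test picks proportionally across tertiles
        test_idx = set()
        quota = [len(t) * n_test / n for t in tertiles]
        counts = [int(q) for q in quota]
        while sum(counts) < n_test:
            frac = [q - c for q, c in zip(quota, counts)]
            counts[int(np.argmax(frac))] += 1
        for tert, k in zip(tertiles, counts):
            if k > 0:
                test_idx.update(rng.choice(tert, size=k, replace=False).tolist())
    return {cid: ("test" if i in test_idx else "train") for i, cid in enumerate(ids)}
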