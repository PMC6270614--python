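"""End-to-end orchestration: structures -> fields -> PLS -> validation -> contours.

A run is fully described by a :class:`RunConfig`; given one config and the
same inputs the emitted report is deterministic (no timestamps inside), so
reruns are byte-identical and any stage can be recomputed from its
predecessors. Defaults mirror the published CoMFA protocol: 2 angstrom
lattice spacing, 125.46 kJ/mol cutoff, sp3 carbon +1 probe of radius
1.52 angstrom, column filter 2.0 kcal/mol, up to 10 PLS components.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import registry
from .contours import contour_levels, export_grid, stdev_coeff_grid
from .fields import (
    FieldSettings,
    ProbeSpec,
    assemble_matrix,
    build_lattice,
    column_filter,
    compute_field_block,
)
from .pls import (
    block_contributions,
    external_validation,
    fit_statistics,
    loo_cv,
    pls_fit,
    predict,
    select_ncomp,
)
from .structures import (
    BENZIMIDAZOLE_SCAFFOLD_SMARTS,
    align_to_reference,
    assign_gasteiger_charges,
    read_structures,
)

__all__ = ["RunConfig", "run_pipeline", "report_tables", "save_report"]

log = logging.getLogger("comfa")


@dataclass
class RunConfig:
    """Flat, typed run configuration (YAML-serialisable)."""

    structures: Optional[str] = None  # aligned SDF/MOL2; None -> embed the series
    activities: Optional[str] = None  # activity CSV; None -> embedded series data
    output_dir: Optional[str] = None
    spacing: float = 2.0
    margin: float = 4.0
    cutoff_kcal: float = 30.0
    probe_radius: float = 1.52
    probe_epsilon: float = 0.107
    probe_charge: float = 1.0
    dielectric_model: str = "distance_dependent"
    excluded_point_policy: str = "column_mean"
    column_filter_sigma: float = 2.0
    filter_in_cv: bool = True
    max_components: int = 10
    scaling: str = "comfa_std"
    charge_model: str = "peoe"  # "peoe" | "input" (keep charges from file)
    reference_compound: str = "39"
    align_scaffold: str = BENZIMIDAZOLE_SCAFFOLD_SMARTS
    seed: int = 2023
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def settings_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def field_settings(self) -> FieldSettings:
        return FieldSettings(
            energy_cutoff=self.cutoff_kcal,
            dielectric_model=self.dielectric_model,
            excluded_point_policy=self.excluded_point_policy,
            column_filter_sigma=self.column_filter_sigma,
            margin=self.margin,
        )

    def probe(self) -> ProbeSpec:
        return ProbeSpec(self.probe_radius, self.probe_epsilon, self.probe_charge)


def _load_inputs(config: RunConfig):
    """Structures + activity records per the config, charges assigned."""
    if config.activities:
        records = registry.read_activity_csv(config.activities)
    else:
        _, records = registry.load_benzimidazole_dataset()
    records = [r for r in records if r.split in ("train", "test")]
    wanted = {r.compound_id for r in records}

    if config.structures:
        molecules = read_structures(config.structures)
        molecules = [m for m in molecules if m.name in wanted]
    else:
        from .structures import embed_series

        compounds, _ = registry.load_benzimidazole_dataset()
        smiles = {c.id: c.smiles for c in compounds if c.id in wanted}
        log.info("embedding %d conformers (seed %d)", len(smiles), config.seed)
        molecules = embed_series(smiles, seed=config.seed)
        molecules, rmsds = align_to_reference(
            molecules, config.align_scaffold, reference_name=config.reference_compound
        )
        log.info("scaffold alignment: max RMSD %.3f", max(rmsds.values()))
    missing = wanted - {m.name for m in molecules}
    if missing:
        raise ValueError(f"no structures for compounds: {sorted(missing)}")
    if config.charge_model == "peoe":
        molecules = [assign_gasteiger_charges(m) for m in molecules]
    order = {r.compound_id: i for i, r in enumerate(records)}
    molecules.sort(key=lambda m: order[m.name])
    return molecules, records


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full 3D-QSAR analysis; returns the run report dict."""
    logging.basicConfig(level=config.log_level)
    settings = config.field_settings()
    probe = config.probe()

    molecules, records = _load_inputs(config)
    ids = [r.compound_id for r in records]
    y = np.array([r.pic50 for r in records])
    split = np.array([r.split for r in records])
    train = split == "train"
    test = split == "test"

    grid = build_lattice(molecules, margin=config.margin, spacing=config.spacing)
    log.info("lattice %s points (%s), spacing %.2f", grid.n_points, grid.dims, grid.spacing)
    steric = compute_field_block(molecules, grid, "steric", probe, settings)
    elec = compute_field_block(molecules, grid, "electrostatic", probe, settings)
    X_full, columns_full = assemble_matrix([steric, elec], settings)

    if config.filter_in_cv:
        # filter on training-row variation only, so the test set never leaks
        Xt, columns, kept = column_filter(
            X_full[train], columns_full, config.column_filter_sigma
        )
        X = X_full[:, kept]
    else:
        X, columns = X_full, list(columns_full)
    log.info("descriptor matrix %s (from %d raw columns)", X.shape, X_full.shape[1])

    blocks = [c[0] for c in columns]
    q2, sep, press_cv = loo_cv(
        X[train], y[train], config.max_components, config.scaling, blocks
    )
    n_comp = select_ncomp(q2)
    model = pls_fit(
        X[train], y[train], n_comp, config.scaling, blocks,
        columns=columns, training_ids=[i for i, t in zip(ids, train) if t],
    )
    y_hat = predict(model, X)
    r2, see, f_stat = fit_statistics(y[train], y_hat[train], n_comp)
    contributions = block_contributions(model, X[train], columns)
    ext = external_validation(y[test], y_hat[test], float(y[train].mean()))

    contour_grids = {}
    for block in ("steric", "electrostatic"):
        values = stdev_coeff_grid(model, X[train], columns, grid, block)
        fav, disfav = contour_levels(values)
        contour_grids[block] = {"values": values, "favored": fav, "disfavored": disfav}

    report = {
        "settings_hash": config.settings_hash(),
        "config": asdict(config),
        "grid": {"origin": list(grid.origin), "spacing": grid.spacing, "dims": list(grid.dims)},
        "n_molecules": len(molecules),
        "n_columns_raw": int(X_full.shape[1]),
        "n_columns_kept": int(X.shape[1]),
        "components_analysis": {
            "n": list(range(1, len(q2) + 1)),
            "q2": [round(float(v), 6) for v in q2],
            "sep": [round(float(v), 6) for v in sep],
            "press_cv": [round(float(v), 6) for v in press_cv],
        },
        "n_components": n_comp,
        "q2": round(float(q2[n_comp - 1]), 6),
        "r2": round(float(r2), 6),
        "see": round(float(see), 6),
        "f": round(float(f_stat), 4),
        "contributions": {k: round(float(v), 6) for k, v in contributions.items()},
        "external": {
            "sd": round(float(ext.sd), 6),
            "press": round(float(ext.press), 6),
            "r2_pred": round(float(ext.r2_pred), 6),
        },
        "predictions": [
            {
                "id": cid,
                "split": s,
                "experimental": round(float(obs), 6),
                "predicted": round(float(pred), 6),
                "residual": round(float(obs - pred), 6),
            }
            for cid, s, obs, pred in zip(ids, split, y, y_hat)
        ],
        "contour_levels": {
            b: {"favored": round(g["favored"], 6), "disfavored": round(g["disfavored"], 6)}
            for b, g in contour_grids.items()
        },
    }

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_report(report, out / "report.json")
        for block, g in contour_grids.items():
            export_grid(g["values"], grid, out / f"{block}.dx", fmt="dx")
        stats_text, table = report_tables(report)
        (out / "statistics.txt").write_text(stats_text)
        table.to_csv(out / "predictions.csv", index=False)
    return report


def save_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def report_tables(report: dict) -> tuple[str, pd.DataFrame]:
    """Human-readable statistics block and the per-compound prediction table."""
    if "n_components" not in report or "predictions" not in report:
        raise ValueError("incomplete run report")
    ca = report["components_analysis"]
    lines = [
        "Model summary",
        f"  N          {report['n_components']}",
        f"  q2         {report['q2']:.3f}",
        f"  r2         {report['r2']:.3f}",
        f"  r2_pred    {report['external']['r2_pred']:.3f}",
        f"  SEE        {report['see']:.3f}",
        f"  SD         {report['external']['sd']:.2f}",
        f"  PRESS      {report['external']['press']:.2f}",
        f"  F          {report['f']:.2f}",
        "  Contribution: "
        + "  ".join(f"{k} {100 * v:.0f}%" for k, v in report["contributions"].items()),
        "",
        "Number of components analysis",
        "  N    " + "".join(f"{n:>8d}" for n in ca["n"]),
        "  q2   " + "".join(f"{v:8.3f}" for v in ca["q2"]),
        "  SEP  " + "".join(f"{v:8.3f}" for v in ca["sep"]),
    ]
    table = pd.DataFrame(report["predictions"])[
        ["id", "split", "experimental", "predicted", "residual"]
    ]
    return "\n".join(lines) + "\n", table
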