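# comfa

Comparative Molecular Field Analysis (CoMFA) 3D-QSAR toolkit, built around a
2-(pyridinyl)-1H-benzimidazole series of cannabinoid CB1 receptor ligands.

CoMFA correlates biological activity with the steric (Lennard-Jones) and
electrostatic (Coulomb) interaction energies a probe atom experiences on a
rectangular lattice around a set of aligned molecules. The many collinear
lattice energies are regressed against activity with partial least squares
(PLS), validated by leave-one-out cross-validation and an external test set,
and mapped back onto 3D space as standard-deviation-times-coefficient
contour grids.

The package provides:

- **`comfa.registry`** — the embedded 47-compound benzimidazole series
  (descriptor-grid enumeration to SMILES/names, literature Ki and pIC50
  values, the published 24-train/5-test partition), Cheng-Prusoff and pIC50
  conversions, and CSV interfaces for new series.
- **`comfa.structures`** — SDF/MOL2 I/O, PEOE (Gasteiger) partial charges,
  Kabsch rigid superposition, common-scaffold series alignment, and seeded
  conformer embedding via RDKit.
- **`comfa.fields`** — steric and electrostatic field lattices (sp3 carbon
  +1 probe, 2.0 A spacing, 30 kcal/mol cutoff), descriptor-matrix assembly
  with the classic excluded-point column-mean policy, and minimum-sigma
  column filtering.
- **`comfa.pls`** — NIPALS PLS1, leave-one-out q2/SEP/PRESS, component
  selection, r2/SEE/F, external-validation SD/PRESS/r2_pred, and per-field
  block contributions.
- **`comfa.contours`** — stdev-times-coefficient grids, percentile contour
  levels, OpenDX and Gaussian-cube export.
- **`comfa.synth`** — a synthetic aligned-series generator with a planted
  linear field-activity model, for end-to-end testing against a known
  ground truth.
- **`comfa.pipeline`** / **`comfa.cli`** — a deterministic end-to-end run
  (alignment, fields, PLS, validation, contour export) driven by a single
  YAML-serialisable configuration, and a `comfa` command-line front end.

## Worked example

Recompute the reported model statistics from the embedded activity tables:

```python
import numpy as np
from comfa import load_benzimidazole_dataset
from comfa.pls import external_validation, fit_statistics

_, records = load_benzimidazole_dataset()
train = [r for r in records if r.split == "train"]
test = [r for r in records if r.split == "test"]
y = np.array([r.pic50 for r in train])
pred = np.array([r.pic50_reported_pred for r in train])

r2, see, f = fit_statistics(y, pred, n_components=7)
print(f"r2={r2:.4f} SEE={see:.4f} F={f:.2f}")
# r2=0.9976 SEE=0.0569 F=943.85

ext = external_validation(
    np.array([r.pic50 for r in test]),
    np.array([r.pic50_reported_pred for r in test]),
    float(y.mean()),
)
print(f"SD={ext.sd:.3f} PRESS={ext.press:.3f} r2_pred={ext.r2_pred:.4f}")
# SD=5.177 PRESS=0.918 r2_pred=0.8226
```

Run the full pipeline on the embedded series (stand-in scaffold alignment,
see the caveat below) and write report, contour grids and tables:

```sh
comfa run --out results/run1
cat results/run1/statistics.txt
```

Generate a synthetic series with a known planted model and recover it:

```python
from comfa.synth import SyntheticSpec, generate
from comfa.pls import loo_cv, pls_fit, select_ncomp

molecules, y, truth = generate(SyntheticSpec(seed=0))
q2, sep, press = loo_cv(truth.matrix, y, 10)
n = select_ncomp(q2)
model = pls_fit(truth.matrix, y, n)
print(f"N={n} q2={q2[n - 1]:.3f} planted columns={truth.planted_columns}")
```

Other CLI entry points: `comfa enumerate` (series SMILES), `comfa fields`
(field matrix from an aligned SDF/MOL2), `comfa fit`, `comfa validate`,
`comfa contours`, `comfa simulate`. Each supports `--help`.

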