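# Methods

This note records the model equations, parameter conventions, numerical
choices and known limitations of the package. Units are angstrom, kcal/mol
and elementary charges (e) throughout unless stated otherwise.

## Dataset and unit conversions

The embedded series comprises 47 2-(pyridinyl)-1H-benzimidazoles spanning a
3 x 2 x 4 x 2 descriptor grid: pyridyl nitrogen position (2/3/4), N1 linker
(naphthalenylcarbonyl vs naphthalenylmethyl), C5/C6 substitution (H/H, F/H,
H/F, CH3/CH3) and naphthalene attachment point (1 vs 2). SMILES and
systematic names are generated from a scaffold template, so the descriptor
tuple is the canonical identity of a compound.

Binding data are CB1 radioligand-displacement affinities ([3H]CP-55,940 at
[L] = 0.5 nM, Kd = 500 pM). IC50 values convert to Ki by Cheng-Prusoff,

    Ki = IC50 / (1 + [L]/Kd),

which equals IC50/2 at these assay constants, and to activity as
pIC50 = -log10(IC50 in M). Compounds displacing < 50% of the radioligand at
1 uM are kept as censored records (bound 1 uM) rather than dropped or
imputed; they carry no pIC50 and never enter a model. Of the measured
compounds, 24 form the training set and 5 the external test set, following
the published partition. Each modelled record also stores the
model-predicted activity published alongside the experimental value; the
pair is treated as observed input data and is what the desk-reproducible
statistics below are computed from.

## Structures, charges and alignment

Molecules are lightweight containers (element, 3D position, partial charge,
per-atom vdW radius/well depth) in a shared cartesian frame. SDF (V2000)
and Tripos MOL2 files are read through RDKit; MOL2 partial charges are
preserved.

Partial charges use PEOE (partial equalization of orbital
electronegativity, Gasteiger-Marsili): electronegativity is the polynomial
chi(q) = a + b q + c q^2 per element and sigma hybridisation, charge flows
across each bond from the less to the more electronegative atom scaled by
chi+ of the donor and damped by 0.5^k at iteration k, for 6 iterations,
seeded from formal charges. Hydrogen uses chi+ = 20.02. Total charge is
conserved by construction. The implementation is independent of RDKit's
Gasteiger routine, which serves as the test oracle (agreement within
0.01 e on reference molecules). The Hueckel pi-correction of
"Gasteiger-Hueckel" charges is not implemented; its parameterisation is
toolkit-specific and the package's statistics checks are property-based,
so the reproducible PEOE sigma model is the default and only charge model.

Rigid superposition is the Kabsch least-squares fit over mapped atom pairs
(proper rotation only, via `scipy` `Rotation.align_vectors`; reflections
are never applied). Series alignment maps a common scaffold SMARTS
(`[#6]n1c(-[c])nc2ccccc21`, the N1-substituted 2-arylbenzimidazole core,
which matches every series member exactly once) and superposes every
molecule onto a reference, by convention the most active compound (39).

## Interaction fields

Fields are evaluated on a rectangular lattice with 2.0 A spacing covering
the aligned set's bounding box plus a 4.0 A margin per side; the flattened
point order is x-major (index = ix*ny*nz + iy*nz + iz). The probe is an
sp3 carbon with vdW radius 1.52 A, well depth 0.107 kcal/mol and +1 e
charge.

Steric energy per point:

    E_s = sum_atoms eps_ij [ (r_m/r)^12 - 2 (r_m/r)^6 ],
    r_m = R_atom + R_probe,  eps_ij = sqrt(eps_atom * eps_probe).

Values above the cutoff are truncated to it and the point is flagged
excluded for that molecule. The cutoff is 30.0 kcal/mol (the conventional
125.46 kJ/mol; the two round to each other at 4.184 kJ/kcal and the
kcal-side value is taken as exact).

Electrostatic energy per point:

    E_e = k sum_i q_i q_probe / (eps(r_i) r_i),  k = 332.0716 kcal A / (mol e^2),

with a distance-dependent dielectric eps = r by default (so the denominator
is r^2), clamped to +/- cutoff. A probe landing exactly on an atom center
is treated as maximal repulsion (distance floored at 1e-9 A, then
truncated), not as an error.

The descriptor matrix concatenates [steric | electrostatic] blocks. At
lattice points sterically excluded for some molecules, that molecule's
electrostatic entry is replaced by the column mean over the non-excluded
molecules (the classic convention; keeping the clamped value is available
as an alternative policy). Columns whose energy standard deviation
(population, ddof=0) across molecules falls below the minimum-sigma filter
(default 2.0 kcal/mol) are dropped before regression; in the pipeline the
filter is computed on training rows only, so the test set cannot leak into
column selection.

## PLS and statistics

Regression is single-response NIPALS PLS. Descriptors are mean-centered;
under the default CoMFA scaling every column is divided by the pooled
standard deviation of its whole block (sqrt of the mean column variance),
putting the two blocks on a common energy scale while preserving relative
variation within a block. Plain centering (`center_only`) is available.
Coefficients are composed back to raw descriptor space, so
yhat = y_mean + (x - x_mean) . beta.

Leave-one-out cross-validation refits everything (centering, scaling,
components) on each n-1 subset and accumulates PRESS_cv(N) for
N = 1..max (default 10):

    q2(N) = 1 - PRESS_cv(N) / SStot,   SEP(N) = sqrt(PRESS_cv(N) / (n - N - 1)),

with SStot about the full training mean. The optimal N is the smallest
count attaining the maximum q2. Fitted-model statistics:

    r2 = 1 - SSres/SStot,  SEE = sqrt(SSres / (n - N - 1)),
    F = (r2/N) / ((1 - r2)/(n - N - 1)).

External validation over the test set, with SD taken about the
training-set mean activity:

    SD = sum (y_test - mean(y_train))^2,   PRESS = sum (y_test - yhat)^2,
    r2_pred = (SD - PRESS) / SD.

Block contributions are the shares of sum |beta_j| s_j per field block
(s_j the training column standard deviation). The same beta_j * s_j
products, mapped back to their lattice points (zero where filtered),
form the contour grids; default iso-levels are the 80th ("favored") and
20th ("disfavored") percentiles of the nonzero values. Grids export as
OpenDX text (angstrom) or Gaussian cube (Bohr, 1.8897259886 Bohr/A); both
writers are in-repo because the formats are simple line-oriented text and
no volumetric-I/O library is among the package's dependencies.

Applied to the embedded experimental/predicted activity tables (n = 24,
N = 7 as selected from the embedded 10-entry q2 profile), these formulas
give r2 = 0.9976, SEE = 0.0569, F = 943.85, SD = 5.177, PRESS = 0.918,
r2_pred = 0.8226 — matching the reported 0.998 / 0.057 / 944.13 / 5.18 /
0.92 / 0.823 within the rounding of the 3-decimal inputs.

## Synthetic generator

`comfa.synth` draws aligned pseudo-molecule series whose activity is
exactly linear in a sparse set of field columns, so every pipeline stage
can be tested against a known ground truth. Study conditions (the frozen
defaults): 30 molecules sharing a rigid 5-carbon scaffold, 4 variable
atoms per molecule placed uniformly within +/- 2 A of the origin with
elements from {C, N, O, F} and charges uniform in +/- 0.3 e; fields on the
standard lattice, filtered at sigma = 2.0; activity y = X w + N(0, 0.3^2)
with w supported on 5 steric columns scaled so the noiseless signal has
standard deviation 1.5. All randomness flows through one seeded generator,
so a seed fully determines the dataset.

Two design constraints make the planted model identifiable, and they are
the reason the support is restricted to steric columns:

1. Electrostatic columns are excluded from the support. The 1/r^2 Coulomb
   kernel is long-ranged, so electrostatic lattice columns are
   near-collinear across the series; a sparse direction planted there is
   indistinguishable from its neighbours by any regression method.
   Steric columns decorrelate over a couple of grid spacings.
2. The planted columns are the highest-variance steric columns subject to
   pairwise |r| < 0.4. For very small series this constraint may admit
   fewer than the requested 5 columns; the generator then shrinks the
   support with a warning and records the actual support in the ground
   truth rather than failing.

Under these conditions, PLS at the LOO-selected component count recovers
the planted model across seeds: cross-validated q2 above 0.75, cosine
similarity between fitted and planted coefficient vectors above 0.8, and
(at zero noise or the default noise) the top-5 columns by |beta_j| s_j
coincide exactly with the planted support. Note the support criterion is
top-k mass, not "all nonzero coefficients": PLS coefficients live in the
Krylov span of X'y and are generically nonzero on every column correlated
with the support, so exact sparsity of the estimate is not a meaningful
invariant. Recovery checks use plain centering, which keeps the comparison
in the native descriptor frame of the planted weights.

## Stand-in alignment and its limits

The original binding model was built on poses docked into a receptor
homology model. Docking, pose scoring and receptor modelling are outside
this package; the pipeline therefore accepts externally aligned poses
(SDF/MOL2, used as-is) and otherwise manufactures its own input by
embedding seeded ETKDG/MMFF conformers and rigidly superposing them on the
common benzimidazole scaffold of compound 39.

This stand-in preserves the scaffold frame but not the docked orientations
of the flexible naphthyl and pyridyl groups, which carry most of the
series' variation. Field statistics computed from it are accordingly much
weaker than the published docked-alignment model (cross-validated q2 near
zero rather than ~0.7, unstable component counts across embedding seeds)
and are reported for pipeline-mechanics verification only — the end-to-end
run is checked for determinism (byte-identical reports across reruns) and
runtime, not for predictive quality. Quantities that depend on the
authors' alignment and original software internals (per-compound
predictions, the 35/65 block contribution split, the q2 = 0.71 itself) are
replaced in the test suite by property-based checks: PLS against a
least-squares oracle at full rank, vectorised LOO against a literal
refit-per-sample loop, closed-form field values, charge-model agreement
with an independent oracle, and planted-model recovery on synthetic data.

## Numerical conventions

- Standard deviations entering the column filter, block contributions and
  contour grids are population values (ddof = 0).
- The LOO prediction for a left-out sample is accumulated component by
  component within one NIPALS pass per left-out sample; this is
  algebraically identical to refitting separate models for each component
  count (verified against the literal loop to 1e-10).
- Component counts are capped at min(n - 1, p) for fitting and
  min(n - 2, p) within LOO; exceeding the cap raises a rank error (fit) or
  trims with a warning (cross-validation).
- Run reports contain no timestamps and round floats to fixed precision,
  so identical configurations produce byte-identical JSON.
- Degenerate inputs fail loudly: constant response (zero SStot), zero
  test-set SD, all-zero contour grids and empty q2 profiles raise or warn
  rather than returning NaN silently.
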