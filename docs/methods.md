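# Methods

This note documents the models, conventions and numerical choices behind
`dloss`, in the spirit of a methods appendix: what is computed, under which
assumptions, and what the synthetic experiments do and do not demonstrate.

## Difference-map synthesis

Maps use Fobs(n)−Fobs(1) amplitude differences with a **fixed first-dataset
phase set** φ_calc(1).  Conventions:

- One Friedel hemisphere is stored; F(−h) = conj(F(h)) is imposed during
  synthesis.  F(000) is never stored, so every map has zero mean and "±Nσ
  contouring" refers to thresholds at N times the population standard
  deviation over the full P1 grid.
- Space group is P1 throughout.  Real-data users must pre-expand symmetry;
  the synthetic generator emits P1 natively.
- **Inter-dataset scaling** is a single overall least-squares scalar
  k = ΣF₁Fₙ / ΣFₙ² applied to the later dataset.  No resolution-binned,
  anisotropic or sigma-weighted scheme is attempted; the scale is logged on
  every run.  This is the simplest defensible protocol; with real data a
  proper scaling program should be run upstream.
- Grid sizes must satisfy N ≥ ⌈2·edge/dmin⌉ per axis.  An index at exactly
  |h| = N/2 folds onto its Friedel mate with a real exponential, which is
  exact at the sampled points, so such grids are accepted; anything coarser
  is rejected with the required minimum in the message.
- The FFT path is validated against an explicit direct Fourier summation of
  the same series (the module's oracle) to ~1e-15 relative in tests.

## Model structure factors

F(h) = Σ_atoms occ · n_e · exp(−B·s²/4) · exp(2πi h·x_frac), s = 1/d.  Each
atom is a single Gaussian with electron-count weight under its isotropic
B-factor envelope — not a Cromer–Mann scattering model.  This reproduces
the *structure* of the problem (peaks at atoms, B-dependent widths,
occupancy-proportional amplitudes) with enough fidelity for difference-map
methodology; absolute scattering physics is out of scope.  Neutral-atom
electron counts are used; ions are not modelled.

## The D_loss metric

D_loss(atom, n) is the maximum of −ρₙ over grid voxels within a vicinity
radius of the atom:

- **Radius**: default 1.5 Å, configurable, always reported.  It covers the
  atom's own density at typical MX resolutions.  Note that bonded
  neighbours lie at 1.2–1.8 Å, so vicinity spheres of adjacent atoms
  overlap; the deepest peak of a damaged atom is therefore often shared
  with its bonded partners (e.g. a carboxylate carbon ties with its
  oxygens).  This is inherent to any vicinity-max construction; a
  nearest-atom voxel partition would remove the overlap and is noted as a
  possible extension.
- **Periodicity**: distances use the minimum-image convention in fractional
  space; atoms at cell edges wrap.  The voxel set is never empty (the
  nearest voxel is always included), and a radius exceeding half the
  shortest cell edge is an error.
- **No clamping**: values may be negative where only density gain occurs.
  Downstream ranking consumes the values as-is.
- Atoms with zero occupancy still receive values — the map does not know
  the model.
- Hydrogens are excluded everywhere; altlocs other than '' / 'A' are
  excluded by default to avoid double-counting a site.

**Cα normalization** maps each value to (D_loss − ⟨D_loss⟩_Cα)/⟨D_loss⟩_Cα
per dose, making the Cα mean exactly 0 by construction.  A zero Cα mean
(e.g. a perfectly flat map) is reported as an error instructing use of raw
values, since the ratio is then undefined — this is the "no signal" case.

**Dataset filter**: non-reference datasets below 1 MGy are excluded by
default.  Below that dose only disulfide chemistry is expected, so such
datasets dilute decarboxylation-oriented statistics; the filter is
disabled by passing a dose floor of `None` (appropriate for low-dose
control series).

## Ranking scheme

Per dataset, atom types are ranked by mean raw D_loss, 0 = most damaged;
across datasets the products of per-dataset ranks are ranked (ascending
product → rank 0).  Consequences and policies:

- A type ranked 0 in any dataset has product 0 — a faithful property of the
  product scheme, not patched.
- Ties (in means or products) are broken by mean per-dataset rank, then
  lexicographic atom-type key; tie-break activations are logged.
- Ranking uses **raw** values (it precedes normalization conceptually);
  signatures and KS comparisons use **Cα-normalized** values.
- Only ranks are comparable across series; raw values are kept per-series
  in all outputs because dose scales between independently collected
  series are not mutually calibrated.

## Statistical tests

- **KS**: scipy's two-sample test.  The default (`method="auto"`) uses the
  exact finite-sample null at the sample sizes arising here; the asymptotic
  formula is available but is measurably conservative at n ≈ 50 (its true
  rejection rate at nominal 5% is ≈ 3.4%; even the exact test's achievable
  size is ≈ 3.9% because the statistic is discrete at equal n = 50).
- **Hotelling T²**: two-sample, pooled covariance, F-transform
  F = T²(n_a+n_b−p−1)/(p(n_a+n_b−2)) ~ F(p, n_a+n_b−p−1).  Requires
  n_a+n_b−2 > p and a non-singular pooled covariance (collinear dose
  columns are reported as such).  At p = 1 it reduces to the squared
  pooled-variance t statistic, which the tests verify.  Null calibration is
  ≈ 5.0% at p=3, n=15 per group.  Power for a mean shift that accumulates
  with dose (0.5σ per dose step over three doses, the generator's damage
  model) is ≈ 0.99; a dose-constant 0.5σ shift gives ≈ 0.43 — a dose series
  cannot shift all doses equally, so the accumulating case is the relevant
  operating point.
- **KDE**: Gaussian kernels, Scott's rule by default, evaluated on ≥ 256
  points spanning the data ± 3 bandwidths; degenerate (constant) samples
  are rejected with a pointer to histograms.
- **Linear R²**: OLS with intercept; constant y is defined as R² = 0 with a
  warning, constant x is an error.

## Structural context

- **H-bonds**: plain distance criterion, Tyr OH to Glu Oε1/Oε2 / Asp
  Oδ1/Oδ2 strictly < 4.0 Å, within the asymmetric unit (no symmetry
  mates).  No angular criterion — consistent with a contact-based
  definition.
- **SASA**: Shrake–Rupley via Biopython (960 sphere points, probe 1.4 Å),
  van der Waals radii C 1.70, N 1.55, O 1.52, S 1.80 Å (configurable).
  The decarboxylation experiment removes Glu {CD, OE1, OE2} and Asp
  {CG, OD1, OD2} — the full CO₂ moiety including the carbon, matching the
  chemistry — before the calculation.  Tyr "ring area" sums CG, CD1, CD2,
  CE1, CE2, CZ and by default OH.  Crystal contacts are not modelled
  (isolated-model SASA); for the synthetic P1 toys, units are padded well
  apart so this is immaterial, but real close-packed crystals will read
  high.
- **Disulfide distance**: SG–SG pairs < 2.5 Å; distance from Tyr OH to the
  bond midpoint by default (nearest-S available via a flag); absent when
  the structure has no disulfide.
- **Bdamage**: packing density = heavy atoms within 7 Å (minimum-image by
  default; a non-periodic mode exists and is the setting in which rigid
  rotation/translation invariance holds exactly).  Equal-width bins over
  observed densities, bins under 10 atoms merged downward, Bdamage =
  B / mean(B of bin), relative change = (Bd₂ − Bd₁)/Bd₁ per matched atom.
  Occupancies are assumed 1 (the generator emits unit occupancies; real
  data should be occupancy-normalized upstream).
- Context correlations require ≥ 8 Tyr residues per series; smaller series
  are skipped and logged, since an R² over a handful of points carries no
  information.

## Synthetic generator: what it emulates, and what it does not

`make_toy_structure` places idealized side chains (with their Cα atoms) of
Tyr, Phe, Glu, Asp, Gln, Asn, Ser, Thr, Leu, Ile, plus disulfide-bonded Cys
pairs, on a cubic site grid (12 Å spacing) in a P1 cell, with seeded random
orientations re-drawn until all inter-residue contacts are ≥ 2 Å.  Two
Tyr–Glu units are composed with OH···Oε1 ≈ 2.9 Å (H-bonded subset); at
least two further Tyr are isolated.  B-factors are uniform in [10, 20] Å²,
occupancies 1.

`make_damage_series` computes dataset-1 structure factors from the intact
model (retaining the phases as φ_calc(1)), then for each later dose applies
cumulative per-type or per-atom occupancy loss (rate × dose step) and/or a
rigid displacement of Tyr/Phe ring atoms along a fixed per-residue random
direction, recomputes amplitudes, and adds Gaussian amplitude noise of sd =
noise_sigma × mean|F| (clipped at 0).  Defaults chosen as the package's
standard study conditions: doses (0.5, 2, 4, 6) MGy, dmin 2.0 Å (2.5 Å in
the test-suite experiments, which keeps a full 20-seed sweep under a
minute), noise_sigma 0.01 — about 1% amplitude error, optimistic but
representative for well-measured series.  Ring-displacement experiments use
0.3 Å per dose step, a subtle disorder well below bond lengths.  Damage is
modelled as occupancy loss (cleavage-like) *or* rigid ring displacement
(disorder-like) precisely so the two hypotheses remain distinguishable in
experiments.

Not emulated: backbone connectivity, realistic lattice packing, bulk
solvent, Wilson-statistics error models, symmetry beyond P1, ions, and
crystal contacts.  Consequently, passing recovery tests demonstrates that
the *pipeline* correctly extracts injected signals from amplitudes under
controlled noise — not that real crystals behave like the toys.

One emergent (and physically faithful) property is worth flagging: with
per-type Glu damage, Tyr residues H-bonded to a damaged carboxylate inherit
part of the partner's loss peak through the 1.5 Å vicinity sphere, so
"untouched" Tyr OH atoms adjacent to damage score above isolated controls.
This is the H-bond-coupling phenomenon the context module is designed to
interrogate, and experiments that need a genuinely untouched Tyr population
must either target non-H-bonded Glu residues or give controls a distinct
injected rate.

## Numerical and policy details

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; fixed seed ⇒ byte-identical fixtures and hash-identical report
  tables.
- Reflection text I/O uses a whitespace table (H K L F1 … PHI1) with
  `# cell:` / `# dmin:` comment headers; reflections missing any dataset
  amplitude are dropped with a logged count; duplicates and negative
  amplitudes are errors.
- CCP4/MRC map I/O (mode 2) goes through gemmi.
- PDB numeric precision is the format's: coordinates 3 d.p., occupancy and
  B 2 d.p.; the round-trip tests treat the first write as the fixed point.
- Every analysis default actually used in a run (vicinity radius, scaling
  scheme, dose floor, tie policy) is written to the run log, making runs
  auditable.

## Known limitations

- Overall (not resolution-binned) difference-amplitude scaling.
- No symmetry support in map synthesis; P1 only.
- SASA without crystal-contact accounting.
- The vicinity-sphere construction shares deep peaks between bonded atoms;
  rank interpretations should treat bonded groups (e.g. a carboxylate) as a
  unit.
- The Hotelling comparison needs n_a+n_b−2 > p; short series with few Tyr
  are reported as not testable rather than forced.
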