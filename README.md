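# dloss

Per-atom quantification of **specific radiation damage** in macromolecular
crystallography (MX) dose series, built around the *D*<sub>loss</sub> metric.

## The problem

During X-ray data collection, protein crystals accumulate dose (MGy) and
suffer localized chemical damage long before global diffraction decay:
disulfide bonds elongate and break, Glu/Asp side chains decarboxylate, and
negative difference density appears around particular atoms.  Whether the
tyrosine hydroxyl belongs on that list is exactly the kind of question that
needs an *objective*, per-atom measure of density loss rather than visual
map inspection.  This package is for crystallographers and methods
developers who want to quantify, rank and correlate such damage across a
dose series.

## The metric and the statistics

Given amplitude sets |F<sub>obs</sub>(n)| for datasets n = 1, 2, … of a dose
series and phases φ<sub>calc</sub>(1) from the first-dataset model, the
difference density

ρ<sub>n</sub>(x) = (1/V) Σ<sub>hkl</sub> (|F<sub>obs</sub>(n)| −
|F<sub>obs</sub>(1)|) · cos(φ<sub>hkl</sub> − 2π **h**·**x**)

is synthesized by FFT (Friedel-completed, F(000) excluded, one overall
least-squares scale per dataset).  For each heavy atom,

*D*<sub>loss</sub>(atom, n) = max over grid points within radius r (default
1.5 Å, minimum-image) of −ρ<sub>n</sub>(x),

i.e. the deepest density *loss* near the atom; it may be negative in pure
density-gain regions.  Downstream:

- **Cα normalization**: (*D*<sub>loss</sub> − ⟨*D*<sub>loss</sub>⟩<sub>Cα</sub>) /
  ⟨*D*<sub>loss</sub>⟩<sub>Cα</sub> per dose, referencing each value to the
  radiation-insensitive backbone Cα set.
- **Atom-type ranking**: atom types (e.g. Glu Oε1, Tyr OH) are ranked per
  dataset by mean raw *D*<sub>loss</sub> (0 = most damaged); across datasets
  the products of per-dataset ranks are ranked again.
- **Damage signatures**: the distribution of Cα-normalized values over all
  heavy atoms of a residue type, compared between topologically similar
  pairs (Tyr–Phe, Asp–Asn, Leu–Ile, Ser–Thr) with the two-sample
  Kolmogorov–Smirnov statistic and Gaussian KDEs.
- **Structural context**: Tyr OH···Glu/Asp carboxylate hydrogen bonds
  (< 4 Å), Shrake–Rupley solvent accessibility (optionally after deleting
  carboxylates, emulating decarboxylation), distance to disulfides, the
  Bdamage metric (B-factor over packing-density-bin mean B), Hotelling T²
  between Tyr subsets and linear R² against covariates.

A fully deterministic synthetic generator (`dloss.synthetic`) builds toy P1
structures with every relevant residue type, injects known occupancy losses
and/or aromatic-ring displacements per dose, adds amplitude noise, and emits
plain-text fixtures — so every stage of the analysis is testable against
known ground truth without any external data.

## Worked example

Generate a decarboxylation series (Glu carboxylate oxygens lose 20% of their
occupancy per dose step, Asp 10%, 1% amplitude noise) and analyse it:

```sh
dloss simulate --seed 5 --out fx --glu-loss 0.2 --asp-loss 0.1
dloss all --pdb fx/model.pdb --reflections fx/reflections.tsv \
      --dose 0.5 --dose 2 --dose 4 --dose 6 --out report
head -6 report/ranks.tsv
```

prints

```
# config_hash: de23165f487d31e6
# seed: 0
        mean_dataset2   rank_dataset2   ... rank_product  rank_overall
GLU-OE1 0.18470341054147232  1          ... 1.0           1
GLU-OE2 0.19165910250044615  0          ... 0.0           0
ASP-OD1 0.08511421200774226  2          ... 8.0           2
```

The two Glu carboxylate oxygens take overall ranks 0 and 1 (most damaged),
the Asp oxygens follow, and the untouched control oxygens (Gln/Asn/Ser/Thr,
Tyr OH) fill the remaining ranks — the injected damage hierarchy is
recovered from the amplitudes alone.  Mean *D*<sub>loss</sub> values rise
with dose (0.18 → 0.37 → 0.55 for Glu Oε1), reflecting the cumulative
injected loss.  `report/` also contains the per-atom table (`dloss.tsv`),
KS signature comparisons (`ks_pairs.tsv`), a run log listing every default
used, and a YAML summary.

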