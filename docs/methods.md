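# Methods

## The measurement being modelled

RedoxSensor Green (RSG) is a fluorogenic probe turned over by
oxidoreductase activity: its green fluorescence in a cell scales with the
cell's respiratory electron-transfer rate, aerobic or anaerobic. When
RSG-stained cells are run through index FACS, each sorted event's
fluorescence and forward scatter are recorded together with the destination
well, and single-cell genome amplification of that well yields a SAG. The
package models the downstream inference: fluorescence → calibrated units →
rate, gated by what the linked genome encodes.

## Bead-standard calibration

Raw cytometer channels are arbitrary and drift day to day. A multi-peak
rainbow-bead sample acquired each day gives (raw median, reference value)
pairs; the standard curve interpolates them piecewise-linearly in
log₁₀–log₁₀ space. Choices:

- **Log-log piecewise linear.** Bead intensities span decades and
  log-linearity is the standard convention for bead-referenced
  (MEF-style) scales. The curve passes through every knot exactly
  (asserted to <1e-12 relative) and is strictly monotone.
- **Drift cancellation.** A uniform multiplicative detector drift scales
  bead knots and cell events alike, so it cancels identically in log
  space; synthetic two-day tests agree to <1e-9.
- **Extrapolation policy.** Default `clamp`: values outside the knot range
  are pinned to the end references and flagged, so no rate is invented
  beyond the calibrated range. `extend` (continue the terminal log-log
  segments) is retained for sensitivity analysis.
- **Peak summaries are medians**, robust to the heavy tails of bead
  clusters. Assignment of events in a mixed bead file to peaks is a 1-D
  k-means on log values with quantile initialization, ties to the lower
  peak.
- Forward scatter is calibrated to estimated diameter (μm) with the same
  machinery using size-standard beads. Whether scatter should also be
  bead-normalized per day is instrument-protocol dependent; here it is,
  symmetrically with fluorescence.

FCS binary parsing is out of scope; event tables enter as the CSV/TSV
dialect (one row per event with `FL1_raw`, `FSC_raw`, stain, well, plate,
day). Rows with non-positive channel values are rejected with a logged
count rather than silently transformed.

## Capability gating

SAG completeness in sediment work is typically a few tens of percent, so a
missing marker gene is weak evidence of absence. The default **core** rule
calls a SAG capable of dissimilatory sulfate reduction iff
{dsrA, dsrB, aprA, aprB} are all annotated; **strict** additionally
requires *sat*. Both are implemented because the per-cell criterion and the
full pathway gene list differ in emphasis in practice; neither is asserted
as "the" published rule. Capability is monotone in the marker set
(property-tested). No completeness correction is applied to capability
fractions by default — observed fractions undercount true capability, and
inflating them would be a modelling claim, not bookkeeping; the recovery
harness instead reports the closed-form expectation (respiring fraction ×
completeness⁴ under core) next to the observation.

## Rate inference

R = a·F^b with configured coefficients (YAML), a > 0, b > 0; b = 1 reduces
to proportionality and is the default in the stock configuration (a =
10⁻³ fmol cell⁻¹ h⁻¹ per calibrated unit, placing 0.01–5 fmol cell⁻¹ h⁻¹
inside the bead-calibrated span). The empirical coefficients for a real
instrument/organism pairing come from wet-lab calibration against
independent rate measurements, which this package does not perform — it
makes the curve explicit, loadable and auditable instead of hard-coded.

Gating rules in `rate_table`: SYTO-9-stained events never receive rates
(that stain marks DNA, not activity — hard assertion); incapable cells are
excluded and counted; fluorescence outside [F_min, F_max] converts but is
flagged, preserving the observed dynamic range while making extrapolation
auditable; two events claiming one (plate, well) make index identity
ambiguous, so both are dropped and the collision logged. Summaries use the
arithmetic mean (the convention for "average rate per cell"), with a
geometric-mean option for lognormal-like data.

## Bulk extrapolation and units

nmol h⁻¹ cm⁻³ = R̄ (fmol cell⁻¹ h⁻¹) × f × C (cells cm⁻³) / 10⁶. The
result object carries a unit trail listing every factor applied. Cell
concentration from sorted counts is a helper (count ÷ analyzed volume ×
overall dilution fold), not an implicit computation. Unit conversion works
on the lattice {fmol, pmol, nmol} × {cell, ml, cm³, L} × {h, day} with
exact rational factors (day = 24 h, 10³ between prefixes, 1 ml = 1 cm³);
per-cell and per-volume bases are not interconvertible without a
concentration. Display rounding is an explicit `decimals` argument kept
separate from conversion; a `paper_decimals` heuristic (integers at ≥10,
one decimal below) matches common reporting practice but published figures
mix precisions, so nothing downstream relies on it. A change in
concentration exactly at an assay's detection limit counts as detectable
(≥ convention: nominally measurable).

## RPKM

RPKM = r / ((L/1000)·(N/10⁶)) with N the **total reads in the sequence
library**, not the mapped total. Gene length is nucleotide bp; protein-space
mapping lengths must be converted upstream. Category means are arithmetic
over member genes, computed per sample by default — the two incubation
conditions' libraries are never pooled unless requested. The algebraic
inversion RPKM·(L/1000)·(N/10⁶) = r is the formula's own oracle and is
asserted to 1e-9 relative on random records. "Mean RPKM" for a multi-sample
category averages within sample by default (per-sample grouping); pooling
across samples is the explicit `pool` option.

## Synthetic data: what it emulates and what it does not

The generator inverts the inference: true per-cell rates (lognormal per
taxon) are pushed through the inverse rate calibration and the inverse
bead curve to raw channels, with multiplicative lognormal noise (the
flow-cytometry convention, since channels are log-distributed) and a
per-day drift factor. Marker dropout is independent Bernoulli
(completeness) per gene the lineage genuinely carries, and never outside
the panel. Ground truth lives in a sidecar table that the inference files
never contain.

The stock community is three taxa: a broad Chloroflexota-like sulfate
reducer (fraction 0.45, lognormal rates with 1st/99th percentiles
~0.03–4.6 fmol cell⁻¹ h⁻¹), a narrower Desulfobacterota-like reducer
(0.15, ~0.08–0.66), and an abundant non-respiring, marker-free
Patescibacteria-like lineage (0.40) that only emits background
fluorescence below the sort floor. The within-lineage fluorescence cv
defaults to 0.1; it is a free parameter of the generator, not an empirical
value. Default problem sizes (10,000 sorted cells for recovery runs, 500
events per bead peak) keep full runs in seconds while leaving sampling
error well inside the asserted tolerances.

Not emulated: particle aggregation and debris, spectral spillover,
sort-purity failures, chimeric amplification, correlated marker dropout
(assembly drops whole regions, so real dropout is not independent per
gene), and any feedback between chemistry and activity during incubation.
Passing recovery tests therefore demonstrates the *inference machinery* is
unbiased under its own assumptions, not that those assumptions hold for a
given instrument or sediment.

## Pipeline

One YAML config drives calibrate → link → gate → rates → summaries → bulk
→ RPKM → composition. Every stage logs counts in/out so denominators stay
reconstructable; outputs are TSV with a `# seed=` header line; the JSON
manifest records input checksums, package version, parameters and seed.
Re-running with identical inputs and seed is byte-identical
(checksum-tested). Config validation is an explicit field walk with named
errors, exit code 2 for validation problems and 3 for data-integrity
problems at the CLI.

## Known limitations

- The rate calibration's empirical coefficients are user-supplied; results
  are only as good as that wet-lab curve.
- Capability fractions are not completeness-corrected (documented
  undercount).
- The unclassified-rank placeholder (`unclassified_<parent>`) keeps cells
  in denominators but can lump genuinely different unclassified lineages.
- Diameter estimation inherits all forward-scatter caveats (refractive
  index, shape); it is a bead-referenced estimate, not a measurement.
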