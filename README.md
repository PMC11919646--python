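# sedrate

Single-cell genome-to-phenome rate inference for sediment microbial
communities: translate bead-standardized index-FACS RedoxSensor Green (RSG)
fluorescence into per-cell sulfate-reduction rates, gate them by the
marker-gene content of the linked single-amplified genomes (SAGs),
extrapolate to bulk volumetric rates, and quantify metatranscriptome
abundance (RPKM) and community composition alongside.

## Who this is for

Microbial ecologists running index fluorescence-activated cell sorting on
RSG-stained environmental samples (sediment slurries, aquifer fluids) who
want to turn per-event cytometer measurements plus SAG annotation tables
into defensible per-cell and per-cm³ rates — and anyone who needs the
bookkeeping around that inference (bead calibration, serial dilutions, unit
conversion, capability fractions) to be explicit and testable.

## The model

**Calibration.** Multi-peak rainbow calibration particles carry reference
values; the per-day standard curve is piecewise linear in
log₁₀(raw)–log₁₀(reference) and cancels uniform multiplicative detector
drift. The same construction maps forward scatter to estimated cell
diameter (μm) via size-standard beads.

**Per-cell rate.** For a cell with calibrated RSG fluorescence *F*, the
sulfate-reduction rate is the power law

    R = a · F^b        [fmol cell⁻¹ h⁻¹]

with coefficients supplied by configuration (*b* = 1 is proportionality).
Rates are emitted only for RSG-stained cells whose linked SAG encodes the
dissimilatory sulfate-reduction pathway — by default the *core* rule
(*dsrA*, *dsrB*, *aprA*, *aprB* all present; *sat* optional), with a
*strict* rule requiring *sat* as well.

**Bulk extrapolation.** A mean per-cell rate R̄, capability fraction *f*
(capable / total sorted cells) and cell concentration *C* (cells cm⁻³)
give the volumetric rate

    nmol h⁻¹ cm⁻³ = R̄ · f · C / 10⁶

**Transcripts.** Reads mapped to SAG genes are normalized as
RPKM = r / ((L/1000)·(N/10⁶)) with *N* the total library reads, and
aggregated as arithmetic mean RPKM per taxon or functional category, per
sample.

## Worked example

`examples/02_single_cell_rates.py` simulates a 10,000-cell index-sorted
plate of a three-taxon community (two sulfate reducers with lognormal true
rates spanning ~0.01–5 fmol cell⁻¹ h⁻¹, one abundant non-respiring
lineage), then runs the full forward inference. It prints:

```
6019 rate estimates (3981 cells excluded: no sulfate-reduction genes)
per-cell rates span 0.010-18.93 fmol cell-1 h-1
          phylum condition    n  mean_rate  min_rate  max_rate
   Chloroflexota     0% O2 4539   0.663178  0.010000 18.925690
Desulfobacterota     0% O2 1480   0.254173  0.043336  0.843877
true mean rate Chloroflexota: 0.663 fmol cell-1 h-1
true mean rate Desulfobacterota: 0.250 fmol cell-1 h-1
```

The inferred per-taxon mean rates (0.663, 0.254) recover the configured
truths (0.663, 0.250) to well under 5%; the excluded cells are the
non-respiring lineage, whose genomes carry no pathway genes. The other
examples cover bead calibration and drift (`01`), bulk extrapolation, unit
conversion and sulfide detectability (`03`), RPKM and
transcript-vs-fluorescence pairing (`04`), and composition profiles and
lineage-set overlap (`05`) — each prints its numbers with a note on what
they mean.

A thin CLI wraps the same functions
(`sedrate simulate|calibrate|rates|bulk|rpkm|composition|run|recover|convert`);
`sedrate run --config run_config.yaml` executes the whole pipeline and
writes a manifest with input checksums and the seed.

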