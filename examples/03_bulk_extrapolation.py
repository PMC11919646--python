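"""Scaling a mean per-cell rate to a bulk volumetric rate.

Combines a mean per-cell sulfate-reduction rate with the capability
fraction and the sediment cell concentration, converts published daily
rates to hourly for comparison, and checks whether the rate in a diluted
slurry would be visible to a bulk sulfide assay.
"""

import json

from sedrate.bulk import (BulkRateInput, convert_rate, dilution_factor,
                          expected_bulk_accumulation, volumetric_rate)

# mean rate 0.55 fmol cell-1 h-1, 60% of sorted cells capable, 1e7 cells/cm3
result = volumetric_rate(BulkRateInput(
    mean_rate_fmol_per_cell_h=0.55,
    capability_fraction=0.60,
    cells_per_cm3=1.0e7))
print(json.dumps(result.as_dict(), indent=2))

# literature rates printed per day, converted to hourly for comparison
for daily in (170, 4670, 200, 4, 80):
    hourly = convert_rate(daily, "nmol day-1 cm-3", "nmol h-1 cm-3")
    print(f"{daily:5d} nmol day-1 cm-3 = {hourly:8.3f} nmol h-1 cm-3")

# a 1:10 slurry diluted 1:10 again is a 1:100 preparation
print("overall dilution fold [10, 10]:", dilution_factor([10, 10]))

# would a dilute slurry accumulate measurable sulfide over 24 h?
delta, detectable = expected_bulk_accumulation(
    rate_nmol_per_h_ml=0.001, duration_h=24.0, detection_limit_uM=0.1)
print(f"24 h accumulation: {delta:.3f} uM "
      f"({'detectable' if detectable else 'below detection'} at 0.1 uM)")

# A rate that is readily quantified per cell can still be invisible to bulk
# chemistry once the community is diluted for sorting — the motivation for
# single-cell rate measurement.
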