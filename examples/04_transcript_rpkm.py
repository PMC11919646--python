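"""RPKM transcript quantification and pairing with cell phenotypes.

Builds a small synthetic transcript library, normalizes read counts to
RPKM, aggregates by functional category, and pairs sulfate-reduction
marker-gene transcript levels with the fluorescence of the cells the
transcripts map to.
"""

import pandas as pd

from sedrate.synthetic import make_transcript_library
from sedrate.transcripts import (add_rpkm, compute_rpkm,
                                 mean_rpkm_by_category,
                                 pair_transcripts_with_rates)

# the normalizing case: 10 reads on a 1 kb gene in a 1 M-read library
print("RPKM(r=10, L=1000, N=1e6) =", compute_rpkm(10, 1000, 10**6))

# a synthetic library over the five sulfate-reduction marker genes
lib = make_transcript_library(
    [("dsrA", 1200, 400), ("dsrB", 1100, 300), ("aprA", 1900, 250),
     ("aprB", 500, 150), ("sat", 1300, 200)],
    library_size=2_000_000, seed=11)
lib["sag_id"] = "P1-A01"
lib["function"] = "sulfate reduction"
print(add_rpkm(lib).to_string(index=False))

print(mean_rpkm_by_category(lib, "function").to_string(index=False))

# pair marker transcript levels with the sorted cell's phenotype
estimates = pd.DataFrame({
    "cell_id": ["P1_A01"], "sag_id": ["P1-A01"],
    "F_cal": [550.0], "rate_fmol_per_cell_h": [0.55]})
paired = pair_transcripts_with_rates(lib, estimates)
print(paired.to_string(index=False))

# mean_marker_rpkm summarizes how actively the cell transcribed the
# pathway; F_cal is the same cell's respiration-probe fluorescence, so the
# two columns compare transcription against realized respiratory activity.
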