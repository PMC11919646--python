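"""Write a complete, purely synthetic demo dataset for pipeline runs.

Produces the file set a real study would supply — event CSV, bead-standard
TSV, SAG catalog TSV, transcript counts TSV, rate-calibration YAML and a run
config — with ground truth in a separate sidecar so nothing leaks into the
inference inputs.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .calibration import FLUORESCENCE, FORWARD_SCATTER
from .synthetic import (SimulationConfig, bead_standard, default_community,
                        default_rate_calibration, make_sorted_plate,
                        make_transcript_library, write_events_csv,
                        write_table_tsv)


def write_demo_inputs(out_dir: Path, seed: int = 11, n_wells: int = 1000,
                      condition: str = "0% O2 +laminarin") -> dict[str, Path]:
    """Generate and write the demo inputs; returns a name -> path map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(seed=seed)
    truth = default_community()
    rate_cal = default_rate_calibration()

    events, sags, truth_table = make_sorted_plate(
        truth, config, n_wells, rate_cal, condition=condition)

    bead_rows = []
    for channel in (FLUORESCENCE, FORWARD_SCATTER):
        std = bead_standard(config, channel)
        for raw, ref in std.peaks:
            bead_rows.append({"channel": channel, "raw_median": raw,
                              "reference_value": ref,
                              "day": std.acquisition_day})
    beads = pd.DataFrame(bead_rows)

    # marker-gene transcripts for a handful of capable SAGs
    capable = sags[(sags[["aprA", "aprB", "dsrA", "dsrB"]].sum(axis=1) == 4)]
    gene_rows = []
    for j, sag_id in enumerate(capable["sag_id"].head(20)):
        lib = make_transcript_library(
            [("dsrA", 1200, 40 + 7 * j), ("dsrB", 1100, 30 + 5 * j),
             ("aprA", 1900, 25 + 3 * j), ("aprB", 500, 15 + 2 * j),
             ("sat", 1300, 20 + 2 * j)],
            library_size=2_000_000, seed=seed + j, sample="lib_0pctO2")
        lib.insert(1, "sag_id", sag_id)
        lib["taxonomy"] = sags.set_index("sag_id").loc[sag_id, "taxonomy"]
        gene_rows.append(lib)
    counts = pd.concat(gene_rows, ignore_index=True)

    paths = {
        "events": out_dir / "events.csv",
        "beads": out_dir / "beads.tsv",
        "sags": out_dir / "sags.tsv",
        "counts": out_dir / "counts.tsv",
        "rate_calibration": out_dir / "rate_calibration.yaml",
        "truth": out_dir / "truth_sidecar.tsv",
        "config": out_dir / "run_config.yaml",
    }
    write_events_csv(events, paths["events"], seed=seed)
    write_table_tsv(beads, paths["beads"], seed=seed)
    write_table_tsv(sags, paths["sags"], seed=seed)
    write_table_tsv(counts, paths["counts"], seed=seed)
    write_table_tsv(truth_table, paths["truth"], seed=seed)
    with open(paths["rate_calibration"], "w") as fh:
        yaml.safe_dump({"a": rate_cal.a, "b": rate_cal.b,
                        "f_min": rate_cal.f_min, "f_max": rate_cal.f_max,
                        "provenance": rate_cal.provenance}, fh)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump({
            "events": "events.csv", "beads": "beads.tsv", "sags": "sags.tsv",
            "counts": "counts.tsv", "rate_calibration": "rate_calibration.yaml",
            "out_dir": "out", "rule": "core", "rank": "phylum",
            "dilution_chain": [10, 10], "analyzed_volume_ml": 1.0,
            "cells_per_cm3": 1.0e7, "seed": seed,
            "conditions": [condition]}, fh, sort_keys=False)
    return paths
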