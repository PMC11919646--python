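"""Synthetic bead samples, sorted plates and transcript libraries.

Every downstream stage (calibration, capability gating, rate inference, bulk
extrapolation, RPKM) is testable without instrument data because this module
generates its inputs from known ground truth:

* multi-peak bead samples with lognormal spread and a per-day multiplicative
  detector-drift factor;
* index-sorted plates of a mixed-taxon community whose RSG fluorescence is
  produced by pushing known true per-cell rates through the *inverse* of the
  rate calibration and the *inverse* of the bead standard curve — so the
  forward pipeline must recover the truth;
* SAG marker-gene tables where genome incompleteness drives independent
  Bernoulli dropout of each marker the lineage genuinely carries;
* transcript libraries with multinomially allocated read counts.

All randomness flows from one explicitly passed seeded generator; ground
truth is written to a sidecar table, never to the files the inference
consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import (BeadStandard, CalibrationCurve, FLUORESCENCE,
                          FORWARD_SCATTER, fit_reference_curve)
from .errors import ConfigError
from .rates import RSG, RateCalibration

EVENT_COLUMNS = ["event_id", "sample_id", "stain", "FL1_raw", "FSC_raw",
                 "well", "plate", "condition", "day"]


def _sigma_from_cv(cv: float) -> float:
    """Lognormal shape parameter giving a multiplicative coefficient of
    variation ``cv`` (median-preserving: cv=0 -> no spread)."""
    if cv < 0:
        raise ConfigError(f"coefficient of variation must be >= 0, got {cv}")
    return float(np.sqrt(np.log1p(cv * cv)))


@dataclass(frozen=True)
class TaxonSpec:
    """Ground-truth description of one lineage in the simulated community."""

    label: str
    fraction: float
    rate_meanlog: float = 0.0     # ln fmol cell^-1 h^-1
    rate_sdlog: float = 0.0
    diameter_meanlog: float = 0.0  # ln um
    diameter_sdlog: float = 0.0
    markers: frozenset = frozenset()
    respiring: bool = True
    taxonomy: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ConfigError(f"taxon fraction must be in [0,1], got "
                              f"{self.fraction} for {self.label}")
        for name, v in (("rate_meanlog", self.rate_meanlog),
                        ("rate_sdlog", self.rate_sdlog),
                        ("diameter_meanlog", self.diameter_meanlog),
                        ("diameter_sdlog", self.diameter_sdlog)):
            if not np.isfinite(v):
                raise ConfigError(f"{name} must be finite for {self.label}")
        if self.rate_sdlog < 0 or self.diameter_sdlog < 0:
            raise ConfigError(f"sdlog must be >= 0 for {self.label}")
        if not self.taxonomy:
            object.__setattr__(
                self, "taxonomy",
                f"d__Bacteria;p__{self.label};c__{self.label}ia;o__;f__;g__;s__")

    @property
    def true_mean_rate(self) -> float:
        """Arithmetic mean of the configured lognormal rate distribution."""
        return float(np.exp(self.rate_meanlog + 0.5 * self.rate_sdlog ** 2))


@dataclass(frozen=True)
class CommunityTruth:
    """The simulated community: lineages, abundances and capabilities."""

    taxa: tuple[TaxonSpec, ...]

    def __post_init__(self) -> None:
        if not self.taxa:
            raise ConfigError("community must contain >=1 taxon")
        total = sum(t.fraction for t in self.taxa)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"taxon fractions must sum to 1, got {total}")

    @property
    def fractions(self) -> np.ndarray:
        return np.array([t.fraction for t in self.taxa])


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; fixed seed => byte-identical outputs.

    ``bead_peaks`` are (reference_value, raw_median, cv) triples for the
    fluorescence standard; ``size_bead_peaks`` the same for the forward
    scatter size standard with micrometre references.  ``drift`` maps
    acquisition-day labels to the multiplicative detector factor applied to
    every raw channel that day.
    """

    seed: int = 0
    n_events: int = 1000
    bead_peaks: tuple = (
        (10.0, 12.0, 0.05), (30.0, 40.0, 0.05), (100.0, 130.0, 0.05),
        (300.0, 420.0, 0.05), (1000.0, 1300.0, 0.05), (3000.0, 4200.0, 0.05),
        (10000.0, 13000.0, 0.05), (30000.0, 42000.0, 0.05))
    size_bead_peaks: tuple = (
        (0.5, 200.0, 0.05), (1.0, 1500.0, 0.05),
        (2.0, 10000.0, 0.05), (4.0, 60000.0, 0.05))
    completeness: float = 1.0
    drift: dict = field(default_factory=lambda: {"day1": 1.0})
    fluorescence_cv: float = 0.1
    scatter_cv: float = 0.1
    fluorescence_floor_raw: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 1.0:
            raise ConfigError(f"completeness must be in [0,1], got "
                              f"{self.completeness}")
        for peaks, what in ((self.bead_peaks, "bead"),
                            (self.size_bead_peaks, "size bead")):
            for ref, raw, cv in peaks:
                if raw <= 0:
                    raise ConfigError(f"non-positive raw median {raw} in "
                                      f"{what} peaks")
                if ref <= 0:
                    raise ConfigError(f"non-positive reference {ref} in "
                                      f"{what} peaks")
                _sigma_from_cv(cv)
        for day, f in self.drift.items():
            if not f > 0:
                raise ConfigError(f"drift factor for {day!r} must be > 0")

    def drift_factor(self, day: str) -> float:
        if day not in self.drift:
            raise ConfigError(f"no drift factor configured for day {day!r}")
        return self.drift[day]

    def rng(self, *stream: int) -> np.random.Generator:
        """Child generator for an independent named stream."""
        return np.random.default_rng([self.seed, *stream])

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["bead_peaks"] = [list(p) for p in self.bead_peaks]
        doc["size_bead_peaks"] = [list(p) for p in self.size_bead_peaks]
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


# --- bead standards ---------------------------------------------------------


def bead_standard(config: SimulationConfig, channel: str = FLUORESCENCE,
                  day: str = "day1") -> BeadStandard:
    """The bead standard an operator would tabulate on ``day`` (raw medians
    carry that day's detector drift)."""
    peaks = config.bead_peaks if channel == FLUORESCENCE else config.size_bead_peaks
    d = config.drift_factor(day)
    return BeadStandard(channel=channel, acquisition_day=day,
                        peaks=tuple((raw * d, ref) for ref, raw, _ in peaks))


def reference_curve(config: SimulationConfig, channel: str = FLUORESCENCE,
                    day: str = "day1", policy: str = "clamp") -> CalibrationCurve:
    return fit_reference_curve(bead_standard(config, channel, day), policy=policy)


def make_bead_sample(config: SimulationConfig, n_per_peak: int,
                     channel: str = FLUORESCENCE, day: str = "day1"
                     ) -> pd.DataFrame:
    """Simulate acquisition of a multi-peak bead sample.

    Events cluster lognormally around each peak's raw median (scaled by the
    day's drift factor); the generating peak index is retained in a
    ``peak_label`` column for testing peak-assignment code.
    """
    peaks = config.bead_peaks if channel == FLUORESCENCE else config.size_bead_peaks
    if len(peaks) < 2:
        raise ConfigError("bead sample needs >=2 peaks")
    if n_per_peak < 1:
        raise ConfigError("n_per_peak must be >= 1")
    d = config.drift_factor(day)
    rng = config.rng(1, {FLUORESCENCE: 0, FORWARD_SCATTER: 1}[channel])
    rows = []
    for k, (ref, raw, cv) in enumerate(peaks):
        sigma = _sigma_from_cv(cv)
        vals = raw * d * np.exp(sigma * rng.standard_normal(n_per_peak))
        rows.append(pd.DataFrame({
            "event_id": [f"bead_{day}_{k}_{i}" for i in range(n_per_peak)],
            "sample_id": f"beads_{channel}_{day}",
            "stain": "beads",
            "raw": vals,
            "peak_label": k,
            "reference_value": ref,
            "day": day,
        }))
    out = pd.concat(rows, ignore_index=True)
    col = "FL1_raw" if channel == FLUORESCENCE else "FSC_raw"
    return out.rename(columns={"raw": col})


# --- sorted plates ----------------------------------------------------------


def _well_names(n: int) -> list[str]:
    """A01..P24 style well labels, extending to extra plates' worth if n>384."""
    rows = "ABCDEFGHIJKLMNOP"
    names = []
    i = 0
    while len(names) < n:
        names.append(f"{rows[(i // 24) % 16]}{i % 24 + 1:02d}")
        if i >= 383:  # beyond one 384-well plate, suffix to stay unique
            names[-1] += f"_{i // 384}"
        i += 1
    return names[:n]


def make_sorted_plate(truth: CommunityTruth, config: SimulationConfig,
                      n_wells: int, rate_cal: RateCalibration,
                      plate: str = "P1", stain: str = RSG,
                      condition: str = "0% O2", day: str = "day1"
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one index-sorted plate of the community.

    Returns ``(events, sags, truth_table)``:

    * ``events`` — the cytometer's view: raw fluorescence and scatter plus
      sort metadata (what the calibration stage consumes);
    * ``sags`` — the annotation table: taxonomy, completeness, marker genes
      after incompleteness-driven dropout (what the gating stage consumes);
    * ``truth_table`` — the sidecar with true rates/taxa/diameters, used only
      by tests and recovery reports.

    A respiring cell's raw fluorescence is the inverse bead-curve image of
    the inverse rate-calibration image of its true rate, times multiplicative
    lognormal noise and the day's drift; non-respiring taxa emit background
    below the configured raw fluorescence floor.
    """
    if n_wells < 1:
        raise ConfigError("n_wells must be >= 1")
    rng = config.rng(2)
    d = config.drift_factor(day)
    fl_curve = reference_curve(config, FLUORESCENCE, day)
    size_curve = reference_curve(config, FORWARD_SCATTER, day)

    taxon_idx = rng.choice(len(truth.taxa), size=n_wells, p=truth.fractions)
    wells = _well_names(n_wells)
    sig_f = _sigma_from_cv(config.fluorescence_cv)
    sig_s = _sigma_from_cv(config.scatter_cv)

    true_rate = np.full(n_wells, np.nan)
    fl_raw = np.empty(n_wells)
    diam_true = np.empty(n_wells)
    for i, ti in enumerate(taxon_idx):
        t = truth.taxa[ti]
        diam_true[i] = np.exp(t.diameter_meanlog
                              + t.diameter_sdlog * rng.standard_normal())
        if t.respiring:
            r = float(np.exp(t.rate_meanlog
                             + t.rate_sdlog * rng.standard_normal()))
            true_rate[i] = r
            f_true = float(rate_cal.inverse(np.array([r]))[0])
            f_noisy = f_true * np.exp(sig_f * rng.standard_normal())
            fl_raw[i] = float(fl_curve.inverse(np.array([f_noisy]))[0])
        else:
            # background: strictly below the fluorescence floor
            fl_raw[i] = config.fluorescence_floor_raw * d \
                * rng.uniform(0.05, 0.95)
    diam_noisy = diam_true * np.exp(sig_s * rng.standard_normal(n_wells))
    fsc_raw = size_curve.inverse(diam_noisy)

    events = pd.DataFrame({
        "event_id": [f"{plate}_{w}" for w in wells],
        "sample_id": f"{plate}_{stain}",
        "stain": stain,
        "FL1_raw": fl_raw,
        "FSC_raw": fsc_raw,
        "well": wells,
        "plate": plate,
        "condition": condition,
        "day": day,
    })

    sag_rows = []
    for i, (w, ti) in enumerate(zip(wells, taxon_idx)):
        t = truth.taxa[ti]
        present = {m: int(m in t.markers
                          and rng.random() < config.completeness)
                   for m in ("sat", "aprA", "aprB", "dsrA", "dsrB")}
        sag_rows.append({"sag_id": f"{plate}-{w}", "plate": plate, "well": w,
                         "taxonomy": t.taxonomy,
                         "completeness": config.completeness * 100.0,
                         **present})
    sags = pd.DataFrame(sag_rows)

    truth_table = pd.DataFrame({
        "plate": plate, "well": wells,
        "true_taxon": [truth.taxa[ti].label for ti in taxon_idx],
        "true_rate_fmol_per_cell_h": true_rate,
        "true_diameter_um": diam_true,
        "respiring": [truth.taxa[ti].respiring for ti in taxon_idx],
    })
    return events, sags, truth_table


# --- transcript libraries ---------------------------------------------------


def make_transcript_library(genes, library_size: int, seed: int,
                            sample: str = "lib1") -> pd.DataFrame:
    """Multinomial read allocation over genes with probabilities
    proportional to expected reads.

    ``genes`` is a list of ``(gene_id, length_bp, expected_reads)``; the
    total mapped reads equals the (rounded) sum of expectations and must not
    exceed ``library_size``.
    """
    if library_size < 1:
        raise ConfigError("library_size must be >= 1")
    genes = list(genes)
    if not genes:
        raise ConfigError("need >=1 gene")
    ids = [g[0] for g in genes]
    lengths = np.array([g[1] for g in genes], dtype=float)
    expected = np.array([g[2] for g in genes], dtype=float)
    if np.any(lengths < 1):
        raise ConfigError("gene lengths must be >= 1 bp")
    if np.any(expected < 0):
        raise ConfigError("expected reads must be >= 0")
    total = int(round(expected.sum()))
    if total > library_size:
        raise ConfigError(f"expected reads ({total}) exceed library size "
                          f"({library_size})")
    rng = np.random.default_rng([seed, 3])
    if total == 0:
        counts = np.zeros(len(genes), dtype=int)
    else:
        counts = rng.multinomial(total, expected / expected.sum())
    return pd.DataFrame({"gene_id": ids, "length_bp": lengths.astype(int),
                         "reads": counts, "library_size": library_size,
                         "sample": sample})


# --- canonical scenario -----------------------------------------------------


def default_community() -> CommunityTruth:
    """The stock three-taxon sediment community used throughout tests,
    examples and the recovery harness.

    Two sulfate-reducing lineages whose true-rate lognormals span roughly
    0.01-5 fmol cell^-1 h^-1 at the 1st/99th percentiles (a broad
    Chloroflexota-like distribution and a narrower Desulfobacterota-like
    one) plus an abundant non-respiring, marker-free Patescibacteria-like
    lineage that only ever shows background fluorescence.
    """
    sr_panel = frozenset({"sat", "aprA", "aprB", "dsrA", "dsrB"})
    return CommunityTruth(taxa=(
        TaxonSpec(label="Chloroflexota", fraction=0.45,
                  rate_meanlog=float(np.log(0.37)), rate_sdlog=1.08,
                  diameter_meanlog=float(np.log(0.8)), diameter_sdlog=0.25,
                  markers=sr_panel, respiring=True),
        TaxonSpec(label="Desulfobacterota", fraction=0.15,
                  rate_meanlog=float(np.log(0.226)), rate_sdlog=0.447,
                  diameter_meanlog=float(np.log(1.0)), diameter_sdlog=0.2,
                  markers=sr_panel, respiring=True),
        TaxonSpec(label="Patescibacteria", fraction=0.40,
                  diameter_meanlog=float(np.log(0.4)), diameter_sdlog=0.15,
                  markers=frozenset(), respiring=False),
    ))


def default_rate_calibration() -> RateCalibration:
    """Stock power-law rate calibration (proportional, a = 1e-3) placing the
    0.01-5 fmol cell^-1 h^-1 range inside the bead-calibrated span."""
    return RateCalibration(a=1e-3, b=1.0, f_min=1.0, f_max=5e4,
                           provenance="synthetic default")


# --- writers ----------------------------------------------------------------


def write_events_csv(events: pd.DataFrame, path: str | Path,
                     seed: int | None = None) -> None:
    _write_table(events, path, sep=",", seed=seed)


def write_table_tsv(df: pd.DataFrame, path: str | Path,
                    seed: int | None = None) -> None:
    _write_table(df, path, sep="\t", seed=seed)


def _write_table(df: pd.DataFrame, path, sep: str, seed: int | None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep=sep, index=False)
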