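"""Per-cell sulfate-reduction rate inference from calibrated RSG fluorescence.

RedoxSensor Green (RSG) fluorescence scales with a cell's respiratory
electron-transfer activity.  Once fluorescence is expressed in bead-calibrated
units, a previously established empirical calibration translates it into a
sulfate-reduction rate.  The calibration is modelled as a power law

    R = a * F**b          [fmol cell^-1 h^-1]

with coefficients supplied by configuration (b = 1 reduces to simple
proportionality).  Rates are only meaningful for cells whose linked genome
encodes the sulfate-reduction pathway, so estimates are emitted exclusively
for capability-gated, RSG-stained cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataIntegrityError
from .sags import RANKS, marker_set, required_markers

logger = logging.getLogger(__name__)

RSG = "RSG"
SYTO9 = "SYTO9"


@dataclass(frozen=True)
class RateCalibration:
    """Power-law fluorescence -> rate calibration R = a * F**b.

    ``a`` is the rate (fmol cell^-1 h^-1) at unit calibrated fluorescence,
    ``b`` the dimensionless exponent; [f_min, f_max] is the fluorescence
    range over which the calibration was established — values outside it are
    converted anyway but flagged as extrapolated.
    """

    a: float
    b: float = 1.0
    f_min: float = 1.0
    f_max: float = 1e6
    provenance: str = ""

    def __post_init__(self) -> None:
        if not (self.a > 0 and np.isfinite(self.a)):
            raise ConfigError(f"calibration coefficient a must be > 0, got {self.a}")
        if not (self.b > 0 and np.isfinite(self.b)):
            raise ConfigError(f"calibration exponent b must be > 0, got {self.b}")
        if not self.f_min < self.f_max:
            raise ConfigError(
                f"calibration range invalid: f_min={self.f_min} >= f_max={self.f_max}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RateCalibration":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict) or "a" not in doc:
            raise ConfigError(f"rate calibration file {path} must define 'a'")
        return cls(a=float(doc["a"]), b=float(doc.get("b", 1.0)),
                   f_min=float(doc.get("f_min", 1.0)),
                   f_max=float(doc.get("f_max", 1e6)),
                   provenance=str(doc.get("provenance", "")))

    def rate(self, f_cal: np.ndarray) -> np.ndarray:
        f_cal = np.asarray(f_cal, dtype=float)
        if np.any(~np.isfinite(f_cal)) or np.any(f_cal <= 0):
            raise ConfigError("calibrated fluorescence must be positive and finite")
        return self.a * f_cal ** self.b

    def inverse(self, rate: np.ndarray) -> np.ndarray:
        """Fluorescence producing a given rate: F = (R/a)**(1/b).

        Used by the synthetic generator to paint known true rates onto cells.
        """
        rate = np.asarray(rate, dtype=float)
        if np.any(rate <= 0):
            raise ConfigError("rates must be positive to invert the calibration")
        return (rate / self.a) ** (1.0 / self.b)


def fluorescence_to_rate(f_cal, cal: RateCalibration):
    """Translate calibrated RSG fluorescence into a per-cell rate
    (fmol cell^-1 h^-1).  Scalar in, scalar out; array in, array out."""
    scalar = np.isscalar(f_cal)
    r = cal.rate(np.atleast_1d(np.asarray(f_cal, dtype=float)))
    return float(r[0]) if scalar else r


def _drop_well_collisions(cells: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Two events claiming one (plate, well) make the index-sort identity
    ambiguous: keep neither, log the collision."""
    if not {"plate", "well"} <= set(cells.columns):
        return cells, 0
    dup_mask = cells.duplicated(subset=["plate", "well"], keep=False)
    n = int(dup_mask.sum())
    if n:
        logger.warning("rate_table: dropping %d events in colliding wells", n)
    return cells.loc[~dup_mask], n


def rate_table(cells: pd.DataFrame, cal: RateCalibration,
               rule: str = "core") -> pd.DataFrame:
    """Per-cell rate estimates for capability-gated, RSG-stained linked cells.

    ``cells`` is a linked-cell table: one row per index-sorted event joined
    to its SAG, with at least ``F_cal`` (calibrated RSG fluorescence),
    ``stain``, marker-gene 0/1 columns, and optionally ``diameter_um``,
    taxonomy ranks and ``condition``.

    Returns one estimate per capable RSG cell; excluded cells are counted in
    ``result.attrs`` (``n_excluded_stain``, ``n_excluded_incapable``,
    ``n_well_collisions``).  SYTO-9-stained events never receive rates: that
    stain marks DNA, not respiratory activity.
    """
    if cal is None:
        raise ConfigError("rate_table requires a rate calibration")
    if "F_cal" not in cells.columns:
        raise ConfigError("linked-cell table lacks calibrated fluorescence 'F_cal'")
    if "stain" not in cells.columns:
        raise ConfigError("linked-cell table lacks 'stain'")

    cells, n_collisions = _drop_well_collisions(cells)

    is_rsg = cells["stain"] == RSG
    n_excl_stain = int((~is_rsg).sum())
    rsg = cells.loc[is_rsg]

    need = required_markers(rule)
    capable = rsg.apply(lambda row: need <= marker_set(row), axis=1) \
        if len(rsg) else pd.Series(dtype=bool)
    n_excl_incap = int((~capable).sum()) if len(rsg) else 0
    kept = rsg.loc[capable] if len(rsg) else rsg

    out = pd.DataFrame(index=kept.index)
    id_col = "event_id" if "event_id" in kept.columns else None
    out["cell_id"] = kept[id_col] if id_col else kept.index.astype(str)
    f = kept["F_cal"].to_numpy(dtype=float)
    out["F_cal"] = f
    out["rate_fmol_per_cell_h"] = cal.rate(f) if len(kept) else []
    out["out_of_cal_range"] = (f < cal.f_min) | (f > cal.f_max)
    if "F_cal_clamped" in kept.columns:
        out["fluorescence_clamped"] = kept["F_cal_clamped"].astype(bool)
    for col in ("diameter_um", "condition", "sag_id", "plate", "well",
                "taxonomy", *RANKS):
        if col in kept.columns:
            out[col] = kept[col]
    if "taxonomy" in kept.columns:
        from .sags import parse_taxonomy
        for rank in ("phylum", "class"):
            if rank not in out.columns:
                out[rank] = [parse_taxonomy(t)[rank] for t in kept["taxonomy"]]
    out = out.reset_index(drop=True)
    out.attrs["n_excluded_stain"] = n_excl_stain
    out.attrs["n_excluded_incapable"] = n_excl_incap
    out.attrs["n_well_collisions"] = n_collisions
    out.attrs["rule"] = rule
    assert (out["rate_fmol_per_cell_h"] >= 0).all()
    return out


def per_taxon_rate_summary(estimates: pd.DataFrame, rank: str = "phylum",
                           by_condition: bool = True,
                           mean: str = "arithmetic") -> pd.DataFrame:
    """Grouped (n, mean, min, max) of per-cell rates, keyed by taxon
    (and incubation condition when available).

    The headline summary is the arithmetic mean rate per capable cell;
    ``mean="geometric"`` is available for lognormal-like rate distributions.
    """
    if len(estimates) == 0:
        raise DataIntegrityError("per_taxon_rate_summary needs >=1 estimate")
    if mean not in ("arithmetic", "geometric"):
        raise ConfigError(f"unknown mean type {mean!r}")
    df = estimates.copy()
    if rank in df.columns:
        df["_taxon"] = df[rank]
    elif "taxonomy" in df.columns:
        from .sags import parse_taxonomy
        df["_taxon"] = [parse_taxonomy(t)[rank] for t in df["taxonomy"]]
    else:
        raise ConfigError(f"estimates carry neither {rank!r} nor 'taxonomy'")
    keys = ["_taxon"]
    if by_condition and "condition" in df.columns:
        keys.append("condition")

    def _agg(g: pd.Series) -> pd.Series:
        vals = g.to_numpy(dtype=float)
        m = float(np.exp(np.mean(np.log(vals)))) if mean == "geometric" \
            else float(vals.mean())
        return pd.Series({"n": len(vals), "mean_rate": m,
                          "min_rate": float(vals.min()),
                          "max_rate": float(vals.max())})

    out = (df.groupby(keys, sort=True)["rate_fmol_per_cell_h"]
           .apply(_agg).unstack().reset_index()
           .rename(columns={"_taxon": rank}))
    out["n"] = out["n"].astype(int)
    return out


def total_sample_fluorescence(events: pd.DataFrame, analyzed_volume_ml: float,
                              column: str = "F_cal") -> float:
    """Volume-normalized total fluorescence of a gated sample.

    Sums the (calibrated) green fluorescence of every gated event and divides
    by the analyzed volume — a whole-community activity proxy that needs no
    genome linkage.
    """
    if not analyzed_volume_ml > 0:
        raise ConfigError(f"analyzed volume must be > 0 ml, got {analyzed_volume_ml}")
    if column not in events.columns:
        raise ConfigError(f"event table lacks fluorescence column {column!r}")
    return float(events[column].to_numpy(dtype=float).sum()) / analyzed_volume_ml
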