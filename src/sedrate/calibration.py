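"""Bead-standard calibration of flow-cytometer channels.

Raw cytometer channels (green fluorescence, forward scatter) are in arbitrary
units that drift from day to day with detector settings.  Multi-peak rainbow
calibration particles carry manufacturer-assigned reference values, so running
a bead sample alongside the cells gives, per acquisition day, a set of
(raw median, reference value) pairs from which a monotone standard curve is
fitted.  Applying that curve expresses every event on a bead-referenced scale
(calibrated fluorescence units, or micrometres for the size standard), which
cancels any uniform multiplicative detector drift.

The curve is piecewise linear in log10(raw) vs log10(reference): bead
intensities span several decades and log-linearity is the standard convention
for molecules-of-equivalent-fluorophore style standardization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CalibrationError

logger = logging.getLogger(__name__)

FLUORESCENCE = "fluorescence"
FORWARD_SCATTER = "forward_scatter"
_CHANNELS = (FLUORESCENCE, FORWARD_SCATTER)

#: default raw column per channel in event tables
CHANNEL_COLUMNS = {FLUORESCENCE: "FL1_raw", FORWARD_SCATTER: "FSC_raw"}


@dataclass(frozen=True)
class BeadStandard:
    """Reference peaks for one bead lot on one channel on one acquisition day.

    ``peaks`` is an ordered list of ``(raw_median, reference_value)`` pairs;
    raw medians are in instrument arbitrary units, reference values in
    calibrated fluorescence units (or micrometres for forward scatter).
    """

    channel: str
    peaks: tuple[tuple[float, float], ...]
    acquisition_day: str = ""

    def __post_init__(self) -> None:
        if self.channel not in _CHANNELS:
            raise CalibrationError(
                f"unknown channel {self.channel!r}; expected one of {_CHANNELS}"
            )
        if len(self.peaks) < 2:
            raise CalibrationError(
                f"bead standard needs >=2 peaks, got {len(self.peaks)}"
            )
        raws = [p[0] for p in self.peaks]
        refs = [p[1] for p in self.peaks]
        for name, vals in (("raw median", raws), ("reference value", refs)):
            for v in vals:
                if not np.isfinite(v) or v <= 0:
                    raise CalibrationError(f"non-positive {name}: {v!r}")
            for lo, hi in zip(vals, vals[1:]):
                if hi <= lo:
                    raise CalibrationError(
                        f"{name}s must be strictly increasing; "
                        f"offending pair ({lo}, {hi})"
                    )

    @classmethod
    def from_table(cls, df: pd.DataFrame, channel: str, day: str | None = None
                   ) -> "BeadStandard":
        """Build from a TSV-style table with columns
        channel, raw_median, reference_value[, day]."""
        sub = df[df["channel"] == channel]
        if day is not None and "day" in sub.columns:
            sub = sub[sub["day"].astype(str) == str(day)]
        sub = sub.sort_values("raw_median")
        peaks = tuple(zip(sub["raw_median"].astype(float),
                          sub["reference_value"].astype(float)))
        return cls(channel=channel, peaks=peaks,
                   acquisition_day="" if day is None else str(day))


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone raw-channel -> calibrated-unit mapping.

    Knots are stored in log10 space.  ``policy`` controls behaviour outside
    the knot range: ``clamp`` pins values to the end references (and flags
    them), ``extend`` continues the terminal log-log segments.
    """

    channel: str
    log_raw: np.ndarray
    log_ref: np.ndarray
    policy: str = "clamp"

    def __post_init__(self) -> None:
        if self.policy not in ("clamp", "extend"):
            raise CalibrationError(f"unknown extrapolation policy {self.policy!r}")

    @property
    def raw_range(self) -> tuple[float, float]:
        return (10.0 ** self.log_raw[0], 10.0 ** self.log_raw[-1])

    def apply(self, raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map raw channel values to calibrated units.

        Returns ``(calibrated, out_of_range)`` where the second array flags
        events outside the knot range (clamped under the default policy).
        """
        raw = np.asarray(raw, dtype=float)
        if np.any(~np.isfinite(raw)) or np.any(raw <= 0):
            raise CalibrationError("raw channel values must be positive and finite")
        x = np.log10(raw)
        flagged = (x < self.log_raw[0]) | (x > self.log_raw[-1])
        if self.policy == "clamp":
            y = np.interp(x, self.log_raw, self.log_ref)
        else:  # extend terminal segments
            y = np.interp(x, self.log_raw, self.log_ref)
            lo_slope = ((self.log_ref[1] - self.log_ref[0])
                        / (self.log_raw[1] - self.log_raw[0]))
            hi_slope = ((self.log_ref[-1] - self.log_ref[-2])
                        / (self.log_raw[-1] - self.log_raw[-2]))
            below = x < self.log_raw[0]
            above = x > self.log_raw[-1]
            y = np.where(below, self.log_ref[0] + lo_slope * (x - self.log_raw[0]), y)
            y = np.where(above, self.log_ref[-1] + hi_slope * (x - self.log_raw[-1]), y)
        return 10.0 ** y, flagged

    def apply_scalar(self, raw: float) -> float:
        return float(self.apply(np.array([raw]))[0][0])

    def inverse(self, ref: np.ndarray) -> np.ndarray:
        """Map calibrated units back to raw channel values (monotone inverse).

        Used by the synthetic-data generator to emit raw channels from known
        calibrated truths; uses the ``extend`` behaviour so round trips are
        exact everywhere the forward curve is unflagged.
        """
        ref = np.asarray(ref, dtype=float)
        if np.any(~np.isfinite(ref)) or np.any(ref <= 0):
            raise CalibrationError("reference values must be positive and finite")
        inv = CalibrationCurve(channel=self.channel, log_raw=self.log_ref,
                               log_ref=self.log_raw, policy="extend")
        return inv.apply(ref)[0]


def fit_reference_curve(standard: BeadStandard, policy: str = "clamp"
                        ) -> CalibrationCurve:
    """Fit the piecewise log-log standard curve through every bead peak."""
    raws = np.array([p[0] for p in standard.peaks], dtype=float)
    refs = np.array([p[1] for p in standard.peaks], dtype=float)
    return CalibrationCurve(channel=standard.channel,
                            log_raw=np.log10(raws),
                            log_ref=np.log10(refs),
                            policy=policy)


def assign_bead_peaks(values: np.ndarray, n_peaks: int,
                      max_iter: int = 100) -> np.ndarray:
    """Partition a mixed bead sample into ``n_peaks`` clusters (1-D k-means).

    Works on log10(value); centers are initialized at evenly spaced sample
    quantiles, ties are broken toward the lower peak.  Returns the peak index
    (0 = dimmest) per event.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise CalibrationError("bead events must have positive channel values")
    if n_peaks < 1:
        raise CalibrationError("n_peaks must be >= 1")
    x = np.log10(values)
    qs = (np.arange(n_peaks) + 0.5) / n_peaks
    centers = np.quantile(x, qs)
    labels = np.zeros(len(x), dtype=int)
    for _ in range(max_iter):
        d = np.abs(x[:, None] - centers[None, :])
        # argmin returns the first (lower) peak on ties
        new_labels = np.argmin(d, axis=1)
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
        for k in range(n_peaks):
            sel = labels == k
            if sel.any():
                centers[k] = x[sel].mean()
        centers = np.sort(centers)
    return labels


def summarize_bead_peaks(values: np.ndarray, n_peaks: int) -> np.ndarray:
    """Per-peak raw medians of a mixed bead sample, dimmest first."""
    labels = assign_bead_peaks(values, n_peaks)
    values = np.asarray(values, dtype=float)
    return np.array([np.median(values[labels == k]) for k in range(n_peaks)])


def apply_calibration(events: pd.DataFrame, curve: CalibrationCurve,
                      raw_column: str | None = None,
                      out_column: str | None = None) -> pd.DataFrame:
    """Add a calibrated column (plus out-of-range flag) to an event table.

    Rows whose raw value is zero/negative or non-finite are rejected
    (dropped) with a logged count, per the gating contract that only events
    with positive channel values are analyzable.
    """
    raw_column = raw_column or CHANNEL_COLUMNS[curve.channel]
    if raw_column not in events.columns:
        raise CalibrationError(f"event table lacks raw column {raw_column!r}")
    default_out = {FLUORESCENCE: "F_cal", FORWARD_SCATTER: "FSC_cal"}[curve.channel]
    out_column = out_column or default_out

    raw = pd.to_numeric(events[raw_column], errors="coerce")
    ok = np.isfinite(raw) & (raw > 0)
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning("apply_calibration: rejected %d events with "
                       "non-positive %s", n_rejected, raw_column)
    out = events.loc[ok].copy()
    cal, flagged = curve.apply(raw[ok].to_numpy())
    out[out_column] = cal
    out[out_column + "_clamped"] = flagged
    out.attrs["n_rejected"] = n_rejected
    return out


def estimate_diameter(events: pd.DataFrame, size_curve: CalibrationCurve,
                      raw_column: str = "FSC_raw") -> pd.DataFrame:
    """Estimate cell diameter (um) from forward scatter via the size-bead curve."""
    if size_curve.channel != FORWARD_SCATTER:
        raise CalibrationError(
            "diameter estimation requires a forward_scatter calibration curve")
    return apply_calibration(events, size_curve, raw_column=raw_column,
                             out_column="diameter_um")
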