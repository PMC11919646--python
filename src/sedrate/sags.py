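"""SAG catalog: taxonomy parsing and sulfate-reduction capability calls.

A single amplified genome (SAG) is the partial genome recovered from one
index-sorted cell.  Capability for dissimilatory sulfate reduction is called
from presence of the pathway's marker genes — sat (sulfate
adenylyltransferase), aprA/aprB (APS reductase) and dsrA/dsrB (dissimilatory
sulfite reductase).  Because SAGs are incomplete (tens of percent of the
genome recovered), absence of a marker is weak evidence, so the default
"core" rule requires the four dsrAB/aprAB subunits and treats sat as
optional; a "strict" rule requiring sat as well is kept as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ConfigError, DataIntegrityError

#: GTDB rank prefixes in order
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")

#: full marker panel of the dissimilatory sulfate-reduction pathway
MARKER_PANEL = frozenset({"sat", "aprA", "aprB", "dsrA", "dsrB"})
#: markers required by the default capability rule
CORE_MARKERS = frozenset({"aprA", "aprB", "dsrA", "dsrB"})

RULES = ("core", "strict")


def parse_taxonomy(gtdb_string: str) -> dict[str, str]:
    """Parse a GTDB rank-prefixed lineage string into the seven ranks.

    Empty ranks inherit an ``unclassified_<parent>`` placeholder so that
    grouping at any rank never silently drops cells.

    >>> parse_taxonomy("d__Bacteria;p__Chloroflexota;c__Dehalococcoidia;"
    ...                "o__;f__;g__;s__")["class"]
    'Dehalococcoidia'
    """
    tokens = [t.strip() for t in gtdb_string.strip().split(";")]
    if len(tokens) != len(RANKS):
        raise DataIntegrityError(
            f"expected {len(RANKS)} semicolon-delimited ranks, "
            f"got {len(tokens)} in {gtdb_string!r}")
    out: dict[str, str] = {}
    parent = "root"
    for rank, prefix, token in zip(RANKS, _PREFIXES, tokens):
        if not token.startswith(prefix):
            raise DataIntegrityError(
                f"malformed rank prefix: expected {prefix!r}, "
                f"offending token {token!r}")
        name = token[len(prefix):]
        if name:
            out[rank] = name
            parent = name
        else:
            # carry the nearest named ancestor, never nest placeholders
            if parent.startswith("unclassified_"):
                out[rank] = parent
            else:
                out[rank] = f"unclassified_{parent}"
    return out


def format_taxonomy(ranks: dict[str, str]) -> str:
    """Inverse of :func:`parse_taxonomy` for well-formed lineages
    (placeholders are rendered back to empty ranks)."""
    parts = []
    for rank, prefix in zip(RANKS, _PREFIXES):
        name = ranks.get(rank, "")
        if name.startswith("unclassified_"):
            name = ""
        parts.append(prefix + name)
    return ";".join(parts)


@dataclass(frozen=True)
class SagRecord:
    """One SAG with its plate/well identity, taxonomy and marker content."""

    sag_id: str
    plate: str
    well: str
    taxonomy: str
    completeness: float  # percent of genome estimated present, [0, 100]
    markers: frozenset[str]

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 100.0:
            raise DataIntegrityError(
                f"completeness must be in [0, 100], got {self.completeness} "
                f"for {self.sag_id}")
        extra = self.markers - MARKER_PANEL
        if extra:
            raise DataIntegrityError(
                f"unknown marker genes {sorted(extra)} for {self.sag_id}; "
                f"panel is {sorted(MARKER_PANEL)}")

    @property
    def ranks(self) -> dict[str, str]:
        return parse_taxonomy(self.taxonomy)


@dataclass(frozen=True)
class CapabilityCall:
    """Sulfate-reduction capability verdict for one SAG."""

    sag_id: str
    capable: bool
    rule: str
    missing_markers: tuple[str, ...]


def required_markers(rule: str) -> frozenset[str]:
    if rule == "core":
        return CORE_MARKERS
    if rule == "strict":
        return MARKER_PANEL
    raise ConfigError(f"unknown capability rule {rule!r}; expected one of {RULES}")


def assess_sr_capability(record: SagRecord, rule: str = "core") -> CapabilityCall:
    """Call sulfate-reduction capability from the SAG's marker-gene content."""
    need = required_markers(rule)
    missing = tuple(sorted(need - record.markers))
    return CapabilityCall(sag_id=record.sag_id, capable=not missing,
                          rule=rule, missing_markers=missing)


def load_sag_table(path_or_df) -> pd.DataFrame:
    """Read a SAG catalog TSV (sag_id, plate, well, taxonomy, completeness,
    one 0/1 column per marker gene) and validate its invariants."""
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, sep="\t", comment="#")
    needed = {"sag_id", "plate", "well", "taxonomy", "completeness"}
    missing = needed - set(df.columns)
    if missing:
        raise DataIntegrityError(f"SAG table lacks columns {sorted(missing)}")
    dup = df.duplicated(subset=["plate", "well"])
    if dup.any():
        bad = df.loc[dup, ["plate", "well"]].iloc[0]
        raise DataIntegrityError(
            f"well must be unique within plate; duplicate at "
            f"plate={bad['plate']!r} well={bad['well']!r}")
    bad_comp = ~df["completeness"].between(0, 100)
    if bad_comp.any():
        raise DataIntegrityError("completeness outside [0, 100] in SAG table")
    return df


def marker_set(row: pd.Series) -> frozenset[str]:
    """Marker genes present in a SAG-table row (missing columns = absent)."""
    return frozenset(m for m in MARKER_PANEL
                     if m in row.index and bool(row[m]) and row[m] == row[m])


def capability_table(sags: pd.DataFrame, rule: str = "core") -> pd.DataFrame:
    """Per-SAG capability calls for a whole catalog."""
    need = required_markers(rule)
    rows = []
    for _, row in sags.iterrows():
        markers = marker_set(row)
        missing = sorted(need - markers)
        rows.append({"sag_id": row["sag_id"], "capable": not missing,
                     "rule": rule, "missing_markers": ";".join(missing)})
    return pd.DataFrame(rows)


def capability_fraction(sags: pd.DataFrame, rank: str | None = None,
                        rule: str = "core") -> pd.DataFrame:
    """Per-lineage fraction of SAGs called capable of sulfate reduction.

    ``rank`` of None yields a single overall group labelled "all".  The
    fraction of capable to total sorted cells is the normalization used when
    extrapolating per-cell rates to bulk volumetric rates.
    """
    if len(sags) == 0:
        raise DataIntegrityError("capability_fraction needs >=1 SAG record")
    if rank is not None and rank not in RANKS:
        raise ConfigError(f"unknown rank {rank!r}; expected one of {RANKS}")
    calls = capability_table(sags, rule=rule)
    merged = sags.merge(calls[["sag_id", "capable"]], on="sag_id")
    if rank is None:
        merged["_group"] = "all"
    else:
        merged["_group"] = [parse_taxonomy(t)[rank] for t in merged["taxonomy"]]
    out = (merged.groupby("_group", sort=True)["capable"]
           .agg(n_capable="sum", n_total="count")
           .reset_index().rename(columns={"_group": "group"}))
    out["n_capable"] = out["n_capable"].astype(int)
    out["fraction"] = out["n_capable"] / out["n_total"]
    return out
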