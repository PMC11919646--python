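"""Community-composition summaries of sorted populations.

Index-sorted plates stained with SYTO-9 profile the total community
(DNA-containing cells) while RSG-stained sorts profile the respiring subset;
comparing their relative abundances per lineage shows which taxa are active
versus merely present.  Lineage sets recovered by different classification
routes (e.g. a SAG-derived database versus a public reference database) are
compared as shared/unique partitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .errors import ConfigError, DataIntegrityError
from .bulk import dilution_factor
from .sags import RANKS, parse_taxonomy


@dataclass(frozen=True)
class CommunityProfile:
    """Per-taxon counts and relative fractions for one sorted sample."""

    sample: str
    stain: str
    condition: str
    counts: dict[str, int]
    fractions: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"sample": self.sample, "stain": self.stain,
                 "condition": self.condition, "taxon": t,
                 "count": self.counts[t], "fraction": self.fractions[t]}
                for t in sorted(self.counts)]
        return pd.DataFrame(rows)


def relative_abundance(counts: dict[str, int], sample: str = "",
                       stain: str = "", condition: str = "") -> CommunityProfile:
    """Relative fractions from per-taxon counts (fraction_i = n_i / n)."""
    clean = {t: int(c) for t, c in counts.items()}
    if any(c < 0 for c in clean.values()):
        raise DataIntegrityError("taxon counts must be non-negative")
    total = sum(clean.values())
    if total < 1:
        raise DataIntegrityError("empty profile: all taxon counts are zero")
    fracs = {t: c / total for t, c in clean.items()}
    return CommunityProfile(sample=sample, stain=stain, condition=condition,
                            counts=clean, fractions=fracs)


def profile_sorted_cells(cells: pd.DataFrame, rank: str = "phylum",
                         pool_duplicate_plates: bool = True) -> pd.DataFrame:
    """Composition profiles of a linked-cell table, per (stain, condition).

    Duplicate plates of the same stain/condition (e.g. the two SYTO-9 total
    community plates) are pooled by default; ``pool_duplicate_plates=False``
    keys profiles by plate as well.
    """
    if rank not in RANKS:
        raise ConfigError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if "taxonomy" not in cells.columns:
        raise ConfigError("linked-cell table lacks 'taxonomy'")
    df = cells.copy()
    df["_taxon"] = [parse_taxonomy(t)[rank] for t in df["taxonomy"]]
    keys = [k for k in ("stain", "condition") if k in df.columns]
    if not pool_duplicate_plates and "plate" in df.columns:
        keys.append("plate")
    frames = []
    for key_vals, grp in df.groupby(keys, sort=True) if keys else [((), df)]:
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        meta = dict(zip(keys, key_vals))
        prof = relative_abundance(grp["_taxon"].value_counts().to_dict(),
                                  sample="|".join(str(v) for v in key_vals),
                                  stain=str(meta.get("stain", "")),
                                  condition=str(meta.get("condition", "")))
        frames.append(prof.to_frame())
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class OverlapPartition:
    """Shared/unique partition of two lineage sets (a Venn comparison)."""

    only_a: tuple[str, ...]
    shared: tuple[str, ...]
    only_b: tuple[str, ...]

    @property
    def cardinalities(self) -> tuple[int, int, int]:
        """(|shared|, |only A|, |only B|)."""
        return (len(self.shared), len(self.only_a), len(self.only_b))

    @property
    def total(self) -> int:
        return len(self.shared) + len(self.only_a) + len(self.only_b)

    def as_dict(self) -> dict:
        return {"shared": list(self.shared), "only_a": list(self.only_a),
                "only_b": list(self.only_b),
                "n_shared": len(self.shared), "n_only_a": len(self.only_a),
                "n_only_b": len(self.only_b), "n_union": self.total}


def classification_overlap(a, b) -> OverlapPartition:
    """Partition two sets of same-rank lineage labels into only-A / shared /
    only-B, in deterministic sorted order.

    A heuristic rank check warns when the two sets appear to mix ranks
    (labels carrying different GTDB rank prefixes).
    """
    a, b = set(a), set(b)

    def _prefixes(s):
        return {lab[:3] for lab in s if len(lab) > 3 and lab[1:3] == "__"}
    if len(_prefixes(a) | _prefixes(b)) > 1:
        warnings.warn("classification_overlap: labels appear to mix taxonomic "
                      "ranks", stacklevel=2)
    return OverlapPartition(only_a=tuple(sorted(a - b)),
                            shared=tuple(sorted(a & b)),
                            only_b=tuple(sorted(b - a)))


def proportion_classified(n_classified: int, n_total: int) -> float:
    """Relative proportion of reads classified: n_classified / n_total."""
    if n_total < 1:
        raise DataIntegrityError("total read count must be >= 1")
    if not 0 <= n_classified <= n_total:
        raise DataIntegrityError(
            f"classified reads ({n_classified}) must be within [0, total "
            f"({n_total})]")
    return n_classified / n_total


def cell_concentration(gated_count: int, analyzed_volume_ml: float,
                       dilution_chain=()) -> float:
    """Cells per ml of (undiluted) source material from a gated event count.

    count / volume gives the concentration at measurement; multiplying by the
    overall dilution fold back-calculates the source concentration.
    """
    if not analyzed_volume_ml > 0:
        raise ConfigError(f"analyzed volume must be > 0 ml, got "
                          f"{analyzed_volume_ml}")
    if gated_count < 0:
        raise DataIntegrityError("gated event count must be >= 0")
    return gated_count / analyzed_volume_ml * dilution_factor(dilution_chain)
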