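"""RPKM transcript quantification and pairing with per-cell phenotypes.

Metatranscriptome reads mapped onto the SAG gene catalog are normalized as
reads per kilobase of gene per million library reads:

    RPKM = r / ((L / 1000) * (N / 1e6))

with r the reads mapped to the gene, L the gene length in bp and N the total
number of reads in the sequence library (not the mapped-read total).
Category-level summaries (taxon or functional grouping) are arithmetic means
of member gene RPKMs, computed per sample so libraries from different
incubation conditions are never silently pooled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError, DataIntegrityError
from .sags import MARKER_PANEL, parse_taxonomy

#: marker genes whose transcripts are averaged when pairing with rates
SR_MARKER_GENES = tuple(sorted(MARKER_PANEL))


def compute_rpkm(reads, length_bp, library_size):
    """RPKM of one gene or an array of genes.

    >>> compute_rpkm(10, 1000, 10**6)
    10.0
    """
    r = np.asarray(reads, dtype=float)
    L = np.asarray(length_bp, dtype=float)
    N = np.asarray(library_size, dtype=float)
    if np.any(L < 1):
        raise ConfigError("gene length must be >= 1 bp")
    if np.any(N < 1):
        raise ConfigError("library size must be >= 1 read")
    if np.any(r < 0):
        raise ConfigError("mapped read counts must be >= 0")
    out = r / ((L / 1000.0) * (N / 1e6))
    return float(out) if out.ndim == 0 else out


def add_rpkm(records: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a counts table with an ``rpkm`` column.

    Expected columns: gene_id, length_bp, reads, library_size (sag_id,
    sample and category columns are carried through untouched).
    """
    needed = {"gene_id", "length_bp", "reads", "library_size"}
    missing = needed - set(records.columns)
    if missing:
        raise DataIntegrityError(f"counts table lacks columns {sorted(missing)}")
    out = records.copy()
    out["rpkm"] = compute_rpkm(out["reads"], out["length_bp"],
                               out["library_size"])
    return out


def mean_rpkm_by_category(records: pd.DataFrame, grouping: str,
                          pool_samples: bool = False) -> pd.DataFrame:
    """Arithmetic mean RPKM per category, with member counts.

    ``grouping`` is a column name ("function", "sag_id", ...) or a taxonomy
    rank ("phylum", "class") resolved from a ``taxonomy`` column.  Records
    missing the grouping label fall in an "unassigned" group.  Groups are
    computed per ``sample`` unless ``pool_samples`` is set.
    """
    df = records.copy()
    if "rpkm" not in df.columns:
        df = add_rpkm(df)
    if grouping in df.columns:
        labels = df[grouping]
    elif grouping in ("phylum", "class", "order", "family", "genus", "species",
                      "domain") and "taxonomy" in df.columns:
        labels = pd.Series([parse_taxonomy(t)[grouping] for t in df["taxonomy"]],
                           index=df.index)
    else:
        raise ConfigError(f"cannot resolve grouping {grouping!r} from columns "
                          f"{sorted(df.columns)}")
    df["_cat"] = labels.fillna("unassigned").replace("", "unassigned")
    keys = ["_cat"]
    if not pool_samples and "sample" in df.columns:
        keys = ["sample", "_cat"]
    out = (df.groupby(keys, sort=True)["rpkm"]
           .agg(mean_rpkm="mean", n_genes="count")
           .reset_index().rename(columns={"_cat": grouping}))
    out["n_genes"] = out["n_genes"].astype(int)
    return out


def _check_unique(records: pd.DataFrame) -> None:
    keys = [k for k in ("sag_id", "gene_id", "sample") if k in records.columns]
    dup = records.duplicated(subset=keys)
    if dup.any():
        bad = records.loc[dup, keys].iloc[0].to_dict()
        raise DataIntegrityError(f"duplicate transcript row for {bad}")


def pair_transcripts_with_rates(records: pd.DataFrame,
                                estimates: pd.DataFrame,
                                marker_genes=SR_MARKER_GENES,
                                include_zero: bool = False) -> pd.DataFrame:
    """Join sulfate-reduction marker transcript levels with cell phenotypes.

    For each SAG, the mean RPKM over its detected marker-gene transcripts
    (sat/aprAB/dsrAB) is paired with the calibrated RSG fluorescence (and
    rate) of the cell the SAG came from — the transcript-vs-phenotype
    comparison.  SAGs with no marker transcripts are absent unless
    ``include_zero`` assigns them mean RPKM 0.  Inner join on ``sag_id``.
    """
    if "sag_id" not in records.columns or "sag_id" not in estimates.columns:
        raise ConfigError("both tables must carry 'sag_id'")
    _check_unique(records)
    df = records.copy()
    if "rpkm" not in df.columns:
        df = add_rpkm(df)
    markers = df[df["gene_id"].isin(marker_genes)]
    per_sag = (markers.groupby("sag_id")["rpkm"].mean()
               .rename("mean_marker_rpkm").reset_index())
    if include_zero:
        all_sags = pd.DataFrame({"sag_id": df["sag_id"].unique()})
        per_sag = all_sags.merge(per_sag, on="sag_id", how="left")
        per_sag["mean_marker_rpkm"] = per_sag["mean_marker_rpkm"].fillna(0.0)
    cols = ["cell_id", "sag_id", "F_cal", "rate_fmol_per_cell_h"]
    cols = [c for c in cols if c in estimates.columns]
    return per_sag.merge(estimates[cols], on="sag_id", how="inner")
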