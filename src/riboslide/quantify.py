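"""Count-matrix quantification: RPKM, read filtering, replicate averaging, TE.

Count tables are genes x libraries DataFrames whose columns are a
MultiIndex of (condition, assay, replicate) with condition in {base, alt}
and assay in {RPF, mRNA}.  Translational efficiency (TE) of a gene in a
condition is the geometric-mean RPF RPKM divided by the geometric-mean
total-mRNA RPKM.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .simulate import TranscriptAnnotation

logger = logging.getLogger(__name__)

READ_FILTER_THRESHOLD = 128


class InputError(ValueError):
    """Malformed or inconsistent quantification input."""


def validate_count_table(counts: pd.DataFrame) -> None:
    if counts.index.duplicated().any():
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        raise InputError(f"duplicate gene_ids: {dups[:5]}")
    if not isinstance(counts.columns, pd.MultiIndex) or counts.columns.nlevels != 3:
        raise InputError(
            "count table needs (condition, assay, replicate) MultiIndex columns"
        )
    if (counts.to_numpy() < 0).any():
        raise InputError("negative counts")


def effective_lengths(
    annotations: Iterable[TranscriptAnnotation], rpf_use_cds: bool = True
) -> dict[str, pd.Series]:
    """Per-assay effective gene lengths (nt) for RPKM.

    mRNA libraries are normalized by the full transcript length.  RPF
    libraries default to the CDS length, since footprints originate from
    the translated region; set ``rpf_use_cds=False`` to use the full
    transcript for both assays.
    """
    ids = [a.gene_id for a in annotations]
    tx = pd.Series([a.tx_len for a in annotations], index=ids, dtype=float)
    cds = pd.Series([a.cds_len for a in annotations], index=ids, dtype=float)
    return {"mRNA": tx, "RPF": cds if rpf_use_cds else tx}


def compute_rpkm(
    counts: pd.DataFrame,
    lengths: pd.Series | Mapping[str, pd.Series],
) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    RPKM = count / (length/1e3) / (library_total/1e6), with the library
    total taken as the column sum of the input table (self-contained; no
    external mapped-read figure).  ``lengths`` is either one gene->nt
    Series applied to every library or a mapping assay->Series.
    """
    validate_count_table(counts)
    if isinstance(lengths, pd.Series):
        lengths = {assay: lengths for assay in counts.columns.levels[1]}

    rpkm = pd.DataFrame(index=counts.index, columns=counts.columns, dtype=float)
    for col in counts.columns:
        _cond, assay, _rep = col
        if assay not in lengths:
            raise InputError(f"no effective lengths for assay {assay!r}")
        length = lengths[assay].reindex(counts.index)
        if length.isna().any():
            missing = counts.index[length.isna()].tolist()
            raise InputError(f"missing length for gene(s): {missing[:5]}")
        if (length <= 0).any():
            bad = counts.index[length <= 0].tolist()
            raise InputError(f"non-positive length for gene(s): {bad[:5]}")
        total = counts[col].sum()
        if total <= 0:
            raise InputError(f"library {col} has zero total reads")
        rpkm[col] = counts[col] / (length / 1e3) / (total / 1e6)
    return rpkm


def filter_low_reads(
    counts: pd.DataFrame, threshold: int = READ_FILTER_THRESHOLD
) -> tuple[pd.Index, pd.Index]:
    """Discard weakly covered genes.

    A gene is kept iff its read total within *every* (condition, assay)
    library group — summed over replicates — reaches ``threshold``, so
    each quantity entering TE is supported in both conditions and assays.
    Returns the (kept, dropped) partition of the gene index.
    """
    if threshold < 0:
        raise InputError("threshold must be >= 0")
    validate_count_table(counts)
    group_sums = counts.T.groupby(level=["condition", "assay"]).sum().T
    keep = (group_sums >= threshold).all(axis=1)
    return counts.index[keep], counts.index[~keep]


def geometric_mean(values) -> float:
    """exp(mean(log v)) of strictly positive replicate values."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of empty input")
    if (arr <= 0).any():
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(arr))))


def _geomean_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Row-wise geometric mean per (condition, assay) replicate group.

    Zeros propagate to a 0 group mean (flagged downstream) instead of
    raising, so a whole table can be reduced in one pass.
    """
    with np.errstate(divide="ignore"):
        logs = np.log(df.to_numpy(dtype=float))
    logged = pd.DataFrame(logs, index=df.index, columns=df.columns)
    out = logged.T.groupby(level=["condition", "assay"]).mean().T
    return np.exp(out)


def compute_te(rpkm: pd.DataFrame, kept: pd.Index) -> pd.DataFrame:
    """Per-condition TE table for the retained genes.

    TE(condition) = geomean(RPF RPKM replicates) / geomean(mRNA RPKM
    replicates).  Genes whose geometric mean is zero in any group are
    excluded with a logged warning rather than silently dropped.

    Returns a DataFrame indexed by gene_id with columns te_base, te_alt,
    rpkm_mrna_base, rpkm_mrna_alt, rpkm_rpf_base, rpkm_rpf_alt.
    """
    sub = rpkm.loc[kept]
    gm = _geomean_frame(sub)
    table = pd.DataFrame(
        {
            "te_base": gm[("base", "RPF")] / gm[("base", "mRNA")],
            "te_alt": gm[("alt", "RPF")] / gm[("alt", "mRNA")],
            "rpkm_mrna_base": gm[("base", "mRNA")],
            "rpkm_mrna_alt": gm[("alt", "mRNA")],
            "rpkm_rpf_base": gm[("base", "RPF")],
            "rpkm_rpf_alt": gm[("alt", "RPF")],
        }
    )
    zero = (gm == 0).any(axis=1)
    if zero.any():
        logger.warning(
            "excluding %d gene(s) with zero geometric-mean RPKM post-filter: %s",
            int(zero.sum()),
            table.index[zero][:5].tolist(),
        )
        table = table.loc[~zero]
    table.index.name = "gene_id"
    return table
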