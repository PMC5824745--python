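"""Library-quality surface: footprint sizes, frame periodicity, replicate
agreement, and sample-level PCA with complete-linkage clustering.

Footprint records are DataFrames with columns gene_id, start (0-based
transcript offset of the 5' end) and length (nt), as written by the
simulator or read from the BED-like footprint file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .simulate import TranscriptAnnotation

logger = logging.getLogger(__name__)

FOOTPRINT_MIN = 28
FOOTPRINT_MAX = 32


def length_filter(
    records: pd.DataFrame, lo: int = FOOTPRINT_MIN, hi: int = FOOTPRINT_MAX
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition records into the size-selected band [lo, hi], inclusive.

    Mirrors excising the 28-32 nt gel slice that holds genuine ribosome
    footprints.
    """
    if lo > hi:
        raise ValueError(f"invalid length band: lo={lo} > hi={hi}")
    keep = records["length"].between(lo, hi)
    return records[keep], records[~keep]


def length_histogram(records: pd.DataFrame) -> pd.Series:
    return records["length"].value_counts().sort_index()


def frame_fractions(
    records: pd.DataFrame,
    annotations: list[TranscriptAnnotation],
) -> tuple[np.ndarray, int]:
    """Fraction of footprint 5' ends in each reading frame over the CDS.

    Frame = (start - utr5_len) mod 3 for records whose 5' end lies at or
    downstream of the CDS start; upstream records are excluded and their
    count returned alongside the three fractions (which sum to 1).
    """
    utr5 = {a.gene_id: a.utr5_len for a in annotations}
    missing = set(records["gene_id"]) - utr5.keys()
    if missing:
        raise KeyError(f"annotation missing for gene(s): {sorted(missing)[:5]}")
    offsets = records["start"].to_numpy() - records["gene_id"].map(utr5).to_numpy()
    in_cds = offsets >= 0
    n_upstream = int((~in_cds).sum())
    if n_upstream:
        logger.warning("%d footprint(s) upstream of the CDS excluded", n_upstream)
    frames = offsets[in_cds] % 3
    if frames.size == 0:
        raise ValueError("no footprints at or downstream of a CDS start")
    fractions = np.bincount(frames, minlength=3) / frames.size
    return fractions, n_upstream


def replicate_r2(
    rpkm: pd.DataFrame, kept: pd.Index | None = None, log: bool = True
) -> pd.DataFrame:
    """Squared Pearson correlation between every pair of libraries.

    Computed on log10(RPKM + 1) by default, which tames the heavy right
    tail of expression values (``log=False`` gives the raw scale), over
    the genes in ``kept`` (default: all).  A constant library yields an
    undefined r^2, reported as NaN.  The matrix is symmetric with a unit
    diagonal.
    """
    sub = rpkm.loc[kept] if kept is not None else rpkm
    values = np.log10(sub.to_numpy(dtype=float) + 1.0) if log else sub.to_numpy(float)
    labels = [f"{c}_{a}_rep{r}" for c, a, r in sub.columns]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    r2 = corr**2
    np.fill_diagonal(r2, 1.0)
    return pd.DataFrame(r2, index=labels, columns=labels)


@dataclass
class PcaClusterResult:
    coordinates: pd.DataFrame  # samples x components
    eigenvalues: np.ndarray
    linkage: np.ndarray  # scipy linkage matrix, complete linkage
    sample_ids: list[str]
    n_genes_used: int


def pca_and_cluster(matrix: pd.DataFrame) -> PcaClusterResult:
    """Sample-level PCA and complete-linkage clustering.

    ``matrix`` holds samples x genes log2 values.  Genes with undefined
    (non-finite) values — log2 of a zero RPKM or TE — are excluded, the
    rest standardized per gene to mean 0, SD 1 (ddof=1; zero-SD genes
    dropped), and sample principal components obtained by
    eigendecomposition of the sample-space Gram form of the covariance.
    Component signs are fixed so each component's largest-magnitude gene
    loading is positive.  Clustering is complete-linkage agglomeration on
    Euclidean distances of the same standardized matrix.
    """
    if matrix.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    finite = np.isfinite(matrix.to_numpy(dtype=float)).all(axis=0)
    x = matrix.to_numpy(dtype=float)[:, finite]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    informative = sd > 0
    x = (x[:, informative] - mean[informative]) / sd[informative]
    s, g = x.shape
    if g == 0:
        raise ValueError("no informative genes after standardization")

    gram = x @ x.T / (s - 1)
    eigval, eigvec = np.linalg.eigh(gram)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    scores = eigvec * np.sqrt(eigval * (s - 1))

    # sign convention: largest-|loading| gene positive per component
    for k in range(scores.shape[1]):
        denom = np.sqrt(eigval[k] * (s - 1))
        if denom == 0:
            continue
        loading = x.T @ eigvec[:, k] / denom
        if loading[np.abs(loading).argmax()] < 0:
            scores[:, k] *= -1

    sample_ids = [
        "_".join(map(str, c)) if isinstance(c, tuple) else str(c)
        for c in matrix.index
    ]
    coords = pd.DataFrame(
        scores,
        index=sample_ids,
        columns=[f"PC{k + 1}" for k in range(scores.shape[1])],
    )
    link = hierarchy.linkage(x, method="complete", metric="euclidean")
    return PcaClusterResult(coords, eigval, link, sample_ids, g)


def dendrogram_text(link: np.ndarray, sample_ids: list[str]) -> str:
    """Nested-list serialization of a linkage with merge heights.

    Leaves print as their sample id; each merge prints as
    ``(left, right):height`` with heights rounded to 6 decimals.
    """
    tree = hierarchy.to_tree(link)

    def render(node) -> str:
        if node.is_leaf():
            return sample_ids[node.id]
        return (
            f"({render(node.get_left())},{render(node.get_right())})"
            f":{node.dist:.6f}"
        )

    return render(tree)


def qc_summary(
    records: pd.DataFrame,
    annotations: list[TranscriptAnnotation],
    rpkm: pd.DataFrame,
    kept: pd.Index | None = None,
    lo: int = FOOTPRINT_MIN,
    hi: int = FOOTPRINT_MAX,
) -> dict:
    """One-stop QC report: length histogram and in-band fraction, frame
    fractions after size selection, and the replicate r^2 matrix."""
    kept_rec, dropped = length_filter(records, lo=lo, hi=hi)
    fractions, n_upstream = frame_fractions(kept_rec, annotations)
    return {
        "length_histogram": length_histogram(records),
        "fraction_in_band": len(kept_rec) / max(len(records), 1),
        "frame_fractions": fractions,
        "n_upstream_excluded": n_upstream,
        "r2": replicate_r2(rpkm, kept=kept),
        "n_records": len(records),
        "n_dropped_by_length": len(dropped),
    }
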