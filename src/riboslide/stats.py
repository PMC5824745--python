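"""Intensity-stratified sliding-window z statistics for differential TE.

For each gene the method forms the log2 ratio (alt/base) and log10
intensity (alt x base) of its geometric-mean TE (or mRNA RPKM) values,
orders genes by increasing intensity, summarizes the local ratio
distribution in a sliding window of 100 genes advancing 50 ranks at a
time, standardizes each gene's ratio against the window whose mean
intensity is closest to its own, converts the z score to a normal
p-value, and adjusts with Benjamini-Hochberg.  Genes are then labeled
down / up / unchanged by joint fold-change and p-value thresholds.

Local standardization against abundance-matched neighbours absorbs the
strong dependence of ratio variance on expression level without fitting
an explicit mean-variance model.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

WINDOW = 100
STEP = 50
P_FLOOR = 1e-300  # keeps p strictly positive ahead of the step-up adjustment


class StatisticError(ValueError):
    pass


def compute_ratio_intensity(
    te: pd.DataFrame, mode: str = "TE"
) -> pd.DataFrame:
    """Per-gene log2 ratio and log10 intensity.

    ratio = alt/base and intensity = alt*base of the condition values:
    TE for ``mode="TE"``, geometric-mean mRNA RPKM for ``mode="RPKM"``
    (the transcription arm of the analysis).  Genes with a non-positive
    value in either condition are excluded with a warning.
    """
    if mode.upper() == "TE":
        alt, base = te["te_alt"], te["te_base"]
    elif mode.upper() == "RPKM":
        alt, base = te["rpkm_mrna_alt"], te["rpkm_mrna_base"]
    else:
        raise ValueError(f"mode must be 'TE' or 'RPKM', got {mode!r}")

    ok = (alt > 0) & (base > 0)
    if (~ok).any():
        logger.warning(
            "excluding %d gene(s) with non-positive %s values",
            int((~ok).sum()), mode,
        )
    out = pd.DataFrame(
        {
            "log2_ratio": np.log2(alt[ok] / base[ok]),
            "log10_intensity": np.log10(alt[ok] * base[ok]),
        }
    )
    out.index.name = "gene_id"
    return out


def _intensity_order(stats: pd.DataFrame) -> pd.Index:
    """Ranks by increasing intensity; ties broken by gene_id for stability."""
    tmp = stats.sort_index()
    return tmp.sort_values("log10_intensity", kind="mergesort").index


def build_windows(
    stats: pd.DataFrame, window: int = WINDOW, step: int = STEP
) -> pd.DataFrame:
    """Sliding-window summaries over the intensity-ordered gene list.

    Full windows start at ranks 0, step, 2*step, ... while they fit; if
    genes remain beyond the last full window, one final window truncated
    at the last gene is appended.  Fewer than ``window`` genes yield a
    single window over everything.  Each row carries the member rank
    range, mean log10 intensity, and mean and sample SD (ddof=1) of the
    log2 ratio.
    """
    n = len(stats)
    if n < 3:
        raise StatisticError("need at least 3 genes to estimate a window SD")
    order = _intensity_order(stats)
    ratio = stats.loc[order, "log2_ratio"].to_numpy()
    intensity = stats.loc[order, "log10_intensity"].to_numpy()

    if n <= window:
        bounds = [(0, n)]
    else:
        starts = list(range(0, n - window + 1, step))
        bounds = [(s, s + window) for s in starts]
        if bounds[-1][1] < n:  # trailing genes beyond the last full start
            bounds.append((starts[-1] + step, n))

    rows = []
    for idx, (lo, hi) in enumerate(bounds):
        r = ratio[lo:hi]
        rows.append(
            {
                "window_index": idx,
                "rank_start": lo,
                "rank_stop": hi,
                "mean_log10_intensity": float(np.mean(intensity[lo:hi])),
                "mean_log2_ratio": float(np.mean(r)),
                "sd_log2_ratio": float(np.std(r, ddof=1)),
            }
        )
    return pd.DataFrame(rows).set_index("window_index")


def assign_windows(stats: pd.DataFrame, windows: pd.DataFrame) -> pd.Series:
    """Assign each gene the window with the closest mean log10 intensity.

    Ties go to the lower window index.
    """
    if windows.empty:
        raise StatisticError("no windows to assign")
    gene_i = stats["log10_intensity"].to_numpy()[:, None]
    win_i = windows["mean_log10_intensity"].to_numpy()[None, :]
    # argmin returns the first (lowest-index) minimizer, the stated tie-break
    choice = np.abs(gene_i - win_i).argmin(axis=1)
    return pd.Series(windows.index.to_numpy()[choice], index=stats.index,
                     name="window_index")


def z_and_p(
    stats: pd.DataFrame,
    assignment: pd.Series,
    windows: pd.DataFrame,
    sided: str = "two",
) -> pd.DataFrame:
    """Window-standardized z scores and normal-CDF p-values.

    z = (log2_ratio - window mean) / window SD.  Two-sided (default):
    p = 2*Phi(-|z|); one-sided: p = Phi(z), the literal lower-tail
    quantile reading.  A window SD of 0 offers no evidence against
    window-typical behaviour: those genes get z=0, p=1 with a warning.
    p is clamped to [1e-300, 1].
    """
    if sided not in ("two", "one"):
        raise ValueError("sided must be 'two' or 'one'")
    mean = windows.loc[assignment, "mean_log2_ratio"].to_numpy()
    sd = windows.loc[assignment, "sd_log2_ratio"].to_numpy()
    ratio = stats["log2_ratio"].to_numpy()

    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "%d gene(s) fall in zero-SD windows; p set to 1", int(degenerate.sum())
        )
    z = np.zeros_like(ratio)
    np.divide(ratio - mean, sd, out=z, where=~degenerate)
    if sided == "two":
        p = 2.0 * sps.norm.sf(np.abs(z))
    else:
        p = sps.norm.cdf(z)
    p[degenerate] = 1.0
    p = np.clip(p, P_FLOOR, 1.0)
    return pd.DataFrame({"z": z, "p": p}, index=stats.index)


def bh_fdr(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up false-discovery rates.

    fdr_(i) = min_{j >= i} m * p_(j) / j over the ascending order
    statistics, capped at 1; ties share a value and input order is
    preserved.
    """
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return np.array([])
    if np.any(arr <= 0) or np.any(arr > 1) or np.any(~np.isfinite(arr)):
        raise ValueError("p-values must lie in (0, 1]")
    m = arr.size
    order = np.argsort(arr, kind="mergesort")
    ranked = (arr[order] * m) / np.arange(1, m + 1)
    fdr_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    fdr = np.empty(m)
    fdr[order] = np.minimum(fdr_sorted, 1.0)
    return fdr


def classify(
    stats: pd.DataFrame,
    ratio_down: float = 0.75,
    ratio_up: float = 1.5,
    alpha: float = 0.05,
) -> pd.Series:
    """Label genes down / up / unchanged.

    down: fold-change ratio <= ratio_down and p < alpha;
    up:   ratio >= ratio_up and p < alpha (boundaries inclusive);
    otherwise unchanged.
    """
    ratio = 2.0 ** stats["log2_ratio"].to_numpy()
    p = stats["p"].to_numpy()
    labels = np.full(len(stats), "unchanged", dtype=object)
    labels[(ratio <= ratio_down) & (p < alpha)] = "down"
    labels[(ratio >= ratio_up) & (p < alpha)] = "up"
    return pd.Series(labels, index=stats.index, name="label")


def select_control_group(
    stats: pd.DataFrame,
    n: int = 325,
    seed: int = 0,
    max_abs_log2_ratio: float = 0.2,
    min_p: float = 0.5,
) -> pd.Index:
    """Seeded control set of clearly unregulated genes.

    Candidates are unchanged genes with |log2 ratio| < 0.2 and p > 0.5;
    the sample is stratified across deciles of log10 intensity so controls
    span the same abundance range as the regulated groups.  If fewer than
    ``n`` candidates exist, all are returned with a warning.
    """
    cand = stats[
        (stats["label"] == "unchanged")
        & (stats["log2_ratio"].abs() < max_abs_log2_ratio)
        & (stats["p"] > min_p)
    ]
    cand = cand.sort_index()  # invariant to input gene order
    if len(cand) <= n:
        if len(cand) < n:
            logger.warning(
                "control pool (%d) smaller than requested n=%d; returning all",
                len(cand), n,
            )
        return cand.index
    rng = np.random.default_rng(seed)
    deciles = pd.qcut(cand["log10_intensity"].rank(method="first"), 10, labels=False)
    chosen: list[str] = []
    remaining = n
    for d, group in cand.groupby(deciles):
        quota = int(round(n * len(group) / len(cand)))
        quota = min(quota, remaining, len(group))
        picked = rng.choice(group.index.to_numpy(), size=quota, replace=False)
        chosen.extend(picked.tolist())
        remaining -= quota
    if remaining > 0:  # rounding shortfall: top up from unchosen candidates
        pool = cand.index.difference(pd.Index(chosen))
        chosen.extend(
            rng.choice(pool.to_numpy(), size=remaining, replace=False).tolist()
        )
    return pd.Index(sorted(chosen), name="gene_id")


def differential_te(
    te: pd.DataFrame,
    mode: str = "TE",
    window: int = WINDOW,
    step: int = STEP,
    sided: str = "two",
    ratio_down: float = 0.75,
    ratio_up: float = 1.5,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full differential-translation statistic on a TE table.

    Returns (gene_stats, windows): gene_stats holds log2_ratio,
    log10_intensity, window_index, z, p, fdr and label per gene, in the
    input gene order.
    """
    ri = compute_ratio_intensity(te, mode=mode)
    windows = build_windows(ri, window=window, step=step)
    assignment = assign_windows(ri, windows)
    zp = z_and_p(ri, assignment, windows, sided=sided)
    out = ri.copy()
    out["window_index"] = assignment
    out["z"] = zp["z"]
    out["p"] = zp["p"]
    out["fdr"] = bh_fdr(zp["p"].to_numpy())
    out["label"] = classify(out, ratio_down=ratio_down, ratio_up=ratio_up, alpha=alpha)
    return out, windows
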