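"""UTR sequence features and regulated-group comparisons.

Per-gene 5'/3'UTR length and GC content, built-in scanners for upstream
open reading frames (uORF), terminal oligopyrimidine tracts (TOP) and the
cytoplasmic polyadenylation element (CPE), ingestion of externally
predicted elements (e.g. GAIT, IRES, whose detection needs RNA structure
and is delegated to dedicated tools), and statistical comparison of
element incidence and length/GC between down-, up-regulated and control
gene groups.

Sequences are sense-strand transcript regions over {A,C,G,T,N}; all
scanners are pure functions of the sequence.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.proportion import proportions_ztest

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}

#: declared external-element vocabulary and the region each may annotate
ELEMENT_REGIONS = {
    "uORF": "utr5",
    "TOP": "utr5",
    "IRES": "utr5",
    "CPE": "utr3",
    "GAIT": "utr3",
}

_CPE_RE = re.compile("TTTTAA?T")


def length_gc(sequence: str) -> tuple[int, float]:
    """Length in bp and GC percentage of a region sequence.

    N bases are excluded from the GC denominator.  An empty sequence (or
    all-N) has length but an undefined GC, returned as NaN.
    """
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in "ACGTN"}
    denom = counts["A"] + counts["C"] + counts["G"] + counts["T"]
    if denom == 0:
        return len(seq), float("nan")
    return len(seq), 100.0 * (counts["G"] + counts["C"]) / denom


@dataclass(frozen=True)
class Uorf:
    start: int       # 0-based position of the A of the ATG
    stop_end: int    # position one past the stop codon's last base
    frame: int       # reading frame relative to the CDS start, in {0,1,2}


def scan_uorf(
    utr5_seq: str, cds_offset: int | None = None, min_codons: int = 0
) -> list[Uorf]:
    """Enumerate upstream open reading frames in a 5'UTR.

    Every ATG whose reading frame reaches an in-frame stop (TAA/TAG/TGA)
    ending at or before the CDS start qualifies; in-frame ATGs sharing a
    stop are counted separately, and ATGs that run into the CDS without a
    stop are not counted.  ``min_codons`` bounds the codons between start
    and stop (default 0, so ATG immediately followed by a stop counts).
    ``cds_offset`` defaults to the sequence end, i.e. the 5'UTR abuts the
    CDS.
    """
    seq = utr5_seq.upper()
    end = len(seq) if cds_offset is None else cds_offset
    found = []
    for start in range(end - 2):
        if seq[start : start + 3] != "ATG":
            continue
        for pos in range(start + 3, end - 2, 3):  # stop must end by the CDS start
            codon = seq[pos : pos + 3]
            if len(codon) < 3:
                break
            if codon in STOP_CODONS:
                if (pos - start - 3) // 3 >= min_codons:
                    found.append(Uorf(start, pos + 3, (start - end) % 3))
                break
    return found


def scan_top(utr5_seq: str, min_run: int = 4) -> bool:
    """Terminal oligopyrimidine tract at the transcription start.

    True iff position 0 is C and positions 1..min_run are all pyrimidines
    (C/T); the sequence must begin at the annotated transcription start.
    """
    seq = utr5_seq.upper()
    if len(seq) < 1 + min_run or seq[0] != "C":
        return False
    return all(b in "CT" for b in seq[1 : 1 + min_run])


def scan_cpe(utr3_seq: str, allow_overlap: bool = False) -> int:
    """Count CPE consensus matches (TTTTAT or TTTTAAT) in a 3'UTR.

    Default counts non-overlapping matches scanning left to right;
    ``allow_overlap`` counts every match position.
    """
    seq = utr3_seq.upper()
    if allow_overlap:
        return sum(1 for _ in re.finditer("(?=(TTTTAA?T))", seq))
    return sum(1 for _ in _CPE_RE.finditer(seq))


@dataclass
class UtrFeatureRecord:
    gene_id: str
    region: str  # utr5 | utr3
    length_bp: int
    gc_percent: float
    n_uorf: int = 0
    has_top: bool = False
    n_cpe: int = 0
    external_elements: set[str] = field(default_factory=set)


def extract_features(
    sequences: dict[tuple[str, str], str]
) -> list[UtrFeatureRecord]:
    """Build per-(gene, region) feature records from region sequences.

    ``sequences`` maps (gene_id, region) -> sequence with region in
    {utr5, utr3}; 5'UTRs are scanned for uORFs and TOP, 3'UTRs for CPE.
    """
    records = []
    for (gene, region), seq in sequences.items():
        if region not in ("utr5", "utr3"):
            continue
        length, gc = length_gc(seq)
        rec = UtrFeatureRecord(gene, region, length, gc)
        if region == "utr5":
            rec.n_uorf = len(scan_uorf(seq))
            rec.has_top = scan_top(seq)
        else:
            rec.n_cpe = scan_cpe(seq)
        records.append(rec)
    return records


def import_elements(
    records: list[UtrFeatureRecord], table: pd.DataFrame
) -> int:
    """Attach externally predicted elements to feature records in place.

    ``table`` needs columns gene_id, region, element_label.  Labels must
    come from the declared vocabulary and sit on their allowed region;
    duplicate rows collapse (set semantics).  Rows for genes absent from
    the study set are skipped; their count is returned and logged.
    """
    required = {"gene_id", "region", "element_label"}
    if not required.issubset(table.columns):
        raise ValueError(f"element table needs columns {sorted(required)}")
    unknown = set(table["element_label"]) - ELEMENT_REGIONS.keys()
    if unknown:
        raise ValueError(f"unknown element label(s): {sorted(unknown)}")
    bad_region = table[
        table["region"] != table["element_label"].map(ELEMENT_REGIONS)
    ]
    if not bad_region.empty:
        offender = bad_region.iloc[0]
        raise ValueError(
            f"element {offender['element_label']} may not annotate region "
            f"{offender['region']} (gene {offender['gene_id']})"
        )
    by_key = {(r.gene_id, r.region): r for r in records}
    skipped = 0
    for row in table.itertuples(index=False):
        rec = by_key.get((row.gene_id, row.region))
        if rec is None:
            skipped += 1
            continue
        rec.external_elements.add(row.element_label)
    if skipped:
        logger.warning("%d element row(s) for genes outside the study set", skipped)
    return skipped


def features_frame(records: list[UtrFeatureRecord]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": r.gene_id,
            "region": r.region,
            "length_bp": r.length_bp,
            "gc_percent": r.gc_percent,
            "n_uorf": r.n_uorf,
            "has_top": r.has_top,
            "n_cpe": r.n_cpe,
            "external_elements": ",".join(sorted(r.external_elements)),
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def _element_presence(df: pd.DataFrame) -> pd.DataFrame:
    """Per-gene boolean table: does the gene carry >=1 of each element."""
    ext = df["external_elements"].str.split(",").apply(
        lambda xs: {x for x in xs if x}
    )
    per_gene = pd.DataFrame(
        {
            "uORF": df["n_uorf"] > 0,
            "TOP": df["has_top"].astype(bool),
            "CPE": df["n_cpe"] > 0,
            "GAIT": ext.apply(lambda s: "GAIT" in s),
            "IRES": ext.apply(lambda s: "IRES" in s),
        }
    )
    per_gene["gene_id"] = df["gene_id"].to_numpy()
    return per_gene.groupby("gene_id").any()


def compare_groups(
    features: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare element incidence and length/GC across gene groups.

    ``groups`` maps gene_id -> group name; the group named ``control``
    is the reference.  For each element the report carries per-group n
    and percent-with-element plus a two-proportion z-test of each group
    against control, flagging significant underrepresentation.  For
    length and GC (per region) it carries group mean +/- SEM, a one-way
    ANOVA p-value and Tukey HSD pairwise p-values against control.
    """
    groups = groups.dropna()
    names = sorted(groups.unique(), key=lambda g: (g == "control", g))
    if "control" not in names:
        raise ValueError("groups must include a 'control' group")
    dup = groups.index[groups.index.duplicated()]
    if len(dup):
        raise ValueError(f"gene(s) in more than one group row: {dup[:5].tolist()}")

    presence = _element_presence(features)
    rows = []
    for element in ["uORF", "TOP", "CPE", "GAIT", "IRES"]:
        stats_by_group = {}
        for g in names:
            members = groups.index[groups == g]
            flags = presence[element].reindex(members).dropna()
            stats_by_group[g] = (len(flags), int(flags.sum()))
        n_ctrl, k_ctrl = stats_by_group["control"]
        for g in names:
            if g == "control":
                continue
            n_g, k_g = stats_by_group[g]
            if n_g == 0 or n_ctrl == 0:
                logger.warning("empty group in %s comparison; skipped", element)
                continue
            if k_g == k_ctrl == 0 or (k_g == n_g and k_ctrl == n_ctrl):
                stat, p = 0.0, 1.0  # identical saturated proportions
            else:
                stat, p = proportions_ztest([k_g, k_ctrl], [n_g, n_ctrl])
            pct_g = 100.0 * k_g / n_g
            pct_ctrl = 100.0 * k_ctrl / n_ctrl
            rows.append(
                {
                    "metric": element,
                    "kind": "element",
                    "group": g,
                    "n_group": n_g,
                    "value_group": pct_g,
                    "n_control": n_ctrl,
                    "value_control": pct_ctrl,
                    "statistic": stat,
                    "p": p,
                    "underrepresented": bool(pct_g < pct_ctrl and p < alpha),
                }
            )

    for region in ("utr5", "utr3"):
        sub = (
            features[features["region"] == region]
            .drop_duplicates(subset="gene_id")  # set semantics on feature rows
            .set_index("gene_id")
        )
        for metric in ("length_bp", "gc_percent"):
            values, labels = [], []
            for g in names:
                members = groups.index[groups == g]
                v = sub[metric].reindex(members).dropna()
                values.append(v)
                labels.extend([g] * len(v))
            if any(len(v) < 2 for v in values):
                logger.warning("group too small for %s/%s ANOVA; skipped",
                               region, metric)
                continue
            arrays = [v.to_numpy(dtype=float) for v in values]
            if all(np.allclose(a, arrays[0][0]) for a in arrays):
                anova_p = 1.0
                tukey_p = {g: 1.0 for g in names if g != "control"}
            else:
                _, anova_p = sps.f_oneway(*arrays)
                tukey = pairwise_tukeyhsd(
                    np.concatenate(arrays), np.array(labels), alpha=alpha
                )
                tk = pd.DataFrame(
                    tukey.summary().data[1:], columns=tukey.summary().data[0]
                )
                tukey_p = {}
                for g in names:
                    if g == "control":
                        continue
                    hit = tk[
                        ((tk["group1"] == g) & (tk["group2"] == "control"))
                        | ((tk["group1"] == "control") & (tk["group2"] == g))
                    ]
                    tukey_p[g] = float(hit["p-adj"].iloc[0])
            ctrl = values[names.index("control")]
            for g in names:
                if g == "control":
                    continue
                v = values[names.index(g)]
                rows.append(
                    {
                        "metric": f"{region}_{metric}",
                        "kind": "continuous",
                        "group": g,
                        "n_group": len(v),
                        "value_group": float(v.mean()),
                        "sem_group": float(v.sem()),
                        "n_control": len(ctrl),
                        "value_control": float(ctrl.mean()),
                        "sem_control": float(ctrl.sem()),
                        "statistic": np.nan,
                        "p": float(anova_p),
                        "p_vs_control": tukey_p[g],
                        "underrepresented": False,
                    }
                )
    return pd.DataFrame(rows)
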