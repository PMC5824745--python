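"""File formats: TSV tables, FASTA region sequences, BED-like footprints.

The interchange dialect is tab-separated text with a header row, '.'
decimal separator and no quoting; floats are written with ``%.10g`` so
repeated runs of the same seeded pipeline are byte-identical.

FASTA records are one sequence per transcript region with headers
``gene|region`` (region in utr5/cds/utr3), parsed with Biopython.
Footprints travel as 6-column BED-like TSV: gene_id, start (0-based),
end (half-open), read_id, length, strand (always '+': transcripts are
sense-strand by contract).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .simulate import SimTruth, TranscriptAnnotation

FLOAT_FORMAT = "%.10g"

COLUMN_LEVELS = ["condition", "assay", "replicate"]


class FormatError(ValueError):
    pass


# --- counts ---------------------------------------------------------------

def _encode_library(col: tuple[str, str, int]) -> str:
    cond, assay, rep = col
    return f"{cond}_{assay}_rep{rep}"


def _decode_library(name: str) -> tuple[str, str, int]:
    try:
        cond, assay, rep = name.split("_")
        if not rep.startswith("rep"):
            raise ValueError
        return cond, assay, int(rep[3:])
    except ValueError:
        raise FormatError(
            f"library column {name!r} is not condition_assay_repN"
        ) from None


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    flat = counts.copy()
    flat.columns = [_encode_library(c) for c in counts.columns]
    flat.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    for col in df.columns:
        bad = df[col][~df[col].apply(lambda v: float(v).is_integer())]
        if len(bad):
            raise FormatError(
                f"non-integer count at gene {bad.index[0]!r}, column {col!r}"
            )
    df = df.astype(np.int64)
    df.columns = pd.MultiIndex.from_tuples(
        [_decode_library(c) for c in df.columns], names=COLUMN_LEVELS
    )
    return df


# --- annotation / truth ---------------------------------------------------

def write_annotation(
    annotations: list[TranscriptAnnotation], path: str | Path
) -> None:
    pd.DataFrame(
        [(a.gene_id, a.utr5_len, a.cds_len, a.utr3_len) for a in annotations],
        columns=["gene_id", "utr5_len", "cds_len", "utr3_len"],
    ).to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> list[TranscriptAnnotation]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "utr5_len", "cds_len", "utr3_len"}
    if not required.issubset(df.columns):
        raise FormatError(f"annotation table needs columns {sorted(required)}")
    return [
        TranscriptAnnotation(
            str(r.gene_id), int(r.utr5_len), int(r.cds_len), int(r.utr3_len)
        )
        for r in df.itertuples(index=False)
    ]


def write_truth(truth: list[SimTruth], path: str | Path) -> None:
    pd.DataFrame(
        [
            (t.gene_id, t.base_expression, t.base_te, t.te_fold_change,
             t.class_truth)
            for t in truth
        ],
        columns=["gene_id", "base_expression", "base_te", "te_fold_change",
                 "class_truth"],
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


# --- footprints -----------------------------------------------------------

def write_footprints(records: pd.DataFrame, path: str | Path) -> None:
    bed = pd.DataFrame(
        {
            "gene_id": records["gene_id"],
            "start": records["start"],
            "end": records["start"] + records["length"],
            "read_id": records["read_id"],
            "length": records["length"],
            "strand": "+",
        }
    )
    bed.to_csv(path, sep="\t", index=False)


def read_footprints(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "start", "end", "read_id", "length"}
    if not required.issubset(df.columns):
        raise FormatError(f"footprint table needs columns {sorted(required)}")
    if ((df["end"] - df["start"]) != df["length"]).any():
        raise FormatError("footprint end - start must equal length")
    return df[["gene_id", "start", "length", "read_id"]]


# --- FASTA ----------------------------------------------------------------

def write_region_fasta(
    annotations: list[TranscriptAnnotation], path: str | Path
) -> None:
    """One record per present region, header ``gene|region``."""
    with open(path, "w") as fh:
        for a in annotations:
            for region, seq in (
                ("utr5", a.utr5_seq), ("cds", a.cds_seq), ("utr3", a.utr3_seq)
            ):
                if seq is not None:
                    fh.write(f">{a.gene_id}|{region}\n")
                    for i in range(0, len(seq), 70):
                        fh.write(seq[i : i + 70] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """id -> uppercase sequence; duplicate ids are an error.

    Multi-line records and CRLF line endings parse identically to LF.
    """
    text = Path(path).read_text().replace("\r\n", "\n")
    out: dict[str, str] = {}
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def read_region_sequences(path: str | Path) -> dict[tuple[str, str], str]:
    """FASTA of region records -> {(gene_id, region): sequence}."""
    out = {}
    for rec_id, seq in read_fasta(path).items():
        if "|" not in rec_id:
            raise FormatError(f"FASTA id {rec_id!r} is not gene|region")
        gene, region = rec_id.rsplit("|", 1)
        out[(gene, region)] = seq
    return out


# --- generic tables -------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_table(path: str | Path, index_col: str | None = "gene_id") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
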