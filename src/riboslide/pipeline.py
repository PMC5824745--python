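"""End-to-end orchestration: simulate -> quantify -> dte -> qc -> utr.

A PipelineConfig (one YAML file) drives every stage; outputs are TSV/
FASTA/JSON files under an output directory plus a manifest recording row
counts and the configuration hash.  Runs are deterministic: the same
config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from . import qc as rqc
from . import quantify, stats, utr
from .simulate import (
    SimConfig,
    simulate_experiment,
    simulate_footprints,
    simulate_sequences,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "riboslide_out"
    seed: int = 0
    simulate_enabled: bool = True
    sim: dict = field(default_factory=dict)            # SimConfig overrides
    generate_sequences: bool = True
    inputs: dict = field(default_factory=dict)         # paths when not simulating
    filter_threshold: int = quantify.READ_FILTER_THRESHOLD
    mode: str = "TE"
    window: int = stats.WINDOW
    step: int = stats.STEP
    sided: str = "two"
    alpha: float = 0.05
    ratio_down: float = 0.75
    ratio_up: float = 1.5
    length_lo: int = rqc.FOOTPRINT_MIN
    length_hi: int = rqc.FOOTPRINT_MAX
    control_n: int = 325
    log_level: str = "INFO"

    def __post_init__(self):
        if not (self.ratio_down < 1 < self.ratio_up):
            raise ValueError("need ratio_down < 1 < ratio_up")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.length_lo > self.length_hi:
            raise ValueError("length_lo must be <= length_hi")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    def sha256(self) -> str:
        """Hash of the analysis-relevant configuration.

        outdir and log_level do not affect the computed results, so runs
        differing only in output location hash (and compare) identical.
        """
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        payload.pop("log_level")
        return hashlib.sha256(
            yaml.safe_dump(payload, sort_keys=True).encode()
        ).hexdigest()

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.sim)


def default_config_template() -> str:
    """Printable default configuration (desk-scale simulation)."""
    cfg = PipelineConfig(
        sim={"n_genes": 2000, "depth_rpf": 1_000_000, "depth_mrna": 1_000_000}
    )
    return cfg.to_yaml()


def _row_count(path: Path) -> int:
    with open(path) as fh:
        return max(sum(1 for _ in fh) - 1, 0)  # minus header


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage and return the output manifest.

    A stage failure aborts downstream stages; files already written are
    listed in the manifest with ``partial: true``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_sha256": config.sha256(),
        "seed": config.seed,
        "files": {},
        "partial": False,
    }

    def record(name: str, path: Path):
        manifest["files"][name] = {
            "path": path.name,
            "rows": _row_count(path) if path.suffix != ".fasta" else None,
        }

    try:
        # --- stage 1: inputs ------------------------------------------------
        sequences = None
        footprints = None
        if config.simulate_enabled:
            sim = config.sim_config()
            annotations, counts, truth = simulate_experiment(sim)
            footprints = simulate_footprints(sim, annotations, counts)
            if config.generate_sequences:
                annotations, motif_truth = simulate_sequences(sim, annotations)
                rio.write_region_fasta(annotations, outdir / "sequences.fasta")
                record("sequences", outdir / "sequences.fasta")
                rio.write_table(motif_truth, outdir / "motif_truth.tsv")
                record("motif_truth", outdir / "motif_truth.tsv")
                sequences = {
                    (a.gene_id, region): seq
                    for a in annotations
                    for region, seq in (("utr5", a.utr5_seq), ("utr3", a.utr3_seq))
                    if seq is not None
                }
            rio.write_annotation(annotations, outdir / "annotation.tsv")
            record("annotation", outdir / "annotation.tsv")
            rio.write_counts(counts, outdir / "counts.tsv")
            record("counts", outdir / "counts.tsv")
            rio.write_truth(truth, outdir / "truth.tsv")
            record("truth", outdir / "truth.tsv")
            rio.write_footprints(footprints, outdir / "footprints.tsv")
            record("footprints", outdir / "footprints.tsv")
        else:
            for key in ("annotation", "counts"):
                path = config.inputs.get(key)
                if not path or not Path(path).exists():
                    raise FileNotFoundError(
                        f"simulation disabled and {key} file missing: {path!r}"
                    )
            annotations = rio.read_annotation(config.inputs["annotation"])
            counts = rio.read_counts(config.inputs["counts"])
            if config.inputs.get("sequences"):
                sequences = rio.read_region_sequences(config.inputs["sequences"])
            if config.inputs.get("footprints"):
                footprints = rio.read_footprints(config.inputs["footprints"])

        # --- stage 2: quantify ----------------------------------------------
        lengths = quantify.effective_lengths(annotations)
        rpkm = quantify.compute_rpkm(counts, lengths)
        kept, dropped = quantify.filter_low_reads(counts, config.filter_threshold)
        te = quantify.compute_te(rpkm, kept)
        rio.write_table(rpkm.set_axis(
            [f"{c}_{a}_rep{r}" for c, a, r in rpkm.columns], axis=1
        ), outdir / "rpkm.tsv")
        record("rpkm", outdir / "rpkm.tsv")
        report = pd.DataFrame(
            {"kept": [g in set(kept) for g in counts.index]}, index=counts.index
        )
        rio.write_table(report, outdir / "filter_report.tsv")
        record("filter_report", outdir / "filter_report.tsv")
        rio.write_table(te, outdir / "te.tsv")
        record("te", outdir / "te.tsv")

        # --- stage 3: differential TE ----------------------------------------
        gene_stats, windows = stats.differential_te(
            te,
            mode=config.mode,
            window=config.window,
            step=config.step,
            sided=config.sided,
            ratio_down=config.ratio_down,
            ratio_up=config.ratio_up,
            alpha=config.alpha,
        )
        rio.write_table(gene_stats, outdir / "dte_results.tsv")
        record("dte_results", outdir / "dte_results.tsv")
        rio.write_table(windows, outdir / "windows.tsv")
        record("windows", outdir / "windows.tsv")

        # --- stage 4: QC ------------------------------------------------------
        if footprints is not None:
            kept_fp, _ = rqc.length_filter(
                footprints, lo=config.length_lo, hi=config.length_hi
            )
            fractions, n_up = rqc.frame_fractions(kept_fp, annotations)
            rio.write_table(
                rqc.length_histogram(footprints).rename("count").to_frame(),
                outdir / "length_histogram.tsv",
            )
            record("length_histogram", outdir / "length_histogram.tsv")
            rio.write_table(
                pd.DataFrame({"frame": [0, 1, 2], "fraction": fractions}),
                outdir / "frame_fractions.tsv",
                index=False,
            )
            record("frame_fractions", outdir / "frame_fractions.tsv")
        r2 = rqc.replicate_r2(rpkm, kept=kept)
        rio.write_table(r2, outdir / "r2.tsv")
        record("r2", outdir / "r2.tsv")

        # transcription PCA: mRNA libraries; translation PCA: per-replicate TE
        mrna = rpkm.loc[kept].xs("mRNA", axis=1, level="assay")
        with np.errstate(divide="ignore"):
            log_mrna = np.log2(mrna.T)
            rpf = rpkm.loc[kept].xs("RPF", axis=1, level="assay")
            log_te_reps = np.log2((rpf / mrna).T)
        for name, mat in (("transcription", log_mrna), ("translation", log_te_reps)):
            mat = mat.set_axis(
                [f"{c}_rep{r}" for c, r in mat.index], axis=0
            )
            res = rqc.pca_and_cluster(mat)
            rio.write_table(res.coordinates, outdir / f"pca_{name}.tsv")
            record(f"pca_{name}", outdir / f"pca_{name}.tsv")
            (outdir / f"dendrogram_{name}.txt").write_text(
                rqc.dendrogram_text(res.linkage, res.sample_ids) + "\n"
            )
            record(f"dendrogram_{name}", outdir / f"dendrogram_{name}.txt")

        # --- stage 5: UTR features -------------------------------------------
        if sequences is not None:
            features = utr.features_frame(utr.extract_features(sequences))
            if config.inputs.get("elements"):
                table = pd.read_csv(config.inputs["elements"], sep="\t")
                records = utr.extract_features(sequences)
                utr.import_elements(records, table)
                features = utr.features_frame(records)
            rio.write_table(features, outdir / "utr_features.tsv", index=False)
            record("utr_features", outdir / "utr_features.tsv")

            labels = gene_stats["label"]
            control = stats.select_control_group(
                gene_stats, n=config.control_n, seed=config.seed
            )
            groups = pd.Series("control", index=control)
            for lab in ("down", "up"):
                members = labels.index[labels == lab]
                groups = pd.concat([groups, pd.Series(lab, index=members)])
            groups = groups[~groups.index.duplicated()]
            if (groups == "down").any() and (groups == "up").any():
                comparison = utr.compare_groups(features, groups)
                rio.write_table(comparison, outdir / "group_comparison.tsv",
                                index=False)
                record("group_comparison", outdir / "group_comparison.tsv")
            else:
                logger.warning("no regulated genes; group comparison skipped")
    except Exception:
        manifest["partial"] = True
        _write_manifest(manifest, outdir)
        raise

    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
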