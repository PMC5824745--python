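"""Seeded synthetic ribosome-profiling experiments.

Generates transcript annotations, negative-binomial count matrices for
footprint (RPF) and total-mRNA libraries in two conditions, per-read
footprint records with controllable length and frame structure, and the
planted per-gene translational-efficiency (TE) ground truth used by the
recovery tests.

The generator emulates the design of a typical two-condition mouse-brain
ribosome-profiling study: 2 biological replicates per condition and assay,
overdispersed counts, a majority of translationally unchanged genes, a
minority with decreased TE and a small minority with increased TE, and
footprint lengths peaked at 28-32 nt with strong 3-nt periodicity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

CONDITIONS = ("base", "alt")
ASSAYS = ("RPF", "mRNA")

#: default footprint-length distribution: peaked on 28-32 nt with light tails,
#: as seen after size-selecting the ribosome-protected gel slice.
DEFAULT_LENGTH_DISTRIBUTION = {
    26: 0.02,
    27: 0.04,
    28: 0.14,
    29: 0.22,
    30: 0.26,
    31: 0.14,
    32: 0.10,
    33: 0.05,
    34: 0.03,
}


class ConfigurationError(ValueError):
    """Raised when a SimConfig violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic ribosome-profiling experiment.

    Parameters
    ----------
    n_genes : number of genes simulated.
    n_replicates : biological replicates per (condition, assay) library group.
    depth_rpf, depth_mrna : expected mapped reads per library.
    dispersion : negative-binomial dispersion ``a`` with var = mu + a*mu^2.
        The default 0.003 is the largest (noisiest) value reproducing
        the near-perfect replicate agreement
        (r^2 > 0.99 of log RPKM) characteristic of well-made libraries.
    frac_down, frac_up : fractions of genes planted with decreased /
        increased TE in the alternative condition.
    effect_down, effect_up : TE fold-changes applied to planted genes.
    length_distribution : footprint length (nt) -> probability.
    frame_bias : probability mass that a footprint 5' end falls in frame 0
        relative to the CDS start; the remainder splits evenly over
        frames 1 and 2.
    seed : master seed; identical configs give bit-identical output.
    """

    n_genes: int = 6000
    n_replicates: int = 2
    depth_rpf: int = 5_000_000
    depth_mrna: int = 5_000_000
    dispersion: float = 0.003
    frac_down: float = 0.05
    frac_up: float = 0.005
    effect_down: float = 0.5
    effect_up: float = 2.0
    length_distribution: dict = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DISTRIBUTION)
    )
    frame_bias: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.depth_rpf <= 0 or self.depth_mrna <= 0:
            raise ConfigurationError("library depths must be positive")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        if not (0 <= self.frac_down <= 1 and 0 <= self.frac_up <= 1):
            raise ConfigurationError("effect fractions must lie in [0, 1]")
        if self.frac_down + self.frac_up > 1:
            raise ConfigurationError("frac_down + frac_up must be <= 1")
        if self.effect_down <= 0 or self.effect_up <= 0:
            raise ConfigurationError("effect fold-changes must be > 0")
        if not (0 <= self.frame_bias <= 1):
            raise ConfigurationError("frame_bias must lie in [0, 1]")
        total = sum(self.length_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"length_distribution probabilities sum to {total}, not 1"
            )

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class TranscriptAnnotation:
    """Per-gene region lengths and optional sense-strand sequences."""

    gene_id: str
    utr5_len: int
    cds_len: int
    utr3_len: int
    utr5_seq: Optional[str] = None
    cds_seq: Optional[str] = None
    utr3_seq: Optional[str] = None

    def __post_init__(self):
        if self.utr5_len < 0 or self.cds_len <= 0 or self.utr3_len < 0:
            raise ValueError(f"{self.gene_id}: invalid region lengths")
        if self.cds_len % 3 != 0:
            raise ValueError(f"{self.gene_id}: cds_len must be a multiple of 3")
        for region, seq, length in (
            ("utr5", self.utr5_seq, self.utr5_len),
            ("cds", self.cds_seq, self.cds_len),
            ("utr3", self.utr3_seq, self.utr3_len),
        ):
            if seq is not None and len(seq) != length:
                raise ValueError(
                    f"{self.gene_id}/{region}: sequence length {len(seq)} "
                    f"!= annotated {length}"
                )
        if self.cds_seq is not None and not self.cds_seq.startswith("ATG"):
            raise ValueError(f"{self.gene_id}: cds_seq must begin with ATG")

    @property
    def tx_len(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len


@dataclass(frozen=True)
class SimTruth:
    """Planted ground truth for one gene."""

    gene_id: str
    base_expression: float
    base_te: float
    te_fold_change: float
    class_truth: str  # down / up / unchanged

    def __post_init__(self):
        expected = (
            "down"
            if self.te_fold_change < 1
            else "up" if self.te_fold_change > 1 else "unchanged"
        )
        if self.class_truth != expected:
            raise ValueError(
                f"{self.gene_id}: class_truth {self.class_truth!r} inconsistent "
                f"with te_fold_change {self.te_fold_change}"
            )


def library_columns(n_replicates: int) -> list[tuple[str, str, int]]:
    """Ordered (condition, assay, replicate) triples for the count matrix."""
    return [
        (cond, assay, rep)
        for cond in CONDITIONS
        for assay in ASSAYS
        for rep in range(1, n_replicates + 1)
    ]


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean mu and var mu + dispersion*mu^2."""
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def _annotations(rng: np.random.Generator, n_genes: int) -> list[TranscriptAnnotation]:
    width = max(4, len(str(n_genes)))
    utr5 = rng.integers(50, 501, size=n_genes)
    cds = 3 * rng.integers(100, 1001, size=n_genes)  # 300..3000 nt, multiple of 3
    utr3 = rng.integers(100, 2001, size=n_genes)
    return [
        TranscriptAnnotation(f"g{i:0{width}d}", int(utr5[i]), int(cds[i]), int(utr3[i]))
        for i in range(n_genes)
    ]


def simulate_experiment(
    config: SimConfig,
) -> tuple[list[TranscriptAnnotation], pd.DataFrame, list[SimTruth]]:
    """Simulate one two-condition RPF/mRNA experiment.

    Returns ``(annotations, counts, truth)`` where ``counts`` is a genes x
    libraries DataFrame with MultiIndex columns (condition, assay,
    replicate).  Expected library column sums equal the configured depths.
    mRNA means are proportional to expression x transcript length; RPF
    means to expression x TE x CDS length, with the planted fold change
    applied in the alternative condition only.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    annotations = _annotations(rng, n)
    gene_ids = [a.gene_id for a in annotations]

    base_expression = rng.lognormal(mean=np.log(50.0), sigma=1.5, size=n)
    base_te = rng.lognormal(mean=0.0, sigma=0.3, size=n)

    # fixed-quota planted effects: exact truth counts for the recovery tests
    n_down = int(round(config.frac_down * n))
    n_up = int(round(config.frac_up * n))
    order = rng.permutation(n)
    fold = np.ones(n)
    fold[order[:n_down]] = config.effect_down
    fold[order[n_down : n_down + n_up]] = config.effect_up

    tx_len = np.array([a.tx_len for a in annotations], dtype=float)
    cds_len = np.array([a.cds_len for a in annotations], dtype=float)

    columns = library_columns(config.n_replicates)
    counts = np.empty((n, len(columns)), dtype=np.int64)
    for j, (cond, assay, _rep) in enumerate(columns):
        if assay == "mRNA":
            w = base_expression * tx_len
            depth = config.depth_mrna
        else:
            te = base_te * (fold if cond == "alt" else 1.0)
            w = base_expression * te * cds_len
            depth = config.depth_rpf
        mu = depth * w / w.sum()
        counts[:, j] = _nb_draw(rng, mu, config.dispersion)

    count_table = pd.DataFrame(
        counts,
        index=pd.Index(gene_ids, name="gene_id"),
        columns=pd.MultiIndex.from_tuples(
            columns, names=["condition", "assay", "replicate"]
        ),
    )

    labels = np.full(n, "unchanged", dtype=object)
    labels[fold < 1] = "down"
    labels[fold > 1] = "up"
    truth = [
        SimTruth(gene_ids[i], float(base_expression[i]), float(base_te[i]),
                 float(fold[i]), str(labels[i]))
        for i in range(n)
    ]
    return annotations, count_table, truth


def simulate_footprints(
    config: SimConfig,
    annotations: list[TranscriptAnnotation],
    counts: pd.DataFrame,
    library: tuple[str, str, int] = ("base", "RPF", 1),
) -> pd.DataFrame:
    """Per-read footprint records for one designated RPF library.

    One record per counted read: lengths drawn from the configured length
    distribution, 5' ends placed on CDS codon boundaries so that a
    ``frame_bias`` fraction lies in frame 0, i.e. satisfies
    ``(start - utr5_len) % 3 == 0``; the remaining mass splits evenly over
    frames 1 and 2.  Deterministic under the config seed.

    Returns a DataFrame with columns gene_id, start (0-based transcript
    offset of the 5' end), length, read_id.
    """
    cond, assay, rep = library
    if assay != "RPF":
        raise ValueError("footprints are simulated for an RPF library")
    if library not in counts.columns:
        raise KeyError(f"library {library} not present in count table")
    ann_by_gene = {a.gene_id: a for a in annotations}
    missing = [g for g in counts.index if g not in ann_by_gene]
    if missing:
        raise KeyError(f"annotation missing for counted gene(s): {missing[:5]}")

    # decorrelate from the count draw but stay a pure function of the config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    reads_per_gene = counts[library].to_numpy()
    total = int(reads_per_gene.sum())

    lengths_support = np.array(sorted(config.length_distribution), dtype=np.int64)
    probs = np.array([config.length_distribution[k] for k in lengths_support])
    probs = probs / probs.sum()

    gene_idx = np.repeat(np.arange(len(counts.index)), reads_per_gene)
    lengths = rng.choice(lengths_support, size=total, p=probs)
    off_frame = (1.0 - config.frame_bias) / 2.0
    frames = rng.choice(
        np.array([0, 1, 2]), size=total, p=[config.frame_bias, off_frame, off_frame]
    )

    utr5 = np.array([ann_by_gene[g].utr5_len for g in counts.index])
    cds = np.array([ann_by_gene[g].cds_len for g in counts.index])
    tx = np.array([ann_by_gene[g].tx_len for g in counts.index])

    # codon index chosen uniformly among positions keeping the read on-transcript
    g_utr5 = utr5[gene_idx]
    max_start = tx[gene_idx] - lengths  # inclusive upper bound on start
    last_codon = np.minimum(
        (cds[gene_idx] - 3) // 3, (max_start - g_utr5 - frames) // 3
    )
    last_codon = np.maximum(last_codon, 0)
    codon = (rng.random(total) * (last_codon + 1)).astype(np.int64)
    starts = g_utr5 + 3 * codon + frames

    gene_ids = counts.index.to_numpy()[gene_idx]
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "start": starts,
            "length": lengths,
            "read_id": [f"read{i:08d}" for i in range(total)],
        }
    )


# ---------------------------------------------------------------------------
# sequence synthesis with planted UTR elements
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")

#: planted motif bodies; wrapping bases insulate them from the background so
#: the planted count is exactly the scanner truth
_UORF_MOTIF = "C" + "ATG" + "GCCGCC" + "TAA" + "C"
_CPE_MOTIF = "G" + "TTTTAT" + "G"
_TOP_PREFIX = "CTTTT"


def _uniform_seq(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _scrub(seq: str, rng: np.random.Generator, patterns: dict[str, tuple[int, str]],
           max_iter: int = 100) -> str:
    """Remove every occurrence of the given motifs from a random background.

    ``patterns`` maps motif -> (index to mutate, replacement alphabet).
    Replacements can create fresh occurrences, so iterate to a fixed point.
    """
    chars = list(seq)
    for _ in range(max_iter):
        dirty = False
        text = "".join(chars)
        for motif, (pos, alphabet) in patterns.items():
            start = text.find(motif)
            while start != -1:
                chars[start + pos] = alphabet[rng.integers(0, len(alphabet))]
                dirty = True
                start = text.find(motif, start + 1)
        if not dirty:
            return "".join(chars)
    raise RuntimeError("motif scrub failed to converge")


def _utr5_background(rng: np.random.Generator, n: int) -> str:
    """ATG-free background whose first base is never C (no accidental TOP)."""
    seq = _scrub(_uniform_seq(rng, n), rng, {"ATG": (2, "ACT")})
    if seq and seq[0] == "C":
        seq = "AG"[rng.integers(0, 2)] + seq[1:]
    return seq


def _utr3_background(rng: np.random.Generator, n: int) -> str:
    """Background free of the CPE consensus TTTTA(A)T."""
    return _scrub(
        _uniform_seq(rng, n),
        rng,
        {"TTTTAT": (4, "CG"), "TTTTAAT": (4, "CG")},
    )


def _splice(background: str, motifs: list[str], min_offset: int = 0) -> str:
    """Insert motifs at evenly spaced cut points of the background."""
    if not motifs:
        return background
    usable = len(background) - min_offset
    pieces, prev = [], 0
    cuts = [min_offset + (i + 1) * usable // (len(motifs) + 1) for i in range(len(motifs))]
    for cut, motif in zip(cuts, motifs):
        pieces.append(background[prev:cut])
        pieces.append(motif)
        prev = cut
    pieces.append(background[prev:])
    return "".join(pieces)


def simulate_sequences(
    config: SimConfig,
    annotations: list[TranscriptAnnotation],
    plant_motifs: bool = True,
    max_uorf: int = 2,
    max_cpe: int = 3,
    top_prob: float = 0.3,
) -> tuple[list[TranscriptAnnotation], pd.DataFrame]:
    """Attach synthetic sequences with a known element census to annotations.

    Backgrounds are i.i.d. uniform over ACGT scrubbed of the scanned motifs
    (no ATG in 5'UTRs, no CPE consensus in 3'UTRs, first 5'UTR base never C),
    then a seeded number of complete uORFs, a terminal oligopyrimidine (TOP)
    prefix, and CPE consensus copies are spliced in.  The returned truth
    table (gene_id, n_uorf, has_top, n_cpe) is therefore exact by
    construction, independent of any scanner.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    out, truth = [], []
    for ann in annotations:
        n_uorf = has_top = n_cpe = 0
        if plant_motifs:
            budget = (ann.utr5_len - len(_TOP_PREFIX)) // len(_UORF_MOTIF)
            n_uorf = int(rng.integers(0, min(max_uorf, max(budget, 0)) + 1))
            has_top = int(rng.random() < top_prob)
            budget3 = ann.utr3_len // len(_CPE_MOTIF)
            n_cpe = int(rng.integers(0, min(max_cpe, max(budget3, 0)) + 1))

        bg_len = ann.utr5_len - n_uorf * len(_UORF_MOTIF)
        utr5 = _utr5_background(rng, bg_len)
        if has_top:
            utr5 = _TOP_PREFIX + utr5[len(_TOP_PREFIX):]
        utr5 = _splice(utr5, [_UORF_MOTIF] * n_uorf,
                       min_offset=len(_TOP_PREFIX) if ann.utr5_len >= 6 else 0)

        utr3 = _splice(
            _utr3_background(rng, ann.utr3_len - n_cpe * len(_CPE_MOTIF)),
            [_CPE_MOTIF] * n_cpe,
        )
        cds = "ATG" + _uniform_seq(rng, ann.cds_len - 3)

        out.append(dataclasses.replace(ann, utr5_seq=utr5, cds_seq=cds, utr3_seq=utr3))
        truth.append((ann.gene_id, n_uorf, bool(has_top), n_cpe))
    truth_df = pd.DataFrame(truth, columns=["gene_id", "n_uorf", "has_top", "n_cpe"])
    return out, truth_df.set_index("gene_id")
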