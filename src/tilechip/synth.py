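"""Synthetic tiling-array data with the statistical structure the analysis
assumes.

The generator builds a toy genome (several autosome-like chromosomes plus
one X-like chromosome), places non-overlapping genes carrying
temporal-spatial class labels, and emits per-probe log2-ratio replicate
tables in which class-dependent enrichment domains with target-specific
shapes (flat gene body, 5'-skewed body, TSS peak, TSS+TES peak, inverted
body, promoter dip) sit on Gaussian probe noise.  Germline-class genes are
depleted from the X-like chromosome, emulating the chromosomal bias of
germline gene content.  A truth table records every implanted domain for
recovery scoring.

Randomness is organized as named, splittable streams derived from one
master seed (genome layout, expression, and one stream per
(target, replicate)), so adding a target or replicate never perturbs the
others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .models import ContractError, GeneModel, GenomeLayout, TRACK_COLUMNS

GERMLINE_PREFIX = "germline"

SHAPES = (
    "flat-body",
    "five-prime-skewed-body",
    "tss-peak",
    "tss-and-tes-peak",
    "anti-expressed",
    "promoter-dip",
)

_STREAM_GENOME = 0
_STREAM_EXPRESSION = 1
_STREAM_CHIP = 2


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class PlacementError(RuntimeError):
    """Genome too small to place the requested genes."""


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults give a desk-scale study-like
    genome (5 autosome-like chromosomes + one X-like, each 1 Mb, ~200
    genes, enrichment amplitude 5 on noise SD 1, 3 replicates)."""

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {
            "chrI": 1_000_000,
            "chrII": 1_000_000,
            "chrIII": 1_000_000,
            "chrIV": 1_000_000,
            "chrV": 1_000_000,
            "chrX": 1_000_000,
        }
    )
    x_like: str = "chrX"
    n_genes: int = 200
    class_mix: dict[str, float] = field(
        default_factory=lambda: {
            "germline-specific": 0.10,
            "germline-expressed": 0.30,
            "ubiquitous": 0.25,
            "embryo-expressed": 0.15,
            "soma-specific": 0.10,
            "silent": 0.10,
        }
    )
    x_germline_depletion: float = 0.05
    probe_length: int = 50
    probe_spacing: int = 50
    n_replicates: int = 3
    noise_sd: float = 1.0
    # effect_table[target][class] -> log2 enrichment amplitude
    effect_table: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "mes4": {
                "germline-specific": 5.0,
                "germline-expressed": 5.0,
                "ubiquitous": 5.0,
                "embryo-expressed": 0.0,
                "soma-specific": 0.0,
                "silent": 0.0,
            },
            "h3k36me3": {
                "germline-specific": 5.0,
                "germline-expressed": 5.0,
                "ubiquitous": 5.0,
                "embryo-expressed": 0.0,
                "soma-specific": 0.0,
                "silent": 0.0,
            },
            "pol2": {
                "germline-specific": 0.0,
                "germline-expressed": 5.0,
                "ubiquitous": 5.0,
                "embryo-expressed": 5.0,
                "soma-specific": 5.0,
                "silent": 0.0,
            },
            "noab": {
                "germline-specific": 0.0,
                "germline-expressed": 0.0,
                "ubiquitous": 0.0,
                "embryo-expressed": 0.0,
                "soma-specific": 0.0,
                "silent": 0.0,
            },
        }
    )
    shape_table: dict[str, str] = field(
        default_factory=lambda: {
            "mes4": "five-prime-skewed-body",
            "h3k36me3": "flat-body",
            "pol2": "tss-and-tes-peak",
            "noab": "flat-body",
        }
    )
    frac_long: float = 0.7  # fraction of genes drawn longer than 2 kb
    min_gene_gap: int = 500
    # expression-array parameters (log2 intensities)
    class_expression: dict[str, float] = field(
        default_factory=lambda: {
            "germline-specific": 7.0,
            "germline-expressed": 8.0,
            "ubiquitous": 9.0,
            "embryo-expressed": 8.0,
            "soma-specific": 6.0,
            "silent": 4.0,
        }
    )
    n_samples: int = 4
    probes_per_gene: int = 3
    probe_offset_sd: float = 0.25
    expression_noise_sd: float = 0.25

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.chrom_lengths) < 2:
            raise ConfigError("need at least 2 chromosomes")
        if any(length <= 0 for length in self.chrom_lengths.values()):
            raise ConfigError("chromosome lengths must be positive")
        if self.x_like not in self.chrom_lengths:
            raise ConfigError(f"X-like chromosome {self.x_like!r} not in chrom_lengths")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("class proportions must sum to 1")
        if not 0.0 <= self.x_germline_depletion <= 1.0:
            raise ConfigError("x_germline_depletion must be in [0, 1]")
        if self.probe_spacing < 1:
            raise ConfigError("probe_spacing must be >= 1")
        if self.probe_length < 1:
            raise ConfigError("probe_length must be >= 1")
        for target, shape in self.shape_table.items():
            if shape not in SHAPES:
                raise ConfigError(f"unknown shape {shape!r} for target {target!r}")
        for target in self.shape_table:
            effects = self.effect_table.get(target)
            if effects is None:
                raise ConfigError(f"no effect row for target {target!r}")
            for cls in self.class_mix:
                if cls not in effects:
                    raise ConfigError(f"no effect for class {cls!r}, target {target!r}")
        for cls in self.class_mix:
            if cls not in self.class_expression:
                raise ConfigError(f"no expression mean for class {cls!r}")

    @property
    def targets(self) -> list[str]:
        return list(self.shape_table)

    def layout(self) -> GenomeLayout:
        return GenomeLayout(lengths=dict(self.chrom_lengths), focal=self.x_like)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def genome_rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAM_GENOME])


def expression_rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAM_EXPRESSION])


def chip_rng(config: SimulationConfig, target: str, replicate: int) -> np.random.Generator:
    return np.random.default_rng(
        [config.seed, _STREAM_CHIP, zlib.crc32(target.encode()), replicate]
    )


@dataclass
class TruthTable:
    """Ground truth of the simulation: one row per implanted enrichment
    interval (gene, class, target, amplitude, interval)."""

    intervals: pd.DataFrame  # gene_id, class_label, target, amplitude, chrom, start, end

    def enriched_intervals(self, target: str) -> pd.DataFrame:
        df = self.intervals
        return df[(df["target"] == target) & (df["amplitude"] != 0.0)].reset_index(drop=True)

    def enriched_gene_counts(self, target: str) -> dict[str, int]:
        """Per-chromosome count of genes with an implanted domain."""
        df = self.enriched_intervals(target)
        return df.groupby("chrom")["gene_id"].nunique().to_dict()

    def write(self, path: str) -> None:
        self.intervals.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _gene_lengths(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    is_long = rng.random(config.n_genes) < config.frac_long
    lengths = np.where(
        is_long,
        rng.integers(2100, 6001, size=config.n_genes),
        rng.integers(900, 1901, size=config.n_genes),
    )
    return lengths.astype(np.int64)


def _exon_blocks(
    rng: np.random.Generator, tx_start: int, length: int
) -> list[tuple[int, int]]:
    """Partition a transcript into alternating exon/intron segments, each at
    least 300 bp, so internal exons can feed triplet analyses."""
    min_seg = 300
    max_exons = max(1, int((length / min_seg + 1) // 2))
    n_exons = int(rng.integers(1, min(4, max_exons) + 1))
    n_seg = 2 * n_exons - 1
    extra = rng.multinomial(length - min_seg * n_seg, [1.0 / n_seg] * n_seg)
    seg_lengths = min_seg + extra
    exons = []
    pos = tx_start
    for i, seg in enumerate(seg_lengths):
        if i % 2 == 0:
            exons.append((pos, pos + int(seg)))
        pos += int(seg)
    return exons


def make_genome(
    config: SimulationConfig,
) -> tuple[GenomeLayout, list[GeneModel], TruthTable]:
    """Place ``n_genes`` non-overlapping genes on the configured genome.

    Class counts follow one multinomial draw over the class mix; gene
    chromosomes are drawn proportional to length, except that germline-class
    genes remain on the X-like chromosome only with probability
    ``x_germline_depletion`` (otherwise they are redrawn among the other
    chromosomes).  Deterministic for a fixed seed.
    """
    layout = config.layout()
    rng = genome_rng(config)
    classes = list(config.class_mix)
    probs = [config.class_mix[c] for c in classes]
    counts = rng.multinomial(config.n_genes, probs)
    labels = np.repeat(classes, counts)
    rng.shuffle(labels)
    lengths = _gene_lengths(rng, config)

    chroms = layout.chroms
    weights = np.array([layout.lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    non_x = [c for c in chroms if c != config.x_like]
    non_x_weights = np.array([layout.lengths[c] for c in non_x], dtype=float)
    non_x_weights /= non_x_weights.sum()

    gene_chroms: list[str] = []
    for label in labels:
        c = chroms[rng.choice(len(chroms), p=weights)]
        if c == config.x_like and str(label).startswith(GERMLINE_PREFIX):
            if not rng.random() < config.x_germline_depletion:
                c = non_x[rng.choice(len(non_x), p=non_x_weights)]
        gene_chroms.append(c)

    strands = np.where(rng.random(config.n_genes) < 0.5, "+", "-")

    # lay genes out chromosome by chromosome with randomized gaps
    per_chrom: dict[str, list[int]] = {c: [] for c in chroms}
    for i, c in enumerate(gene_chroms):
        per_chrom[c].append(i)
    starts = np.zeros(config.n_genes, dtype=np.int64)
    for c, idxs in per_chrom.items():
        if not idxs:
            continue
        total = int(lengths[idxs].sum()) + config.min_gene_gap * (len(idxs) + 1)
        if total > layout.lengths[c]:
            raise PlacementError(
                f"cannot place {len(idxs)} genes on chromosome {c!r} "
                f"(need {total} bp, have {layout.lengths[c]})"
            )
        slack = layout.lengths[c] - total
        gaps = rng.multinomial(slack, [1.0 / (len(idxs) + 1)] * (len(idxs) + 1))
        pos = 0
        for j, i in enumerate(idxs):
            pos += config.min_gene_gap + int(gaps[j])
            starts[i] = pos
            pos += int(lengths[i])

    genes: list[GeneModel] = []
    for i in range(config.n_genes):
        tx_start = int(starts[i])
        tx_end = tx_start + int(lengths[i])
        exons = _exon_blocks(rng, tx_start, int(lengths[i]))
        genes.append(
            GeneModel(
                gene_id=f"gene_{i + 1:04d}",
                chrom=gene_chroms[i],
                strand=str(strands[i]),
                tx_start=tx_start,
                tx_end=tx_end,
                exons=exons,
                class_label=str(labels[i]),
            )
        )

    truth_rows = []
    for g in genes:
        for target in config.targets:
            amplitude = config.effect_table[target][g.class_label]
            for s, e in _truth_intervals(g, config.shape_table[target], layout):
                truth_rows.append(
                    {
                        "gene_id": g.gene_id,
                        "class_label": g.class_label,
                        "target": target,
                        "amplitude": amplitude,
                        "chrom": g.chrom,
                        "start": s,
                        "end": e,
                    }
                )
    truth = TruthTable(
        intervals=pd.DataFrame(
            truth_rows,
            columns=["gene_id", "class_label", "target", "amplitude", "chrom", "start", "end"],
        )
    )
    return layout, genes, truth


_PEAK_HALF_WIDTH = 500  # support half-width of TSS/TES peak shapes, bp
_PEAK_SIGMA = 250.0


def _truth_intervals(
    gene: GeneModel, shape: str, layout: GenomeLayout
) -> list[tuple[int, int]]:
    L = layout.lengths[gene.chrom]

    def clip(s: int, e: int) -> tuple[int, int]:
        return max(0, s), min(L, e)

    if shape in ("flat-body", "five-prime-skewed-body", "anti-expressed", "promoter-dip"):
        return [clip(gene.tx_start, gene.tx_end)]
    if shape == "tss-peak":
        return [clip(gene.tss - _PEAK_HALF_WIDTH, gene.tss + _PEAK_HALF_WIDTH)]
    if shape == "tss-and-tes-peak":
        return [
            clip(gene.tss - _PEAK_HALF_WIDTH, gene.tss + _PEAK_HALF_WIDTH),
            clip(gene.tes - _PEAK_HALF_WIDTH, gene.tes + _PEAK_HALF_WIDTH),
        ]
    raise ConfigError(f"unknown shape {shape!r}")


def _shape_multiplier(
    shape: str,
    rel: np.ndarray,
    contained: np.ndarray,
    gene_len: int,
) -> np.ndarray:
    """Noiseless per-probe multiplier in [-1, 1] for one gene.

    ``rel`` is the probe midpoint relative to the TSS in transcription
    orientation; ``contained`` marks probes fully inside the transcript.
    """
    out = np.zeros_like(rel, dtype=float)
    L = gene_len
    if shape == "flat-body":
        out[contained] = 1.0
    elif shape == "five-prime-skewed-body":
        body = contained
        rise = body & (rel < 500)
        out[rise] = rel[rise] / 500.0
        fall = body & (rel >= 500)
        out[fall] = 1.0 - 0.4 * (rel[fall] - 500) / max(L - 500, 1)
    elif shape == "tss-peak":
        near = np.abs(rel) <= 3 * _PEAK_SIGMA
        out[near] = np.exp(-(rel[near] ** 2) / (2 * _PEAK_SIGMA**2))
    elif shape == "tss-and-tes-peak":
        for center in (0, L):
            d = rel - center
            near = np.abs(d) <= 3 * _PEAK_SIGMA
            out[near] = np.maximum(out[near], np.exp(-(d[near] ** 2) / (2 * _PEAK_SIGMA**2)))
    elif shape == "anti-expressed":
        out[contained] = -1.0
    elif shape == "promoter-dip":
        out[contained] = 1.0
        promoter = (rel >= -300) & (rel < 0)
        out[promoter] = -0.5
    else:
        raise ConfigError(f"unknown shape {shape!r}")
    return out


def tile_probes(layout: GenomeLayout, probe_length: int = 50, spacing: int = 50) -> pd.DataFrame:
    """Tile every chromosome end to end; the probe count per chromosome is
    floor((length - probe_length)/spacing) + 1."""
    frames = []
    for chrom in layout.chroms:
        L = layout.lengths[chrom]
        if L < probe_length:
            continue
        starts = np.arange(0, L - probe_length + 1, spacing, dtype=np.int64)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + probe_length,
                    "probe_id": [f"{chrom}_{i}" for i in range(len(starts))],
                    "value": 0.0,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[TRACK_COLUMNS]


def noiseless_signal(
    genes: list[GeneModel],
    probes: pd.DataFrame,
    config: SimulationConfig,
    target: str,
) -> np.ndarray:
    """Per-probe noiseless mean: sum over genes of shape x amplitude."""
    if target not in config.shape_table:
        raise ConfigError(f"unknown target {target!r}")
    shape = config.shape_table[target]
    starts = probes["start"].to_numpy(np.int64)
    ends = probes["end"].to_numpy(np.int64)
    mids = (starts + ends) // 2
    chrom_arr = probes["chrom"].to_numpy(str)
    signal = np.zeros(len(probes))
    chrom_index: dict[str, np.ndarray] = {}
    for chrom in np.unique(chrom_arr):
        chrom_index[chrom] = np.flatnonzero(chrom_arr == chrom)
    margin = 2000
    for g in genes:
        amplitude = config.effect_table[target][g.class_label]
        if amplitude == 0.0:
            continue
        idx = chrom_index.get(g.chrom)
        if idx is None:
            continue
        m = mids[idx]
        lo = np.searchsorted(m, g.tx_start - margin, side="left")
        hi = np.searchsorted(m, g.tx_end + margin, side="right")
        sub = idx[lo:hi]
        rel = (
            mids[sub] - g.tx_start if g.strand == "+" else g.tx_end - mids[sub]
        ).astype(float)
        contained = (starts[sub] >= g.tx_start) & (ends[sub] <= g.tx_end)
        signal[sub] += amplitude * _shape_multiplier(shape, rel, contained, g.length)
    return signal


def simulate_chip(
    genes: list[GeneModel],
    layout: GenomeLayout,
    config: SimulationConfig,
    target: str,
) -> list[pd.DataFrame]:
    """Replicate set of per-probe log2-ratio tables for one ChIP target.

    Replicates share the noiseless signal and differ only in Gaussian
    probe noise drawn from the (target, replicate) stream.
    """
    probes = tile_probes(layout, config.probe_length, config.probe_spacing)
    signal = noiseless_signal(genes, probes, config, target)
    replicates = []
    for rep in range(config.n_replicates):
        rng = chip_rng(config, target, rep)
        track = probes.copy()
        noise = rng.normal(0.0, config.noise_sd, len(probes)) if config.noise_sd > 0 else 0.0
        track["value"] = signal + noise
        replicates.append(track)
    return replicates


def simulate_expression(
    genes: list[GeneModel], config: SimulationConfig
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Expression array: ``probes_per_gene`` probes per gene across
    ``n_samples`` samples, log2 scale.

    probe value = class mean + per-probe offset + per-(probe, sample) noise.
    Returns (matrix indexed by probe id, probe -> gene map).
    """
    rng = expression_rng(config)
    probe_ids = []
    probe_to_gene: dict[str, str] = {}
    values = np.zeros((len(genes) * config.probes_per_gene, config.n_samples))
    for i, g in enumerate(genes):
        base = config.class_expression[g.class_label]
        offsets = (
            rng.normal(0.0, config.probe_offset_sd, config.probes_per_gene)
            if config.probe_offset_sd > 0
            else np.zeros(config.probes_per_gene)
        )
        noise = (
            rng.normal(0.0, config.expression_noise_sd, (config.probes_per_gene, config.n_samples))
            if config.expression_noise_sd > 0
            else np.zeros((config.probes_per_gene, config.n_samples))
        )
        for j in range(config.probes_per_gene):
            pid = f"{g.gene_id}_p{j + 1}"
            probe_ids.append(pid)
            probe_to_gene[pid] = g.gene_id
            values[i * config.probes_per_gene + j] = base + offsets[j] + noise[j]
    matrix = pd.DataFrame(
        values,
        index=pd.Index(probe_ids, name="probe_id"),
        columns=[f"sample_{k + 1}" for k in range(config.n_samples)],
    )
    return matrix, probe_to_gene
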