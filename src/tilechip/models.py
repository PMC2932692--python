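"""Core in-memory containers shared across the package.

Coordinates are 0-based, half-open everywhere.  Exporters convert to the
1-based conventions of on-disk formats where required.

Per-probe signal ("tracks") travel as :class:`pandas.DataFrame` objects with
columns ``chrom, start, end, probe_id, value`` sorted by ``(chrom, start)``;
:func:`validate_track` enforces that contract at module boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRACK_COLUMNS = ["chrom", "start", "end", "probe_id", "value"]


class ContractError(ValueError):
    """An input violated a documented precondition."""


class DegenerateInputError(ValueError):
    """Statistically degenerate input (e.g. zero variance)."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome-name -> length (bp) map with a designated focal
    chromosome (the chromosome whose peak depletion/enrichment is tested)."""

    lengths: dict[str, int]
    focal: str = "X"

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ContractError("layout needs at least one chromosome")
        for name, length in self.lengths.items():
            if length <= 0:
                raise ContractError(f"chromosome {name!r} has non-positive length {length}")
        if self.focal not in self.lengths:
            raise ContractError(f"focal chromosome {self.focal!r} not in layout")

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths


@dataclass
class GeneModel:
    """A gene with one transcript model: bounds, strand, exon blocks, and
    optional class label / expression value."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    class_label: str | None = None
    expression: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ContractError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.tx_start < self.tx_end:
            raise ContractError(f"gene {self.gene_id}: tx_start must be < tx_end")
        if not self.exons:
            self.exons = [(self.tx_start, self.tx_end)]
        prev_end = None
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ContractError(f"gene {self.gene_id}: exon ({s},{e}) outside transcript")
            if prev_end is not None and s < prev_end:
                raise ContractError(f"gene {self.gene_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start

    @property
    def tss(self) -> int:
        """Transcript start site as a point coordinate (strand-aware)."""
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def tes(self) -> int:
        """Transcript end site as a point coordinate (strand-aware)."""
        return self.tx_end if self.strand == "+" else self.tx_start

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i][1] < self.exons[i + 1][0]
        ]


@dataclass
class Window:
    """One sliding-window evaluation: interval, member-probe mean, and
    (after scoring) raw and Bonferroni-adjusted upper-tail p-values.

    p-values are carried in natural-log space (``log_raw_p``/``log_adj_p``)
    so that tails far beyond float underflow remain comparable; the linear
    fields underflow to 0.0 gracefully.
    """

    chrom: str
    start: int
    end: int
    mean_z: float
    n_probes: int
    raw_p: float | None = None
    adj_p: float | None = None
    log_raw_p: float | None = None
    log_adj_p: float | None = None


@dataclass
class Peak:
    """A maximal run of merged significant windows."""

    chrom: str
    start: int
    end: int
    summit: int
    mean_z: float
    adj_p: float
    log_adj_p: float
    peak_id: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ContractError(f"peak {self.peak_id}: start must be < end")
        if not (self.start <= self.summit < self.end):
            raise ContractError(f"peak {self.peak_id}: summit outside interval")


@dataclass
class ExonTriplet:
    """An internal exon together with both flanking introns, all at least a
    minimum length; intervals are genomic, orientation given by ``strand``."""

    gene_id: str
    chrom: str
    strand: str
    intron_up: tuple[int, int]
    exon: tuple[int, int]
    intron_down: tuple[int, int]

    @property
    def exon_start(self) -> int:
        """5' boundary of the exon in transcription orientation."""
        return self.exon[0] if self.strand == "+" else self.exon[1]

    @property
    def exon_end(self) -> int:
        """3' boundary of the exon in transcription orientation."""
        return self.exon[1] if self.strand == "+" else self.exon[0]


def validate_track(track: pd.DataFrame, name: str = "track") -> pd.DataFrame:
    """Check the probe-track DataFrame contract; returns the track."""
    missing = [c for c in TRACK_COLUMNS if c not in track.columns]
    if missing:
        raise ContractError(f"{name}: missing columns {missing}")
    if len(track) and not np.isfinite(track["value"].to_numpy(float)).all():
        raise ContractError(f"{name}: non-finite values")
    return track


def midpoints(track: pd.DataFrame) -> np.ndarray:
    """Probe point locations: the midpoint, rounded down."""
    return (track["start"].to_numpy(np.int64) + track["end"].to_numpy(np.int64)) // 2


def same_probe_set(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    if len(a) != len(b):
        return False
    return (
        a["chrom"].to_numpy(str) == b["chrom"].to_numpy(str)
    ).all() and (a["start"].to_numpy() == b["start"].to_numpy()).all()


def sort_track(track: pd.DataFrame) -> pd.DataFrame:
    return track.sort_values(["chrom", "start"], kind="mergesort", ignore_index=True)
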