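"""Readers and writers for every on-disk format the pipeline touches.

All formats are plain text: TSV probe tables, bedGraph, BED12 gene models,
BED6+ peak calls, and assorted TSV tables.  Readers validate against the
declared genome layout and reject out-of-bounds coordinates rather than
clamping them.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .models import (
    ContractError,
    GeneModel,
    GenomeLayout,
    Peak,
    TRACK_COLUMNS,
    sort_track,
    validate_track,
)


class FormatError(ValueError):
    """A file failed structural validation."""


# ---------------------------------------------------------------------------
# probe tables


def read_probe_table(path: str | os.PathLike, layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Read a TSV probe table (chrom, start, end, probe_id, value).

    Records come back sorted by (chrom, start).  With a layout, coordinates
    outside chromosome bounds raise a :class:`FormatError` naming the line.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "probe_id": str},
        )
    except ValueError as exc:
        raise FormatError(f"{path}: unparseable probe table: {exc}") from exc
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna() & df["value"].notna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, +1 1-based
        raise FormatError(f"{path}: non-numeric value at line {line}")
    df["value"] = values.astype(float)
    if (df["start"] >= df["end"]).any():
        raise FormatError(f"{path}: probe with start >= end")
    if layout is not None:
        for i, (chrom, end) in enumerate(zip(df["chrom"], df["end"])):
            if chrom not in layout:
                raise FormatError(f"{path}: unknown chromosome {chrom!r} at line {i + 2}")
            if end > layout.lengths[chrom]:
                raise FormatError(
                    f"{path}: probe beyond end of {chrom} at line {i + 2} (end={end})"
                )
    return sort_track(df[TRACK_COLUMNS])


def write_probe_table(track: pd.DataFrame, path: str | os.PathLike) -> None:
    validate_track(track)
    track[TRACK_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_bedgraph(track: pd.DataFrame, path: str | os.PathLike) -> None:
    """bedGraph is 0-based half-open, so coordinates pass through unchanged."""
    validate_track(track)
    track[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", index=False, header=False, float_format="%.6g"
    )


# ---------------------------------------------------------------------------
# BED12 gene models


def read_genes_bed12(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from BED12; exon blocks are reconstructed from
    blockStarts/blockSizes.  tx_start is always the smaller coordinate."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 BED fields, got {len(fields)}")
            chrom, start, end, name, _score, strand = fields[:6]
            start, end = int(start), int(end)
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise FormatError(f"{path}:{lineno}: blockCount inconsistent with block lists")
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            if exons[-1][1] > end:
                raise FormatError(f"{path}:{lineno}: block extends past chromEnd")
            genes.append(
                GeneModel(gene_id=name, chrom=chrom, strand=strand, tx_start=start, tx_end=end, exons=exons)
            )
    return genes


def write_genes_bed12(genes: list[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.tx_start) for s, e in g.exons)
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(g.tx_start),
                        str(g.tx_end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(g.tx_start),
                        str(g.tx_end),
                        "0",
                        str(len(g.exons)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# peaks (BED6+: name, score = 10 * mean z rounded, then summit / adj_p / log_adj_p)

_PEAK_HEADER = "#chrom\tstart\tend\tname\tscore\tstrand\tsummit\tmean_z\tadj_p\tlog_adj_p"


def write_peaks_bed(peaks: list[Peak], path: str | os.PathLike) -> None:
    """Write peaks as BED6+ with summit, mean z and adjusted p columns.

    Input must be sorted by (chrom, start); the file round-trips losslessly
    through :func:`read_peaks_bed`.
    """
    for prev, cur in zip(peaks, peaks[1:]):
        if (cur.chrom, cur.start) < (prev.chrom, prev.start):
            raise ContractError("peaks must be sorted by (chrom, start)")
    with open(path, "w") as fh:
        fh.write(_PEAK_HEADER + "\n")
        for p in peaks:
            score = int(round(min(1000.0, max(0.0, 10.0 * p.mean_z))))
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        p.peak_id,
                        str(score),
                        ".",
                        str(p.summit),
                        repr(float(p.mean_z)),
                        repr(float(p.adj_p)),
                        repr(float(p.log_adj_p)),
                    ]
                )
                + "\n"
            )


def read_peaks_bed(path: str | os.PathLike) -> list[Peak]:
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise FormatError(f"{path}:{lineno}: expected 10 peak fields")
            peaks.append(
                Peak(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    summit=int(f[6]),
                    mean_z=float(f[7]),
                    adj_p=float(f[8]),
                    log_adj_p=float(f[9]),
                    peak_id=f[3],
                )
            )
    return peaks


# ---------------------------------------------------------------------------
# simple TSV tables


def read_class_labels(path: str | os.PathLike) -> dict[str, str]:
    """TSV with columns gene_id, class_label -> mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "class_label"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns gene_id, class_label")
    return dict(zip(df["gene_id"], df["class_label"]))


def write_class_labels(labels: dict[str, str], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"gene_id": list(labels), "class_label": list(labels.values())}
    ).to_csv(path, sep="\t", index=False)


def read_expression_values(path: str | os.PathLike) -> dict[str, float]:
    """TSV with columns gene_id, expression -> mapping."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "expression"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns gene_id, expression")
    return dict(zip(df["gene_id"].astype(str), df["expression"].astype(float)))


def write_expression_values(values: dict[str, float], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"gene_id": list(values), "expression": list(values.values())}
    ).to_csv(path, sep="\t", index=False, float_format="%.8g")
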