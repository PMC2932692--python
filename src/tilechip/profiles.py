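"""Metagene and exon-boundary signal profiles.

Genes are oriented so that transcription runs left to right (minus-strand
genes are mirrored) and probes are pooled across genes of a group into
fixed-width bins relative to an anchor (TSS, TES, or exon boundaries).  Bin
values are the mean over all contributing probes, with 1.96*SEM confidence
half-widths; empty bins are NaN, not zero.

Two conventions exist for the TSS window: ``"results"`` (the default) spans
1 kb upstream to 1.5 kb downstream of the TSS, ``"methods"`` spans 1.5 kb
upstream to 1 kb downstream.  The TES window always spans 1.5 kb upstream
to 1 kb downstream of the TES.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import ContractError, ExonTriplet, GeneModel, midpoints, validate_track

BIN_SIZE = 50

TSS_WINDOWS = {"results": (-1000, 1500), "methods": (-1500, 1000)}
TES_WINDOW = (-1500, 1000)
EXON_START_WINDOW = (-300, 200)
EXON_END_WINDOW = (-200, 300)


@dataclass
class ProfileMatrix:
    """Binned group-average profile around one anchor.

    ``mean``, ``ci`` and ``n`` are (groups x bins); empty bins hold NaN
    means with n = 0.  ``bin_centers`` are bp relative to the anchor.
    """

    anchor: str
    bin_centers: np.ndarray
    groups: list[str]
    mean: np.ndarray
    ci: np.ndarray
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gi, group in enumerate(self.groups):
            for bi, center in enumerate(self.bin_centers):
                rows.append(
                    {
                        "anchor": self.anchor,
                        "group": group,
                        "bin_center": int(center),
                        "mean": self.mean[gi, bi],
                        "ci": self.ci[gi, bi],
                        "n_probes": int(self.n[gi, bi]),
                    }
                )
        return pd.DataFrame(rows)


def quantile_bin_genes(
    genes: list[GeneModel], k: int = 5, min_len: int = 2000
) -> dict[str, int]:
    """Split genes longer than ``min_len`` into ``k`` expression groups of
    equal size (+-1), ranked low to high; group k-1 is the most expressed.

    Ties are broken by stable gene-id order.  Genes must carry an
    ``expression`` value.
    """
    eligible = [g for g in genes if g.length > min_len]
    for g in eligible:
        if g.expression is None:
            raise ContractError(f"gene {g.gene_id} has no expression value")
    if len(eligible) < k:
        raise ContractError(f"only {len(eligible)} eligible genes for {k} groups")
    order = sorted(eligible, key=lambda g: (g.expression, g.gene_id))
    chunks = np.array_split(np.arange(len(order)), k)
    out: dict[str, int] = {}
    for gi, chunk in enumerate(chunks):
        for i in chunk:
            out[order[i].gene_id] = gi
    return out


def _bin_index(rel: np.ndarray, lo: int, hi: int, n_bins: int) -> np.ndarray:
    """Nearest-bin-center assignment for positions relative to the anchor.

    Bins are ``BIN_SIZE`` wide from ``lo`` to ``hi``; a position exactly
    midway between two centers (a bin boundary) goes to the left bin.
    Returns -1 for positions outside [lo, hi].
    """
    rel = np.asarray(rel, dtype=float)
    q = (rel - lo) / BIN_SIZE
    idx = np.floor(q).astype(int)
    on_boundary = (q == idx) & (idx > 0)
    idx[on_boundary] -= 1
    idx[(rel < lo) | (rel > hi)] = -1
    idx[idx >= n_bins] = -1
    return idx


class _Accumulator:
    """Pooled-probe Welford-style accumulation per (group, bin)."""

    def __init__(self, n_groups: int, n_bins: int) -> None:
        self.n = np.zeros((n_groups, n_bins), dtype=np.int64)
        self.s1 = np.zeros((n_groups, n_bins))
        self.s2 = np.zeros((n_groups, n_bins))

    def add(self, group: int, bins: np.ndarray, values: np.ndarray) -> None:
        keep = bins >= 0
        bins, values = bins[keep], values[keep]
        np.add.at(self.n[group], bins, 1)
        np.add.at(self.s1[group], bins, values)
        np.add.at(self.s2[group], bins, values**2)

    def finish(self, anchor: str, centers: np.ndarray, groups: list[str]) -> ProfileMatrix:
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = self.s1 / self.n
            var = self.s2 / self.n - mean**2
            var = np.clip(var, 0.0, None)
            sem = np.sqrt(var / self.n)
        mean[self.n == 0] = np.nan
        ci = 1.96 * sem
        ci[self.n == 0] = np.nan
        return ProfileMatrix(anchor=anchor, bin_centers=centers, groups=groups, mean=mean, ci=ci, n=self.n)


def _track_by_chrom(track: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    mids_all = midpoints(track)
    vals_all = track["value"].to_numpy(float)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, idx in track.groupby("chrom", sort=False).indices.items():
        idx = np.asarray(idx)
        order = np.argsort(mids_all[idx], kind="mergesort")
        out[str(chrom)] = (mids_all[idx][order], vals_all[idx][order])
    return out


def metagene_profile(
    track: pd.DataFrame,
    genes: list[GeneModel],
    groups: dict[str, int],
    anchor: str = "TSS",
    convention: str = "results",
    n_bins: int = 50,
) -> ProfileMatrix:
    """Pooled-probe average profile around the TSS or TES for gene groups.

    Probe midpoints are mapped into transcription-relative coordinates
    (minus-strand genes mirrored) and assigned to the nearest of ``n_bins``
    50-bp bin centers.
    """
    validate_track(track)
    if anchor not in ("TSS", "TES"):
        raise ContractError("anchor must be 'TSS' or 'TES'")
    lo, hi = TSS_WINDOWS[convention] if anchor == "TSS" else TES_WINDOW
    group_ids = sorted(set(groups.values()))
    if not group_ids:
        raise ContractError("no gene groups supplied")
    counts = {gi: 0 for gi in group_ids}
    for g in genes:
        if g.gene_id in groups:
            counts[groups[g.gene_id]] += 1
    for gi, c in counts.items():
        if c == 0:
            raise ContractError(f"gene group {gi!r} contains no genes")
    gmap = {gi: i for i, gi in enumerate(group_ids)}
    by_chrom = _track_by_chrom(track)
    acc = _Accumulator(len(group_ids), n_bins)
    centers = np.array([lo + BIN_SIZE * i + BIN_SIZE // 2 for i in range(n_bins)])
    for g in genes:
        if g.gene_id not in groups or g.chrom not in by_chrom:
            continue
        mids, vals = by_chrom[g.chrom]
        a = g.tss if anchor == "TSS" else g.tes
        if g.strand == "+":
            glo, ghi = a + lo, a + hi
        else:
            glo, ghi = a - hi, a - lo
        i0 = np.searchsorted(mids, glo, side="left")
        i1 = np.searchsorted(mids, ghi, side="right")
        m = mids[i0:i1]
        rel = (m - a) if g.strand == "+" else (a - m)
        acc.add(gmap[groups[g.gene_id]], _bin_index(rel, lo, hi, n_bins), vals[i0:i1])
    return acc.finish(anchor, centers, [str(gi) for gi in group_ids])


def find_exon_triplets(genes: list[GeneModel], min_len: int = 300) -> list[ExonTriplet]:
    """All internal exons whose own length and both flanking introns'
    lengths are >= min_len; a gene may contribute several triplets."""
    out: list[ExonTriplet] = []
    for g in genes:
        introns = g.introns
        for i in range(1, len(g.exons) - 1):
            exon = g.exons[i]
            left, right = introns[i - 1], introns[i]
            if (
                exon[1] - exon[0] >= min_len
                and left[1] - left[0] >= min_len
                and right[1] - right[0] >= min_len
            ):
                if g.strand == "+":
                    up, down = left, right
                else:
                    up, down = right, left
                out.append(
                    ExonTriplet(
                        gene_id=g.gene_id,
                        chrom=g.chrom,
                        strand=g.strand,
                        intron_up=up,
                        exon=exon,
                        intron_down=down,
                    )
                )
    return out


def exon_boundary_profile(
    track: pd.DataFrame,
    triplets: list[ExonTriplet],
    groups: dict[str, int],
    baseline_subtract: bool = False,
) -> tuple[ProfileMatrix, ProfileMatrix, int]:
    """Profiles around exon starts (-300..+200) and exon ends (-200..+300)
    over intron-exon-intron triplets, 10 bins of 50 bp each.

    With ``baseline_subtract``, each triplet's probe values are first reduced
    by the mean over its two intronic intervals; triplets without intronic
    probes are skipped and counted in the returned third element.  Triplet
    group = group of the host gene.
    """
    validate_track(track)
    group_ids = sorted(set(groups.values()))
    if not group_ids:
        raise ContractError("no gene groups supplied")
    gmap = {gi: i for i, gi in enumerate(group_ids)}
    by_chrom = _track_by_chrom(track)
    n_bins_st = (EXON_START_WINDOW[1] - EXON_START_WINDOW[0]) // BIN_SIZE
    n_bins_en = (EXON_END_WINDOW[1] - EXON_END_WINDOW[0]) // BIN_SIZE
    acc_st = _Accumulator(len(group_ids), n_bins_st)
    acc_en = _Accumulator(len(group_ids), n_bins_en)
    skipped = 0
    for t in triplets:
        if t.gene_id not in groups or t.chrom not in by_chrom:
            continue
        mids, vals = by_chrom[t.chrom]
        baseline = 0.0
        if baseline_subtract:
            intronic = []
            for s, e in (t.intron_up, t.intron_down):
                i0 = np.searchsorted(mids, s, side="left")
                i1 = np.searchsorted(mids, e, side="left")
                intronic.append(vals[i0:i1])
            intronic = np.concatenate(intronic) if intronic else np.array([])
            if intronic.size == 0:
                skipped += 1
                continue
            baseline = float(intronic.mean())
        group = gmap[groups[t.gene_id]]
        for anchor, (lo, hi), acc, n_bins in (
            (t.exon_start, EXON_START_WINDOW, acc_st, n_bins_st),
            (t.exon_end, EXON_END_WINDOW, acc_en, n_bins_en),
        ):
            if t.strand == "+":
                glo, ghi = anchor + lo, anchor + hi
            else:
                glo, ghi = anchor - hi, anchor - lo
            i0 = np.searchsorted(mids, glo, side="left")
            i1 = np.searchsorted(mids, ghi, side="right")
            m = mids[i0:i1]
            rel = (m - anchor) if t.strand == "+" else (anchor - m)
            acc.add(group, _bin_index(rel, lo, hi, n_bins), vals[i0:i1] - baseline)
    labels = [str(gi) for gi in group_ids]
    centers_st = np.array(
        [EXON_START_WINDOW[0] + BIN_SIZE * i + BIN_SIZE // 2 for i in range(n_bins_st)]
    )
    centers_en = np.array(
        [EXON_END_WINDOW[0] + BIN_SIZE * i + BIN_SIZE // 2 for i in range(n_bins_en)]
    )
    return (
        acc_st.finish("exon-start", centers_st, labels),
        acc_en.finish("exon-end", centers_en, labels),
        skipped,
    )
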