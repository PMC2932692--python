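"""Relating peaks to genes and chromosomes.

Covers gene-level signal averaging (mean z over probes fully contained in
the transcript), peak-gene overlap relations with a body > upstream >
downstream precedence, a summit-based genomic-feature hierarchy
(exon > intron > 3' flank > 5' flank > distal), chromosome-distribution
statistics under a uniform-by-length null, and summit densities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .models import ContractError, GeneModel, GenomeLayout, Peak, midpoints, validate_track

RELATIONS = ("gene-body", "upstream-1kb", "downstream-1kb", "intergenic")
FEATURES = ("exon", "intron", "3'", "5'", "distal")


# ---------------------------------------------------------------------------
# gene-level scores


def gene_mean_z(track: pd.DataFrame, gene: GeneModel) -> float:
    """Mean z over probes fully contained in [tx_start, tx_end); NaN when no
    probe qualifies."""
    validate_track(track)
    sel = (
        (track["chrom"].to_numpy(str) == gene.chrom)
        & (track["start"].to_numpy() >= gene.tx_start)
        & (track["end"].to_numpy() <= gene.tx_end)
    )
    if not sel.any():
        return float("nan")
    return float(track["value"].to_numpy(float)[sel].mean())


def gene_score_table(
    tracks: dict[str, pd.DataFrame],
    genes: list[GeneModel],
    rna_z: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-gene mean z for each named track, plus optional RNA z and the
    gene's class label and chromosome; one row per gene."""
    rows = []
    # vectorized containment per track: sort probes once per (track, chrom)
    per_track: dict[str, dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]] = {}
    for name, track in tracks.items():
        validate_track(track, name)
        d: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, idx in track.groupby("chrom", sort=False).indices.items():
            idx = np.asarray(idx)
            starts = track["start"].to_numpy()[idx]
            order = np.argsort(starts, kind="mergesort")
            d[str(chrom)] = (
                starts[order],
                track["end"].to_numpy()[idx][order],
                track["value"].to_numpy(float)[idx][order],
            )
        per_track[name] = d
    for g in genes:
        row: dict[str, object] = {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "class_label": g.class_label,
        }
        for name, d in per_track.items():
            if g.chrom not in d:
                row[name] = float("nan")
                continue
            starts, ends, vals = d[g.chrom]
            lo = np.searchsorted(starts, g.tx_start, side="left")
            hi = np.searchsorted(starts, g.tx_end, side="left")
            contained = ends[lo:hi] <= g.tx_end
            row[name] = float(vals[lo:hi][contained].mean()) if contained.any() else float("nan")
        if rna_z is not None:
            row["rna_z"] = rna_z.get(g.gene_id, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# peak-gene relations


def _flanks(gene: GeneModel, flank: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """Strand-aware (upstream, downstream) flank intervals of width ``flank``."""
    if gene.strand == "+":
        up = (gene.tx_start - flank, gene.tx_start)
        down = (gene.tx_end, gene.tx_end + flank)
    else:
        up = (gene.tx_end, gene.tx_end + flank)
        down = (gene.tx_start - flank, gene.tx_start)
    return up, down


def peaks_to_genes(
    peaks: list[Peak], genes: list[GeneModel], flank: int = 1000
) -> tuple[pd.DataFrame, set[str], set[str]]:
    """Assign each peak one relation (body > upstream > downstream >
    intergenic) and collect the body-overlap ("bound") gene set.

    Returns (annotation frame, bound gene ids, flank-only gene ids).  A peak
    overlapping several genes lists all of them for its winning relation.
    """
    body_trees: dict[str, IntervalTree] = {}
    up_trees: dict[str, IntervalTree] = {}
    down_trees: dict[str, IntervalTree] = {}
    for g in genes:
        body_trees.setdefault(g.chrom, IntervalTree()).addi(g.tx_start, g.tx_end, g.gene_id)
        up, down = _flanks(g, flank)
        if up[0] < up[1]:
            up_trees.setdefault(g.chrom, IntervalTree()).addi(max(0, up[0]), up[1], g.gene_id)
        if down[0] < down[1]:
            down_trees.setdefault(g.chrom, IntervalTree()).addi(max(0, down[0]), down[1], g.gene_id)

    rows = []
    bound: set[str] = set()
    flank_only: set[str] = set()
    for p in peaks:
        hits_body = sorted(
            iv.data for iv in body_trees.get(p.chrom, IntervalTree()).overlap(p.start, p.end)
        )
        hits_up = sorted(
            iv.data for iv in up_trees.get(p.chrom, IntervalTree()).overlap(p.start, p.end)
        )
        hits_down = sorted(
            iv.data for iv in down_trees.get(p.chrom, IntervalTree()).overlap(p.start, p.end)
        )
        if hits_body:
            relation, gene_ids = "gene-body", hits_body
            bound.update(hits_body)
        elif hits_up:
            relation, gene_ids = "upstream-1kb", hits_up
        elif hits_down:
            relation, gene_ids = "downstream-1kb", hits_down
        else:
            relation, gene_ids = "intergenic", []
        flank_only.update(set(hits_up) | set(hits_down))
        rows.append(
            {"peak_id": p.peak_id, "relation": relation, "gene_ids": ",".join(gene_ids)}
        )
    flank_only -= bound
    return pd.DataFrame(rows, columns=["peak_id", "relation", "gene_ids"]), bound, flank_only


def assign_summit_feature(peak: Peak, genes: list[GeneModel], flank: int = 1000) -> str:
    """Feature label of the peak summit under the hierarchy
    exon > intron > 3' > 5' > distal; flanks are strand-aware."""
    s = peak.summit
    in_exon = in_intron = in_3p = in_5p = False
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        for es, ee in g.exons:
            if es <= s < ee:
                in_exon = True
        for is_, ie in g.introns:
            if is_ <= s < ie:
                in_intron = True
        up, down = _flanks(g, flank)
        if down[0] <= s < down[1]:
            in_3p = True
        if up[0] <= s < up[1]:
            in_5p = True
    if in_exon:
        return "exon"
    if in_intron:
        return "intron"
    if in_3p:
        return "3'"
    if in_5p:
        return "5'"
    return "distal"


def summit_feature_counts(
    peaks: list[Peak], genes: list[GeneModel], flank: int = 1000
) -> pd.Series:
    counts = {f: 0 for f in FEATURES}
    for p in peaks:
        counts[assign_summit_feature(p, genes, flank=flank)] += 1
    return pd.Series(counts)


# ---------------------------------------------------------------------------
# chromosome distribution


@dataclass
class ChromDistribution:
    """Observed vs length-expected peak counts per chromosome, the exact
    binomial tail for the focal chromosome (log10), and a chi-square test
    over all chromosomes."""

    table: pd.DataFrame  # chrom, observed, expected
    focal: str
    focal_observed: int
    focal_expected: float
    focal_tail: str  # "depletion" or "enrichment"
    focal_log10_p: float
    chi2_stat: float
    chi2_df: int
    chi2_log10_p: float

    @property
    def focal_p(self) -> float:
        return 10.0**self.focal_log10_p


def chromosome_distribution_from_counts(
    observed: dict[str, int], layout: GenomeLayout, focal: str | None = None
) -> ChromDistribution:
    """Uniform-by-length null on per-chromosome peak counts.

    The focal chromosome gets an exact binomial tail in log space: lower
    tail P(K <= obs) when observed < expected (depletion), else upper tail
    P(K >= obs).  A genome-wide chi-square (df = #chromosomes - 1) is
    reported alongside.
    """
    focal = focal or layout.focal
    for chrom in observed:
        if chrom not in layout:
            raise ContractError(f"chromosome {chrom!r} not in layout")
    total = sum(observed.get(c, 0) for c in layout.chroms)
    if total == 0:
        raise ContractError("no peaks to test")
    tot_len = layout.total_length
    rows = []
    for c in layout.chroms:
        rows.append(
            {
                "chrom": c,
                "observed": observed.get(c, 0),
                "expected": total * layout.lengths[c] / tot_len,
            }
        )
    table = pd.DataFrame(rows)
    p_focal = layout.lengths[focal] / tot_len
    obs_focal = observed.get(focal, 0)
    exp_focal = total * p_focal
    if obs_focal < exp_focal:
        tail = "depletion"
        log_p = stats.binom.logcdf(obs_focal, total, p_focal)
    else:
        tail = "enrichment"
        log_p = stats.binom.logsf(obs_focal - 1, total, p_focal)
    chi2 = float(((table["observed"] - table["expected"]) ** 2 / table["expected"]).sum())
    df = len(layout.chroms) - 1
    chi2_log_p = stats.chi2.logsf(chi2, df) if df > 0 else 0.0
    return ChromDistribution(
        table=table,
        focal=focal,
        focal_observed=obs_focal,
        focal_expected=float(exp_focal),
        focal_tail=tail,
        focal_log10_p=float(log_p / math.log(10)),
        chi2_stat=chi2,
        chi2_df=df,
        chi2_log10_p=float(chi2_log_p / math.log(10)),
    )


def chromosome_distribution(
    peaks: list[Peak], layout: GenomeLayout, focal: str | None = None
) -> ChromDistribution:
    counts: dict[str, int] = {}
    for p in peaks:
        counts[p.chrom] = counts.get(p.chrom, 0) + 1
    return chromosome_distribution_from_counts(counts, layout, focal=focal)


def peak_density(peaks: list[Peak], chrom: str, start: int, end: int) -> float:
    """Peaks per kb: count of summits in [start, end) over (end-start)/1000."""
    if not start < end:
        raise ContractError("zero- or negative-length region")
    n = sum(1 for p in peaks if p.chrom == chrom and start <= p.summit < end)
    return n / ((end - start) / 1000.0)
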