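"""End-to-end orchestration: simulate -> normalize -> call peaks ->
annotate -> profile -> gene sets, with artifacts and a JSON run report.

Every stage writes plain-text artifacts (TSV/BED/bedGraph) into the output
directory; re-running with the same configuration reproduces them
byte-for-byte.  The report carries per-stage counts, the conservation
identities the stages declare (e.g. candidate peaks = final peaks + removed
peaks), recovery scores against the simulation truth, and wall-clock
timings.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import arrayio
from .annotate import (
    chromosome_distribution,
    gene_score_table,
    peaks_to_genes,
    summit_feature_counts,
)
from .expression import expression_pipeline
from .genesets import classify_high_low, evidence_fraction, overlap_enrichment
from .models import GeneModel, Peak
from .normalization import average_replicates, zscore_track
from .peakcalling import find_peaks
from .profiles import (
    exon_boundary_profile,
    find_exon_triplets,
    metagene_profile,
    quantile_bin_genes,
)
from .synth import GERMLINE_PREFIX, SimulationConfig, make_genome, simulate_chip, simulate_expression

log = logging.getLogger("tilechip")


@dataclass
class RunConfig:
    """Stage parameters for one reproducible synthetic run; defaults match
    the standard analysis settings (500/100 windows, 1e-20 cutoff, 1 kb
    flanks, 50 x 50-bp profile bins, expression quintiles, z > 1 / z < 0
    thresholds, 250-bp smoothing, 100-bp control gap)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    peak_target: str = "mes4"
    control_target: str | None = "noab"
    window: int = 500
    step: int = 100
    cutoff: float = 1e-20
    min_probes: int = 1
    max_gap: int = 100
    flank: int = 1000
    n_expression_groups: int = 5
    min_gene_len: int = 2000
    high_targets: dict[str, float] = field(
        default_factory=lambda: {"mes4": 1.0, "h3k36me3": 1.0}
    )
    low_targets: dict[str, float] = field(default_factory=lambda: {"pol2": 0.0})
    tss_convention: str = "results"

    def validate(self) -> None:
        self.simulation.validate()
        if self.peak_target not in self.simulation.targets:
            raise ValueError(f"peak target {self.peak_target!r} not simulated")
        if self.control_target and self.control_target not in self.simulation.targets:
            raise ValueError(f"control target {self.control_target!r} not simulated")
        for t in list(self.high_targets) + list(self.low_targets):
            if t not in self.simulation.targets:
                raise ValueError(f"threshold target {t!r} not simulated")
        if self.window < 1 or self.step < 1 or self.flank < 0:
            raise ValueError("window, step must be >= 1 and flank >= 0")
        if not 0 < self.cutoff <= 1:
            raise ValueError("cutoff must be in (0, 1]")


def recovery_scores(peaks: list[Peak], truth_intervals: pd.DataFrame) -> tuple[float, float]:
    """(recall, precision) of peak intervals against implanted domains.

    Recall: fraction of truth intervals overlapped by >= 1 peak.
    Precision: fraction of peaks overlapping >= 1 truth interval.
    """
    truths = [
        (row.chrom, int(row.start), int(row.end)) for row in truth_intervals.itertuples()
    ]
    if not truths:
        return float("nan"), float("nan")

    def overlaps(p: Peak, t: tuple[str, int, int]) -> bool:
        return p.chrom == t[0] and p.start < t[2] and t[1] < p.end

    recall_hits = sum(1 for t in truths if any(overlaps(p, t) for p in peaks))
    recall = recall_hits / len(truths)
    if not peaks:
        return recall, float("nan")
    precision = sum(1 for p in peaks if any(overlaps(p, t) for t in truths)) / len(peaks)
    return recall, precision


def run_pipeline(config: RunConfig, outdir: str | os.PathLike) -> dict:
    """Execute all stages, write artifacts under ``outdir``, return the run
    report (also written as ``report.json``)."""
    config.validate()
    os.makedirs(outdir, exist_ok=True)
    outdir = str(outdir)
    report: dict = {"stages": {}, "config": _config_dict(config)}
    sim = config.simulation

    def stage(name: str):
        log.info("stage %s", name)
        return _StageTimer(report, name)

    with stage("simulate"):
        layout, genes, truth = make_genome(sim)
        truth.write(os.path.join(outdir, "truth.tsv"))
        arrayio.write_genes_bed12(genes, os.path.join(outdir, "genes.bed12"))
        arrayio.write_class_labels(
            {g.gene_id: g.class_label for g in genes},
            os.path.join(outdir, "class_labels.tsv"),
        )
        replicates = {t: simulate_chip(genes, layout, sim, t) for t in sim.targets}
        expr_matrix, probe_to_gene = simulate_expression(genes, sim)
        expr_matrix.to_csv(os.path.join(outdir, "expression_matrix.tsv"), sep="\t", float_format="%.6g")
        report["stages"]["simulate"]["n_genes"] = len(genes)
        report["stages"]["simulate"]["n_probes"] = len(replicates[sim.targets[0]][0])

    with stage("normalize"):
        tracks: dict[str, pd.DataFrame] = {}
        for t, reps in replicates.items():
            z_reps = [zscore_track(r) for r in reps]
            tracks[t] = average_replicates(z_reps)
            arrayio.write_probe_table(tracks[t], os.path.join(outdir, f"z_{t}.tsv"))
            arrayio.write_bedgraph(tracks[t], os.path.join(outdir, f"z_{t}.bedgraph"))

    with stage("expression"):
        per_gene, rna_z = expression_pipeline(expr_matrix, probe_to_gene)
        arrayio.write_expression_values(
            dict(zip(rna_z.index, per_gene.mean(axis=1))),
            os.path.join(outdir, "gene_expression.tsv"),
        )
        expr_by_gene = dict(zip(per_gene.index, per_gene.mean(axis=1)))
        for g in genes:
            g.expression = float(expr_by_gene.get(g.gene_id, np.nan))

    with stage("callpeaks"):
        control_peaks: list[Peak] = []
        if config.control_target:
            control_peaks, control_info = find_peaks(
                tracks[config.control_target],
                layout=layout,
                window=config.window,
                step=config.step,
                cutoff=config.cutoff,
                min_probes=config.min_probes,
            )
            arrayio.write_peaks_bed(control_peaks, os.path.join(outdir, "control_peaks.bed"))
        peaks, info = find_peaks(
            tracks[config.peak_target],
            layout=layout,
            window=config.window,
            step=config.step,
            cutoff=config.cutoff,
            min_probes=config.min_probes,
            control_peaks=control_peaks,
            max_gap=config.max_gap,
        )
        arrayio.write_peaks_bed(peaks, os.path.join(outdir, "peaks.bed"))
        st = report["stages"]["callpeaks"]
        st.update(info)
        st["n_control_peaks"] = len(control_peaks)
        assert st["n_candidate_peaks"] - st["n_removed_by_control"] == st["n_peaks"]

    with stage("annotate"):
        annotations, bound, flank_only = peaks_to_genes(peaks, genes, flank=config.flank)
        annotations.to_csv(os.path.join(outdir, "peak_annotations.tsv"), sep="\t", index=False)
        features = summit_feature_counts(peaks, genes, flank=config.flank)
        dist = chromosome_distribution(peaks, layout, focal=sim.x_like)
        dist.table.to_csv(os.path.join(outdir, "chrom_distribution.tsv"), sep="\t", index=False, float_format="%.6g")
        st = report["stages"]["annotate"]
        st["relation_counts"] = annotations["relation"].value_counts().to_dict()
        st["summit_features"] = features.to_dict()
        st["n_bound_genes"] = len(bound)
        st["n_flank_only_genes"] = len(flank_only)
        st["focal_observed"] = dist.focal_observed
        st["focal_expected"] = dist.focal_expected
        st["focal_tail"] = dist.focal_tail
        st["focal_log10_p"] = dist.focal_log10_p
        assert sum(st["relation_counts"].values()) == len(peaks)

    with stage("profile"):
        groups = quantile_bin_genes(genes, k=config.n_expression_groups, min_len=config.min_gene_len)
        prof_frames = []
        for t in (config.peak_target, *(k for k in ("pol2",) if k in tracks and k != config.peak_target)):
            for anchor in ("TSS", "TES"):
                prof = metagene_profile(
                    tracks[t], genes, groups, anchor=anchor, convention=config.tss_convention
                )
                frame = prof.to_frame()
                frame.insert(0, "target", t)
                prof_frames.append(frame)
        pd.concat(prof_frames, ignore_index=True).to_csv(
            os.path.join(outdir, "metagene_profiles.tsv"), sep="\t", index=False, float_format="%.6g"
        )
        triplets = find_exon_triplets(genes)
        start_prof, end_prof, skipped = exon_boundary_profile(
            tracks[config.peak_target], triplets, groups, baseline_subtract=True
        )
        pd.concat([start_prof.to_frame(), end_prof.to_frame()], ignore_index=True).to_csv(
            os.path.join(outdir, "exon_boundary_profiles.tsv"), sep="\t", index=False, float_format="%.6g"
        )
        st = report["stages"]["profile"]
        st["n_grouped_genes"] = len(groups)
        st["n_triplets"] = len(triplets)
        st["n_triplets_skipped"] = skipped

    with stage("genesets"):
        scores = gene_score_table(tracks, genes, rna_z=rna_z.to_dict())
        scores.to_csv(os.path.join(outdir, "gene_scores.tsv"), sep="\t", index=False, float_format="%.6g")
        selected = classify_high_low(scores, config.high_targets, config.low_targets)
        germline = {
            g.gene_id for g in genes if g.class_label.startswith(GERMLINE_PREFIX)
        }
        universe = {g.gene_id for g in genes}
        st = report["stages"]["genesets"]
        st["n_selected"] = len(selected)
        if selected:
            frac, pct = evidence_fraction(selected, germline)
            st["evidence_fraction"] = frac
            st["evidence_percent"] = pct
        if bound and germline:
            ov = overlap_enrichment(bound & universe, germline, universe)
            st["bound_vs_germline_fold"] = ov.fold
            st["bound_vs_germline_log10_p"] = ov.log10_p
            st["bound_vs_germline_tail"] = ov.tail

    with stage("recovery"):
        recall, precision = recovery_scores(peaks, truth.enriched_intervals(config.peak_target))
        report["stages"]["recovery"]["recall"] = recall
        report["stages"]["recovery"]["precision"] = precision

    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    return report


class _StageTimer:
    def __init__(self, report: dict, name: str) -> None:
        self.report = report
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        self.report["stages"][self.name] = {}
        return self

    def __exit__(self, exc_type, exc, tb):
        self.report["stages"][self.name]["seconds"] = round(time.perf_counter() - self.t0, 3)
        if exc_type is not None:
            self.report["stages"][self.name]["failed"] = True
            log.error("stage %s failed", self.name)
        return False


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
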