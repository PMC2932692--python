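"""Sliding-window peak detection on standardized tiling-array tracks.

The caller scores 500-bp windows stepped every 100 bp against a Gaussian
background whose standard deviation is estimated from the negative values of
the track, reflected about zero (signal is assumed strictly positive, so
negative probes sample the noise).  Window means are tested with an
upper-tail normal p-value, Bonferroni-corrected by the number of evaluated
windows, and significant windows are merged into peaks.  Peaks close to
peaks called in a mock-IP (no-antibody) control are discarded.

Tail probabilities are carried in natural-log space so that extremely
significant windows remain ordered past float underflow.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .models import (
    ContractError,
    GenomeLayout,
    Peak,
    Window,
    midpoints,
    validate_track,
)


def estimate_null_sd(values: np.ndarray) -> float:
    """Background SD from negative values reflected about zero:
    sqrt(mean(v^2) over v < 0)."""
    values = np.asarray(values, dtype=float)
    neg = values[values < 0]
    if neg.size == 0:
        raise ValueError("cannot estimate background: no negative values (signal-only input)")
    return float(np.sqrt(np.mean(neg**2)))


def slide_windows(
    track: pd.DataFrame,
    layout: GenomeLayout | None = None,
    window: int = 500,
    step: int = 100,
    min_probes: int = 1,
) -> list[Window]:
    """Evaluate all windows starting at 0, step ``step``, per chromosome.

    A probe belongs to a window iff its midpoint lies in [start, start+window).
    Windows holding fewer than ``min_probes`` probes are skipped.  Window
    starts run to the chromosome end (from ``layout`` when given, else the
    last probe end), so a chromosome shorter than the window still yields its
    single truncated-coverage window.
    """
    validate_track(track)
    if min_probes < 1:
        raise ContractError("min_probes must be >= 1")
    mids_all = midpoints(track)
    values_all = track["value"].to_numpy(float)
    out: list[Window] = []
    for chrom, idx in track.groupby("chrom", sort=False).indices.items():
        idx = np.asarray(idx)
        order = np.argsort(mids_all[idx], kind="mergesort")
        mids = mids_all[idx][order]
        vals = values_all[idx][order]
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        if layout is not None:
            chrom_len = layout.lengths[str(chrom)]
        else:
            chrom_len = int(track["end"].to_numpy()[idx].max())
        starts = np.arange(0, max(chrom_len, 1), step, dtype=np.int64)
        lo = np.searchsorted(mids, starts, side="left")
        hi = np.searchsorted(mids, starts + window, side="left")
        n = hi - lo
        keep = np.flatnonzero(n >= min_probes)
        for i in keep:
            s = int(starts[i])
            out.append(
                Window(
                    chrom=str(chrom),
                    start=s,
                    end=s + window,
                    mean_z=float((csum[hi[i]] - csum[lo[i]]) / n[i]),
                    n_probes=int(n[i]),
                )
            )
    return out


def window_pvalue(
    mean_z: float, n_probes: int, null_sd: float, n_windows: int
) -> tuple[float, float, float, float]:
    """Upper-tail p of the window mean under Normal(0, null_sd/sqrt(n)),
    plus its Bonferroni adjustment; returns (raw_p, adj_p, log_raw, log_adj).

    Logs are natural logs, computed with the exact log-survival function so
    extreme tails stay meaningful.
    """
    if n_probes == 0:
        raise ContractError("window has no probes")
    if null_sd <= 0:
        raise ContractError("null_sd must be positive")
    if n_windows < 1:
        raise ContractError("n_windows must be >= 1")
    scale = null_sd / math.sqrt(n_probes)
    log_raw = float(stats.norm.logsf(mean_z, loc=0.0, scale=scale))
    log_adj = min(0.0, log_raw + math.log(n_windows))
    return math.exp(log_raw), math.exp(log_adj), log_raw, log_adj


def score_windows(
    windows: list[Window], null_sd: float, n_windows: int | None = None
) -> list[Window]:
    """Attach raw and Bonferroni-adjusted p-values to every window.

    ``n_windows`` defaults to the number of evaluated windows genome-wide.
    """
    if n_windows is None:
        n_windows = len(windows)
    for w in windows:
        w.raw_p, w.adj_p, w.log_raw_p, w.log_adj_p = window_pvalue(
            w.mean_z, w.n_probes, null_sd, n_windows
        )
    return windows


def call_peaks(
    windows: list[Window],
    track: pd.DataFrame,
    cutoff: float = 1e-20,
) -> list[Peak]:
    """Merge significant windows (adjusted p <= cutoff, boundary inclusive)
    into peaks.

    Overlapping or bookended significant windows on one chromosome merge;
    peak bounds are the union, the summit is the midpoint of the
    maximum-value probe within the peak (leftmost on ties), mean_z comes
    from the most significant merged window, and adj_p is the minimum over
    merged windows.
    """
    validate_track(track)
    log_cut = math.log(cutoff)
    sig = [w for w in windows if w.log_adj_p is not None and w.log_adj_p <= log_cut]
    sig.sort(key=lambda w: (w.chrom, w.start))
    mids_all = midpoints(track)
    vals_all = track["value"].to_numpy(float)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, idx in track.groupby("chrom", sort=False).indices.items():
        idx = np.asarray(idx)
        order = np.argsort(mids_all[idx], kind="mergesort")
        by_chrom[str(chrom)] = (mids_all[idx][order], vals_all[idx][order])

    peaks: list[Peak] = []
    group: list[Window] = []

    def flush() -> None:
        if not group:
            return
        chrom = group[0].chrom
        start = min(w.start for w in group)
        end = max(w.end for w in group)
        best = min(group, key=lambda w: (w.log_adj_p, -w.mean_z, w.start))
        mids, vals = by_chrom[chrom]
        lo = np.searchsorted(mids, start, side="left")
        hi = np.searchsorted(mids, end, side="left")
        seg = vals[lo:hi]
        if seg.size:
            summit = int(mids[lo + int(np.argmax(seg))])
        else:  # cannot happen for windows that held probes; keep a defined value
            summit = start
        peaks.append(
            Peak(
                chrom=chrom,
                start=start,
                end=end,
                summit=summit,
                mean_z=best.mean_z,
                adj_p=min(w.adj_p for w in group),
                log_adj_p=min(w.log_adj_p for w in group),
                peak_id=f"peak_{len(peaks) + 1}",
            )
        )

    for w in sig:
        if group and w.chrom == group[-1].chrom and w.start <= max(g.end for g in group):
            group.append(w)
        else:
            flush()
            group = [w]
    flush()
    return peaks


def subtract_control_peaks(
    peaks: list[Peak], control_peaks: list[Peak], max_gap: int = 100
) -> list[Peak]:
    """Drop peaks whose edge-to-edge gap to a same-chromosome control peak
    is <= max_gap (overlap counts as gap 0); survivors keep their ids."""
    controls: dict[str, list[tuple[int, int]]] = {}
    for c in control_peaks:
        controls.setdefault(c.chrom, []).append((c.start, c.end))
    kept: list[Peak] = []
    for p in peaks:
        removed = False
        for cs, ce in controls.get(p.chrom, ()):
            gap = max(cs - p.end, p.start - ce, 0)
            if gap <= max_gap:
                removed = True
                break
        if not removed:
            kept.append(p)
    return kept


def find_peaks(
    track: pd.DataFrame,
    layout: GenomeLayout | None = None,
    window: int = 500,
    step: int = 100,
    cutoff: float = 1e-20,
    min_probes: int = 1,
    control_peaks: list[Peak] | None = None,
    max_gap: int = 100,
) -> tuple[list[Peak], dict]:
    """Full chain: background estimate -> windows -> scoring -> merging ->
    optional control subtraction.  Returns (peaks, bookkeeping dict)."""
    null_sd = estimate_null_sd(track["value"].to_numpy(float))
    windows = slide_windows(track, layout=layout, window=window, step=step, min_probes=min_probes)
    score_windows(windows, null_sd)
    candidates = call_peaks(windows, track, cutoff=cutoff)
    if control_peaks:
        final = subtract_control_peaks(candidates, control_peaks, max_gap=max_gap)
    else:
        final = list(candidates)
    info = {
        "null_sd": null_sd,
        "n_windows": len(windows),
        "n_candidate_peaks": len(candidates),
        "n_removed_by_control": len(candidates) - len(final),
        "n_peaks": len(final),
    }
    return final, info
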