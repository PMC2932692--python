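"""Normalization of two-channel tiling-array signal.

Raw per-probe intensities become log2 sample/reference ratios, which are
standardized per replicate to mean zero and unit standard deviation
(z-scores) over all probes genome-wide.  Replicates are then averaged.  A
condition whose global signal is perturbed (e.g. an RNAi depletion sample)
can instead be anchored to a reference condition: an affine map is fitted so
that mean and SD over an anchor chromosome match the reference, and applied
genome-wide.

The standard deviation used throughout is the population SD (divide by n).
Pass ``ddof=1`` to :func:`zscore_standardize` for the sample convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import (
    ContractError,
    DegenerateInputError,
    midpoints,
    same_probe_set,
    validate_track,
)


def log2_ratio(sample: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Per-probe log2(sample/reference); both channels must be positive."""
    sample = np.asarray(sample, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if sample.shape != reference.shape:
        raise ContractError("channel arrays differ in shape")
    for name, arr in (("sample", sample), ("reference", reference)):
        bad = np.flatnonzero(arr <= 0)
        if bad.size:
            raise ValueError(f"non-positive {name} intensity at probe index {bad[0]}")
    return np.log2(sample / reference)


def zscore_standardize(values: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Standardize to mean 0, SD 1 (population SD by default)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ContractError("need at least 2 values to standardize")
    sd = values.std(ddof=ddof)
    if sd == 0:
        raise DegenerateInputError("zero variance: cannot standardize")
    return (values - values.mean()) / sd


def zscore_track(track: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    validate_track(track)
    out = track.copy()
    out["value"] = zscore_standardize(track["value"].to_numpy(float), ddof=ddof)
    return out


def anchored_normalize(
    track: pd.DataFrame, reference: pd.DataFrame, anchor_chrom: str
) -> pd.DataFrame:
    """Affine-map ``track`` so its anchor-chromosome mean/SD match
    ``reference`` over the same probes; the map is applied genome-wide."""
    validate_track(track)
    validate_track(reference, "reference")
    if not same_probe_set(track, reference):
        raise ContractError("track and reference must share the probe set")
    on_anchor = track["chrom"].to_numpy(str) == anchor_chrom
    if on_anchor.sum() < 2:
        raise ContractError(f"anchor chromosome {anchor_chrom!r} has fewer than 2 probes")
    v = track["value"].to_numpy(float)
    r = reference["value"].to_numpy(float)
    v_mu, v_sd = v[on_anchor].mean(), v[on_anchor].std()
    r_mu, r_sd = r[on_anchor].mean(), r[on_anchor].std()
    if v_sd == 0:
        raise DegenerateInputError(f"zero dispersion on anchor chromosome {anchor_chrom!r}")
    a = r_sd / v_sd
    b = r_mu - a * v_mu
    out = track.copy()
    out["value"] = a * v + b
    return out


def smooth_median(track: pd.DataFrame, span: int = 250) -> pd.DataFrame:
    """Windowed median: each probe's value becomes the median over probes of
    the same chromosome whose midpoints lie within +-span/2 (closed ends)."""
    validate_track(track)
    out = track.copy()
    values = track["value"].to_numpy(float)
    mids = midpoints(track)
    smoothed = np.empty_like(values)
    half = span / 2.0
    for _, idx in track.groupby("chrom", sort=False).indices.items():
        idx = np.asarray(idx)
        m = mids[idx]
        order = np.argsort(m, kind="mergesort")
        m_sorted = m[order]
        v_sorted = values[idx][order]
        lo = np.searchsorted(m_sorted, m_sorted - half, side="left")
        hi = np.searchsorted(m_sorted, m_sorted + half, side="right")
        sm = np.array([np.median(v_sorted[a:b]) for a, b in zip(lo, hi)])
        smoothed[idx[order]] = sm
    out["value"] = smoothed
    return out


def average_replicates(tracks: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-probe arithmetic mean across replicate tracks on one probe set."""
    if not tracks:
        raise ContractError("need at least one replicate")
    first = tracks[0]
    validate_track(first)
    for t in tracks[1:]:
        validate_track(t)
        if not same_probe_set(first, t):
            raise ContractError("replicates must share the probe set")
    out = first.copy()
    out["value"] = np.mean([t["value"].to_numpy(float) for t in tracks], axis=0)
    return out


def pairwise_correlation(
    tracks: list[pd.DataFrame],
    labels: list[str] | None = None,
    span: int = 250,
) -> pd.DataFrame:
    """Genome-wide Pearson correlation matrix between tracks, computed on
    all probes after windowed-median smoothing over ``span`` bp."""
    if len(tracks) < 2:
        raise ContractError("need at least 2 tracks")
    first = tracks[0]
    for t in tracks[1:]:
        if not same_probe_set(first, t):
            raise ContractError("tracks must share the probe set")
    if labels is None:
        labels = [f"track{i}" for i in range(len(tracks))]
    smoothed = np.vstack(
        [smooth_median(t, span=span)["value"].to_numpy(float) for t in tracks]
    )
    sds = smoothed.std(axis=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        raise DegenerateInputError(
            f"correlation undefined: track {labels[zero[0]]!r} has zero variance after smoothing"
        )
    mat = np.corrcoef(smoothed)
    return pd.DataFrame(mat, index=labels, columns=labels)
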