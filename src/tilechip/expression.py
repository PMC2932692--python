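"""Summarizing multi-probe, multi-sample expression arrays.

The chain is: quantile normalization across samples (so all samples share
one marginal distribution), median-polish summarization of each gene's
probes x samples submatrix under the additive model
``value ~ gene + sample + probe``, averaging across samples, and z-scoring
across genes.  Values are assumed to be on the log2 scale already.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .models import ContractError
from .normalization import zscore_standardize


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force all columns to share the cross-column mean marginal
    distribution, preserving within-column order; ties take the average of
    the tied order-statistic means."""
    X = matrix.to_numpy(float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ContractError("need a 2-D matrix with >= 2 samples")
    if np.isnan(X).any():
        raise ContractError("missing values not supported")
    n = X.shape[0]
    mean_sorted = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(X.shape[1]):
        ranks = rankdata(X[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, mean_sorted)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def median_polish(
    X: np.ndarray, max_iter: int = 10, tol: float = 1e-6
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey median polish of a rows x cols matrix.

    Returns (overall, row_effects, col_effects, residuals).  Iteration
    starts with a row sweep and stops when the largest sweep update falls
    below ``tol`` or after ``max_iter`` iterations.
    """
    X = np.asarray(X, dtype=float)
    resid = X.copy()
    overall = 0.0
    row = np.zeros(X.shape[0])
    col = np.zeros(X.shape[1])
    for _ in range(max_iter):
        rdelta = np.median(resid, axis=1)
        resid -= rdelta[:, None]
        row += rdelta
        delta = np.median(col)
        col -= delta
        overall += delta
        cdelta = np.median(resid, axis=0)
        resid -= cdelta[None, :]
        col += cdelta
        delta = np.median(row)
        row -= delta
        overall += delta
        if max(np.abs(rdelta).max(initial=0.0), np.abs(cdelta).max(initial=0.0)) < tol:
            break
    return overall, row, col, resid


def summarize_genes(matrix: pd.DataFrame, probe_to_gene: dict[str, str]) -> pd.DataFrame:
    """One expression value per gene and sample via median polish.

    ``matrix`` has probes as rows (index = probe id) and samples as
    columns; each probe must map to exactly one gene.  The returned frame
    has genes as rows and the gene + sample effects as values (the probe
    effect is removed).
    """
    unknown = [p for p in matrix.index if p not in probe_to_gene]
    if unknown:
        raise ContractError(f"probe {unknown[0]!r} has no gene assignment")
    genes = sorted(set(probe_to_gene[p] for p in matrix.index))
    rows = []
    for gene in genes:
        probes = [p for p in matrix.index if probe_to_gene[p] == gene]
        sub = matrix.loc[probes].to_numpy(float)
        overall, _row, col, _resid = median_polish(sub)
        rows.append(overall + col)
    return pd.DataFrame(rows, index=genes, columns=matrix.columns)


def average_and_zscore(gene_values: pd.DataFrame) -> pd.Series:
    """Average each gene across samples, then z-score across genes
    (population SD)."""
    if gene_values.shape[1] < 1:
        raise ContractError("need at least one sample")
    means = gene_values.mean(axis=1).to_numpy(float)
    return pd.Series(zscore_standardize(means), index=gene_values.index, name="rna_z")


def expression_pipeline(
    matrix: pd.DataFrame, probe_to_gene: dict[str, str]
) -> tuple[pd.DataFrame, pd.Series]:
    """quantile normalize -> median-polish summarize -> average + z-score.

    Returns (per-gene per-sample values, per-gene RNA z-scores).
    """
    normed = quantile_normalize(matrix)
    per_gene = summarize_genes(normed, probe_to_gene)
    return per_gene, average_and_zscore(per_gene)
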