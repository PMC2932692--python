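"""Gene-class summaries and gene-set statistics on a gene score table.

The gene score table (one row per gene, one column of mean z per ChIP
target plus an RNA z column) is the substrate for boxplot-style class
summaries, threshold classification (e.g. high MES-4 and H3K36me3, low
Pol II), and hypergeometric set-overlap enrichment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import ContractError


@dataclass
class BoxplotSummary:
    """Five percentiles (2.5/25/50/75/97.5), n, and the 95% median CI
    half-width from the standard notch formula 1.57*IQR/sqrt(n)."""

    group: str
    p2_5: float
    p25: float
    p50: float
    p75: float
    p97_5: float
    n: int
    n_missing: int
    median_ci_halfwidth: float


def class_summary(
    table: pd.DataFrame, target: str, classes: dict[str, list[str]]
) -> dict[str, BoxplotSummary]:
    """Boxplot summaries of ``target`` scores for each named gene class.

    ``classes`` maps class label -> gene ids.  Missing scores are excluded
    (counted in ``n_missing``); percentiles use linear interpolation.
    """
    if target not in table.columns:
        raise ContractError(f"unknown target column {target!r}")
    scores = table.set_index("gene_id")[target]
    out: dict[str, BoxplotSummary] = {}
    for label, gene_ids in classes.items():
        if not gene_ids:
            raise ContractError(f"class {label!r} is empty")
        vals = scores.reindex(gene_ids).to_numpy(float)
        missing = int(np.isnan(vals).sum())
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ContractError(f"class {label!r} has no scored genes")
        p = np.percentile(vals, [2.5, 25, 50, 75, 97.5])
        iqr = p[3] - p[1]
        out[label] = BoxplotSummary(
            group=label,
            p2_5=float(p[0]),
            p25=float(p[1]),
            p50=float(p[2]),
            p75=float(p[3]),
            p97_5=float(p[4]),
            n=int(vals.size),
            n_missing=missing,
            median_ci_halfwidth=float(1.57 * iqr / math.sqrt(vals.size)),
        )
    return out


def classify_high_low(
    table: pd.DataFrame,
    high_targets: dict[str, float],
    low_targets: dict[str, float],
) -> set[str]:
    """Genes whose score is strictly above threshold for every high target
    and strictly below for every low target; genes missing any required
    score are excluded."""
    for t in list(high_targets) + list(low_targets):
        if t not in table.columns:
            raise ContractError(f"unknown target column {t!r}")
    mask = pd.Series(True, index=table.index)
    for t, thr in high_targets.items():
        col = table[t].astype(float)
        mask &= col.notna() & (col > thr)
    for t, thr in low_targets.items():
        col = table[t].astype(float)
        mask &= col.notna() & (col < thr)
    return set(table.loc[mask, "gene_id"])


@dataclass
class OverlapResult:
    observed: int
    expected: float
    fold: float
    tail: str  # "enrichment" or "depletion"
    log10_p: float

    @property
    def p(self) -> float:
        return 10.0**self.log10_p


def overlap_enrichment(set_a: set[str], set_b: set[str], universe: set[str]) -> OverlapResult:
    """Fold enrichment of |A ∩ B| over |A||B|/|U| with an exact
    hypergeometric tail (upper for enrichment, lower for depletion),
    computed in log space."""
    if not universe:
        raise ContractError("empty universe")
    if not set_a <= universe or not set_b <= universe:
        raise ContractError("sets must be subsets of the universe")
    M, K, n = len(universe), len(set_a), len(set_b)
    obs = len(set_a & set_b)
    expected = K * n / M
    fold = obs / expected if expected > 0 else float("nan")
    if obs >= expected:
        tail = "enrichment"
        log_p = stats.hypergeom.logsf(obs - 1, M, K, n)
    else:
        tail = "depletion"
        log_p = stats.hypergeom.logcdf(obs, M, K, n)
    return OverlapResult(
        observed=obs,
        expected=expected,
        fold=fold,
        tail=tail,
        log10_p=float(log_p / math.log(10)),
    )


def evidence_fraction(gene_set: set[str], evidence: set[str]) -> tuple[float, int]:
    """Fraction of the set carrying an evidence label, with the rounded
    percentage; returns (exact fraction, rounded percent)."""
    if not gene_set:
        raise ContractError("empty gene set")
    frac = len(gene_set & evidence) / len(gene_set)
    return frac, int(round(100 * frac))
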