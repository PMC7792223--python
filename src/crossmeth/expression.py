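"""Simplified negative-binomial time-effect testing on pooled RNA counts.

This is a deliberately small, deterministic stand-in for a full RNA-seq
differential-expression fit: median-of-ratios size factors, a gene-wise
method-of-moments NB dispersion, and a likelihood-ratio test of a
time-point factor against an intercept-only mean model (2 df).  The
integration stage accepts an externally produced DE table with the same
columns, so this module is replaceable without touching downstream code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from .multitest import adjust_bh
from .types import ContrastSpec, SampleMeta, ValidationError

log = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8
PSEUDOCOUNT = 0.5


@dataclass
class ExpressionCountMatrix:
    """Genes x pools matrix of raw RNA counts for one tissue."""

    genes: list
    pools: list  # SampleMeta with pool_id set
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.genes), len(self.pools)):
            raise ValidationError("count matrix shape mismatch")
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def tissue(self) -> Optional[str]:
        return self.pools[0].tissue if self.pools else None

    def time_points(self) -> np.ndarray:
        return np.array([p.time_point for p in self.pools])


@dataclass
class DEGeneRecord:
    gene_id: str
    tissue: str
    p_time: float
    q_time: float = float("nan")
    p_line: Optional[float] = None
    log2fc_12: float = float("nan")
    log2fc_23: float = float("nan")
    passes_filter: bool = False


def normalize_size_factors(counts: ExpressionCountMatrix) -> np.ndarray:
    """Median-of-ratios size factors against the geometric-mean pseudo-
    reference, re-centred so the factors' geometric mean is 1."""
    mat = counts.counts.astype(float)
    if (mat.sum(axis=0) == 0).any():
        raise ValidationError("a pool has all-zero counts")
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValidationError("no gene has nonzero counts in every pool")
    logs = np.log(mat[positive])
    log_ref = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_ref, axis=0))
    return factors / np.exp(np.mean(np.log(factors)))


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood (variance mu + alpha*mu^2)."""
    r = 1.0 / alpha
    mu = np.maximum(mu, 1e-12)
    return float(
        np.sum(
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1.0)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def _fit_group_mean(y: np.ndarray, s: np.ndarray, alpha: float) -> float:
    """MLE of the common expression level m with per-pool offsets s_j
    (mu_j = s_j * m) under NB2 with known dispersion."""

    def score(m: float) -> float:
        mu = s * m
        return float(np.sum(y / m - s * (1.0 + alpha * y) / (1.0 + alpha * mu)))

    m0 = y.sum() / s.sum()
    if m0 <= 0:
        return 0.0
    lo, hi = m0 * 1e-3, m0 * 1e3
    try:
        if score(lo) * score(hi) > 0:
            return m0
        return float(optimize.brentq(score, lo, hi, xtol=1e-10 * m0))
    except ValueError:
        return m0


def estimate_dispersion(normalized: np.ndarray, times: np.ndarray) -> float:
    """Method-of-moments dispersion from within-time-group residual
    moments of normalized counts, floored at ``DISPERSION_FLOOR``."""
    group_vars = []
    for t in np.unique(times):
        grp = normalized[times == t]
        if grp.size >= 2:
            group_vars.append(grp.var(ddof=1))
    mean = normalized.mean()
    if not group_vars or mean <= 0:
        return DISPERSION_FLOOR
    var = float(np.mean(group_vars))
    return max((var - mean) / mean**2, DISPERSION_FLOOR)


def test_time_effect_nb(
    counts: ExpressionCountMatrix, size_factors: np.ndarray
) -> list:
    """Per-gene NB LRT of a time-point factor mean model vs intercept-only.

    Genes with all-zero counts are skipped with a warning.  ``q_time`` is
    BH-adjusted over all tested genes; fold changes for both pairwise
    contrasts are attached to each record.
    """
    times = counts.time_points()
    if len(np.unique(times)) != 3:
        raise ValidationError("time-effect test requires all three time points")
    for t in np.unique(times):
        if (times == t).sum() < 2:
            raise ValidationError(f"time point {t} has fewer than 2 pools")

    s = np.asarray(size_factors, dtype=float)
    records = []
    pvals = []
    lfc12 = log2fc_contrast(counts, s, ContrastSpec.delta12())
    lfc23 = log2fc_contrast(counts, s, ContrastSpec.delta23())
    for g, gene in enumerate(counts.genes):
        y = counts.counts[g].astype(float)
        if y.sum() == 0:
            log.warning("gene %s skipped (all-zero counts)", gene)
            continue
        norm = y / s
        alpha = estimate_dispersion(norm, times)
        ll_full = 0.0
        for t in np.unique(times):
            mask = times == t
            m = _fit_group_mean(y[mask], s[mask], alpha)
            ll_full += _nb_loglik(y[mask], s[mask] * m, alpha)
        m0 = _fit_group_mean(y, s, alpha)
        ll_null = _nb_loglik(y, s * m0, alpha)
        lrt = max(2.0 * (ll_full - ll_null), 0.0)
        p = float(stats.chi2.sf(lrt, df=2))
        records.append(
            DEGeneRecord(
                gene_id=gene,
                tissue=counts.tissue,
                p_time=p,
                log2fc_12=float(lfc12[g]),
                log2fc_23=float(lfc23[g]),
            )
        )
        pvals.append(p)
    if records:
        qvals = adjust_bh(np.array(pvals))
        for rec, q in zip(records, qvals):
            rec.q_time = float(q)
    return records


def log2fc_contrast(
    counts: ExpressionCountMatrix, size_factors: np.ndarray, contrast: ContrastSpec
) -> np.ndarray:
    """log2((mean normalized count at time_b + 0.5) / (mean at time_a + 0.5));
    positive values mean higher expression at the later time."""
    if not contrast.is_pairwise:
        raise ValidationError("log2fc requires a pairwise contrast")
    times = counts.time_points()
    norm = counts.counts / np.asarray(size_factors, dtype=float)
    mean_a = norm[:, times == contrast.time_a].mean(axis=1)
    mean_b = norm[:, times == contrast.time_b].mean(axis=1)
    return np.log2((mean_b + PSEUDOCOUNT) / (mean_a + PSEUDOCOUNT))


def filter_time_responsive_genes(
    records: Sequence[DEGeneRecord],
    line_p: Optional[dict] = None,
    q_threshold: float = 0.05,
    line_threshold: float = 0.05,
) -> list:
    """Select genes with a time effect (q_time < 0.05) and, when a
    selection-line p-value is supplied, no line effect (adjusted > 0.05)."""
    adj_line: dict[str, float] = {}
    if line_p:
        genes = list(line_p)
        adjusted = adjust_bh(np.array([line_p[g] for g in genes]))
        adj_line = dict(zip(genes, adjusted))
    out = []
    for rec in records:
        ok = rec.q_time < q_threshold
        if ok and adj_line:
            lp = adj_line.get(rec.gene_id)
            rec.p_line = lp
            ok = lp is None or lp > line_threshold
        rec.passes_filter = bool(ok)
        if rec.passes_filter:
            out.append(rec)
    return out


def de_to_frame(records: Sequence[DEGeneRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "tissue": [r.tissue for r in records],
            "p_time": [r.p_time for r in records],
            "q_time": [r.q_time for r in records],
            "log2fc_12": [r.log2fc_12 for r in records],
            "log2fc_23": [r.log2fc_23 for r in records],
            "passes_filter": [r.passes_filter for r in records],
        }
    )


def de_from_frame(frame: pd.DataFrame, tissue: str) -> list:
    """Build DE records from an externally produced table (gene_id, p_time,
    q_time, log2fc_12, log2fc_23)."""
    records = []
    for _, row in frame.iterrows():
        records.append(
            DEGeneRecord(
                gene_id=str(row["gene_id"]),
                tissue=tissue,
                p_time=float(row["p_time"]),
                q_time=float(row["q_time"]),
                log2fc_12=float(row["log2fc_12"]),
                log2fc_23=float(row["log2fc_23"]),
            )
        )
    return records
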