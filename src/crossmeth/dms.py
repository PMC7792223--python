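"""Per-site differential methylation testing.

Two test families are provided, both binomial likelihood-ratio tests on the
raw read counts:

* pairwise contrast — two time-point groups, closed-form pooled-proportion
  MLEs, 1 df, with an optional (default-on) quasi-binomial scale
  correction for replicate overdispersion; a site is a DMS when the pooled
  methylation difference is at least ``diff_threshold`` percentage points
  *and* the BH-adjusted p-value is at most ``q_threshold`` (defaults 15 pp
  and 0.01);
* omnibus time effect — logit-link binomial regression fitted by IRLS,
  comparing intercept + time-point factor + temperature against intercept +
  temperature (2 df); significance at q <= 0.01.

Sites called in both tissues are tissue-general, in exactly one
tissue-specific.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, xlogy

from .multitest import adjust_bh
from .types import ContrastSpec, GenomicSite, MethylationCountTable, ValidationError

log = logging.getLogger(__name__)


@dataclass
class DMSRecord:
    """One site's differential methylation test result."""

    site: GenomicSite
    tissue: str
    contrast: ContrastSpec
    meth_diff: float  # percentage points, later minus earlier
    lrt_stat: float
    df: int
    p: float
    q: float = float("nan")
    is_dms: bool = False
    converged: bool = True


@dataclass(frozen=True)
class TissueClassRecord:
    site: GenomicSite
    contrast: ContrastSpec
    klass: str  # general | rbc_specific | liver_specific


def _binomial_loglik(meth: np.ndarray, cov: np.ndarray, p) -> np.ndarray:
    """Binomial log-likelihood without the combinatorial constant (cancels
    in every ratio formed here)."""
    return xlogy(meth, p) + xlogy(cov - meth, 1.0 - p)


def test_pairwise_contrast(
    table: MethylationCountTable,
    contrast: ContrastSpec,
    diff_threshold: float = 15.0,
    q_threshold: float = 0.01,
    overdispersion_correction: bool = True,
) -> list:
    """Two-group binomial LRT per site between the contrast's time points.

    Group proportions are coverage-pooled (sum methylated / sum coverage).
    Sites with zero total coverage in either group are skipped with a
    warning.  q-values (BH) are computed over all tested sites of the run.

    Biological replicates are usually overdispersed relative to the
    binomial, which makes the plain likelihood ratio anti-conservative; by
    default the statistic is therefore scaled by a per-site quasi-binomial
    dispersion factor estimated from Pearson residuals of per-sample
    counts around the group proportions (floored at 1).  Pass
    ``overdispersion_correction=False`` for the plain test (the default of
    methylKit-style callers).
    """
    if not contrast.is_pairwise:
        raise ValidationError("test_pairwise_contrast requires a pairwise contrast")
    times = table.time_points()
    in_a = times == contrast.time_a
    in_b = times == contrast.time_b
    if not in_a.any() or not in_b.any():
        raise ValidationError(
            f"contrast {contrast.label}: both time points need at least one sample"
        )

    meth_a = table.methylated[:, in_a].sum(axis=1)
    cov_a = table.coverage[:, in_a].sum(axis=1)
    meth_b = table.methylated[:, in_b].sum(axis=1)
    cov_b = table.coverage[:, in_b].sum(axis=1)

    testable = (cov_a > 0) & (cov_b > 0)
    n_skipped = int((~testable).sum())
    if n_skipped:
        log.warning("%d sites skipped (zero coverage in a group)", n_skipped)

    with np.errstate(divide="ignore", invalid="ignore"):
        p_a = np.where(cov_a > 0, meth_a / np.maximum(cov_a, 1), np.nan)
        p_b = np.where(cov_b > 0, meth_b / np.maximum(cov_b, 1), np.nan)
        p_0 = (meth_a + meth_b) / np.maximum(cov_a + cov_b, 1)

    ll_alt = _binomial_loglik(meth_a, cov_a, p_a) + _binomial_loglik(meth_b, cov_b, p_b)
    ll_null = _binomial_loglik(meth_a, cov_a, p_0) + _binomial_loglik(meth_b, cov_b, p_0)
    lrt = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    if overdispersion_correction:
        phi = _pairwise_dispersion(table, in_a, in_b, p_a, p_b)
        lrt = lrt / phi
    pvals = stats.chi2.sf(lrt, df=1)
    diff_pp = 100.0 * (p_b - p_a)

    idx = np.nonzero(testable)[0]
    qvals = adjust_bh(pvals[idx])
    records = []
    for k, i in enumerate(idx):
        q = float(qvals[k])
        records.append(
            DMSRecord(
                site=table.sites[i],
                tissue=table.tissue,
                contrast=contrast,
                meth_diff=float(diff_pp[i]),
                lrt_stat=float(lrt[i]),
                df=1,
                p=float(pvals[i]),
                q=q,
                is_dms=bool(abs(diff_pp[i]) >= diff_threshold and q <= q_threshold),
            )
        )
    return records


def _pairwise_dispersion(
    table: MethylationCountTable,
    in_a: np.ndarray,
    in_b: np.ndarray,
    p_a: np.ndarray,
    p_b: np.ndarray,
) -> np.ndarray:
    """Per-site quasi-binomial scale factor: Pearson chi-square of
    per-sample counts around their group's pooled proportion, divided by
    its residual degrees of freedom, floored at 1."""
    phi_num = np.zeros(table.n_sites)
    n_used = np.zeros(table.n_sites)
    for mask, p_g in ((in_a, p_a), (in_b, p_b)):
        cov = table.coverage[:, mask].astype(float)
        meth = table.methylated[:, mask].astype(float)
        mu = cov * p_g[:, None]
        var = np.maximum(cov * (p_g * (1.0 - p_g))[:, None], 1e-12)
        resid2 = np.where(cov > 0, (meth - mu) ** 2 / var, 0.0)
        phi_num += resid2.sum(axis=1)
        n_used += (cov > 0).sum(axis=1)
    df_resid = np.maximum(n_used - 2, 1)
    return np.maximum(phi_num / df_resid, 1.0)


def _irls_binomial(
    X: np.ndarray,
    meth: np.ndarray,
    cov: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
    eta_bound: float = 30.0,
) -> tuple[float, bool]:
    """Fit a logit-link binomial regression by IRLS; return (loglik, converged).

    Deviance-increase steps are halved; the linear predictor is clipped to
    +-``eta_bound`` so complete separation yields a finite fit.
    """
    n, p = X.shape
    beta = np.zeros(p)
    # initialize intercept at the pooled logit
    pooled = (meth.sum() + 0.5) / (cov.sum() + 1.0)
    beta[0] = np.log(pooled / (1.0 - pooled))

    def loglik(b: np.ndarray) -> float:
        eta = np.clip(X @ b, -eta_bound, eta_bound)
        mu = expit(eta)
        return float(np.sum(_binomial_loglik(meth, cov, mu)))

    ll = loglik(beta)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -eta_bound, eta_bound)
        mu = expit(eta)
        w = cov * mu * (1.0 - mu)
        w = np.maximum(w, 1e-10)
        z = eta + (meth - cov * mu) / w
        XtW = X.T * w
        try:
            delta = np.linalg.solve(XtW @ X + 1e-10 * np.eye(p), XtW @ z) - beta
        except np.linalg.LinAlgError:
            break
        step = 1.0
        new_ll = loglik(beta + delta)
        while new_ll < ll - 1e-12 and step > 1e-4:
            step *= 0.5
            new_ll = loglik(beta + step * delta)
        beta = beta + step * delta
        if abs(new_ll - ll) < tol * (abs(ll) + 1.0):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    return ll, converged


def test_time_omnibus(
    table: MethylationCountTable,
    q_threshold: float = 0.01,
    include_temperature: bool = True,
) -> list:
    """Per-site model comparison: does a time-point factor improve on a
    temperature-only model?  LRT with 2 df; q over all tested sites."""
    times = table.time_points()
    if set(times) != {1, 2, 3}:
        raise ValidationError("omnibus test requires samples at all three time points")
    temp = np.array([s.temperature_env == "warm" for s in table.samples], dtype=float)

    cols = [np.ones(table.n_samples)]
    if include_temperature:
        cols.append(temp)
    X_null = np.column_stack(cols)
    X_full = np.column_stack(cols + [(times == 2).astype(float), (times == 3).astype(float)])

    # later-vs-earlier summary difference (pp) across the full time course
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled = lambda mask: (  # noqa: E731 - local closure keeps the loop flat
            table.methylated[:, mask].sum(axis=1)
            / np.maximum(table.coverage[:, mask].sum(axis=1), 1)
        )
    diff_pp = 100.0 * (pooled(times == 3) - pooled(times == 1))

    records = []
    pvals = []
    for i in range(table.n_sites):
        cov = table.coverage[i]
        meth = table.methylated[i]
        used = cov > 0
        if not used.any():
            log.warning("site %s skipped (no coverage)", table.sites[i])
            continue
        ll_null, conv_null = _irls_binomial(X_null[used], meth[used], cov[used])
        ll_full, conv_full = _irls_binomial(X_full[used], meth[used], cov[used])
        lrt = max(2.0 * (ll_full - ll_null), 0.0)
        p = float(stats.chi2.sf(lrt, df=2))
        records.append(
            DMSRecord(
                site=table.sites[i],
                tissue=table.tissue,
                contrast=ContrastSpec.omnibus(),
                meth_diff=float(diff_pp[i]),
                lrt_stat=float(lrt),
                df=2,
                p=p,
                converged=conv_null and conv_full,
            )
        )
        pvals.append(p)
    if records:
        qvals = adjust_bh(np.array(pvals))
        for rec, q in zip(records, qvals):
            rec.q = float(q)
            rec.is_dms = bool(q <= q_threshold)
    return records


def classify_tissue_generality(
    rbc: Sequence[DMSRecord], liver: Sequence[DMSRecord], contrast: ContrastSpec
) -> list:
    """Classify shared sites as tissue-general (DMS in both) or
    rbc-/liver-specific (DMS in exactly one); non-DMS sites are omitted."""
    for rec in list(rbc) + list(liver):
        if rec.contrast != contrast:
            raise ValidationError("record contrast does not match the requested contrast")
    rbc_by_site = {r.site: r for r in rbc}
    liver_by_site = {r.site: r for r in liver}
    out = []
    for site in rbc_by_site.keys() & liver_by_site.keys():
        in_rbc = rbc_by_site[site].is_dms
        in_liver = liver_by_site[site].is_dms
        if in_rbc and in_liver:
            klass = "general"
        elif in_rbc:
            klass = "rbc_specific"
        elif in_liver:
            klass = "liver_specific"
        else:
            continue
        out.append(TissueClassRecord(site=site, contrast=contrast, klass=klass))
    out.sort(key=lambda r: r.site)
    return out


def dms_to_frame(records: Sequence[DMSRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.site.chrom for r in records],
            "pos": [r.site.pos for r in records],
            "strand": [r.site.strand for r in records],
            "tissue": [r.tissue for r in records],
            "contrast": [r.contrast.label for r in records],
            "meth_diff": [r.meth_diff for r in records],
            "lrt": [r.lrt_stat for r in records],
            "df": [r.df for r in records],
            "p": [r.p for r in records],
            "q": [r.q for r in records],
            "is_dms": [r.is_dms for r in records],
        }
    )


def classification_to_frame(records: Sequence[TissueClassRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.site.chrom for r in records],
            "pos": [r.site.pos for r in records],
            "strand": [r.site.strand for r in records],
            "contrast": [r.contrast.label for r in records],
            "class": [r.klass for r in records],
        }
    )
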