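"""Cross-tissue concordance of temporal methylation change.

Samples of a tissue differ in mean and spread of methylation (see
:mod:`crossmeth.qc`), so raw proportion differences between time points are
not comparable across tissues.  Each retained site is therefore
standardized to z-scores across the tissue's samples, the per-site change
between two time points is the difference of time-point means of z, and
concordance between tissues is the Pearson correlation of these changes
over a chosen site set (all DMS, promoter DMS, or TSS DMS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .types import (
    ContrastSpec,
    GenomicSite,
    MethylationProportionMatrix,
    ValidationError,
)

log = logging.getLogger(__name__)


@dataclass
class ZScoreMatrix:
    sites: list
    samples: list
    z: np.ndarray

    @property
    def tissue(self) -> Optional[str]:
        return self.samples[0].tissue if self.samples else None

    def time_points(self) -> np.ndarray:
        return np.array([s.time_point for s in self.samples])


@dataclass
class ChangeVector:
    tissue: str
    contrast: ContrastSpec
    sites: list
    change: np.ndarray

    def as_dict(self) -> dict:
        return dict(zip(self.sites, self.change))


@dataclass
class ConcordanceResult:
    contrast: ContrastSpec
    scope: str  # all_dms | promoter | TSS
    n: int
    r: float
    df: int
    p: float


def zscore_standardize(
    props: MethylationProportionMatrix, mode: str = "site"
) -> ZScoreMatrix:
    """Standardize methylation proportions to z-scores.

    ``mode='site'`` (default): per site, subtract the mean over the
    tissue's samples and divide by the sample (n-1) standard deviation;
    zero-variance sites are dropped with a warning.  ``'sample'`` and
    ``'grand'`` standardize per sample column or by the grand mean/SD and
    are provided for sensitivity analyses.
    """
    if props.n_samples < 3:
        raise ValidationError("standardization needs at least 3 samples")
    values = props.values
    if not np.isfinite(values).all():
        raise ValidationError("standardization requires complete proportions")

    if mode == "site":
        mean = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, ddof=1, keepdims=True)
        keep = sd[:, 0] > 0
        if not keep.any():
            log.warning("all sites have zero standard deviation; empty z-matrix")
        dropped = int((~keep).sum())
        if dropped:
            log.warning("dropped %d zero-variance sites before standardization", dropped)
        z = (values[keep] - mean[keep]) / sd[keep]
        sites = [s for s, k in zip(props.sites, keep) if k]
    elif mode == "sample":
        mean = values.mean(axis=0, keepdims=True)
        sd = values.std(axis=0, ddof=1, keepdims=True)
        z = (values - mean) / sd
        sites = list(props.sites)
    elif mode == "grand":
        z = (values - values.mean()) / values.std(ddof=1)
        sites = list(props.sites)
    else:
        raise ValidationError(f"unknown standardization mode {mode!r}")
    return ZScoreMatrix(sites=sites, samples=list(props.samples), z=z)


def change_between_timepoints(z: ZScoreMatrix, contrast: ContrastSpec) -> ChangeVector:
    """Per-site mean z at the later time minus mean z at the earlier time."""
    if not contrast.is_pairwise:
        raise ValidationError("change requires a pairwise contrast")
    times = z.time_points()
    in_a = times == contrast.time_a
    in_b = times == contrast.time_b
    if not in_a.any() or not in_b.any():
        raise ValidationError(f"contrast {contrast.label}: a time point has no samples")
    change = z.z[:, in_b].mean(axis=1) - z.z[:, in_a].mean(axis=1)
    return ChangeVector(tissue=z.tissue, contrast=contrast, sites=list(z.sites), change=change)


def correlate_tissue_changes(
    a: ChangeVector,
    b: ChangeVector,
    site_subset: Optional[Sequence[GenomicSite]] = None,
    scope: str = "all_dms",
) -> ConcordanceResult:
    """Pearson correlation of per-site changes between two tissues.

    ``site_subset`` is normally the sites called DMS in at least one tissue
    for the contrast, optionally restricted to a region category.
    """
    if a.contrast != b.contrast:
        raise ValidationError("change vectors must share a contrast")
    map_a = a.as_dict()
    map_b = b.as_dict()
    if site_subset is None:
        shared = [s for s in a.sites if s in map_b]
    else:
        shared = [s for s in site_subset if s in map_a and s in map_b]
    n = len(shared)
    if n < 3:
        raise ValidationError(f"correlation needs at least 3 paired sites, got {n}")
    x = np.array([map_a[s] for s in shared])
    y = np.array([map_b[s] for s in shared])
    r, p = stats.pearsonr(x, y)
    return ConcordanceResult(contrast=a.contrast, scope=scope, n=n, r=float(r), df=n - 2, p=float(p))
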