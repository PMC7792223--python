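"""Linking temporal methylation change to expression change.

Two analyses live here:

* Candidate genes — per (gene, CpG site) Pearson correlation between the
  per-female *average pairwise change* in methylation and in expression.
  The averaging scheme handles the cross-sectional design (different
  females at each time point): every later-time female is compared with
  every earlier-time female, and each female keeps the mean of her
  pairwise later-minus-earlier differences.
* Genome-wide quadrants — each (significant CpG, significant gene, region
  membership) pair is placed by the signs of (delta methylation, log2 fold
  change) into Q1 (hypo/up), Q2 (hyper/up), Q3 (hyper/down), Q4
  (hypo/down) after trimming small changes, and TSS-region associations
  are tested for enrichment of the concordant quadrants Q1 or Q3 against
  the 10 kb downstream control region with a Fisher exact test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dms import DMSRecord
from .expression import DEGeneRecord
from .multitest import adjust_bh
from .regions import RegionAssignment
from .types import (
    ContrastSpec,
    GenomicSite,
    MethylationProportionMatrix,
    ValidationError,
)

log = logging.getLogger(__name__)

QUADRANTS = ("Q1", "Q2", "Q3", "Q4")
CONCORDANT = ("Q1", "Q3")  # expected negative methylation-expression relation
TISSUE_PAIRS = ("liver-liver", "RBC-liver", "RBC-ovary", "RBC-hypothalamus")


@dataclass
class PairwiseChangeVector:
    """Per-female average later-minus-earlier change, earlier-time females
    first, then later-time females."""

    contrast: ContrastSpec
    female_ids: list
    change: np.ndarray


@dataclass
class CandidateGeneResult:
    gene_id: str
    site: GenomicSite
    region: str
    contrast: ContrastSpec
    r: float
    p: float
    p_adj: float = float("nan")
    undefined: bool = False


@dataclass(frozen=True)
class QuadrantAssociation:
    site: GenomicSite
    gene_id: str
    region: str
    tissue_pair: str
    contrast_label: str
    delta_meth: float  # percentage points
    log2fc: float
    quadrant: str


@dataclass
class EnrichmentResult:
    test_region: str
    control_region: str
    table: np.ndarray  # 2x2: rows (test, control) x cols (Q1|Q3, Q2|Q4)
    odds_ratio: float
    p: float
    continuity_corrected: bool = False


def pairwise_change_matrix(
    earlier: Sequence[float],
    later: Sequence[float],
    contrast: ContrastSpec,
    earlier_ids: Optional[Sequence[str]] = None,
    later_ids: Optional[Sequence[str]] = None,
) -> PairwiseChangeVector:
    """Average pairwise later-minus-earlier change per female.

    Each earlier-time female receives the mean of (every later value minus
    her value); each later-time female the mean of (her value minus every
    earlier value).  Females with a missing (NaN) value are omitted with a
    warning.
    """
    if not contrast.is_pairwise:
        raise ValidationError("pairwise change requires a pairwise contrast")
    earlier = np.asarray(earlier, dtype=float)
    later = np.asarray(later, dtype=float)
    earlier_ids = list(earlier_ids) if earlier_ids is not None else [
        f"t{contrast.time_a}_f{i}" for i in range(len(earlier))
    ]
    later_ids = list(later_ids) if later_ids is not None else [
        f"t{contrast.time_b}_f{i}" for i in range(len(later))
    ]

    keep_e = np.isfinite(earlier)
    keep_l = np.isfinite(later)
    if not keep_e.all() or not keep_l.all():
        log.warning(
            "omitting %d females with missing values",
            int((~keep_e).sum() + (~keep_l).sum()),
        )
    earlier, later = earlier[keep_e], later[keep_l]
    earlier_ids = [f for f, k in zip(earlier_ids, keep_e) if k]
    later_ids = [f for f, k in zip(later_ids, keep_l) if k]
    if earlier.size == 0 or later.size == 0:
        raise ValidationError("both time points need at least one female")

    per_earlier = later.mean() - earlier  # mean over later females, per earlier female
    per_later = later - earlier.mean()  # mean over earlier females, per later female
    return PairwiseChangeVector(
        contrast=contrast,
        female_ids=earlier_ids + later_ids,
        change=np.concatenate([per_earlier, per_later]),
    )


def correlate_candidate_gene(
    meth: PairwiseChangeVector,
    expr: PairwiseChangeVector,
    gene_id: str = "",
    site: Optional[GenomicSite] = None,
    region: str = "promoter",
) -> CandidateGeneResult:
    """Pearson correlation across per-female average changes; zero-variance
    inputs yield a flagged undefined result (excluded from BH later)."""
    if meth.contrast != expr.contrast:
        raise ValidationError("methylation and expression contrasts differ")
    if meth.female_ids != expr.female_ids:
        raise ValidationError("female ordering differs between vectors")
    n = len(meth.change)
    if n < 4:
        raise ValidationError(f"candidate-gene correlation needs n >= 4, got {n}")
    if np.std(meth.change) == 0 or np.std(expr.change) == 0:
        return CandidateGeneResult(
            gene_id, site, region, meth.contrast, float("nan"), float("nan"), undefined=True
        )
    r, p = stats.pearsonr(meth.change, expr.change)
    return CandidateGeneResult(gene_id, site, region, meth.contrast, float(r), float(p))


def adjust_candidate_results(results: Sequence[CandidateGeneResult]) -> None:
    """BH-adjust p-values in place across all defined tests of a contrast."""
    defined = [r for r in results if not r.undefined]
    if not defined:
        return
    adjusted = adjust_bh(np.array([r.p for r in defined]))
    for rec, q in zip(defined, adjusted):
        rec.p_adj = float(q)


def mean_methylation_change(
    props: MethylationProportionMatrix, contrast: ContrastSpec
) -> dict:
    """Per-site change in mean methylation percentage between time points:
    average proportion x 100 across females per time point, then later
    minus earlier."""
    if not contrast.is_pairwise:
        raise ValidationError("methylation change requires a pairwise contrast")
    times = props.time_points()
    in_a = times == contrast.time_a
    in_b = times == contrast.time_b
    if not in_a.any() or not in_b.any():
        raise ValidationError("both time points need samples")
    delta = 100.0 * (props.values[:, in_b].mean(axis=1) - props.values[:, in_a].mean(axis=1))
    return dict(zip(props.sites, delta))


def assign_quadrant(delta_meth: float, log2fc: float) -> str:
    """Quadrant by joint signs: (hypo, up) Q1; (hyper, up) Q2; (hyper, down)
    Q3; (hypo, down) Q4.  Zero inputs must have been trimmed upstream."""
    if delta_meth == 0 or log2fc == 0:
        raise ValidationError("zero change reached quadrant assignment; trim first")
    if log2fc > 0:
        return "Q1" if delta_meth < 0 else "Q2"
    return "Q3" if delta_meth > 0 else "Q4"


def build_quadrant_associations(
    dms: Sequence[DMSRecord],
    de: Sequence[DEGeneRecord],
    assignment: RegionAssignment,
    delta_meth: dict,
    contrast: ContrastSpec,
    tissue_pair: str,
    trim_meth: float = 5.0,
    trim_lfc: float = 0.5,
) -> list:
    """One association per (significant site, significant gene, region
    membership) pair surviving the trimming thresholds.

    ``dms`` are the omnibus-significant sites, ``de`` the time-responsive
    genes (their per-contrast log2 fold change is used), ``delta_meth`` the
    per-site raw percentage change for the contrast.
    """
    if tissue_pair not in TISSUE_PAIRS:
        raise ValidationError(f"tissue_pair must be one of {TISSUE_PAIRS}")
    sig_sites = [rec.site for rec in dms if rec.is_dms]
    lfc_by_gene = {}
    for rec in de:
        if not rec.passes_filter:
            continue
        lfc_by_gene[rec.gene_id] = rec.log2fc_12 if contrast.time_a == 1 else rec.log2fc_23
    if not sig_sites or not lfc_by_gene:
        log.warning("no significant sites or genes; empty association list")
        return []

    out = []
    for site in sig_sites:
        dm = delta_meth.get(site)
        if dm is None or abs(dm) < trim_meth:
            continue
        for gene_id, region in assignment.get(site):
            lfc = lfc_by_gene.get(gene_id)
            if lfc is None or abs(lfc) < trim_lfc:
                continue
            out.append(
                QuadrantAssociation(
                    site=site,
                    gene_id=gene_id,
                    region=region,
                    tissue_pair=tissue_pair,
                    contrast_label=contrast.label,
                    delta_meth=float(dm),
                    log2fc=float(lfc),
                    quadrant=assign_quadrant(dm, lfc),
                )
            )
    return out


def fisher_exact_p(table, alternative: str = "two-sided") -> float:
    """Fisher exact p-value for a 2x2 table (two-sided by default: the sum
    of hypergeometric probabilities of tables, at fixed margins, no more
    likely than the observed one)."""
    return float(stats.fisher_exact(np.asarray(table), alternative=alternative)[1])


def fisher_enrichment(
    assocs: Sequence[QuadrantAssociation],
    test_region: str = "TSS",
    control_region: str = "down10kb",
    alternative: str = "two-sided",
) -> EnrichmentResult:
    """Fisher exact test of concordant-quadrant (Q1 or Q3) proportion in the
    test region against the control region.

    The odds ratio reported is the sample (unconditional) odds ratio; a 0.5
    continuity correction is applied, and flagged, only when the table has
    a zero cell.
    """
    table = np.zeros((2, 2), dtype=np.int64)
    found = {test_region: False, control_region: False}
    for a in assocs:
        if a.region not in found:
            continue
        found[a.region] = True
        row = 0 if a.region == test_region else 1
        col = 0 if a.quadrant in CONCORDANT else 1
        table[row, col] += 1
    for region, ok in found.items():
        if not ok:
            raise ValidationError(f"no associations in region {region!r}")

    p = fisher_exact_p(table, alternative)
    corrected = bool((table == 0).any())
    t = table + 0.5 if corrected else table.astype(float)
    odds_ratio = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return EnrichmentResult(
        test_region=test_region,
        control_region=control_region,
        table=table,
        odds_ratio=float(odds_ratio),
        p=float(p),
        continuity_corrected=corrected,
    )


def associations_to_frame(assocs: Sequence[QuadrantAssociation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [a.site.chrom for a in assocs],
            "pos": [a.site.pos for a in assocs],
            "strand": [a.site.strand for a in assocs],
            "gene_id": [a.gene_id for a in assocs],
            "region": [a.region for a in assocs],
            "tissue_pair": [a.tissue_pair for a in assocs],
            "contrast": [a.contrast_label for a in assocs],
            "delta_meth": [a.delta_meth for a in assocs],
            "log2fc": [a.log2fc for a in assocs],
            "quadrant": [a.quadrant for a in assocs],
        }
    )


def candidates_to_frame(results: Sequence[CandidateGeneResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "chrom": [r.site.chrom if r.site else "" for r in results],
            "pos": [r.site.pos if r.site else -1 for r in results],
            "region": [r.region for r in results],
            "contrast": [r.contrast.label for r in results],
            "r": [r.r for r in results],
            "p": [r.p for r in results],
            "p_adj": [r.p_adj for r in results],
            "undefined": [r.undefined for r in results],
        }
    )
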