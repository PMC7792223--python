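"""Site filtering shared by every downstream analysis.

The analysis set for a tissue is: sites with at least ``min_cov`` reads in
*every* sample of that tissue, minus sites whose methylation proportion is
0 in all samples or 1 in all samples (invariant sites carry no temporal
signal).  Cross-tissue analyses further restrict to the site intersection.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import (
    MethylationCountTable,
    MethylationProportionMatrix,
    ValidationError,
)

log = logging.getLogger(__name__)


def filter_min_coverage(table: MethylationCountTable, min_cov: int = 10) -> MethylationCountTable:
    """Keep sites with coverage >= ``min_cov`` in every sample of the tissue."""
    if min_cov < 1:
        raise ValidationError(f"min_cov must be >= 1, got {min_cov}")
    if table.n_sites == 0:
        raise ValidationError("cannot filter an empty table")
    keep = (table.coverage >= min_cov).all(axis=1)
    return table.subset_sites(keep)


def compute_proportions(table: MethylationCountTable) -> MethylationProportionMatrix:
    return table.proportions()


def filter_invariant_sites(props: MethylationProportionMatrix) -> MethylationProportionMatrix:
    """Drop sites whose proportion is 0 across all samples or 1 across all
    samples.  Constant-but-intermediate sites (e.g. 0.5 everywhere) are kept."""
    all_zero = (props.values == 0.0).all(axis=1)
    all_one = (props.values == 1.0).all(axis=1)
    keep = ~(all_zero | all_one)
    dropped = int((~keep).sum())
    if dropped:
        log.info("dropped %d invariant (all-0 or all-1) sites", dropped)
    return props.subset_sites(keep)


def intersect_tissues(
    a: MethylationCountTable, b: MethylationCountTable
) -> tuple[MethylationCountTable, MethylationCountTable]:
    """Restrict two single-tissue tables to their common sites, same order."""
    common = sorted(set(a.sites) & set(b.sites))
    if not common:
        log.warning("tissue intersection is empty (%s vs %s)", a.tissue, b.tissue)
    index_a = {site: i for i, site in enumerate(a.sites)}
    index_b = {site: i for i, site in enumerate(b.sites)}
    return (
        a.subset_sites([index_a[s] for s in common]),
        b.subset_sites([index_b[s] for s in common]),
    )
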