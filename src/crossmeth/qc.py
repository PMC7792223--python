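"""Sample-level QC on methylation proportions.

Samples from the same tissue can differ systematically in mean and spread of
per-site methylation (library composition, conversion efficiency).  Before
comparing temporal changes across tissues we quantify these differences with
rank-based k-sample tests: Kruskal-Wallis for location and Fligner-Killeen
for scale, treating each sample's vector of site proportions as one group.
Heterogeneity here motivates the z-score standardization applied in the
concordance stage.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .types import MethylationProportionMatrix, QCSampleStats, ValidationError


def qc_sample_stats(props: MethylationProportionMatrix) -> QCSampleStats:
    """Per-sample mean/variance over sites plus location- and scale-
    homogeneity p-values across samples.

    Variances use the population (divide-by-n) convention: they are
    descriptive summaries, not estimators.
    """
    if props.n_samples < 2:
        raise ValidationError("QC needs at least 2 samples")
    if props.n_sites < 2:
        raise ValidationError("QC needs at least 2 sites per sample")
    values = props.values
    if not np.isfinite(values).all():
        raise ValidationError("QC requires complete proportions (filter coverage first)")

    means = values.mean(axis=0)
    variances = values.var(axis=0)  # population variance

    columns = [values[:, j] for j in range(values.shape[1])]
    if all(np.array_equal(col, columns[0]) for col in columns[1:]):
        # degenerate: identical samples; rank tests are 0/undefined
        location_stat, location_p = 0.0, 1.0
        scale_stat, scale_p = 0.0, 1.0
    else:
        location_stat, location_p = stats.kruskal(*columns)
        scale_stat, scale_p = stats.fligner(*columns)

    return QCSampleStats(
        sample_ids=[s.sample_id for s in props.samples],
        means=means,
        variances=variances,
        location_stat=float(location_stat),
        location_p=float(location_p),
        scale_stat=float(scale_stat),
        scale_p=float(scale_p),
    )
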