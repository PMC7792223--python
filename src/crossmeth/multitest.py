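"""Multiple-testing correction shared across the pipeline.

Every "q-value" in this package is a Benjamini-Hochberg step-up adjusted
p-value (FDR control under independence/PRDS); the estimator is exposed in
one place so the whole pipeline uses the same convention.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

from .types import ValidationError


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, order-aligned with the input."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("adjust_bh expects a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
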