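"""Parameter-recovery and calibration evaluations on synthetic cohorts.

These routines run the full analysis path on generated data with known
ground truth and summarize how well it is recovered: cross-tissue
concordance of called DMS, caller sensitivity and empirical FDR, null
calibration of the DMS caller and of the quadrant enrichment test, and
power of the enrichment test under transcription-start-site-specific
methylation-expression coupling.  They back both the test suite and the
reproduction script.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .concordance import (
    change_between_timepoints,
    correlate_tissue_changes,
    zscore_standardize,
)
from .dms import test_pairwise_contrast
from .filters import filter_min_coverage, intersect_tissues
from .integrate import fisher_enrichment
from .simulate import (
    SimulationConfig,
    simulate_associations,
    simulate_genome,
    simulate_methylation,
)
from .types import ContrastSpec

log = logging.getLogger(__name__)


def recovery_run(
    seed: int,
    fraction_general: float,
    n_sites: int = 20_000,
    effect_pp: float = 25.0,
    tissue: str = "RBC",
    overdispersion_correction: bool = True,
) -> dict:
    """Simulate a two-tissue cohort, call DMS for the first contrast, and
    summarize recovery.

    Returns the cross-tissue Pearson r of z-scored changes over the union
    of called DMS, plus the caller's sensitivity and empirical FDR in
    ``tissue``.  Sensitivity is measured over sites carrying the full
    configured effect in that tissue (sites whose baseline sat too close
    to 0 or 1 to realize the whole shift are excluded from the
    denominator); a false discovery is a call at a site with no true
    effect in that tissue.
    """
    config = SimulationConfig(
        seed=seed,
        n_sites=n_sites,
        n_genes=50,
        chrom_length=max(5_000_000, n_sites * 300),
        fraction_general=fraction_general,
        effect_pp=effect_pp,
    )
    _, sites = simulate_genome(config)
    tables, truth = simulate_methylation(config, sites)
    filtered = {t: filter_min_coverage(tab) for t, tab in tables.items()}
    rbc, liver = intersect_tissues(filtered["RBC"], filtered["liver"])
    shared = {"RBC": rbc, "liver": liver}

    contrast = ContrastSpec.delta12()
    dms = {
        t: test_pairwise_contrast(
            tab, contrast, overdispersion_correction=overdispersion_correction
        )
        for t, tab in shared.items()
    }
    union = sorted({r.site for recs in dms.values() for r in recs if r.is_dms})
    changes = {
        t: change_between_timepoints(zscore_standardize(tab.proportions()), contrast)
        for t, tab in shared.items()
    }
    conc = correlate_tissue_changes(changes["RBC"], changes["liver"], union)

    st = truth.site_truth.set_index(["chrom", "pos", "strand"])
    recs = dms[tissue]
    rows = st.loc[[(r.site.chrom, r.site.pos, r.site.strand) for r in recs]]
    affected = rows["affected_tissue"].isin(["both", tissue]).to_numpy()
    true_eff = np.where(affected, np.abs(rows["true_d12_pp"].to_numpy()), 0.0)
    called = np.array([r.is_dms for r in recs])

    full = true_eff >= effect_pp - 1e-6
    n_false = int((called & (true_eff == 0)).sum())
    return {
        "n_sites_analyzed": len(recs),
        "n_dms_union": conc.n,
        "concordance_r": conc.r,
        "concordance_p": conc.p,
        "sensitivity": float(called[full].mean()) if full.any() else float("nan"),
        "fdr": n_false / max(int(called.sum()), 1),
        "n_called": int(called.sum()),
    }


def null_dms_rate(
    seed: int, n_sites: int = 5_000, overdispersion_correction: bool = True
) -> dict:
    """Fraction of tested sites reaching q <= 0.01 when no site has any
    true temporal effect (false-positive calibration of the DMS caller)."""
    config = SimulationConfig(
        seed=seed,
        n_sites=n_sites,
        n_genes=20,
        chrom_length=max(3_000_000, n_sites * 300),
        fraction_temporal=0.0,
    )
    _, sites = simulate_genome(config)
    tables, _ = simulate_methylation(config, sites)
    table = filter_min_coverage(tables["RBC"])
    recs = test_pairwise_contrast(
        table,
        ContrastSpec.delta12(),
        overdispersion_correction=overdispersion_correction,
    )
    rate = float(np.mean([r.q <= 0.01 for r in recs]))
    return {"rate": rate, "n_tested": len(recs)}


def fisher_null_calibration(seed: int, n_reps: int = 500, n_per_region: int = 40) -> dict:
    """Rejection rate of the quadrant enrichment test at p <= 0.05 when
    methylation and expression changes are uncoupled in both regions."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        assocs = simulate_associations(rng, n_per_region=n_per_region, k=0.0)
        if fisher_enrichment(assocs).p <= 0.05:
            rejections += 1
    return {"rate": rejections / n_reps, "n_reps": n_reps}


def enrichment_power(
    seed: int, n_reps: int = 100, n_per_region: int = 30, k: float = 0.05
) -> dict:
    """Fraction of replicates with enrichment p <= 0.05 when the test
    region's log2 fold changes follow -k x (methylation change) + noise."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        assocs = simulate_associations(rng, n_per_region=n_per_region, k=k)
        if fisher_enrichment(assocs).p <= 0.05:
            hits += 1
    return {"rate": hits / n_reps, "n_reps": n_reps}
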