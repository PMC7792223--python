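"""End-to-end orchestration: simulate/load -> filter -> annotate -> DMS ->
concordance -> DE -> candidate genes -> quadrant enrichment.

Every stage writes a TSV checkpoint with a provenance header (config hash,
seed, package version), and identical config + seed reproduce identical
output bodies.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as cio
from .concordance import (
    change_between_timepoints,
    correlate_tissue_changes,
    zscore_standardize,
)
from .dms import (
    classification_to_frame,
    classify_tissue_generality,
    dms_to_frame,
    test_pairwise_contrast,
    test_time_omnibus,
)
from .expression import (
    de_to_frame,
    filter_time_responsive_genes,
    normalize_size_factors,
    test_time_effect_nb,
)
from .filters import filter_invariant_sites, filter_min_coverage, intersect_tissues
from .integrate import (
    adjust_candidate_results,
    associations_to_frame,
    build_quadrant_associations,
    candidates_to_frame,
    correlate_candidate_gene,
    fisher_enrichment,
    mean_methylation_change,
    pairwise_change_matrix,
)
from .qc import qc_sample_stats
from .regions import (
    assign_sites_to_regions,
    build_region_intervals,
    write_regions_bed,
)
from .simulate import (
    SimulationConfig,
    simulate_expression,
    simulate_genome,
    simulate_methylation,
)
from .types import ContrastSpec, ValidationError

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds and switches of a pipeline run."""

    seed: int
    simulate: Optional[SimulationConfig] = None
    min_cov: int = 10
    dms_diff: float = 15.0  # percentage points
    dms_q: float = 0.01
    omnibus_q: float = 0.01
    trim_meth: float = 5.0  # percentage points
    trim_lfc: float = 0.5
    de_q: float = 0.05
    tss_up: int = 300
    tss_down: int = 50
    prom_up: int = 2000
    prom_down: int = 200
    flank: int = 10000
    standardize: str = "site"  # site | sample | grand
    fisher_alternative: str = "two-sided"
    run_omnibus: bool = True
    run_expression: bool = True

    def __post_init__(self) -> None:
        for name in ("min_cov", "dms_diff", "dms_q", "omnibus_q", "trim_meth", "trim_lfc", "de_q"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.simulate is None:
            self.simulate = SimulationConfig(seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulate"]["expression_tissues"] = list(d["simulate"]["expression_tissues"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulate", None)
        if sim is not None:
            sim = dict(sim)
            if "expression_tissues" in sim:
                sim["expression_tissues"] = tuple(sim["expression_tissues"])
            sim = SimulationConfig(**sim)
        return cls(simulate=sim, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _provenance(config: PipelineConfig) -> str:
    return f"crossmeth {__version__} | config {config.digest()} | seed {config.seed}"


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage on a simulated bundle; returns the in-memory
    results and writes TSV checkpoints under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = _provenance(config)
    results: dict = {"config_digest": config.digest()}
    t0 = time.time()

    def stage(name: str) -> None:
        log.info("[%6.1fs] stage: %s", time.time() - t0, name)

    stage("simulate")
    sim = config.simulate
    genes, sites = simulate_genome(sim)
    tables, truth = simulate_methylation(sim, sites)

    stage("filter")
    filtered = {}
    for tissue, table in tables.items():
        filtered[tissue] = filter_min_coverage(table, config.min_cov)
    rbc, liver = intersect_tissues(filtered["RBC"], filtered["liver"])
    shared = {"RBC": rbc, "liver": liver}
    props = {}
    for tissue, table in shared.items():
        p = filter_invariant_sites(table.proportions())
        props[tissue] = p
        cio.write_proportions(p, outdir / f"proportions_{tissue}.tsv", header)
    # keep the two tissues on a common post-filter site set
    common_sites = sorted(set(props["RBC"].sites) & set(props["liver"].sites))
    for tissue in shared:
        index = {s: i for i, s in enumerate(props[tissue].sites)}
        props[tissue] = props[tissue].subset_sites([index[s] for s in common_sites])
        site_index = {s: i for i, s in enumerate(shared[tissue].sites)}
        shared[tissue] = shared[tissue].subset_sites([site_index[s] for s in common_sites])
        cio.write_wide_counts(shared[tissue], outdir / f"counts_{tissue}.tsv", header)
    results["n_shared_sites"] = len(common_sites)

    stage("qc")
    qc_rows = []
    for tissue, p in props.items():
        stats_ = qc_sample_stats(p)
        results[f"qc_{tissue}"] = stats_
        frame = stats_.to_frame()
        frame["tissue"] = tissue
        frame["location_p"] = stats_.location_p
        frame["scale_p"] = stats_.scale_p
        qc_rows.append(frame)
    cio._write_tsv(pd.concat(qc_rows, ignore_index=True), outdir / "qc.tsv", header)

    stage("annotate")
    intervals = build_region_intervals(
        genes,
        tss_up=config.tss_up,
        tss_down=config.tss_down,
        prom_up=config.prom_up,
        prom_down=config.prom_down,
        flank=config.flank,
    )
    write_regions_bed(intervals, outdir / "regions.bed")
    assignment = assign_sites_to_regions(common_sites, intervals)
    cio._write_tsv(assignment.to_frame(), outdir / "site_regions.tsv", header)
    results["assignment"] = assignment

    stage("dms")
    contrasts = [ContrastSpec.delta12(), ContrastSpec.delta23()]
    dms_records: dict = {}
    class_records: dict = {}
    for contrast in contrasts:
        for tissue, table in shared.items():
            dms_records[(tissue, contrast.label)] = test_pairwise_contrast(
                table, contrast, config.dms_diff, config.dms_q
            )
        class_records[contrast.label] = classify_tissue_generality(
            dms_records[("RBC", contrast.label)],
            dms_records[("liver", contrast.label)],
            contrast,
        )
    cio._write_tsv(
        pd.concat([dms_to_frame(r) for r in dms_records.values()], ignore_index=True),
        outdir / "dms_pairwise.tsv",
        header,
    )
    cio._write_tsv(
        pd.concat(
            [classification_to_frame(r) for r in class_records.values()], ignore_index=True
        ),
        outdir / "dms_classes.tsv",
        header,
    )
    results["dms"] = dms_records
    results["classes"] = class_records

    stage("concordance")
    zmats = {t: zscore_standardize(p, config.standardize) for t, p in props.items()}
    concordance = {}
    conc_rows = []
    for contrast in contrasts:
        changes = {
            t: change_between_timepoints(z, contrast) for t, z in zmats.items()
        }
        dms_union = {
            r.site
            for t in shared
            for r in dms_records[(t, contrast.label)]
            if r.is_dms
        }
        scopes = {"all_dms": dms_union}
        for region in ("promoter", "TSS"):
            scopes[region] = dms_union & assignment.sites_in_region(region)
        for scope, subset in scopes.items():
            try:
                res = correlate_tissue_changes(
                    changes["RBC"], changes["liver"], sorted(subset), scope
                )
            except ValidationError:
                log.warning("concordance %s/%s skipped (<3 paired sites)", contrast.label, scope)
                continue
            concordance[(contrast.label, scope)] = res
            conc_rows.append(
                (contrast.label, scope, res.n, res.r, res.df, res.p)
            )
    cio._write_tsv(
        pd.DataFrame(conc_rows, columns=["contrast", "scope", "n", "r", "df", "p"]),
        outdir / "concordance.tsv",
        header,
    )
    results["concordance"] = concordance

    omnibus: dict = {}
    if config.run_omnibus:
        stage("omnibus")
        for tissue, table in shared.items():
            omnibus[tissue] = test_time_omnibus(table, config.omnibus_q)
        cio._write_tsv(
            pd.concat([dms_to_frame(r) for r in omnibus.values()], ignore_index=True),
            outdir / "dms_omnibus.tsv",
            header,
        )
    results["omnibus"] = omnibus

    if config.run_expression:
        stage("expression")
        expr, candidates = simulate_expression(sim, genes, sites, truth)
        de_records = {}
        for tissue, mat in expr.items():
            factors = normalize_size_factors(mat)
            records = test_time_effect_nb(mat, factors)
            filter_time_responsive_genes(records, q_threshold=config.de_q)
            de_records[tissue] = records
        cio._write_tsv(
            pd.concat([de_to_frame(r) for r in de_records.values()], ignore_index=True),
            outdir / "de_genes.tsv",
            header,
        )
        results["de"] = de_records

        stage("candidate_genes")
        candidate_results = []
        meth_liver = props["liver"]
        female_time = {
            s.female_id: s.time_point for s in meth_liver.samples
        }
        cand_sites = {
            region: assignment.sites_in_region(region) for region in ("TSS", "promoter")
        }
        site_pos = {s: i for i, s in enumerate(meth_liver.sites)}
        for contrast in contrasts:
            per_contrast = []
            for gene_id in sorted(candidates["gene_id"].unique()):
                gene_expr = candidates[candidates["gene_id"] == gene_id]
                e_vals = gene_expr[gene_expr["time_point"] == contrast.time_a]["value"].to_numpy()
                l_vals = gene_expr[gene_expr["time_point"] == contrast.time_b]["value"].to_numpy()
                expr_vec = pairwise_change_matrix(e_vals, l_vals, contrast)
                for region in ("TSS", "promoter"):
                    for site in sorted(cand_sites[region]):
                        pairs = assignment.get(site)
                        if (gene_id, region) not in pairs or site not in site_pos:
                            continue
                        row = meth_liver.values[site_pos[site]]
                        times = meth_liver.time_points()
                        m_vec = pairwise_change_matrix(
                            row[times == contrast.time_a],
                            row[times == contrast.time_b],
                            contrast,
                        )
                        per_contrast.append(
                            correlate_candidate_gene(m_vec, expr_vec, gene_id, site, region)
                        )
            adjust_candidate_results(per_contrast)
            candidate_results.extend(per_contrast)
        cio._write_tsv(
            candidates_to_frame(candidate_results), outdir / "candidate_correlations.tsv", header
        )
        results["candidates"] = candidate_results

        stage("integrate")
        assoc_rows = []
        enrich_rows = []
        enrichment = {}
        associations = {}
        for contrast in contrasts:
            for tissue_pair, meth_tissue, expr_tissue in (
                ("liver-liver", "liver", "liver"),
                ("RBC-liver", "RBC", "liver"),
                ("RBC-ovary", "RBC", "ovary"),
                ("RBC-hypothalamus", "RBC", "hypothalamus"),
            ):
                if expr_tissue not in de_records or not omnibus.get(meth_tissue):
                    continue
                delta = mean_methylation_change(props[meth_tissue], contrast)
                passing = [r for r in de_records[expr_tissue] if r.passes_filter]
                assocs = build_quadrant_associations(
                    omnibus[meth_tissue],
                    passing,
                    assignment,
                    delta,
                    contrast,
                    tissue_pair,
                    config.trim_meth,
                    config.trim_lfc,
                )
                associations[(tissue_pair, contrast.label)] = assocs
                if assocs:
                    assoc_rows.append(associations_to_frame(assocs))
                try:
                    enr = fisher_enrichment(assocs, alternative=config.fisher_alternative)
                except ValidationError as exc:
                    log.warning(
                        "enrichment %s/%s skipped: %s", tissue_pair, contrast.label, exc
                    )
                    continue
                enrichment[(tissue_pair, contrast.label)] = enr
                enrich_rows.append(
                    (
                        tissue_pair,
                        contrast.label,
                        *enr.table.ravel().tolist(),
                        enr.odds_ratio,
                        enr.p,
                    )
                )
        cio._write_tsv(
            pd.concat(assoc_rows, ignore_index=True)
            if assoc_rows
            else associations_to_frame([]),
            outdir / "quadrant_associations.tsv",
            header,
        )
        cio._write_tsv(
            pd.DataFrame(
                enrich_rows,
                columns=[
                    "tissue_pair",
                    "contrast",
                    "test_q13",
                    "test_q24",
                    "control_q13",
                    "control_q24",
                    "odds_ratio",
                    "p",
                ],
            ),
            outdir / "enrichment.tsv",
            header,
        )
        results["associations"] = associations
        results["enrichment"] = enrichment

    results["truth"] = truth
    config.to_yaml(outdir / "config.yaml")
    stage("done")
    return results
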