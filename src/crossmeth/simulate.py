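"""Seeded generator of the full input bundle with known ground truth.

The generator emulates the study design the pipeline targets: 18 females
sampled cross-sectionally at 3 time points (6 per time point), two
temperature environments balanced within time point, 6 families, RRBS
methylation counts for two tissues (RBC and liver), pooled RNA counts
(2 pools x 3 females per time point) for the expression tissues, and a
per-female candidate-gene expression table.

Methylation counts are beta-binomial (binomial reads around a per-cell
proportion drawn with intra-site correlation ``rho``), on top of a logit
scale model: site baseline + cumulative temporal effect (realized in both
tissues for tissue-general sites, one tissue for tissue-specific sites) +
per-sample shift + family effect + optional temperature effect.  Coverage
is negative binomial.  Expression change can be negatively coupled to the
true TSS methylation change of the same gene, which is what the quadrant
enrichment stage is designed to detect.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .integrate import QuadrantAssociation, assign_quadrant
from .regions import GeneModel, assign_sites_to_regions, build_region_intervals
from .types import (
    GenomicSite,
    MethylationCountTable,
    SampleMeta,
    ValidationError,
)
from .expression import ExpressionCountMatrix

log = logging.getLogger(__name__)

METH_TISSUES = ("RBC", "liver")


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the emulated study design."""

    seed: int
    # genome
    n_genes: int = 200
    chrom_length: int = 20_000_000
    n_sites: int = 5000
    site_quota_per_region: int = 1
    # cohort
    n_females_per_timepoint: int = 6
    n_families: int = 6
    # methylation model (logit scale unless noted)
    baseline_logit_mean: float = 0.0
    baseline_logit_sd: float = 1.5
    fraction_temporal: float = 0.1
    fraction_general: float = 0.3
    effect_pp: float = 25.0  # percentage points per contrast
    sample_shift_sd: float = 0.15
    family_sd: float = 0.1
    temperature_effect: float = 0.0
    coverage_mean: float = 30.0
    coverage_dispersion: float = 10.0  # NB size parameter
    rho: float = 0.02  # beta-binomial intra-site correlation
    # expression model
    expression_tissues: tuple = ("liver", "ovary", "hypothalamus")
    pools_per_timepoint: int = 2
    expr_baseline_mean: float = 100.0
    expr_baseline_log_sd: float = 1.0
    expr_dispersion: float = 0.05
    fraction_de: float = 0.2
    expr_log2_effect: float = 1.0
    depth_factor_sd: float = 0.15
    # methylation -> expression coupling (TSS sites of the source tissue)
    coupling_k: float = 0.0
    coupling_noise_sd: float = 0.3
    coupling_source_tissue: str = "RBC"
    coupling_target_tissue: str = "ovary"
    # candidate genes (per-female, qPCR-like)
    n_candidate_genes: int = 7
    candidate_noise_sd: float = 0.2

    def __post_init__(self) -> None:
        for name in ("fraction_temporal", "fraction_general", "fraction_de"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {value}")
        if not 0.0 <= self.rho < 1.0:
            raise ValidationError("rho must be in [0, 1)")
        if self.seed is None:
            raise ValidationError("seed is mandatory")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent deterministic stream per generator stage."""
        tag = zlib.crc32(stream.encode()) % (2**31)
        return np.random.default_rng([self.seed % (2**31), tag])


@dataclass
class GroundTruth:
    """Generating parameters of the emitted tables, for recovery tests."""

    site_truth: pd.DataFrame  # per site: temporal/general flags, true effects
    gene_truth: Optional[pd.DataFrame] = None  # per gene: DE flags, shifts, coupling

    def true_effect(self, site: GenomicSite, tissue: str, contrast_label: str) -> float:
        row = self.site_truth.loc[
            (self.site_truth["chrom"] == site.chrom)
            & (self.site_truth["pos"] == site.pos)
            & (self.site_truth["strand"] == site.strand)
        ]
        if row.empty:
            return 0.0
        row = row.iloc[0]
        if row["affected_tissue"] not in ("both", tissue):
            return 0.0
        return float(row[f"true_{contrast_label}_pp"])


def simulate_genome(config: SimulationConfig) -> tuple[list, list]:
    """Non-overlapping genes on both strands plus CpG sites with guaranteed
    per-region quotas; the remaining sites are uniform over the chromosome."""
    rng = config.rng("genome")
    flank = 10_000
    margin = flank + 2_500
    gene_lengths = rng.integers(2_000, 8_001, size=config.n_genes)
    spacing = gene_lengths + 2 * flank + 2_000
    needed = int(spacing.sum()) + 2 * margin
    if needed > config.chrom_length:
        raise ValidationError(
            f"chrom_length {config.chrom_length} cannot hold {config.n_genes} genes "
            f"with 10 kb flanks; need at least {needed}"
        )
    starts = margin + np.concatenate([[0], np.cumsum(spacing[:-1])])
    genes = []
    for i, (start, length) in enumerate(zip(starts, gene_lengths)):
        start, end = int(start), int(start + length - 1)
        strand = "+" if rng.random() < 0.5 else "-"
        mid = start + int(length) // 2
        exons = [(start, mid - 100), (mid + 100, end)] if length > 400 else [(start, end)]
        genes.append(
            GeneModel(
                gene_id=f"g{i + 1:04d}",
                chrom="chr1",
                strand=strand,
                tx_start=start,
                tx_end=end,
                exons=exons,
            )
        )

    positions: set[int] = set()
    intervals = build_region_intervals(genes)
    quota = config.site_quota_per_region
    if quota > 0:
        for iv in intervals:
            for _ in range(quota):
                for _attempt in range(100):
                    pos = int(rng.integers(iv.start, iv.end + 1))
                    if pos not in positions:
                        positions.add(pos)
                        break
    quota_positions = set(positions)
    uniform: list[int] = []
    while len(quota_positions) + len(uniform) < config.n_sites:
        need = config.n_sites - len(quota_positions) - len(uniform)
        draw = rng.integers(1, config.chrom_length + 1, size=max(need, 16))
        for p in draw:
            p = int(p)
            if p not in positions:
                positions.add(p)
                uniform.append(p)
    # quota sites always kept; uniform filler trimmed to the requested total
    n_fill = max(config.n_sites - len(quota_positions), 0)
    positions_list = sorted(quota_positions | set(uniform[:n_fill]))
    strands = rng.choice(["+", "-"], size=len(positions_list))
    sites = [GenomicSite("chr1", p, s) for p, s in zip(positions_list, strands)]
    return genes, sites


def _cohort(config: SimulationConfig, tissue: str) -> list:
    samples = []
    k = config.n_females_per_timepoint
    for t in (1, 2, 3):
        for j in range(k):
            fem = (t - 1) * k + j + 1
            samples.append(
                SampleMeta(
                    sample_id=f"F{fem:02d}_{tissue}",
                    female_id=f"F{fem:02d}",
                    tissue=tissue,
                    time_point=t,
                    temperature_env="warm" if j < (k + 1) // 2 else "cold",
                    family_id=f"fam{(fem - 1) % config.n_families + 1}",
                )
            )
    return samples


def simulate_methylation(
    config: SimulationConfig, sites: Sequence[GenomicSite]
) -> tuple[dict, GroundTruth]:
    """Beta-binomial methylation count tables for both tissues plus the
    per-site ground truth of temporal effects."""
    rng = config.rng("methylation")
    n = len(sites)
    baseline = rng.normal(config.baseline_logit_mean, config.baseline_logit_sd, size=n)
    p1 = expit(baseline)

    temporal = rng.random(n) < config.fraction_temporal
    general = temporal & (rng.random(n) < config.fraction_general)
    specific_tissue = np.where(rng.random(n) < 0.5, "RBC", "liver")
    affected = np.where(general, "both", np.where(temporal, specific_tissue, ""))

    sign12 = rng.choice([-1.0, 1.0], size=n)
    sign23 = rng.choice([-1.0, 1.0], size=n)
    eff = config.effect_pp / 100.0
    p2 = np.clip(p1 + np.where(temporal, sign12 * eff, 0.0), 0.02, 0.98)
    p3 = np.clip(p2 + np.where(temporal, sign23 * eff, 0.0), 0.02, 0.98)

    truth = pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "strand": [s.strand for s in sites],
            "is_temporal": temporal,
            "is_general": general,
            "affected_tissue": affected,
            "true_d12_pp": 100.0 * (p2 - p1),
            "true_d23_pp": 100.0 * (p3 - p2),
        }
    )
    truth.loc[~truth["is_temporal"], ["true_d12_pp", "true_d23_pp"]] = 0.0

    tables = {}
    p_by_time = {1: p1, 2: p2, 3: p3}
    for tissue in METH_TISSUES:
        samples = _cohort(config, tissue)
        n_samples = len(samples)
        sample_shift = rng.normal(0.0, config.sample_shift_sd, size=n_samples)
        family_ids = sorted({s.family_id for s in samples})
        fam_effect = dict(
            zip(family_ids, rng.normal(0.0, config.family_sd, size=len(family_ids)))
        )
        logits = np.empty((n, n_samples))
        tissue_affected = (affected == "both") | (affected == tissue)
        for j, s in enumerate(samples):
            pt = np.where(tissue_affected, p_by_time[s.time_point], p1)
            eta = (
                logit(np.clip(pt, 1e-6, 1 - 1e-6))
                + sample_shift[j]
                + fam_effect[s.family_id]
                + (config.temperature_effect if s.temperature_env == "warm" else 0.0)
            )
            logits[:, j] = eta
        probs = expit(logits)

        size = config.coverage_dispersion
        nb_p = size / (size + config.coverage_mean)
        coverage = np.maximum(rng.negative_binomial(size, nb_p, size=(n, n_samples)), 1)
        if config.rho > 0:
            c = 1.0 / config.rho - 1.0
            cell_p = rng.beta(np.maximum(probs * c, 1e-8), np.maximum((1 - probs) * c, 1e-8))
        else:
            cell_p = probs
        methylated = rng.binomial(coverage, cell_p)
        tables[tissue] = MethylationCountTable(
            sites=list(sites), samples=samples, coverage=coverage, methylated=methylated
        )
    return tables, GroundTruth(site_truth=truth)


def _gene_time_shifts(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    sites: Sequence[GenomicSite],
    truth: GroundTruth,
    rng: np.random.Generator,
    tissue: str,
) -> pd.DataFrame:
    """Per-gene true log2 shifts per contrast; coupled genes follow
    -k * true TSS methylation change, others are independent DE effects."""
    coupled_delta: dict[str, list] = {}
    if config.coupling_k != 0 and tissue == config.coupling_target_tissue:
        intervals = [iv for iv in build_region_intervals(genes) if iv.region == "TSS"]
        st = truth.site_truth
        temporal_sites = [
            GenomicSite(r.chrom, int(r.pos), r.strand)
            for r in st.itertuples()
            if r.is_temporal and r.affected_tissue in ("both", config.coupling_source_tissue)
        ]
        assignment = assign_sites_to_regions(temporal_sites, intervals)
        for site, pairs in assignment.memberships.items():
            d12 = truth.true_effect(site, config.coupling_source_tissue, "d12")
            d23 = truth.true_effect(site, config.coupling_source_tissue, "d23")
            for gene_id, _region in pairs:
                coupled_delta.setdefault(gene_id, []).append((d12, d23))

    rows = []
    for g in genes:
        if g.gene_id in coupled_delta:
            d12 = float(np.mean([d[0] for d in coupled_delta[g.gene_id]]))
            d23 = float(np.mean([d[1] for d in coupled_delta[g.gene_id]]))
            shift12 = -config.coupling_k * d12 + rng.normal(0.0, config.coupling_noise_sd)
            shift23 = -config.coupling_k * d23 + rng.normal(0.0, config.coupling_noise_sd)
            is_de, coupled = True, True
        else:
            is_de = bool(rng.random() < config.fraction_de)
            coupled = False
            shift12 = float(rng.choice([-1.0, 1.0]) * config.expr_log2_effect) if is_de else 0.0
            shift23 = float(rng.choice([-1.0, 1.0]) * config.expr_log2_effect) if is_de else 0.0
        rows.append((g.gene_id, tissue, is_de, coupled, shift12, shift23))
    return pd.DataFrame(
        rows, columns=["gene_id", "tissue", "is_de", "is_coupled", "shift12_log2", "shift23_log2"]
    )


def simulate_expression(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    sites: Sequence[GenomicSite],
    truth: GroundTruth,
) -> tuple[dict, pd.DataFrame]:
    """Pooled NB expression counts per tissue plus the per-female
    candidate-gene table; extends ``truth`` with the gene-level truth."""
    rng = config.rng("expression")
    n_genes = len(genes)
    base_mean = np.exp(
        rng.normal(np.log(config.expr_baseline_mean), config.expr_baseline_log_sd, size=n_genes)
    )

    matrices = {}
    gene_truth_frames = []
    for tissue in config.expression_tissues:
        shifts = _gene_time_shifts(config, genes, sites, truth, rng, tissue)
        gene_truth_frames.append(shifts)
        cum_log2 = {
            1: np.zeros(n_genes),
            2: shifts["shift12_log2"].to_numpy(),
            3: shifts["shift12_log2"].to_numpy() + shifts["shift23_log2"].to_numpy(),
        }
        pools = []
        means = []
        k = config.n_females_per_timepoint
        pool_size = max(k // config.pools_per_timepoint, 1)
        for t in (1, 2, 3):
            for p in range(config.pools_per_timepoint):
                depth = float(np.exp(rng.normal(0.0, config.depth_factor_sd)))
                pools.append(
                    SampleMeta(
                        sample_id=f"{tissue}_t{t}_p{p + 1}",
                        female_id=f"pool_t{t}_p{p + 1}",
                        tissue=tissue,
                        time_point=t,
                        temperature_env="warm" if p % 2 == 0 else "cold",
                        pool_id=f"t{t}_p{p + 1}",
                    )
                )
                means.append(pool_size * base_mean * np.power(2.0, cum_log2[t]) * depth)
        mu = np.column_stack(means)
        r = 1.0 / config.expr_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
        matrices[tissue] = ExpressionCountMatrix(
            genes=[g.gene_id for g in genes], pools=pools, counts=counts
        )
    truth.gene_truth = pd.concat(gene_truth_frames, ignore_index=True)

    # candidate genes: per-female continuous expression in the liver
    intervals = build_region_intervals(genes)
    reg_genes = {
        iv.gene_id for iv in intervals if iv.region in ("TSS", "promoter")
    }
    candidate_ids = sorted(reg_genes)[: config.n_candidate_genes]
    liver_shifts = _gene_time_shifts(config, genes, sites, truth, rng, "liver")
    shift_map = liver_shifts.set_index("gene_id")[["shift12_log2", "shift23_log2"]]
    rows = []
    k = config.n_females_per_timepoint
    for gene_id in candidate_ids:
        gi = [g.gene_id for g in genes].index(gene_id)
        s12 = float(shift_map.loc[gene_id, "shift12_log2"])
        s23 = float(shift_map.loc[gene_id, "shift23_log2"])
        cum = {1: 0.0, 2: s12, 3: s12 + s23}
        for t in (1, 2, 3):
            for j in range(k):
                fem = (t - 1) * k + j + 1
                value = base_mean[gi] * 2.0 ** cum[t] * float(
                    np.exp(rng.normal(0.0, config.candidate_noise_sd))
                )
                rows.append((gene_id, f"F{fem:02d}", t, value))
    candidates = pd.DataFrame(rows, columns=["gene_id", "female_id", "time_point", "value"])
    return matrices, candidates


def simulate_associations(
    rng: np.random.Generator,
    n_per_region: int = 30,
    k: float = 0.0,
    noise_sd: float = 0.3,
    lfc_sd: float = 0.8,
    delta_sd: float = 15.0,
    trim_meth: float = 5.0,
    trim_lfc: float = 0.5,
) -> list:
    """Direct association-level generator for enrichment calibration.

    Draws (delta methylation, log2FC) pairs for a TSS test region and a
    10 kb-downstream control region until each has ``n_per_region``
    trimming survivors.  With ``k`` > 0 the TSS log2FC follows
    ``-k * delta + Normal(0, noise_sd)`` (negative coupling); the control
    region's log2FC is always independent of its delta.
    """
    out: list[QuadrantAssociation] = []
    counter = 0
    for region in ("TSS", "down10kb"):
        kept = 0
        while kept < n_per_region:
            delta = float(rng.normal(0.0, delta_sd))
            if region == "TSS" and k != 0.0:
                lfc = float(-k * delta + rng.normal(0.0, noise_sd))
            else:
                lfc = float(rng.normal(0.0, lfc_sd))
            if abs(delta) < trim_meth or abs(lfc) < trim_lfc:
                continue
            counter += 1
            kept += 1
            out.append(
                QuadrantAssociation(
                    site=GenomicSite("chr1", counter, "+"),
                    gene_id=f"g{counter:04d}",
                    region=region,
                    tissue_pair="RBC-ovary",
                    contrast_label="d12",
                    delta_meth=delta,
                    log2fc=lfc,
                    quadrant=assign_quadrant(delta, lfc),
                )
            )
    return out


def write_bundle(
    outdir,
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    tables: dict,
    truth: GroundTruth,
    expression: Optional[dict] = None,
    candidates: Optional[pd.DataFrame] = None,
) -> None:
    """Write the complete fixture bundle in the formats the pipeline reads."""
    from pathlib import Path

    from . import io as cio
    from .regions import write_gene_models

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gene_models(genes, outdir / "genes.gff3")
    all_samples = [s for table in tables.values() for s in table.samples]
    cio.write_metadata(all_samples, outdir / "samples.tsv")
    for tissue, table in tables.items():
        cov_dir = outdir / f"coverage_{tissue}"
        cov_dir.mkdir(exist_ok=True)
        for j, meta in enumerate(table.samples):
            cio.write_coverage_file(table, j, cov_dir / f"{meta.sample_id}.cov")
        cio.write_wide_counts(table, outdir / f"counts_{tissue}.tsv")
    truth.site_truth.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    if truth.gene_truth is not None:
        truth.gene_truth.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    if expression:
        for tissue, mat in expression.items():
            frame = pd.DataFrame(
                mat.counts, index=mat.genes, columns=[p.sample_id for p in mat.pools]
            )
            frame.index.name = "gene_id"
            frame.to_csv(outdir / f"expression_{tissue}.tsv", sep="\t")
            cio.write_metadata(mat.pools, outdir / f"pools_{tissue}.tsv")
    if candidates is not None:
        candidates.to_csv(outdir / "candidate_expression.tsv", sep="\t", index=False)
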