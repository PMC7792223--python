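"""Strand-aware genomic region construction and CpG-site assignment.

Regions are anchored on the annotated gene span.  With the TSS at the
transcript start (plus strand) or end (minus strand):

* ``TSS``       — 300 bp upstream to 50 bp downstream of the TSS (351 bp,
                  spanning 350 bp of flanking sequence around the start);
* ``promoter``  — 2000 bp upstream to 200 bp downstream of the TSS;
* ``gene_body`` — the full transcript span (exons and introns);
* ``up10kb`` / ``down10kb`` — the 10 kb blocks adjacent to the gene body.

"Upstream" follows transcription: larger coordinates for minus-strand
genes.  Coordinates are 1-based inclusive throughout; BED export converts
to 0-based half-open.  A CpG may fall in several regions of several genes
and every membership is reported (the categories overlap by construction).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import gffutils
import pandas as pd
from intervaltree import IntervalTree

from .types import GenomicSite, ValidationError

log = logging.getLogger(__name__)

REGION_KINDS = ("TSS", "promoter", "gene_body", "up10kb", "down10kb")
# most regulatory first; used only when priority assignment is requested
REGION_PRIORITY = {r: i for i, r in enumerate(REGION_KINDS)}


@dataclass
class GeneModel:
    """A gene-level annotation record: span, strand and exon structure."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: missing or bad strand {self.strand!r}")
        if self.tx_end < self.tx_start:
            raise ValidationError(f"gene {self.gene_id}: end < start")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for a, b in self.exons:
            if b < a or a < self.tx_start or b > self.tx_end:
                raise ValidationError(f"gene {self.gene_id}: exon ({a},{b}) outside span")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end


@dataclass(frozen=True)
class RegionInterval:
    """A named region of one gene, 1-based inclusive coordinates."""

    gene_id: str
    region: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.region not in REGION_KINDS:
            raise ValidationError(f"unknown region kind {self.region!r}")
        if self.end < self.start:
            raise ValidationError(f"{self.gene_id}/{self.region}: end < start")

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass
class RegionAssignment:
    """Mapping from CpG site to its (gene_id, region) memberships."""

    memberships: dict

    def get(self, site: GenomicSite) -> list:
        return self.memberships.get(site, [])

    def sites_in_region(self, region: str) -> set:
        return {
            site
            for site, pairs in self.memberships.items()
            if any(r == region for _, r in pairs)
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (site.chrom, site.pos, site.strand, gene, region)
            for site, pairs in self.memberships.items()
            for gene, region in pairs
        ]
        return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "gene_id", "region"])


def load_gene_models(path) -> list:
    """Read gene-level records (with exons when present) from GFF3/GTF."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes = []
    for feature in db.features_of_type("gene"):
        exons = [
            (exon.start, exon.end)
            for exon in db.children(feature, featuretype="exon")
        ]
        if feature.strand not in ("+", "-"):
            raise ValidationError(f"gene {feature.id}: missing strand")
        genes.append(
            GeneModel(
                gene_id=feature.id,
                chrom=feature.seqid,
                strand=feature.strand,
                tx_start=feature.start,
                tx_end=feature.end,
                exons=exons,
            )
        )
    return genes


def write_gene_models(genes: Sequence[GeneModel], path) -> None:
    """Write gene (and exon) records as GFF3."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for g in genes:
            handle.write(
                f"{g.chrom}\tcrossmeth\tgene\t{g.tx_start}\t{g.tx_end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for k, (a, b) in enumerate(g.exons, start=1):
                handle.write(
                    f"{g.chrom}\tcrossmeth\texon\t{a}\t{b}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{k};Parent={g.gene_id}\n"
                )


def build_region_intervals(
    genes: Sequence[GeneModel],
    tss_up: int = 300,
    tss_down: int = 50,
    prom_up: int = 2000,
    prom_down: int = 200,
    flank: int = 10000,
) -> list:
    """Construct TSS/promoter/gene-body/flank intervals for every gene.

    All extents are truncated at coordinate 1 (logged); an upstream flank
    that would lie entirely before the chromosome start is dropped.
    """
    for name, value in (
        ("tss_up", tss_up),
        ("tss_down", tss_down),
        ("prom_up", prom_up),
        ("prom_down", prom_down),
        ("flank", flank),
    ):
        if value <= 0:
            raise ValidationError(f"{name} must be positive, got {value}")

    intervals: list[RegionInterval] = []
    for g in genes:
        if g.strand == "+":
            tss = g.tx_start
            windows = {
                "TSS": (tss - tss_up, tss + tss_down),
                "promoter": (tss - prom_up, tss + prom_down),
                "gene_body": (g.tx_start, g.tx_end),
                "up10kb": (g.tx_start - flank, g.tx_start - 1),
                "down10kb": (g.tx_end + 1, g.tx_end + flank),
            }
        else:
            tss = g.tx_end
            windows = {
                "TSS": (tss - tss_down, tss + tss_up),
                "promoter": (tss - prom_down, tss + prom_up),
                "gene_body": (g.tx_start, g.tx_end),
                "up10kb": (g.tx_end + 1, g.tx_end + flank),
                "down10kb": (g.tx_start - flank, g.tx_start - 1),
            }
        for region, (start, end) in windows.items():
            if end < 1:
                log.info("%s/%s lies entirely before coordinate 1; dropped", g.gene_id, region)
                continue
            if start < 1:
                log.info("%s/%s truncated at coordinate 1", g.gene_id, region)
                start = 1
            intervals.append(RegionInterval(g.gene_id, region, g.chrom, start, end))
    return intervals


def assign_sites_to_regions(
    sites: Sequence[GenomicSite],
    intervals: Sequence[RegionInterval],
    priority_assignment: bool = False,
) -> RegionAssignment:
    """Map each site to every (gene, region) interval containing it
    (endpoints inclusive).  With ``priority_assignment`` each site keeps,
    per gene, only its most regulatory category (TSS > promoter >
    gene_body > up10kb > down10kb)."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for iv in intervals:
        # intervaltree is half-open; +1 makes the 1-based end inclusive
        trees[iv.chrom].addi(iv.start, iv.end + 1, (iv.gene_id, iv.region))

    memberships: dict[GenomicSite, list] = {}
    for site in sites:
        hits = [hit.data for hit in trees[site.chrom][site.pos]] if site.chrom in trees else []
        hits.sort(key=lambda gr: (gr[0], REGION_PRIORITY[gr[1]]))
        if priority_assignment and hits:
            best: dict[str, tuple] = {}
            for gene, region in hits:
                if gene not in best or REGION_PRIORITY[region] < REGION_PRIORITY[best[gene][1]]:
                    best[gene] = (gene, region)
            hits = sorted(best.values())
        memberships[site] = hits
    return RegionAssignment(memberships)


def write_regions_bed(intervals: Sequence[RegionInterval], path) -> None:
    """BED6 export: 0-based half-open, name = gene_id|region."""
    with open(path, "w") as handle:
        for iv in intervals:
            handle.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.gene_id}|{iv.region}\t0\t.\n"
            )
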