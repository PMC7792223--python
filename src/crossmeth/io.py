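"""Readers and writers for methylation count tables and sample metadata.

Two on-disk dialects are supported:

* Bismark "coverage" files, one per sample: six whitespace/tab separated
  columns ``chrom start end pct_methylated count_methylated
  count_unmethylated`` with 1-based coordinates (start == end for a CpG).
* A wide TSV with one row per site and a ``<sample>.cov`` / ``<sample>.meth``
  column pair per sample, convenient for fixtures and checkpoints.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    GenomicSite,
    MethylationCountTable,
    MethylationProportionMatrix,
    SampleMeta,
    ValidationError,
)

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised for malformed input lines; message names file and line number."""


def _parse_coverage_line(line: str, path: str, lineno: int) -> tuple:
    fields = line.split()
    if len(fields) != 6:
        raise ParseError(f"{path}:{lineno}: expected 6 fields, got {len(fields)}")
    try:
        chrom = fields[0]
        start = int(fields[1])
        end = int(fields[2])
        n_meth = int(fields[4])
        n_unmeth = int(fields[5])
        float(fields[3])  # percent column, informational only
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from None
    if start < 1 or end < start:
        raise ParseError(f"{path}:{lineno}: bad coordinates {start}-{end}")
    if n_meth < 0 or n_unmeth < 0:
        raise ParseError(f"{path}:{lineno}: negative counts")
    return chrom, start, n_meth, n_meth + n_unmeth


def read_coverage_file(
    paths: Sequence, metas: Sequence[SampleMeta], strand: str = "+"
) -> MethylationCountTable:
    """Read one Bismark coverage file per sample and merge on the site union.

    Cells absent from a sample's file get coverage 0 (no imputation); the
    downstream minimum-coverage filter removes them.  Bismark coverage files
    carry no strand column, so all sites take ``strand`` (default ``+``).
    """
    if len(paths) != len(metas):
        raise ValidationError("one coverage file per sample is required")
    per_sample: list[dict] = []
    for path, meta in zip(paths, metas):
        counts: dict[GenomicSite, tuple[int, int]] = {}
        n_lines = 0
        with open(path) as handle:
            for lineno, raw in enumerate(handle, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                chrom, pos, n_meth, n_total = _parse_coverage_line(line, str(path), lineno)
                site = GenomicSite(chrom, pos, strand)
                if site in counts:
                    raise ParseError(f"{path}:{lineno}: duplicate site {chrom}:{pos}")
                counts[site] = (n_total, n_meth)
                n_lines += 1
        if n_lines == 0:
            log.warning("coverage file %s for sample %s is empty", path, meta.sample_id)
        per_sample.append(counts)

    all_sites = sorted(set().union(*per_sample)) if per_sample else []
    coverage = np.zeros((len(all_sites), len(metas)), dtype=np.int64)
    methylated = np.zeros_like(coverage)
    for j, counts in enumerate(per_sample):
        for i, site in enumerate(all_sites):
            if site in counts:
                coverage[i, j], methylated[i, j] = counts[site]
    return MethylationCountTable(all_sites, list(metas), coverage, methylated)


def write_coverage_file(table: MethylationCountTable, sample_index: int, path) -> None:
    """Write one sample's counts in Bismark coverage format (cells with
    coverage 0 are omitted, matching what a methylation caller would emit)."""
    cov = table.coverage[:, sample_index]
    meth = table.methylated[:, sample_index]
    with open(path, "w") as handle:
        for i, site in enumerate(table.sites):
            if cov[i] == 0:
                continue
            pct = 100.0 * meth[i] / cov[i]
            handle.write(
                f"{site.chrom}\t{site.pos}\t{site.pos}\t{pct:.6g}\t{meth[i]}\t{cov[i] - meth[i]}\n"
            )


def read_metadata(path) -> list[SampleMeta]:
    """Read the sample metadata TSV (sample_id, female_id, tissue, time_point,
    temperature_env, family_id, pool_id)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "female_id", "tissue", "time_point", "temperature_env"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing metadata columns {sorted(missing)}")
    metas = []
    for _, row in frame.iterrows():
        pool = row.get("pool_id")
        metas.append(
            SampleMeta(
                sample_id=row["sample_id"],
                female_id=row["female_id"],
                tissue=row["tissue"],
                time_point=int(row["time_point"]),
                temperature_env=row["temperature_env"],
                family_id=row.get("family_id", "") or "",
                pool_id=None if pd.isna(pool) or pool == "" else pool,
            )
        )
    return metas


def write_metadata(metas: Sequence[SampleMeta], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metas],
            "female_id": [m.female_id for m in metas],
            "tissue": [m.tissue for m in metas],
            "time_point": [m.time_point for m in metas],
            "temperature_env": [m.temperature_env for m in metas],
            "family_id": [m.family_id for m in metas],
            "pool_id": [m.pool_id if m.pool_id is not None else "" for m in metas],
        }
    ).to_csv(path, sep="\t", index=False)


def read_wide_counts(path, metas: Sequence[SampleMeta]) -> MethylationCountTable:
    """Read the wide TSV dialect: chrom, pos, strand, then ``<id>.cov`` and
    ``<id>.meth`` column pairs for every sample in ``metas``."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    sites = [
        GenomicSite(str(c), int(p), str(s))
        for c, p, s in zip(frame["chrom"], frame["pos"], frame["strand"])
    ]
    coverage = np.zeros((len(sites), len(metas)), dtype=np.int64)
    methylated = np.zeros_like(coverage)
    for j, meta in enumerate(metas):
        cov_col = f"{meta.sample_id}.cov"
        meth_col = f"{meta.sample_id}.meth"
        if cov_col not in frame.columns or meth_col not in frame.columns:
            raise ParseError(f"{path}: missing columns for sample {meta.sample_id}")
        coverage[:, j] = frame[cov_col].to_numpy()
        methylated[:, j] = frame[meth_col].to_numpy()
    return MethylationCountTable(sites, list(metas), coverage, methylated)


def write_wide_counts(table: MethylationCountTable, path, header: Optional[str] = None) -> None:
    data = {
        "chrom": [s.chrom for s in table.sites],
        "pos": [s.pos for s in table.sites],
        "strand": [s.strand for s in table.sites],
    }
    for j, meta in enumerate(table.samples):
        data[f"{meta.sample_id}.cov"] = table.coverage[:, j]
        data[f"{meta.sample_id}.meth"] = table.methylated[:, j]
    _write_tsv(pd.DataFrame(data), path, header)


def write_proportions(props: MethylationProportionMatrix, path, header: Optional[str] = None) -> None:
    data = {
        "chrom": [s.chrom for s in props.sites],
        "pos": [s.pos for s in props.sites],
        "strand": [s.strand for s in props.sites],
    }
    for j, meta in enumerate(props.samples):
        data[meta.sample_id] = props.values[:, j]
    _write_tsv(pd.DataFrame(data), path, header)


def _write_tsv(frame: pd.DataFrame, path, header: Optional[str] = None) -> None:
    """Write a TSV, optionally preceded by '#'-prefixed provenance lines."""
    with open(path, "w") as handle:
        if header:
            for line in header.splitlines():
                handle.write(f"# {line}\n")
        frame.to_csv(handle, sep="\t", index=False)
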