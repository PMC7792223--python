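"""Core domain types for cross-tissue methylation analysis.

The central container is :class:`MethylationCountTable`, a sites x samples
pair of integer matrices (total coverage and methylated read counts) for one
tissue, mirroring what an RRBS pipeline emits per CpG after alignment and
methylation calling.  All downstream statistics operate on these containers
or on the derived :class:`MethylationProportionMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-")
TISSUES = ("RBC", "liver", "hypothalamus", "ovary")
TEMPERATURE_ENVS = ("warm", "cold")


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass(frozen=True, order=True)
class GenomicSite:
    """A single CpG cytosine: chromosome, 1-based position, strand."""

    chrom: str
    pos: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"site position must be >= 1, got {self.pos}")
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}, got {self.strand!r}")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one biological sample (one female, one tissue)."""

    sample_id: str
    female_id: str
    tissue: str
    time_point: int
    temperature_env: str
    family_id: str = ""
    pool_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.time_point not in (1, 2, 3):
            raise ValidationError(f"time_point must be 1, 2 or 3, got {self.time_point}")
        if self.temperature_env not in TEMPERATURE_ENVS:
            raise ValidationError(
                f"temperature_env must be one of {TEMPERATURE_ENVS}, got {self.temperature_env!r}"
            )


@dataclass(frozen=True)
class ContrastSpec:
    """A time contrast: either a pairwise comparison or the omnibus time effect."""

    label: str
    time_a: Optional[int] = None
    time_b: Optional[int] = None

    def __post_init__(self) -> None:
        if self.label == "omnibus":
            if self.time_a is not None or self.time_b is not None:
                raise ValidationError("omnibus contrast takes no time points")
        else:
            if self.time_a is None or self.time_b is None:
                raise ValidationError("pairwise contrast needs time_a and time_b")
            if not self.time_a < self.time_b:
                raise ValidationError("time_a must precede time_b")

    @property
    def is_pairwise(self) -> bool:
        return self.label != "omnibus"

    @classmethod
    def delta12(cls) -> "ContrastSpec":
        return cls("d12", 1, 2)

    @classmethod
    def delta23(cls) -> "ContrastSpec":
        return cls("d23", 2, 3)

    @classmethod
    def omnibus(cls) -> "ContrastSpec":
        return cls("omnibus")


def _check_sample_set(samples: Sequence[SampleMeta]) -> None:
    tissues = {s.tissue for s in samples}
    if len(tissues) > 1:
        raise ValidationError(f"samples span several tissues: {sorted(tissues)}")
    pairs = [(s.female_id, s.tissue) for s in samples]
    if len(set(pairs)) != len(pairs):
        raise ValidationError("duplicate (female_id, tissue) among samples")


def _check_site_list(sites: Sequence[GenomicSite]) -> None:
    if len(set(sites)) != len(sites):
        raise ValidationError("duplicate (chrom, pos, strand) among sites")


@dataclass
class MethylationCountTable:
    """Per-CpG (coverage, methylated) counts for the samples of one tissue."""

    sites: list
    samples: list
    coverage: np.ndarray
    methylated: np.ndarray

    def __post_init__(self) -> None:
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        self.methylated = np.asarray(self.methylated, dtype=np.int64)
        shape = (len(self.sites), len(self.samples))
        if self.coverage.shape != shape or self.methylated.shape != shape:
            raise ValidationError(
                f"matrix shape {self.coverage.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        if (self.coverage < 0).any() or (self.methylated < 0).any():
            raise ValidationError("counts must be non-negative")
        if (self.methylated > self.coverage).any():
            raise ValidationError("methylated count exceeds coverage")
        _check_sample_set(self.samples)
        _check_site_list(self.sites)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def tissue(self) -> Optional[str]:
        return self.samples[0].tissue if self.samples else None

    def time_points(self) -> np.ndarray:
        return np.array([s.time_point for s in self.samples])

    def subset_sites(self, index) -> "MethylationCountTable":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.nonzero(index)[0]
        index = index.astype(np.int64, copy=False)
        return MethylationCountTable(
            sites=[self.sites[i] for i in index],
            samples=list(self.samples),
            coverage=self.coverage[index],
            methylated=self.methylated[index],
        )

    def proportions(self) -> "MethylationProportionMatrix":
        """Methylated / coverage; NaN where a cell has zero coverage."""
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.where(self.coverage > 0, self.methylated / np.maximum(self.coverage, 1), np.nan)
        return MethylationProportionMatrix(
            sites=list(self.sites), samples=list(self.samples), values=values
        )

    def site_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [s.chrom for s in self.sites],
                "pos": [s.pos for s in self.sites],
                "strand": [s.strand for s in self.sites],
            }
        )


@dataclass
class MethylationProportionMatrix:
    """Sites x samples matrix of methylation proportions in [0, 1]."""

    sites: list
    samples: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        shape = (len(self.sites), len(self.samples))
        if self.values.shape != shape:
            raise ValidationError("proportion matrix shape mismatch")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and ((finite < 0).any() or (finite > 1).any()):
            raise ValidationError("proportions must lie in [0, 1]")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def tissue(self) -> Optional[str]:
        return self.samples[0].tissue if self.samples else None

    def time_points(self) -> np.ndarray:
        return np.array([s.time_point for s in self.samples])

    def subset_sites(self, index) -> "MethylationProportionMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.nonzero(index)[0]
        index = index.astype(np.int64, copy=False)
        return MethylationProportionMatrix(
            sites=[self.sites[i] for i in index],
            samples=list(self.samples),
            values=self.values[index],
        )


@dataclass
class QCSampleStats:
    """Per-sample location/scale summaries plus homogeneity test p-values."""

    sample_ids: list
    means: np.ndarray
    variances: np.ndarray
    location_stat: float
    location_p: float
    scale_stat: float
    scale_p: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "mean": self.means, "variance": self.variances}
        )
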