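"""Domain types shared across the pipeline.

Coordinates are 1-based inclusive internally (pileup convention); BED-style
output written by :mod:`stratascan.io` is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SEXES = ("male", "female")
ASSAYS = ("dna", "rna")

#: canonical column order for site-count tables
SITE_COLUMNS = ["scaffold", "pos", "sample", "A", "C", "G", "T"]


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass(frozen=True)
class SampleInfo:
    """One sequenced individual."""

    sample_id: str
    sex: str
    population: str
    assay: str = "dna"

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not self.population:
            raise ValidationError("population must be non-empty")
        if self.assay not in ASSAYS:
            raise ValidationError(f"assay must be one of {ASSAYS}, got {self.assay!r}")


def validate_sample_sheet(samples: Sequence[SampleInfo]) -> None:
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate sample ids in sample sheet: {dup}")


@dataclass(frozen=True)
class GeneModel:
    """A gene interval on a scaffold, optionally anchored to a chromosome."""

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    chromosome: str | None = None
    strand: str = "."
    exonic_length: int | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"gene {self.gene_id}: need 1 <= start <= end, got {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        exl = self.exonic_length
        if exl is None:
            object.__setattr__(self, "exonic_length", self.end - self.start + 1)
        elif exl < 1:
            raise ValidationError(f"gene {self.gene_id}: exonic_length must be >= 1")


@dataclass(frozen=True)
class Chromosome:
    chrom_id: str
    length: int
    is_sex_chromosome: bool = False


@dataclass(frozen=True)
class ScaffoldPlacement:
    scaffold_id: str
    chromosome: str
    chrom_start: int  # 1-based inclusive
    chrom_end: int

    @property
    def length(self) -> int:
        return self.chrom_end - self.chrom_start + 1

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.chrom_start + self.chrom_end)


@dataclass
class GenomeLayout:
    """Ordered scaffold placements along chromosomes, one of which may be the
    sex chromosome."""

    chromosomes: list[Chromosome]
    scaffolds: list[ScaffoldPlacement] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_id = {c.chrom_id: c for c in self.chromosomes}
        if len(by_id) != len(self.chromosomes):
            raise ValidationError("duplicate chromosome ids")
        n_sex = sum(c.is_sex_chromosome for c in self.chromosomes)
        if n_sex > 1:
            raise ValidationError("at most one chromosome may be flagged as the sex chromosome")
        seen: set[str] = set()
        per_chrom: dict[str, list[ScaffoldPlacement]] = {}
        for s in self.scaffolds:
            if s.scaffold_id in seen:
                raise ValidationError(f"scaffold {s.scaffold_id} placed twice")
            seen.add(s.scaffold_id)
            if s.chromosome not in by_id:
                raise ValidationError(f"scaffold {s.scaffold_id} on unknown chromosome {s.chromosome}")
            if s.chrom_start < 1 or s.chrom_end < s.chrom_start:
                raise ValidationError(f"scaffold {s.scaffold_id}: bad interval")
            if s.chrom_end > by_id[s.chromosome].length:
                raise ValidationError(
                    f"scaffold {s.scaffold_id} extends past end of {s.chromosome}"
                )
            per_chrom.setdefault(s.chromosome, []).append(s)
        for chrom, placed in per_chrom.items():
            placed.sort(key=lambda s: s.chrom_start)
            for a, b in zip(placed, placed[1:]):
                if b.chrom_start <= a.chrom_end:
                    raise ValidationError(
                        f"scaffolds {a.scaffold_id} and {b.scaffold_id} overlap on {chrom}"
                    )

    @property
    def sex_chromosome(self) -> str | None:
        for c in self.chromosomes:
            if c.is_sex_chromosome:
                return c.chrom_id
        return None

    @property
    def autosomes(self) -> list[str]:
        return [c.chrom_id for c in self.chromosomes if not c.is_sex_chromosome]

    def chromosome_length(self, chrom_id: str) -> int:
        for c in self.chromosomes:
            if c.chrom_id == chrom_id:
                return c.length
        raise KeyError(chrom_id)

    def scaffolds_on(self, chrom_id: str) -> list[ScaffoldPlacement]:
        out = [s for s in self.scaffolds if s.chromosome == chrom_id]
        out.sort(key=lambda s: s.chrom_start)
        return out

    def scaffold_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scaffold": [s.scaffold_id for s in self.scaffolds],
                "chromosome": [s.chromosome for s in self.scaffolds],
                "chrom_start": [s.chrom_start for s in self.scaffolds],
                "chrom_end": [s.chrom_end for s in self.scaffolds],
            }
        )


@dataclass
class WindowTrack:
    """Moving-average values along one chromosome with a flat bootstrap band.

    ``positions`` are the unit (scaffold or gene) midpoints in bp spanned by
    each window's centre; ``values[i]`` is the mean over units ``i..i+window-1``.
    """

    chromosome: str
    positions: np.ndarray  # window midpoint, bp
    values: np.ndarray
    window: int
    ci_low: float
    ci_high: float
    window_starts: np.ndarray | None = None  # bp of first spanned unit
    window_ends: np.ndarray | None = None  # bp of last spanned unit

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValidationError("positions and values must align")
        if self.ci_low > self.ci_high:
            raise ValidationError("ci_low must be <= ci_high")

    @property
    def significant(self) -> np.ndarray:
        return (self.values < self.ci_low) | (self.values > self.ci_high)

    def to_frame(self) -> pd.DataFrame:
        n = len(self.values)
        starts = self.window_starts if self.window_starts is not None else self.positions
        ends = self.window_ends if self.window_ends is not None else self.positions
        return pd.DataFrame(
            {
                "chromosome": [self.chromosome] * n,
                "pos": self.positions,
                "window_start": np.asarray(starts, dtype=float),
                "window_end": np.asarray(ends, dtype=float),
                "value": self.values,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "significant": self.significant,
            }
        )


@dataclass(frozen=True)
class StratumCall:
    """A run of consecutive significant windows interpreted as a stratum."""

    chromosome: str
    start: int  # bp, 1-based inclusive
    end: int
    evidence: str  # coverage_deficit | snp_excess
    n_windows: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError("stratum end must exceed start")
        if self.evidence not in ("coverage_deficit", "snp_excess"):
            raise ValidationError(f"unknown evidence class {self.evidence!r}")


def site_counts_frame(
    scaffold: Iterable[str],
    pos: Iterable[int],
    sample: Iterable[str],
    counts: np.ndarray,
) -> pd.DataFrame:
    """Assemble a canonical site-count table (one row per site per sample)."""
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValidationError("counts must be an (n, 4) array of A,C,G,T")
    if (counts < 0).any():
        raise ValidationError("negative allele counts")
    df = pd.DataFrame(
        {
            "scaffold": pd.Series(scaffold, dtype=str),
            "pos": pd.Series(pos, dtype=np.int64),
            "sample": pd.Series(sample, dtype=str),
            "A": counts[:, 0].astype(np.int64),
            "C": counts[:, 1].astype(np.int64),
            "G": counts[:, 2].astype(np.int64),
            "T": counts[:, 3].astype(np.int64),
        }
    )
    if (df["pos"] < 1).any():
        raise ValidationError("positions must be >= 1")
    return df


def coverage_of(sites: pd.DataFrame) -> pd.Series:
    """Per-row site coverage: A+C+G+T."""
    return sites[["A", "C", "G", "T"]].sum(axis=1)
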