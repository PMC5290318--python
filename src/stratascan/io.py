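"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats
-------
site counts   TSV ``scaffold pos sample A C G T`` or samtools text pileup
              (one sample per file).
gene table    BED6+ — ``chrom start end name score strand exonic_length``
              where chrom is the *scaffold* and name the gene id.
sample sheet  TSV ``sample_id sex population assay``.
layout        TSV with a chromosome section and a scaffold-placement section.
track         BED-like TSV, 0-based half-open on disk.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .model import (
    Chromosome,
    GeneModel,
    GenomeLayout,
    SampleInfo,
    ScaffoldPlacement,
    ValidationError,
    WindowTrack,
    site_counts_frame,
    validate_sample_sheet,
)

log = logging.getLogger(__name__)

_SITE_HEADER = ["scaffold", "pos", "sample", "A", "C", "G", "T"]


class ParseError(ValueError):
    def __init__(self, path, lineno: int, msg: str):
        super().__init__(f"{path}:{lineno}: {msg}")
        self.lineno = lineno


# ---------------------------------------------------------------------------
# site counts
# ---------------------------------------------------------------------------

def read_site_counts(
    path: str | Path,
    format: str = "tsv",
    sample_id: str | None = None,
) -> pd.DataFrame:
    """Read per-site allele counts.

    ``format='tsv'`` expects the canonical seven-column table (header
    optional).  ``format='mpileup'`` decodes samtools text pileup for a single
    sample; ``sample_id`` then names that sample.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_counts_tsv(path)
    if format == "mpileup":
        if sample_id is None:
            raise ValidationError("sample_id is required for mpileup input")
        return _read_mpileup(path, sample_id)
    raise ValidationError(f"unknown site-count format {format!r}")


def _read_counts_tsv(path: Path) -> pd.DataFrame:
    rows: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[:2] == ["scaffold", "pos"]:  # header
                continue
            if len(parts) != 7:
                raise ParseError(path, lineno, f"expected 7 columns, got {len(parts)}")
            try:
                counts = [int(p) for p in parts[3:7]]
                pos = int(parts[1])
            except ValueError as e:
                raise ParseError(path, lineno, f"non-integer field: {e}") from None
            if any(c < 0 for c in counts):
                raise ParseError(path, lineno, "negative allele count")
            if pos < 1:
                raise ParseError(path, lineno, "position must be >= 1")
            rows.append((parts[0], pos, parts[2], *counts))
    if not rows:
        log.warning("no site-count records in %s", path)
        return site_counts_frame([], [], [], np.empty((0, 4), dtype=int))
    df = pd.DataFrame(rows, columns=_SITE_HEADER)
    return site_counts_frame(
        df["scaffold"], df["pos"], df["sample"], df[["A", "C", "G", "T"]].to_numpy()
    )


def write_site_counts(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, columns=_SITE_HEADER)
    return path


_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_INDEL_RE = re.compile(r"[+-](\d+)")


def decode_pileup_bases(bases: str, ref: str) -> tuple[int, int, int, int]:
    """Decode one mpileup read-base string into A,C,G,T counts.

    Handles ``. ,`` (reference match), ``ACGTacgt`` (mismatch), ``^X`` read
    start with mapping quality, ``$`` read end, ``+n``/``-n`` indels and
    ``*``/``N`` placeholders (skipped).
    """
    counts = [0, 0, 0, 0]
    ref_idx = _BASE_IDX.get(ref.upper())
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # caret + mapping-quality char
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            m = _INDEL_RE.match(bases, i)
            if not m:
                raise ValueError(f"malformed indel at offset {i} in {bases!r}")
            length = int(m.group(1))
            i = m.end() + length
            continue
        if c in ".,":
            if ref_idx is None:
                raise ValueError(f"reference-match symbol with ambiguous ref {ref!r}")
            counts[ref_idx] += 1
        else:
            idx = _BASE_IDX.get(c.upper())
            if idx is not None:
                counts[idx] += 1
            # '*', 'N', '<', '>' carry no allele information
        i += 1
    return tuple(counts)  # type: ignore[return-value]


def _read_mpileup(path: Path, sample_id: str) -> pd.DataFrame:
    scaffolds: list[str] = []
    positions: list[int] = []
    counts: list[tuple[int, int, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ParseError(path, lineno, f"expected >=5 pileup columns, got {len(parts)}")
            scaf, pos_s, ref, depth_s, bases = parts[:5]
            try:
                pos = int(pos_s)
                int(depth_s)
            except ValueError:
                raise ParseError(path, lineno, "non-integer position/depth") from None
            try:
                cnt = decode_pileup_bases(bases, ref)
            except ValueError as e:
                raise ParseError(path, lineno, str(e)) from None
            scaffolds.append(scaf)
            positions.append(pos)
            counts.append(cnt)
    if not counts:
        log.warning("no pileup records in %s", path)
        return site_counts_frame([], [], [], np.empty((0, 4), dtype=int))
    return site_counts_frame(
        scaffolds, positions, [sample_id] * len(positions), np.array(counts)
    )


# ---------------------------------------------------------------------------
# scaffold -> chromosome assignment
# ---------------------------------------------------------------------------

def assign_scaffolds(
    gene_hits: pd.DataFrame,
    threshold: float = 0.70,
    scaffold_lengths: dict[str, int] | None = None,
) -> GenomeLayout:
    """Assign scaffolds to chromosomes by gene-hit majority and order them.

    ``gene_hits`` needs columns ``gene_id, scaffold_id, ref_chromosome,
    ref_start`` with one row per gene (multi-hit genes resolved upstream).  A
    scaffold is assigned to the chromosome carrying at least ``threshold`` of
    its genes, otherwise discarded; assigned scaffolds are ordered along each
    chromosome by the median reference start of their genes and laid
    end-to-end.  Physical scaffold lengths may be supplied; the fallback is
    the bp span of the scaffold's mapped genes.
    """
    if gene_hits.empty:
        raise ValidationError("empty gene-hit table")
    if not 0.5 < threshold <= 1.0:
        raise ValidationError(f"threshold must be in (0.5, 1], got {threshold}")
    required = {"gene_id", "scaffold_id", "ref_chromosome", "ref_start"}
    missing = required - set(gene_hits.columns)
    if missing:
        raise ValidationError(f"gene-hit table missing columns {sorted(missing)}")
    if gene_hits["gene_id"].duplicated().any():
        raise ValidationError("gene-hit table must contain exactly one hit per gene")

    # deterministic regardless of input row order
    hits = gene_hits.sort_values(["scaffold_id", "gene_id"], kind="mergesort")

    assigned: dict[str, tuple[str, float, int]] = {}  # scaffold -> (chrom, order key, length)
    n_discarded = 0
    for scaffold, grp in hits.groupby("scaffold_id", sort=True):
        frac = grp["ref_chromosome"].value_counts(normalize=True)
        top_chrom = frac.idxmax()
        if frac.max() < threshold:
            n_discarded += 1
            continue
        on_top = grp[grp["ref_chromosome"] == top_chrom]
        order_key = float(on_top["ref_start"].median())
        if scaffold_lengths and scaffold in scaffold_lengths:
            length = int(scaffold_lengths[scaffold])
        else:
            length = max(int(on_top["ref_start"].max() - on_top["ref_start"].min()) + 1, 1)
        assigned[scaffold] = (str(top_chrom), order_key, length)
    if n_discarded:
        log.info("discarded %d scaffolds below the %.0f%% majority threshold",
                 n_discarded, 100 * threshold)

    placements: list[ScaffoldPlacement] = []
    chrom_lengths: dict[str, int] = {}
    by_chrom: dict[str, list[tuple[float, str, int]]] = {}
    for scaffold, (chrom, key, length) in assigned.items():
        by_chrom.setdefault(chrom, []).append((key, scaffold, length))
    for chrom in sorted(by_chrom):
        cursor = 1
        for _, scaffold, length in sorted(by_chrom[chrom]):
            placements.append(
                ScaffoldPlacement(scaffold, chrom, cursor, cursor + length - 1)
            )
            cursor += length
        chrom_lengths[chrom] = cursor - 1
    chromosomes = [Chromosome(c, chrom_lengths[c]) for c in sorted(chrom_lengths)]
    return GenomeLayout(chromosomes=chromosomes, scaffolds=placements)


# ---------------------------------------------------------------------------
# layout, genes, samples
# ---------------------------------------------------------------------------

def write_layout(layout: GenomeLayout, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#chromosome\tlength\tis_sex_chromosome\n")
        for c in layout.chromosomes:
            fh.write(f"C\t{c.chrom_id}\t{c.length}\t{int(c.is_sex_chromosome)}\n")
        fh.write("#scaffold\tchromosome\tchrom_start\tchrom_end\n")
        for s in layout.scaffolds:
            fh.write(f"S\t{s.scaffold_id}\t{s.chromosome}\t{s.chrom_start}\t{s.chrom_end}\n")
    return path


def read_layout(path: str | Path) -> GenomeLayout:
    chromosomes: list[Chromosome] = []
    scaffolds: list[ScaffoldPlacement] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "C" and len(parts) == 4:
                chromosomes.append(Chromosome(parts[1], int(parts[2]), bool(int(parts[3]))))
            elif parts[0] == "S" and len(parts) == 5:
                scaffolds.append(
                    ScaffoldPlacement(parts[1], parts[2], int(parts[3]), int(parts[4]))
                )
            else:
                raise ParseError(path, lineno, f"unrecognized layout record {parts[0]!r}")
    return GenomeLayout(chromosomes=chromosomes, scaffolds=scaffolds)


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read genes from BED6+ (scaffold, 0-based start, end, gene_id, score,
    strand[, exonic_length])."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(path, lineno, "need at least 6 BED columns")
            try:
                start0, end0 = int(parts[1]), int(parts[2])
                exonic = int(parts[6]) if len(parts) > 6 else None
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinate") from None
            genes.append(
                GeneModel(
                    gene_id=parts[3],
                    scaffold_id=parts[0],
                    start=start0 + 1,
                    end=end0,
                    strand=parts[5],
                    exonic_length=exonic,
                )
            )
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.scaffold_id}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}"
                f"\t{g.exonic_length}\n"
            )
    return path


def read_sample_sheet(path: str | Path) -> list[SampleInfo]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "sex", "population"}
    if not required <= set(df.columns):
        raise ValidationError(f"sample sheet must have columns {sorted(required)}")
    samples = [
        SampleInfo(
            sample_id=r.sample_id,
            sex=r.sex,
            population=r.population,
            assay=getattr(r, "assay", "dna") or "dna",
        )
        for r in df.itertuples()
    ]
    validate_sample_sheet(samples)
    return samples


def write_sample_sheet(samples: Iterable[SampleInfo], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "sex": [s.sex for s in samples],
            "population": [s.population for s in samples],
            "assay": [s.assay for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# window tracks
# ---------------------------------------------------------------------------

_TRACK_HEADER = ["chrom", "start", "end", "value", "ci_low", "ci_high", "significant"]


def write_track(track: WindowTrack, path: str | Path) -> Path:
    """Write a window track as BED-like TSV (0-based half-open)."""
    path = Path(path)
    pos = track.positions
    if np.any(np.diff(pos) < 0):
        raise ValidationError("track positions must be sorted")
    df = track.to_frame()
    out = pd.DataFrame(
        {
            "chrom": df["chromosome"],
            "start": (df["pos"].round().astype(np.int64) - 1).clip(lower=0),
            "end": df["pos"].round().astype(np.int64),
            "value": df["value"].map(lambda v: f"{v:.10f}"),
            "ci_low": df["ci_low"].map(lambda v: f"{v:.10f}"),
            "ci_high": df["ci_high"].map(lambda v: f"{v:.10f}"),
            "significant": df["significant"].astype(int),
        }
    )
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_TRACK_HEADER) + "\n")
        out.to_csv(fh, sep="\t", index=False, header=False)
    return path


def read_track(path: str | Path, window: int = 0) -> WindowTrack:
    df = pd.read_csv(path, sep="\t", comment="#", names=_TRACK_HEADER)
    if df.empty:
        return WindowTrack("", np.array([]), np.array([]), window, 0.0, 0.0)
    ci_low = float(df["ci_low"].iloc[0])
    ci_high = float(df["ci_high"].iloc[0])
    return WindowTrack(
        chromosome=str(df["chrom"].iloc[0]),
        positions=df["end"].to_numpy(dtype=float),
        values=df["value"].to_numpy(dtype=float),
        window=window,
        ci_low=ci_low,
        ci_high=ci_high,
    )
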