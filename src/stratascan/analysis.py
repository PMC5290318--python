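"""In-memory composition of the per-stage statistics.

These functions chain the elementary operations in :mod:`stratascan.sexdiff`
into the tables the scans and tests consume, without touching disk; the
file-based pipeline stages are thin wrappers around them.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import GenomeLayout, SampleInfo, ValidationError
from .sexdiff import (
    call_snp_sites,
    coverage_contrast,
    gene_snp_density,
    normalize_by_x_median,
    relative_to_reference,
    snp_density_contrast,
)


def genes_from_layout(layout: GenomeLayout) -> pd.DataFrame:
    """One genic unit per placed scaffold, spanning it (the synthetic
    genome's annotation)."""
    rows = [
        {
            "gene_id": f"gene_{s.scaffold_id}",
            "scaffold": s.scaffold_id,
            "start": 1,
            "end": s.length,
            "chromosome": s.chromosome,
            "pos": int(s.midpoint),
        }
        for s in layout.scaffolds
    ]
    return pd.DataFrame(rows)


def coverage_table(
    counts: pd.DataFrame,
    samples: Sequence[SampleInfo],
    layout: GenomeLayout,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-scaffold M:F coverage contrast with genomic coordinates, ordered
    along each chromosome."""
    cov = coverage_contrast(counts, samples, pseudocount=pseudocount)
    scaf = layout.scaffold_table()
    scaf["pos"] = (scaf["chrom_start"] + scaf["chrom_end"]) // 2
    cov = cov.merge(scaf[["scaffold", "chromosome", "pos"]], on="scaffold")
    return cov.sort_values(["chromosome", "pos"]).reset_index(drop=True)


def density_table(
    counts: pd.DataFrame,
    samples: Sequence[SampleInfo],
    genes: pd.DataFrame,
    min_cov: int = 10,
    minor_frac: float = 0.3,
    pseudocount: float = 1.0,
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-gene M:F SNP-density contrast with genomic coordinates."""
    flagged = call_snp_sites(counts, min_cov=min_cov, minor_frac=minor_frac)
    dens = gene_snp_density(flagged, genes)
    contrast = snp_density_contrast(dens, samples, pseudocount=pseudocount,
                                    pooled=pooled)
    contrast = contrast.merge(genes[["gene_id", "chromosome", "pos"]], on="gene_id")
    return contrast.sort_values(["chromosome", "pos"]).reset_index(drop=True)


def normalized_density_series(
    counts: pd.DataFrame,
    samples: Sequence[SampleInfo],
    genes: pd.DataFrame,
    sex: str,
    min_cov: int = 10,
    minor_frac: float = 0.3,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene mean SNP density of one sex, logged and normalized by the
    X-chromosome median (so populations of different overall diversity become
    comparable)."""
    flagged = call_snp_sites(counts, min_cov=min_cov, minor_frac=minor_frac)
    dens = gene_snp_density(flagged, genes)
    sex_ids = {s.sample_id for s in samples if s.sex == sex}
    if not sex_ids:
        raise ValidationError(f"no {sex} samples in this population")
    sub = dens[dens["sample"].isin(sex_ids)]
    per_gene = sub.groupby("gene_id", observed=True)["snp_density"].mean()
    logged = np.log2(per_gene + pseudocount)
    sex_chrom_ids = genes.loc[genes["chromosome"] == _sex_chromosome(genes), "gene_id"]
    return normalize_by_x_median(logged, sex_chrom_ids)


def _sex_chromosome(genes: pd.DataFrame) -> str:
    for c in genes["chromosome"].unique():
        if str(c).lower().endswith("x"):
            return c
    raise ValidationError("no sex chromosome recognizable in gene table")


def population_table(
    datasets: Mapping[str, tuple[pd.DataFrame, Sequence[SampleInfo]]],
    genes: pd.DataFrame,
    min_cov: int = 10,
    minor_frac: float = 0.3,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """The convergence-test gene table.

    One row per gene with columns ``chromosome, pos, lab`` (lab M:F log2 SNP
    density) and one column per wild population: its X-median-normalized male
    SNP density relative to the normalized lab-female reference.
    """
    if "lab" not in datasets:
        raise ValidationError("datasets must include the 'lab' reference")
    lab_counts, lab_samples = datasets["lab"]
    lab = density_table(lab_counts, lab_samples, genes, min_cov, minor_frac,
                        pseudocount)
    table = genes[["gene_id", "chromosome", "pos"]].set_index("gene_id")
    table["lab"] = lab.set_index("gene_id")["log2_mf"]
    lab_female = normalized_density_series(
        lab_counts, lab_samples, genes, "female", min_cov, minor_frac, pseudocount
    )
    for name, (counts, samples) in datasets.items():
        if name == "lab":
            continue
        pop_male = normalized_density_series(
            counts, samples, genes, "male", min_cov, minor_frac, pseudocount
        )
        table[name] = relative_to_reference(pop_male, lab_female)
    return table.reset_index()
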