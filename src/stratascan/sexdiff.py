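"""Male/female contrast statistics: scaffold coverage, genic SNP density and
expression, each summarized as a pseudocounted log2 M:F ratio.

Conventions
-----------
* A site is "sequenced" when at least one read covers it; unsequenced sites
  never enter a coverage denominator.
* SNP calling: sites with coverage below ``min_cov`` are excluded from both
  numerator and denominator; among retained sites a SNP is called when the
  second-most-frequent allele count is at least ``minor_frac`` times the site
  coverage (equivalently, major-allele fraction ≤ 1 − minor_frac).
* Every logged quantity receives a +1 pseudocount before log2, including
  densities in [0, 1]: log2(x + 1) − log2(y + 1).
* Per-population per-sex summaries are means of per-individual values.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import SampleInfo, ValidationError, coverage_of

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# elementary contrasts
# ---------------------------------------------------------------------------

def mf_log2_ratio(m, f, pseudocount: float = 1.0):
    """log2(m + pseudocount) − log2(f + pseudocount); accepts scalars or arrays."""
    m = np.asarray(m, dtype=float)
    f = np.asarray(f, dtype=float)
    if (m < 0).any() or (f < 0).any():
        raise ValidationError("mf_log2_ratio requires non-negative inputs")
    out = np.log2(m + pseudocount) - np.log2(f + pseudocount)
    return float(out) if out.ndim == 0 else out


def _sex_of(samples: Sequence[SampleInfo]) -> dict[str, str]:
    return {s.sample_id: s.sex for s in samples}


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def scaffold_coverage(sites: pd.DataFrame) -> pd.DataFrame:
    """Mean depth per (scaffold, sample) over sequenced sites.

    Rows with zero total count are treated as unsequenced and excluded;
    (scaffold, sample) pairs with no sequenced site are absent from the
    result (flagged missing, logged).
    """
    df = sites.copy()
    df["coverage"] = coverage_of(df)
    n_pairs = df.groupby(["scaffold", "sample"], observed=True).size().shape[0]
    df = df[df["coverage"] > 0]
    out = (
        df.groupby(["scaffold", "sample"], observed=True)["coverage"]
        .mean()
        .rename("mean_coverage")
        .reset_index()
    )
    if len(out) < n_pairs:
        log.info("%d scaffold×sample pairs had no sequenced sites and were dropped",
                 n_pairs - len(out))
    return out


def coverage_contrast(
    sites: pd.DataFrame,
    samples: Sequence[SampleInfo],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-scaffold male/female mean coverage and log2 M:F contrast."""
    cov = scaffold_coverage(sites)
    cov["sex"] = cov["sample"].map(_sex_of(samples))
    if cov["sex"].isna().any():
        unknown = cov.loc[cov["sex"].isna(), "sample"].unique()
        raise ValidationError(f"samples missing from sample sheet: {list(unknown)[:5]}")
    per_sex = (
        cov.groupby(["scaffold", "sex"], observed=True)["mean_coverage"]
        .mean()
        .unstack("sex")
    )
    per_sex = per_sex.dropna(subset=["male", "female"])
    per_sex["log2_mf"] = mf_log2_ratio(
        per_sex["male"].to_numpy(), per_sex["female"].to_numpy(), pseudocount
    )
    return per_sex.reset_index().rename(
        columns={"male": "male_mean", "female": "female_mean"}
    )


# ---------------------------------------------------------------------------
# SNP density
# ---------------------------------------------------------------------------

def call_snp_sites(
    sites: pd.DataFrame, min_cov: int = 10, minor_frac: float = 0.3
) -> pd.DataFrame:
    """Flag SNP sites per row of a site-count table.

    Adds ``coverage``, ``retained`` (coverage ≥ min_cov) and ``is_snp``
    (retained and second allele ≥ minor_frac × coverage) columns.
    """
    if min_cov < 1:
        raise ValidationError("min_cov must be >= 1")
    if not 0 < minor_frac <= 0.5:
        raise ValidationError("minor_frac must be in (0, 0.5]")
    counts = sites[["A", "C", "G", "T"]].to_numpy(dtype=np.int64)
    cov = counts.sum(axis=1)
    second = np.partition(counts, 2, axis=1)[:, 2]
    retained = cov >= min_cov
    out = sites.copy()
    out["coverage"] = cov
    out["retained"] = retained
    out["is_snp"] = retained & (second >= minor_frac * cov)
    return out


def gene_snp_density(
    flagged: pd.DataFrame,
    genes: pd.DataFrame,
) -> pd.DataFrame:
    """Per-(gene, sample) SNP density over retained genic sites.

    ``genes`` needs columns ``gene_id, scaffold, start, end`` (1-based
    inclusive).  Only sites inside a gene count; (gene, sample) cells with
    zero retained sites are dropped.
    """
    required = {"gene_id", "scaffold", "start", "end"}
    if not required <= set(genes.columns):
        raise ValidationError(f"gene table must have columns {sorted(required)}")
    sites = flagged[flagged["retained"]]
    merged = sites.merge(genes[["gene_id", "scaffold", "start", "end"]], on="scaffold")
    merged = merged[(merged["pos"] >= merged["start"]) & (merged["pos"] <= merged["end"])]
    grouped = merged.groupby(["gene_id", "sample"], observed=True)
    dens = grouped.agg(
        snp_sites=("is_snp", "sum"), filtered_sites=("is_snp", "size")
    ).reset_index()
    dens = dens[dens["filtered_sites"] > 0]
    dens["snp_density"] = dens["snp_sites"] / dens["filtered_sites"]
    return dens


def snp_density_contrast(
    density: pd.DataFrame,
    samples: Sequence[SampleInfo],
    pseudocount: float = 1.0,
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-gene per-sex SNP density and the log2 M:F contrast.

    Default: per-sex density is the mean of per-individual densities.  With
    ``pooled=True`` SNP and filtered-site counts are summed across a sex's
    individuals before dividing.
    """
    df = density.copy()
    df["sex"] = df["sample"].map(_sex_of(samples))
    if df["sex"].isna().any():
        unknown = df.loc[df["sex"].isna(), "sample"].unique()
        raise ValidationError(f"samples missing from sample sheet: {list(unknown)[:5]}")
    if pooled:
        sums = df.groupby(["gene_id", "sex"], observed=True)[
            ["snp_sites", "filtered_sites"]
        ].sum()
        per_sex = (sums["snp_sites"] / sums["filtered_sites"]).unstack("sex")
    else:
        per_sex = (
            df.groupby(["gene_id", "sex"], observed=True)["snp_density"]
            .mean()
            .unstack("sex")
        )
    for sex in ("male", "female"):
        if sex not in per_sex.columns:
            per_sex[sex] = np.nan
    n_before = len(per_sex)
    per_sex = per_sex.dropna(subset=["male", "female"])
    if len(per_sex) < n_before:
        log.info("%d genes lacked data in one sex and were dropped", n_before - len(per_sex))
    per_sex["log2_mf"] = mf_log2_ratio(
        per_sex["male"].to_numpy(), per_sex["female"].to_numpy(), pseudocount
    )
    return per_sex.reset_index().rename(
        columns={"male": "male_density", "female": "female_density"}
    )


def per_sample_log2_density(
    density: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """log2(density + pseudocount) per (gene, sample) — the unit the wild-
    population normalization works on."""
    df = density.copy()
    df["log2_density"] = np.log2(df["snp_density"] + pseudocount)
    return df[["gene_id", "sample", "log2_density"]]


# ---------------------------------------------------------------------------
# normalization for cross-population comparison
# ---------------------------------------------------------------------------

def normalize_by_x_median(values: pd.Series, x_gene_ids: Iterable[str]) -> pd.Series:
    """Subtract the median over X-linked genes, so the X median becomes 0.

    ``values`` is a per-gene series (one population+sex); ``x_gene_ids`` the
    X-linked subset of its index.
    """
    x_ids = [g for g in x_gene_ids if g in values.index]
    if not x_ids:
        raise ValidationError("no X-linked genes available for normalization")
    return values - float(values.loc[x_ids].median())


def relative_to_reference(pop_values: pd.Series, ref_values: pd.Series) -> pd.Series:
    """Population value minus reference (lab-female) value on shared genes."""
    shared = pop_values.index.intersection(ref_values.index)
    if len(shared) == 0:
        raise ValidationError("no genes shared with the reference")
    dropped = (len(pop_values) - len(shared)) + (len(ref_values) - len(shared))
    if dropped:
        log.info("%d gene entries outside the shared set were dropped", dropped)
    return pop_values.loc[shared] - ref_values.loc[shared]


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def rpkm(
    counts: pd.DataFrame,
    exonic_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Reads per kilobase of exon per million mapped reads.

    ``counts`` is gene×sample; ``library_sizes`` defaults to per-sample
    column sums of the retained genes.
    """
    lengths = exonic_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValidationError("every gene needs an exonic length")
    if (lengths < 1).any():
        raise ValidationError("exonic lengths must be >= 1")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if library_sizes.isna().any() or (library_sizes <= 0).any():
        raise ValidationError("library sizes must be positive for every sample")
    return counts.div(lengths / 1e3, axis=0).div(library_sizes / 1e6, axis=1)


def expression_filter(
    rpkm_matrix: pd.DataFrame,
    samples: Sequence[SampleInfo],
    threshold: float = 2.0,
) -> pd.Index:
    """Genes expressed at ≥ threshold RPKM in at least half the individuals
    of either sex."""
    sex_of = _sex_of(samples)
    males = [c for c in rpkm_matrix.columns if sex_of.get(c) == "male"]
    females = [c for c in rpkm_matrix.columns if sex_of.get(c) == "female"]
    if not males or not females:
        raise ValidationError("expression filter needs at least one sample of each sex")
    ok_m = (rpkm_matrix[males] >= threshold).sum(axis=1) >= math.ceil(len(males) / 2)
    ok_f = (rpkm_matrix[females] >= threshold).sum(axis=1) >= math.ceil(len(females) / 2)
    return rpkm_matrix.index[ok_m | ok_f]


def expression_contrast(
    rpkm_matrix: pd.DataFrame,
    samples: Sequence[SampleInfo],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene mean RPKM by sex and the log2 M:F expression ratio."""
    sex_of = _sex_of(samples)
    males = [c for c in rpkm_matrix.columns if sex_of.get(c) == "male"]
    females = [c for c in rpkm_matrix.columns if sex_of.get(c) == "female"]
    if not males or not females:
        raise ValidationError("need at least one sample of each sex")
    out = pd.DataFrame(
        {
            "male_mean": rpkm_matrix[males].mean(axis=1),
            "female_mean": rpkm_matrix[females].mean(axis=1),
        }
    )
    out["log2_mf"] = mf_log2_ratio(
        out["male_mean"].to_numpy(), out["female_mean"].to_numpy(), pseudocount
    )
    out.index.name = "gene_id"
    return out.reset_index()
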