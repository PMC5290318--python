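"""Faster-X divergence aggregation and inference.

Per-ortholog substitution counts (from branch-model codon analyses run
upstream) are filtered, then aggregated per genomic category by summing
substitutions and sites before dividing — dN = ΣDN/ΣN, dS = ΣDS/ΣS,
ω = dN/dS — which avoids the unstable per-gene ratios of short or
low-dS genes.  Between-category differences are assessed by label
permutation; uncertainty by bootstrap over genes within a category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ValidationError

log = logging.getLogger(__name__)

ORTHOLOG_COLUMNS = ["gene_id", "category", "DN", "DS", "N", "S", "branch_ds", "aln_len"]
STATISTICS = ("dN", "dS", "omega")


def read_ortholog_table(path) -> pd.DataFrame:
    """Read a per-ortholog divergence TSV.

    Accepts either substitution counts (columns ``DN, DS``) or per-gene rates
    (``dn, ds``), in which case counts are reconstructed as rate × sites.
    """
    df = pd.read_csv(path, sep="\t")
    cols = set(df.columns)
    if not {"N", "S"} <= cols:
        raise ValidationError("ortholog table needs site-count columns N and S")
    if not {"DN", "DS"} <= cols:
        if {"dn", "ds"} <= cols:
            df["DN"] = df["dn"] * df["N"]
            df["DS"] = df["ds"] * df["S"]
        else:
            raise ValidationError("ortholog table needs (DN, DS) or (dn, ds)")
    if "branch_ds" not in cols:
        df["branch_ds"] = df["DS"] / df["S"]
    if "aln_len" not in cols:
        df["aln_len"] = df["N"] + df["S"]
    return validate_orthologs(df)


def validate_orthologs(rows: pd.DataFrame) -> pd.DataFrame:
    if (rows["N"] <= 0).any() or (rows["S"] <= 0).any():
        raise ValidationError("site counts N and S must be positive")
    if (rows[["DN", "DS"]] < 0).to_numpy().any():
        raise ValidationError("substitution counts must be non-negative")
    if (rows["aln_len"] < 0).any():
        raise ValidationError("alignment lengths must be non-negative")
    return rows


def filter_orthologs(
    rows: pd.DataFrame, min_len: int = 300, max_ds: float = 2.0
) -> pd.DataFrame:
    """Drop short alignments (< min_len bp) and saturated genes (dS > max_ds);
    boundary values are retained."""
    short = rows["aln_len"] < min_len
    saturated = rows["branch_ds"] > max_ds
    if short.any() or saturated.any():
        log.info("filtered %d short and %d saturated orthologs",
                 int(short.sum()), int(saturated.sum()))
    return rows[~short & ~saturated].reset_index(drop=True)


@dataclass
class CategoryDivergence:
    category: str
    n_genes: int
    dN: float
    dS: float
    omega: float  # NaN when ΣDS = 0
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "category": self.category,
            "n_genes": self.n_genes,
            "dN": self.dN,
            "dS": self.dS,
            "omega": self.omega,
        }
        for stat, (lo, hi) in self.ci.items():
            d[f"{stat}_ci_low"] = lo
            d[f"{stat}_ci_high"] = hi
        return d


def _sums_to_stats(dn_sum, n_sum, ds_sum, s_sum):
    dN = np.asarray(dn_sum, dtype=float) / np.asarray(n_sum, dtype=float)
    dS = np.asarray(ds_sum, dtype=float) / np.asarray(s_sum, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = np.where(dS > 0, dN / np.where(dS > 0, dS, 1.0), np.nan)
    return dN, dS, omega


def aggregate_divergence(rows: pd.DataFrame, category: str) -> CategoryDivergence:
    """Sum-then-divide divergence for one category (never a mean of per-gene
    ratios)."""
    sub = rows[rows["category"] == category]
    if sub.empty:
        raise ValidationError(f"no orthologs in category {category!r}")
    dn_sum, n_sum = float(sub["DN"].sum()), float(sub["N"].sum())
    ds_sum, s_sum = float(sub["DS"].sum()), float(sub["S"].sum())
    dN, dS, omega = _sums_to_stats(dn_sum, n_sum, ds_sum, s_sum)
    if ds_sum == 0:
        log.warning("category %s has zero synonymous substitutions; omega undefined",
                    category)
    return CategoryDivergence(category, len(sub), float(dN), float(dS), float(omega))


def _stat_from_arrays(DN, DS, N, S, statistic: str):
    """Statistic over axis −1 sums; works on (reps, n) permutation blocks."""
    dn_sum = DN.sum(axis=-1)
    ds_sum = DS.sum(axis=-1)
    n_sum = N.sum(axis=-1)
    s_sum = S.sum(axis=-1)
    dN, dS, omega = _sums_to_stats(dn_sum, n_sum, ds_sum, s_sum)
    return {"dN": dN, "dS": dS, "omega": omega}[statistic]


def category_permutation_test(
    rows: pd.DataFrame,
    cat_a: str,
    cat_b: str,
    statistic: str = "omega",
    reps: int = 1000,
    tail: str = "one_tailed_a_greater",
    seed: int = 0,
) -> float:
    """Label-permutation P for a between-category difference in dN, dS or ω.

    Observed Δ = stat(a) − stat(b); category labels are permuted among the
    pooled genes ``reps`` times preserving group sizes.  The add-one
    estimator (count+1)/(reps+1) is reported, so P is never exactly zero.
    """
    if statistic not in STATISTICS:
        raise ValidationError(f"statistic must be one of {STATISTICS}")
    if tail not in ("one_tailed_a_greater", "two_tailed"):
        raise ValidationError(f"unknown tail {tail!r}")
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    a = rows[rows["category"] == cat_a]
    b = rows[rows["category"] == cat_b]
    if a.empty or b.empty:
        raise ValidationError("both categories must be non-empty")
    n_a = len(a)
    pool = pd.concat([a, b], ignore_index=True)
    DN = pool["DN"].to_numpy(float)
    DS = pool["DS"].to_numpy(float)
    N = pool["N"].to_numpy(float)
    S = pool["S"].to_numpy(float)
    n = len(pool)

    def delta(idx_a, idx_b):
        return (_stat_from_arrays(DN[idx_a], DS[idx_a], N[idx_a], S[idx_a], statistic)
                - _stat_from_arrays(DN[idx_b], DS[idx_b], N[idx_b], S[idx_b], statistic))

    obs = delta(np.arange(n_a), np.arange(n_a, n))
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((reps, n)), axis=1)
    d_perm = delta(perms[:, :n_a], perms[:, n_a:])
    if tail == "one_tailed_a_greater":
        count = int(np.sum(d_perm >= obs))
    else:
        count = int(np.sum(np.abs(d_perm) >= abs(obs)))
    return (count + 1) / (reps + 1)


def bootstrap_ci_divergence(
    rows: pd.DataFrame,
    category: str,
    reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap CIs (resampling genes with replacement within the
    category) for dN, dS and ω."""
    sub = rows[rows["category"] == category]
    if sub.empty:
        raise ValidationError(f"no orthologs in category {category!r}")
    n = len(sub)
    DN = sub["DN"].to_numpy(float)
    DS = sub["DS"].to_numpy(float)
    N = sub["N"].to_numpy(float)
    S = sub["S"].to_numpy(float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(reps, n))
    out: dict[str, tuple[float, float]] = {}
    for stat in STATISTICS:
        vals = _stat_from_arrays(DN[idx], DS[idx], N[idx], S[idx], stat)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            out[stat] = (float("nan"), float("nan"))
            continue
        lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        out[stat] = (float(lo), float(hi))
    return out


def divergence_report(
    rows: pd.DataFrame,
    categories: list[str] | None = None,
    reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Point estimates plus bootstrap CIs for every category."""
    if categories is None:
        categories = sorted(rows["category"].unique())
    out = []
    for i, cat in enumerate(categories):
        cd = aggregate_divergence(rows, cat)
        cd.ci = bootstrap_ci_divergence(rows, cat, reps=reps, alpha=alpha,
                                        seed=seed + i)
        out.append(cd.to_dict())
    return pd.DataFrame(out)
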