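"""Cross-population convergence testing.

Upstream and downstream populations of each watershed are contrasted gene by
gene (normalized M:F SNP density), and the probability of observing the
X-linked pattern by chance is estimated by dropping random 10-Mb windows on
the autosomes: a window "qualifies" when every river shows a significant
upstream excess AND the lab population's median contrast in the window
clears the autosomal 95% band, mirroring the criteria applied to the real
candidate region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import GenomeLayout, ValidationError
from .windows import autosomal_bootstrap_ci

log = logging.getLogger(__name__)

ALTERNATIVES = {"greater": "greater", "less": "less", "two_sided": "two-sided"}


def wilcoxon_rank_sum(x, y, alternative: str = "two_sided") -> tuple[float, float]:
    """Mann–Whitney U rank-sum test of x against y.

    Exact enumeration when n+m ≤ 16 with no ties; otherwise the normal
    approximation with midrank tie correction.  Returns (U for x, P).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be non-empty")
    if alternative not in ALTERNATIVES:
        raise ValidationError(f"alternative must be one of {sorted(ALTERNATIVES)}")
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (tie_free and len(pooled) <= 16) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=ALTERNATIVES[alternative], method=method)
    return float(res.statistic), float(res.pvalue)


def river_contrast(up_values, down_values) -> float:
    """One-tailed P for upstream normalized M:F SNP density exceeding
    downstream, over genes of one region."""
    up = np.asarray(up_values, dtype=float)
    down = np.asarray(down_values, dtype=float)
    if len(up) == 0 or len(down) == 0:
        raise ValidationError("region has no genes in one of the populations")
    _, p = wilcoxon_rank_sum(up, down, alternative="greater")
    return p


@dataclass
class ConvergenceResult:
    region: tuple[str, int, int] | None
    per_river_p: dict[str, float]
    n_windows_sampled: int
    n_windows_qualifying: int
    empirical_p: float
    seed: int
    n_redraws: int = 0
    lab_band: tuple[float, float] = (float("nan"), float("nan"))
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "region": list(self.region) if self.region else None,
            "per_river_p": self.per_river_p,
            "n_windows_sampled": self.n_windows_sampled,
            "n_windows_qualifying": self.n_windows_qualifying,
            "empirical_p": self.empirical_p,
            "seed": self.seed,
            "n_redraws": self.n_redraws,
            "lab_band": list(self.lab_band),
        }


def _region_values(gene_table: pd.DataFrame, column: str,
                   chrom: str, start: int, end: int) -> np.ndarray:
    sel = (
        (gene_table["chromosome"] == chrom)
        & (gene_table["pos"] > start)
        & (gene_table["pos"] <= end)
    )
    return gene_table.loc[sel, column].dropna().to_numpy()


def region_river_pvalues(
    gene_table: pd.DataFrame,
    rivers: list[str],
    region: tuple[str, int, int],
) -> dict[str, float]:
    """Per-river one-tailed up>down P on a genomic region.

    ``gene_table`` has one row per gene with columns ``chromosome, pos`` and
    ``<river>_up`` / ``<river>_down`` normalized contrast columns.
    """
    chrom, start, end = region
    out = {}
    for river in rivers:
        up = _region_values(gene_table, f"{river}_up", chrom, start, end)
        down = _region_values(gene_table, f"{river}_down", chrom, start, end)
        out[river] = river_contrast(up, down)
    return out


def convergence_permutation(
    gene_table: pd.DataFrame,
    layout: GenomeLayout,
    rivers: list[str],
    region: tuple[str, int, int] | None = None,
    window_mb: float = 10.0,
    reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    lab_band: tuple[float, float] | None = None,
    band_window: int = 40,
    estimator: str = "plain",
    min_genes: int = 2,
) -> ConvergenceResult:
    """Estimate how often a random autosomal 10-Mb window reproduces the
    convergent pattern.

    Each replicate drops a uniformly random ``window_mb`` window on an
    autosome (chromosome chosen proportional to its valid span).  The window
    qualifies when every river's one-tailed up>down rank-sum P is < alpha and
    the median lab contrast in the window exceeds the upper bound of the
    autosomal 95% band.  Windows with fewer than ``min_genes`` genes for any
    river are redrawn (counted).  ``estimator='add_one'`` reports
    (count+1)/(reps+1) instead of count/reps.
    """
    if len(rivers) < 3:
        raise ValidationError("need at least 3 watershed pairs")
    if estimator not in ("plain", "add_one"):
        raise ValidationError(f"unknown estimator {estimator!r}")
    for river in rivers:
        for suffix in ("_up", "_down"):
            if f"{river}{suffix}" not in gene_table.columns:
                raise ValidationError(f"gene table missing column {river}{suffix}")
    window_bp = int(window_mb * 1e6)
    autosomes = [
        (c.chrom_id, c.length - window_bp)
        for c in layout.chromosomes
        if not c.is_sex_chromosome and c.length >= window_bp
    ]
    if not autosomes:
        raise ValidationError(f"no autosome is at least {window_mb} Mb long")
    spans = np.array([max(a[1], 1) for a in autosomes], dtype=float)
    probs = spans / spans.sum()

    rng = np.random.default_rng(seed)
    autosomal_lab = gene_table.loc[
        gene_table["chromosome"].isin([a[0] for a in autosomes + [
            (c.chrom_id, 0) for c in layout.chromosomes if not c.is_sex_chromosome
        ]]),
        "lab",
    ].dropna().to_numpy()
    if lab_band is None:
        lab_band = autosomal_bootstrap_ci(
            autosomal_lab, window=band_window, reps=reps, alpha=alpha, seed=rng
        )

    n_qualifying = 0
    n_redraws = 0
    max_attempts = 20 * reps
    attempts = 0
    sampled = 0
    while sampled < reps and attempts < max_attempts:
        attempts += 1
        ci = rng.choice(len(autosomes), p=probs)
        chrom, span = autosomes[ci]
        start = int(rng.integers(0, span + 1))
        end = start + window_bp
        river_vals = {}
        ok = True
        for river in rivers:
            up = _region_values(gene_table, f"{river}_up", chrom, start, end)
            down = _region_values(gene_table, f"{river}_down", chrom, start, end)
            if len(up) < min_genes or len(down) < min_genes:
                ok = False
                break
            river_vals[river] = (up, down)
        if not ok:
            n_redraws += 1
            continue
        sampled += 1
        all_sig = all(
            river_contrast(up, down) < alpha for up, down in river_vals.values()
        )
        if not all_sig:
            continue
        lab_vals = _region_values(gene_table, "lab", chrom, start, end)
        if len(lab_vals) and float(np.median(lab_vals)) > lab_band[1]:
            n_qualifying += 1
    if sampled < reps:
        raise ValidationError(
            f"could not sample {reps} gene-bearing windows "
            f"({sampled} sampled, {n_redraws} redraws)"
        )
    if n_redraws:
        log.info("redrew %d windows with fewer than %d genes", n_redraws, min_genes)

    if estimator == "plain":
        emp_p = n_qualifying / sampled
    else:
        emp_p = (n_qualifying + 1) / (sampled + 1)

    per_river_p = (
        region_river_pvalues(gene_table, rivers, region) if region else {}
    )
    return ConvergenceResult(
        region=region,
        per_river_p=per_river_p,
        n_windows_sampled=sampled,
        n_windows_qualifying=n_qualifying,
        empirical_p=emp_p,
        seed=seed,
        n_redraws=n_redraws,
        lab_band=lab_band,
    )
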