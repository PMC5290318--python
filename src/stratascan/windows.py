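"""Sliding-window scans with autosomal bootstrap confidence bands.

A chromosome is an ordered sequence of units (scaffolds for coverage, genes
for SNP density and expression).  The scan is a step-1 moving average over
``window`` units; the null band is the empirical 95% interval of the mean of
``window`` autosomal units drawn without replacement, one flat band per
statistic.  Runs of consecutive significant windows become stratum calls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import StratumCall, ValidationError, WindowTrack

DEFAULT_WINDOW = 40
DEFAULT_REPS = 1000
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_RUN = 5


def moving_average(values, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Step-1 moving mean; no partial windows, so output length is
    ``n − window + 1``."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if window < 1:
        raise ValidationError("window must be >= 1")
    if window > n:
        raise ValidationError(f"window {window} exceeds sequence length {n}")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(values, kernel, mode="valid")


def autosomal_bootstrap_ci(
    autosomal_values,
    window: int = DEFAULT_WINDOW,
    reps: int = DEFAULT_REPS,
    alpha: float = DEFAULT_ALPHA,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Flat null band for a window mean under autosomal exchangeability.

    Each replicate draws ``window`` autosomal units without replacement and
    records their mean; the band is the empirical (α/2, 1−α/2) percentile
    interval over ``reps`` replicates.
    """
    pool = np.asarray(autosomal_values, dtype=float)
    if len(pool) < window:
        raise ValidationError(
            f"autosomal pool ({len(pool)}) smaller than window ({window})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    means = np.empty(reps)
    for r in range(reps):
        means[r] = pool[rng.choice(len(pool), size=window, replace=False)].mean()
    lo, hi = np.percentile(means, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def scan_chromosome(
    chromosome: str,
    unit_positions,
    unit_values,
    autosomal_values,
    window: int = DEFAULT_WINDOW,
    reps: int = DEFAULT_REPS,
    alpha: float = DEFAULT_ALPHA,
    seed: int | np.random.Generator = 0,
    band: tuple[float, float] | None = None,
) -> WindowTrack:
    """Moving average of per-unit values along one chromosome, with the
    autosomal bootstrap band.  Units must be supplied in genomic order; a
    precomputed ``band`` may be passed to share one band across chromosomes.
    """
    pos = np.asarray(unit_positions, dtype=float)
    vals = np.asarray(unit_values, dtype=float)
    if len(pos) != len(vals):
        raise ValidationError("positions and values must align")
    if np.any(np.diff(pos) < 0):
        raise ValidationError("unit positions must be sorted")
    if band is None:
        band = autosomal_bootstrap_ci(autosomal_values, window, reps, alpha, seed)
    means = moving_average(vals, window)
    mid = moving_average(pos, window)  # midpoint of spanned units
    return WindowTrack(
        chromosome=chromosome,
        positions=mid,
        values=means,
        window=window,
        ci_low=band[0],
        ci_high=band[1],
        window_starts=pos[: len(means)],
        window_ends=pos[window - 1:],
    )


def call_strata(
    track: WindowTrack,
    statistic: str,
    min_run: int = DEFAULT_MIN_RUN,
) -> list[StratumCall]:
    """Stratum calls from runs of consecutive significant windows.

    ``statistic='coverage'`` calls runs below the band (male coverage
    deficit); ``statistic='snp_density'`` calls runs above it (male SNP
    excess).  A run must span at least ``min_run`` windows; its interval runs
    from the first window's position to the last window's position (window
    positions are the midpoint of the spanned units, so the boundary
    estimate is centred rather than smeared by a full window span).
    """
    if statistic == "coverage":
        mask = track.values < track.ci_low
        evidence = "coverage_deficit"
    elif statistic == "snp_density":
        mask = track.values > track.ci_high
        evidence = "snp_excess"
    else:
        raise ValidationError(f"unknown statistic {statistic!r}")
    starts = track.positions
    ends = track.positions
    calls: list[StratumCall] = []
    i = 0
    n = len(mask)
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and mask[j + 1]:
            j += 1
        if j - i + 1 >= min_run:
            calls.append(
                StratumCall(
                    chromosome=track.chromosome,
                    start=int(starts[i]),
                    end=int(ends[j]),
                    evidence=evidence,
                    n_windows=j - i + 1,
                )
            )
        i = j + 1
    return calls


def significant_fraction(tracks: list[WindowTrack]) -> float:
    """Fraction of windows outside the band across a set of tracks."""
    total = sum(len(t.values) for t in tracks)
    if total == 0:
        return float("nan")
    hits = sum(int(t.significant.sum()) for t in tracks)
    return hits / total


def calls_to_frame(calls: list[StratumCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chromosome": [c.chromosome for c in calls],
            "start": [c.start for c in calls],
            "end": [c.end for c in calls],
            "evidence": [c.evidence for c in calls],
            "n_windows": [c.n_windows for c in calls],
        }
    )
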