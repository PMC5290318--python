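"""Synthetic resequencing summaries with known sex-chromosome strata.

The generator emulates the statistical structure the downstream analysis
assumes, at desk scale:

* per-site coverage is negative-binomially overdispersed around a mean depth;
* males carry two sex-chromosome haplotypes (X and Y); in a stratum a
  fraction ``y_loss`` (δ) of Y-derived reads fails to map back to the X-built
  assembly, so the male mean depth is ``depth × (1 − δ/2)``;
* fixed X–Y differences occur at per-site rate ``xy_divergence`` (ρ) inside a
  stratum and appear as male-only heterozygosity: at such a site the
  Y (alternate) allele is carried by the retained Y reads, a fraction
  ``(1 − δ)/(2 − δ)`` of the male coverage;
* replicate watershed populations share the autosomal model but differ in how
  far the young stratum extends and in how diverged it is;
* expression counts are Poisson around length × RPKM × library size with a
  sex-biased subset of stratum genes;
* ortholog substitution counts are Poisson around category-level rates.

Every dataset is accompanied by a truth table sufficient to score stratum
recovery without re-reading the generator internals.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    Chromosome,
    GenomeLayout,
    SampleInfo,
    ScaffoldPlacement,
    ValidationError,
)

ORTHOLOG_CATEGORIES = ("X_stratum1", "X_stratum2", "autosome")


def _rng(*keys) -> np.random.Generator:
    """Deterministic stream keyed by integers/strings; adding a population or
    individual never perturbs the streams of the others."""
    entropy = [k if isinstance(k, (int, np.integer)) else zlib.crc32(str(k).encode())
               for k in keys]
    return np.random.default_rng(np.random.SeedSequence([int(e) for e in entropy]))


@dataclass(frozen=True)
class StratumSpec:
    """One non-recombining interval on the sex chromosome."""

    start: int
    end: int
    y_loss: float = 0.0  # δ: fraction of Y-derived reads failing to map
    xy_divergence: float = 0.0  # ρ: per-site probability of a fixed X–Y difference
    name: str = "stratum"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError("stratum end must exceed start")
        if not 0 <= self.y_loss <= 1:
            raise ValidationError("y_loss must be in [0, 1]")
        if not 0 <= self.xy_divergence <= 1:
            raise ValidationError("xy_divergence must be in [0, 1]")


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    stratum2_extent: int | None = None  # bp; None = the base stratum's extent
    divergence_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.divergence_multiplier < 0:
            raise ValidationError("divergence_multiplier must be >= 0")


@dataclass(frozen=True)
class ExpressionSpec:
    n_genes: int = 2000
    log_rpkm_loc: float = 3.5  # natural-log location of the RPKM lognormal
    log_rpkm_scale: float = 0.8
    sex_bias_fraction: float = 0.3  # of sex-chromosome stratum genes
    bias_magnitude: float = 1.0  # |log2 M:F| for biased genes
    library_size: float = 20e6
    min_gene_len: int = 500
    max_gene_len: int = 3000

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if not 0 <= self.sex_bias_fraction <= 1:
            raise ValidationError("sex_bias_fraction must be in [0, 1]")
        if self.library_size <= 0:
            raise ValidationError("library_size must be > 0")


@dataclass(frozen=True)
class OrthologSpec:
    n_per_category: int = 500
    n_sites: int = 600  # nonsynonymous sites per gene (centre of the draw)
    s_sites: int = 200  # synonymous sites per gene
    dn: Mapping[str, float] = field(
        default_factory=lambda: {"autosome": 0.010, "X_stratum1": 0.015, "X_stratum2": 0.015}
    )
    ds: Mapping[str, float] = field(
        default_factory=lambda: {"autosome": 0.10, "X_stratum1": 0.10, "X_stratum2": 0.10}
    )

    def __post_init__(self) -> None:
        if self.n_per_category < 1:
            raise ValidationError("n_per_category must be >= 1")
        for cat, v in self.ds.items():
            if v <= 0:
                raise ValidationError(f"ds must be > 0 (category {cat}): dN/dS undefined")


@dataclass
class SimSpec:
    """Full parameterization of the synthetic experiment."""

    seed: int
    layout: GenomeLayout
    strata: list[StratumSpec]
    pi: float = 0.001  # baseline per-site heterozygosity, both sexes, genome-wide
    depth: float = 20.0  # mean per-site coverage
    dispersion: float = 5.0  # NB size k; Var = m + m^2/k (Poisson as k -> inf)
    n_per_sex: int = 4
    sites_per_scaffold: int = 200
    populations: list[PopulationSpec] = field(
        default_factory=lambda: [PopulationSpec("lab")]
    )
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    orthologs: OrthologSpec = field(default_factory=OrthologSpec)

    def __post_init__(self) -> None:
        if not 0 <= self.pi <= 1:
            raise ValidationError("pi must be in [0, 1]")
        if self.depth <= 0:
            raise ValidationError("depth must be > 0")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")
        if self.n_per_sex < 1:
            raise ValidationError("n_per_sex must be >= 1")
        sex = self.layout.sex_chromosome
        if sex is None and self.strata:
            raise ValidationError("strata given but layout has no sex chromosome")
        length = self.layout.chromosome_length(sex) if sex else None
        for s in self.strata:
            if length is not None and (s.start < 0 or s.end > length):
                raise ValidationError(f"stratum {s.name} outside the sex chromosome")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate population names")

    def population(self, name: str) -> PopulationSpec:
        for p in self.populations:
            if p.name == name:
                return p
        raise ValidationError(f"population {name!r} not in spec")


# ---------------------------------------------------------------------------
# defaults: the synthetic guppy-like genome
# ---------------------------------------------------------------------------

def default_layout(
    n_autosomes: int = 2,
    autosome_mb: float = 25.0,
    sex_chrom_mb: float = 26.0,
    scaffold_kb: float = 200.0,
) -> GenomeLayout:
    """A sex chromosome plus autosomes, tiled with equal-size scaffolds."""
    scaffold_len = int(scaffold_kb * 1e3)
    chroms: list[Chromosome] = []
    scaffolds: list[ScaffoldPlacement] = []
    specs = [(f"chr{i + 1}", int(autosome_mb * 1e6), False) for i in range(n_autosomes)]
    specs.append(("chrX", int(sex_chrom_mb * 1e6), True))
    for chrom_id, length, is_sex in specs:
        n_scaf = length // scaffold_len
        chroms.append(Chromosome(chrom_id, n_scaf * scaffold_len, is_sex))
        for j in range(n_scaf):
            start = j * scaffold_len + 1
            scaffolds.append(
                ScaffoldPlacement(f"{chrom_id}_scaf{j:04d}", chrom_id, start,
                                  start + scaffold_len - 1)
            )
    return GenomeLayout(chromosomes=chroms, scaffolds=scaffolds)


def default_sim_spec(seed: int = 0, **overrides) -> SimSpec:
    """The default synthetic experiment: an old, coverage-reduced stratum at
    22–25 Mb, a younger SNP-excess stratum at 15–22 Mb, a lab population and
    three watershed up/down pairs where upstream populations have a longer,
    twice-as-diverged young stratum."""
    layout = overrides.pop("layout", None) or default_layout()
    strata = overrides.pop("strata", None)
    if strata is None:
        strata = [
            StratumSpec(22_000_000, 25_000_000, y_loss=0.5, xy_divergence=0.005,
                        name="stratum1"),
            StratumSpec(15_000_000, 22_000_000, y_loss=0.0, xy_divergence=0.005,
                        name="stratum2"),
        ]
    populations = overrides.pop("populations", None)
    if populations is None:
        populations = [PopulationSpec("lab")]
        for river in ("Yarra", "Quare", "Aripo"):
            populations.append(
                PopulationSpec(f"{river}_up", stratum2_extent=7_000_000,
                               divergence_multiplier=2.0)
            )
            populations.append(
                PopulationSpec(f"{river}_down", stratum2_extent=5_000_000,
                               divergence_multiplier=1.0)
            )
    return SimSpec(seed=seed, layout=layout, strata=strata,
                   populations=populations, **overrides)


def null_sim_spec(seed: int = 0, **overrides) -> SimSpec:
    """All sex/population effects switched off: every downstream contrast has
    expectation zero genome-wide."""
    strata = [
        StratumSpec(22_000_000, 25_000_000, 0.0, 0.0, name="stratum1"),
        StratumSpec(15_000_000, 22_000_000, 0.0, 0.0, name="stratum2"),
    ]
    populations = [PopulationSpec("lab")]
    for river in ("Yarra", "Quare", "Aripo"):
        populations.append(PopulationSpec(f"{river}_up"))
        populations.append(PopulationSpec(f"{river}_down"))
    return default_sim_spec(seed, strata=strata, populations=populations, **overrides)


# ---------------------------------------------------------------------------
# effective strata per population
# ---------------------------------------------------------------------------

def effective_strata(spec: SimSpec, population: str) -> list[StratumSpec]:
    """Apply a population's young-stratum extent and divergence multiplier.

    The youngest stratum (lowest start) grows from its start by
    ``stratum2_extent`` bp, capped at the next stratum's start; ρ is scaled by
    ``divergence_multiplier`` in every stratum.
    """
    pop = spec.population(population)
    strata = sorted(spec.strata, key=lambda s: s.start)
    out: list[StratumSpec] = []
    for i, s in enumerate(strata):
        rho = min(s.xy_divergence * pop.divergence_multiplier, 1.0)
        start, end = s.start, s.end
        if i == 0 and pop.stratum2_extent is not None and len(strata) > 1:
            cap = strata[1].start
            end = min(start + int(pop.stratum2_extent), cap)
        out.append(replace(s, start=start, end=end, xy_divergence=rho))
    return [s for s in out if s.end > s.start]


def expected_log2_mf_coverage(depth: float, delta: float, pseudocount: float = 1.0) -> float:
    """Analytic expectation of the pseudocounted log2 M:F mean coverage."""
    return float(np.log2(depth * (1 - delta / 2) + pseudocount)
                 - np.log2(depth + pseudocount))


# ---------------------------------------------------------------------------
# site counts
# ---------------------------------------------------------------------------

def _site_grid(spec: SimSpec):
    """Per-site arrays across the whole layout: scaffold index, local 1-based
    position, chromosome, genomic bp."""
    scaf_ids: list[str] = []
    scaf_idx: list[np.ndarray] = []
    local: list[np.ndarray] = []
    genomic: list[np.ndarray] = []
    chrom: list[np.ndarray] = []
    for i, s in enumerate(spec.layout.scaffolds):
        n = min(spec.sites_per_scaffold, s.length)
        spacing = s.length // n
        loc = spacing * np.arange(n, dtype=np.int64) + 1
        scaf_ids.append(s.scaffold_id)
        scaf_idx.append(np.full(n, i, dtype=np.int32))
        local.append(loc)
        genomic.append(s.chrom_start - 1 + loc)
        chrom.append(np.full(n, s.chromosome, dtype=object))
    return (scaf_ids,
            np.concatenate(scaf_idx),
            np.concatenate(local),
            np.concatenate(genomic),
            np.concatenate(chrom))


def simulate_site_counts(
    spec: SimSpec, population: str
) -> tuple[pd.DataFrame, list[SampleInfo], pd.DataFrame]:
    """Simulate allele-count profiles for every individual of one population.

    Returns the canonical site-count table, the sample sheet, and a truth
    table with one row per sex-chromosome region giving the generative
    parameters and the analytic expectations they imply.
    """
    strata = effective_strata(spec, population)
    scaf_ids, scaf_idx, local_pos, genomic_pos, site_chrom = _site_grid(spec)
    n_sites = len(local_pos)
    sex_chrom = spec.layout.sex_chromosome
    on_sex = site_chrom == sex_chrom if sex_chrom else np.zeros(n_sites, bool)

    delta = np.zeros(n_sites)
    rho = np.zeros(n_sites)
    for s in strata:
        mask = on_sex & (genomic_pos > s.start) & (genomic_pos <= s.end)
        delta[mask] = s.y_loss
        rho[mask] = s.xy_divergence

    pop_rng = _rng(spec.seed, population, "sites")
    ref = pop_rng.integers(0, 4, n_sites)
    alt = (ref + pop_rng.integers(1, 4, n_sites)) % 4
    # fixed X–Y differences are positional: shared by every male of the population
    xy_site = pop_rng.random(n_sites) < rho
    # Y-allele read fraction among male reads at an X–Y difference site
    with np.errstate(invalid="ignore"):
        p_y = (1 - delta) / (2 - delta)

    k = spec.dispersion
    samples: list[SampleInfo] = []
    frames: list[pd.DataFrame] = []
    for sex, tag in (("male", "M"), ("female", "F")):
        for j in range(spec.n_per_sex):
            sid = f"{population}_{tag}{j + 1}"
            samples.append(SampleInfo(sid, sex, population, "dna"))
            rng = _rng(spec.seed, population, sid)
            m = np.full(n_sites, spec.depth)
            if sex == "male":
                m = m * (1 - delta / 2)
            cov = rng.negative_binomial(k, k / (k + m))
            het = rng.random(n_sites) < spec.pi
            p_alt = np.full(n_sites, 0.5)
            if sex == "male":
                p_alt = np.where(xy_site, p_y, 0.5)
                het = het | xy_site
            alt_n = np.where(het, rng.binomial(cov, p_alt), 0)
            counts = np.zeros((n_sites, 4), dtype=np.int64)
            np.add.at(counts, (np.arange(n_sites), ref), cov - alt_n)
            np.add.at(counts, (np.arange(n_sites), alt), alt_n)
            frames.append(
                pd.DataFrame(
                    {
                        "scaffold": pd.Categorical.from_codes(scaf_idx, scaf_ids),
                        "pos": local_pos,
                        "sample": sid,
                        "A": counts[:, 0],
                        "C": counts[:, 1],
                        "G": counts[:, 2],
                        "T": counts[:, 3],
                    }
                )
            )
    df = pd.concat(frames, ignore_index=True)
    df["scaffold"] = df["scaffold"].astype(str)
    truth = _truth_table(spec, population, strata)
    return df, samples, truth


def _truth_table(spec: SimSpec, population: str, strata: Sequence[StratumSpec]) -> pd.DataFrame:
    rows = []
    for s in strata:
        rows.append(
            {
                "population": population,
                "chromosome": spec.layout.sex_chromosome,
                "start": s.start,
                "end": s.end,
                "region": s.name,
                "y_loss": s.y_loss,
                "xy_divergence": s.xy_divergence,
                "expected_log2_mf_coverage": expected_log2_mf_coverage(spec.depth, s.y_loss),
                "expected_male_het_rate": spec.pi + s.xy_divergence * (s.y_loss < 1.0),
                "expected_female_het_rate": spec.pi,
            }
        )
    rows.append(
        {
            "population": population,
            "chromosome": "*autosomes*",
            "start": 0,
            "end": 0,
            "region": "autosomal_baseline",
            "y_loss": 0.0,
            "xy_divergence": 0.0,
            "expected_log2_mf_coverage": 0.0,
            "expected_male_het_rate": spec.pi,
            "expected_female_het_rate": spec.pi,
        }
    )
    return pd.DataFrame(rows)


def truth_intervals(truth: pd.DataFrame, evidence: str) -> list[tuple[int, int]]:
    """Merged sex-chromosome intervals where a given signal is expected.

    ``coverage_deficit``: strata with δ > 0.  ``snp_excess``: strata with
    ρ > 0 (and δ < 1 so some Y reads remain).  Touching intervals merge.
    """
    regions = truth[truth["region"] != "autosomal_baseline"]
    if evidence == "coverage_deficit":
        regions = regions[regions["y_loss"] > 0]
    elif evidence == "snp_excess":
        regions = regions[(regions["xy_divergence"] > 0) & (regions["y_loss"] < 1)]
    else:
        raise ValidationError(f"unknown evidence class {evidence!r}")
    ivals = sorted((int(r.start), int(r.end)) for r in regions.itertuples())
    merged: list[tuple[int, int]] = []
    for start, end in ivals:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------

def watershed_pairs(populations: Sequence[PopulationSpec]) -> list[str]:
    """River names from ``<river>_up`` / ``<river>_down`` population pairs."""
    ups = {p.name[:-3] for p in populations if p.name.endswith("_up")}
    downs = {p.name[:-5] for p in populations if p.name.endswith("_down")}
    missing = ups ^ downs
    if missing:
        raise ValidationError(f"watershed pair(s) missing a member: {sorted(missing)}")
    return sorted(ups)


def simulate_populations(
    spec: SimSpec,
) -> tuple[dict[str, tuple[pd.DataFrame, list[SampleInfo]]], pd.DataFrame]:
    """Simulate every population in the spec (lab reference plus watershed
    up/down pairs).  Autosomes are identical in distribution across
    populations; only the sex chromosome differs."""
    names = [p.name for p in spec.populations]
    if "lab" not in names:
        raise ValidationError("populations must include a 'lab' reference")
    rivers = watershed_pairs(spec.populations)
    if not rivers:
        raise ValidationError("populations must include at least one up/down pair")
    datasets: dict[str, tuple[pd.DataFrame, list[SampleInfo]]] = {}
    truths = []
    for name in names:
        counts, samples, truth = simulate_site_counts(spec, name)
        datasets[name] = (counts, samples)
        truths.append(truth)
    return datasets, pd.concat(truths, ignore_index=True)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _place_genes(spec: SimSpec, n_genes: int) -> pd.DataFrame:
    """Distribute genes across chromosomes proportional to length, evenly
    spaced along each."""
    lengths = np.array([c.length for c in spec.layout.chromosomes], dtype=float)
    alloc = np.floor(n_genes * lengths / lengths.sum()).astype(int)
    while alloc.sum() < n_genes:
        alloc[int(np.argmax(lengths / (alloc + 1)))] += 1
    rows = []
    g = 0
    for c, n in zip(spec.layout.chromosomes, alloc):
        if n == 0:
            continue
        pos = np.linspace(c.length / (2 * n), c.length - c.length / (2 * n), n)
        for p in pos:
            rows.append({"gene_id": f"g{g:05d}", "chromosome": c.chrom_id,
                         "pos": int(p), "is_sex": c.is_sex_chromosome})
            g += 1
    return pd.DataFrame(rows)


def simulate_expression(
    spec: SimSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a gene×sample read-count matrix for the lab population.

    Returns (counts, genes, truth): ``genes`` carries chromosome, position and
    exonic length; ``truth`` the per-gene true log2 M:F expression ratio.
    """
    ex = spec.expression
    genes = _place_genes(spec, ex.n_genes)
    rng = _rng(spec.seed, "expression")
    n = len(genes)
    base_rpkm = rng.lognormal(ex.log_rpkm_loc, ex.log_rpkm_scale, n)
    lengths = rng.integers(ex.min_gene_len, ex.max_gene_len + 1, n)

    in_stratum = np.zeros(n, dtype=bool)
    for s in spec.strata:
        in_stratum |= (genes["is_sex"].to_numpy()
                       & (genes["pos"].to_numpy() > s.start)
                       & (genes["pos"].to_numpy() <= s.end))
    biased = in_stratum & (rng.random(n) < ex.sex_bias_fraction)
    sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    true_log2_mf = np.where(biased, sign * ex.bias_magnitude, 0.0)

    rpkm_m = base_rpkm * 2.0 ** (true_log2_mf / 2)
    rpkm_f = base_rpkm * 2.0 ** (-true_log2_mf / 2)
    lib_m = ex.library_size / 1e6
    len_kb = lengths / 1e3

    counts = {}
    samples = []
    for sex, tag, rpkm in (("male", "M", rpkm_m), ("female", "F", rpkm_f)):
        for j in range(spec.n_per_sex):
            sid = f"lab_rna_{tag}{j + 1}"
            samples.append(SampleInfo(sid, sex, "lab", "rna"))
            srng = _rng(spec.seed, "expression", sid)
            counts[sid] = srng.poisson(rpkm * len_kb * lib_m)
    counts_df = pd.DataFrame(counts, index=genes["gene_id"])
    counts_df.index.name = "gene_id"
    genes = genes.assign(length=lengths)
    truth = genes[["gene_id", "chromosome", "pos"]].assign(true_log2_mf=true_log2_mf)
    return counts_df, genes, truth


def expression_samples(spec: SimSpec) -> list[SampleInfo]:
    out = []
    for sex, tag in (("male", "M"), ("female", "F")):
        for j in range(spec.n_per_sex):
            out.append(SampleInfo(f"lab_rna_{tag}{j + 1}", sex, "lab", "rna"))
    return out


# ---------------------------------------------------------------------------
# orthologs
# ---------------------------------------------------------------------------

def simulate_orthologs(spec: SimSpec) -> pd.DataFrame:
    """Per-ortholog substitution counts: DN ~ Poisson(dN·N), DS ~ Poisson(dS·S)
    with category-level rates."""
    o = spec.orthologs
    rng = _rng(spec.seed, "orthologs")
    rows = []
    for cat in ORTHOLOG_CATEGORIES:
        if cat not in o.dn or cat not in o.ds:
            raise ValidationError(f"ortholog rates missing for category {cat}")
        n_genes = o.n_per_category
        N = rng.integers(max(o.n_sites // 2, 1), o.n_sites * 3 // 2 + 1, n_genes)
        S = rng.integers(max(o.s_sites // 2, 1), o.s_sites * 3 // 2 + 1, n_genes)
        DN = rng.poisson(o.dn[cat] * N)
        DS = rng.poisson(o.ds[cat] * S)
        for i in range(n_genes):
            rows.append(
                {
                    "gene_id": f"{cat}_g{i:04d}",
                    "category": cat,
                    "DN": int(DN[i]),
                    "DS": int(DS[i]),
                    "N": int(N[i]),
                    "S": int(S[i]),
                    "branch_ds": DS[i] / S[i],
                    "aln_len": int(N[i] + S[i]),
                }
            )
    return pd.DataFrame(rows)
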