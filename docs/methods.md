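# Methods

## The inference problem

On a young sex-chromosome pair, the Y diverges from the X in strata set by
when each region stopped recombining. Mapping male and female short reads
to an X-derived (female) assembly turns that history into two measurable
sex contrasts:

* **Coverage.** Males carry one X and one Y. Where the Y has diverged
  enough that a fraction δ of Y reads no longer maps, male depth falls to
  `depth × (1 − δ/2)` while female depth is unchanged — a log2 M:F
  coverage deficit (−0.415 at δ = 0.5, before pseudocounting).
* **SNP density.** Where Y reads still map but carry fixed X–Y
  differences (per-site rate ρ), those differences appear as male-only
  heterozygous sites: an excess of male SNPs with no coverage deficit.

An old stratum therefore shows the coverage signal; a younger stratum the
SNP signal. The package's job is to estimate these contrasts, decide where
along the chromosome they are significant, and compare the extent of the
young stratum across populations.

## Statistics

**Coverage** per scaffold and sample is total depth over sequenced sites
divided by the number of sequenced sites (unsequenced sites never enter
the denominator). **SNP calling** uses per-site allele counts: sites with
coverage < `min_cov` (default 10) are excluded from numerator and
denominator; among retained sites, a SNP is called when the
second-most-frequent allele count ≥ `minor_frac` (default 0.3) × coverage.
The published rule this implements is phrased as a "major allele frequency
of 0.3 times the site coverage", which is only meaningful read as a bound
on the minor allele (equivalently, major-allele fraction ≤ 0.7); that
reading is fixed here and exposed as a parameter. **Density** per gene and
individual is ΣSNP sites / Σretained genic sites; genes with zero retained
sites are dropped. Per-sex summaries are means of per-individual values (a
pooled-count alternative is available via `pooled=True`).

All logged quantities receive the **+1 pseudocount**: contrasts are
`log2(x + 1) − log2(x′ + 1)`, including densities in [0, 1] and RPKM. This
is deliberate fidelity to the established procedure rather than a
numerically optimal transform; its main consequence is attenuation —
a raw ratio r is compressed toward 0 by roughly x/(x + 1) at magnitude x —
which matters for interpreting effect sizes (see the coverage expectation
below) but not for rank-based tests.

**Cross-population comparability.** Wild populations differ in depth and
diversity, so per-gene log2 values are normalized by subtracting the
median over X-linked genes of the same population and sex; population
contrasts are then taken relative to the normalized lab-female reference
on shared genes.

**Window scan.** A step-1 moving average over `window` = 40 units
(scaffolds for coverage, genes for density/expression), no partial
windows; window positions are the midpoint of the spanned units. The null
band is the empirical 2.5–97.5 percentile interval of the mean of
`window` autosomal units drawn *without replacement*, 1,000 replicates —
the null distribution of a window mean under autosomal exchangeability —
and is flat (one band per statistic). Stratum calls are maximal runs of
≥ `min_run` = 5 consecutive significant windows, below the band for
coverage (evidence `coverage_deficit`) or above it for SNP density
(`snp_excess`). Call boundaries are the first and last significant
window's *midpoint*: with a w-unit window the outermost spanned unit would
displace each boundary by nearly a full window span and is fragile to
single marginal windows chaining onto the run, whereas the midpoint is a
centred estimate whose bias is at most half a window span. Any boundary
from a w-unit moving average is uncertain at that scale; callers needing
tighter edges should rescan with a smaller window.

**Convergence test.** For each watershed, upstream vs downstream
normalized male SNP density on the candidate region is compared with a
one-tailed Wilcoxon rank-sum test (exact enumeration when n+m ≤ 16 and
tie-free, normal approximation with midrank tie correction otherwise).
The chance probability of the convergent pattern is estimated by dropping
1,000 uniform 10-Mb windows on the autosomes (chromosome chosen
proportional to its valid span); a window qualifies when every river's
one-tailed P < 0.05 **and** the median lab M:F SNP density in the window
exceeds the upper bound of the autosomal 95% band (the same flat band the
scan uses). Windows with fewer than 2 genes for any river are redrawn and
counted. The empirical P is count/reps by default; the add-one estimator
(count+1)/(reps+1) is available for conservatism.

**Faster-X.** After dropping alignments < 300 bp and genes with branch
dS > 2 (strict inequalities; boundary values are retained), category
divergence is aggregated sum-then-divide — `dN = ΣD_N/ΣN`,
`dS = ΣD_S/ΣS`, `ω = dN/dS` — never as a mean of per-gene ratios, which
short or low-dS genes would dominate. Between-category tests permute
category labels among the pooled genes (1,000 replicates, group sizes
preserved) with the add-one P estimator, one-tailed for the directional
ω prediction and two-tailed for dN and dS; uncertainty comes from a
percentile bootstrap over genes within a category. The permutation scheme
is label permutation (the standard reading for genomic-category
contrasts); gene resampling is a different null and is not offered.

## The synthetic-data generator

`stratascan.simulate` emulates the statistical structure the analysis
assumes, not reads: per-site coverage is negative-binomial with mean
`depth` (default 20×, a realistic resequencing depth) and dispersion k
(default 5; Var = m + m²/k, Poisson recovered as k → ∞). Baseline
heterozygosity π (default 0.001/site) applies to both sexes genome-wide
with a Binomial(cov, ½) allele split. Inside a stratum, males additionally
carry fixed X–Y differences at rate ρ (default 0.005/site, matching an
older, more diverged stratum); at such a site the Y allele is carried by
the retained Y-read fraction, so the allele split is
Binomial(cov, (1−δ)/(2−δ)) — this retention-weighted split, rather than a
flat ½, makes the δ → 1 limit correct (no Y reads, no male-specific
heterozygosity) and makes δ = 0.5 sites borderline against the 0.3
calling threshold, as diverged-stratum sites genuinely are. X–Y difference
positions are drawn once per population (fixed differences are shared by
a population's males). The default geometry is a 26-Mb sex chromosome
with an old stratum at 22–25 Mb (δ = 0.5, ρ = 0.005) and a young stratum
at 15–22 Mb (δ = 0, ρ = 0.005), 200-kb scaffolds, one genic unit per
scaffold, and two 25-Mb autosomes. Watershed pairs modify only the sex
chromosome: the young stratum's extent grows from its start by
`stratum2_extent` (default 7 Mb upstream, 5 Mb downstream) and ρ is scaled
by `divergence_multiplier` (default 2 upstream, 1 downstream) — upstream
populations have a longer, more diverged young stratum, the configuration
the convergence test is designed to detect. Four individuals per sex per
population. Expression counts are Poisson around
length × RPKM × library size with a lognormal RPKM distribution
(ln-location 3.5, ln-scale 0.8) and ±1 log2-unit sex bias in 30% of
stratum genes; ortholog counts are Poisson around category rates
(dN 0.015 on X vs 0.010 autosomal, dS 0.10 everywhere: ω_X = 1.5 ω_A,
500 genes per category). One RNG stream per (population, individual),
keyed by CRC32 of the names, so adding a population never perturbs
another's data. Effect sizes are package choices documented here — the
source literature reports signs and significance, not simulation-ready
magnitudes.

Each dataset carries a truth table (stratum intervals, generative
parameters, analytic expectations) sufficient to score recovery without
reopening the generator.

**What the generator does not emulate:** mapping artefacts and
mappability variation, linkage between sites, GC/repeat-driven coverage
trends, reference bias beyond the δ mechanism, library-size variation, and
real orthology/alignment error. Passing recovery tests therefore shows the
*inference chain* is correct under its assumed model, not that the model
captures every property of real resequencing data.

## Problem sizes and numerical choices

Test and acceptance runs use 300 genic sites per 200-kb scaffold for the
main experiment: per-gene SNP densities are then estimated from enough
filtered sites that the prescribed upstream/downstream effect
(multiplier 2) is resolved by the rank-sum contrasts with high power — a
10-seed audit gave worst-case per-river P ≈ 0.001 — while a full
seven-population simulation stays under a minute. The type-I audit of the
scan uses window 10 over three seeds because significance of overlapping
windows is ~window-fold autocorrelated; the narrower window yields enough
effectively independent windows to check the flagged fraction against α.
With the +1 pseudocount at depth 20, the expected in-stratum coverage
contrast at δ = 0.5 is log2(16/21) = −0.392 rather than the asymptotic
log2(0.75) = −0.415; both the tests and the reported quantities use the
simulated depth, and the attenuation shrinks as depth grows. Degenerate
inputs are contracts, not crashes: empty site files warn and return empty
collections, genes or scaffold×sample cells with no retained sites are
dropped and logged, ω is flagged undefined when ΣD_S = 0, and a
convergence window short of genes is redrawn and counted. Percentile
bootstrap/permutation intervals use empirical quantiles with no smoothing;
ties in the rank-sum statistic take midranks.

## Known limitations

* Scaffold orientation within a chromosome is not modeled (placement is by
  gene-median position); at 40-scaffold window resolution orientation does
  not affect the statistics, but sub-scaffold boundary estimates would
  need it.
* RPKM uses raw library sizes (sums of retained-gene counts); TMM-style
  effective library sizes are out of scope, so strongly composition-biased
  libraries would need external normalization.
* The coverage model ties male depth loss to Y-read mis-mapping only;
  duplications or X-ampliconic regions that *raise* male coverage are not
  represented.
* Boundary recovery is limited to roughly half a window span by the moving
  average itself; the tests assert recovery within one window span.
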