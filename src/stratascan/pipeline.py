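"""End-to-end orchestration of the synthetic stratum-detection experiment.

Stages exchange plain TSV files inside one run directory so every
intermediate is inspectable and diffable:

    simulate    site counts, sample sheets, truth, layout, genes,
                expression counts, ortholog table
    coverage    per-scaffold M:F coverage contrast (lab)
    snpdensity  per-gene M:F SNP density (lab) and per-population
                normalized contrasts (wild rivers)
    expression  RPKM, expression filter, per-gene M:F expression
    scan        window tracks and stratum calls
    converge    watershed convergence permutation test
    fasterx     category divergence, permutation and bootstrap inference

Each stage leaves a manifest (parameters, seed, input checksums) next to its
outputs; a fixed global seed makes every stage, and hence the whole run,
byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from . import __version__
from .analysis import (
    coverage_table,
    density_table,
    genes_from_layout,
    population_table,
)
from .convergence import convergence_permutation
from .fasterx import (
    category_permutation_test,
    divergence_report,
    filter_orthologs,
    read_ortholog_table,
)
from .model import GenomeLayout, ValidationError
from .sexdiff import expression_contrast, expression_filter, rpkm
from .simulate import (
    SimSpec,
    default_layout,
    default_sim_spec,
    expression_samples,
    null_sim_spec,
    simulate_expression,
    simulate_orthologs,
    simulate_populations,
    truth_intervals,
)
from .windows import call_strata, calls_to_frame, scan_chromosome, significant_fraction

log = logging.getLogger(__name__)

STAGES = ["simulate", "coverage", "snpdensity", "expression", "scan", "converge", "fasterx"]


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "stratascan_run"
    null_model: bool = False
    # generator scale
    n_autosomes: int = 2
    autosome_mb: float = 25.0
    sex_chrom_mb: float = 26.0
    scaffold_kb: float = 200.0
    sites_per_scaffold: int = 100
    n_per_sex: int = 4
    depth: float = 20.0
    dispersion: float = 5.0
    pi: float = 0.001
    # analysis parameters
    min_cov: int = 10
    minor_frac: float = 0.3
    pseudocount: float = 1.0
    fpkm_threshold: float = 2.0
    window: int = 40
    reps: int = 1000
    alpha: float = 0.05
    min_run: int = 5
    window_mb: float = 10.0
    min_len: int = 300
    max_ds: float = 2.0
    region: tuple[str, int, int] = ("chrX", 15_000_000, 25_000_000)
    stages: list[str] = field(default_factory=lambda: list(STAGES))

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValidationError(
                f"unknown stage(s) {sorted(unknown)}; valid stages: {STAGES}"
            )
        if self.reps < 1 or self.window < 1 or self.min_run < 1:
            raise ValidationError("reps, window and min_run must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "region" in raw:
            raw["region"] = tuple(raw["region"])
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def sim_spec(self) -> SimSpec:
        layout = default_layout(
            n_autosomes=self.n_autosomes,
            autosome_mb=self.autosome_mb,
            sex_chrom_mb=self.sex_chrom_mb,
            scaffold_kb=self.scaffold_kb,
        )
        factory = null_sim_spec if self.null_model else default_sim_spec
        return factory(
            self.seed,
            layout=layout,
            sites_per_scaffold=self.sites_per_scaffold,
            n_per_sex=self.n_per_sex,
            depth=self.depth,
            dispersion=self.dispersion,
            pi=self.pi,
        )


def _checksum(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, config: PipelineConfig,
                    inputs: list[Path], outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": config.seed,
        "parameters": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(config).items()},
        "inputs": {str(p): _checksum(p) for p in inputs if p.exists()},
        "outputs": [str(p) for p in outputs],
        "completed_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    tmp = outdir / f".{stage}.manifest.json.tmp"
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    tmp.replace(outdir / f"{stage}.manifest.json")


def _require(outdir: Path, name: str, producer: str) -> Path:
    p = outdir / name
    if not p.exists():
        raise FileNotFoundError(
            f"missing input {p}; run the '{producer}' stage first"
        )
    return p


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, outdir: Path) -> list[Path]:
    spec = config.sim_spec()
    outputs: list[Path] = []
    datasets, truth = simulate_populations(spec)
    outputs.append(sio.write_layout(spec.layout, outdir / "layout.tsv"))
    genes = genes_from_layout(spec.layout)
    genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    outputs.append(outdir / "genes.tsv")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    outputs.append(outdir / "truth.tsv")
    all_samples = []
    for name, (counts, samples) in datasets.items():
        outputs.append(sio.write_site_counts(counts, outdir / f"sites_{name}.tsv"))
        all_samples.extend(samples)
    outputs.append(sio.write_sample_sheet(all_samples, outdir / "samples.tsv"))

    expr_counts, expr_genes, expr_truth = simulate_expression(spec)
    expr_counts.to_csv(outdir / "expression_counts.tsv", sep="\t")
    expr_genes.to_csv(outdir / "expression_genes.tsv", sep="\t", index=False)
    expr_truth.to_csv(outdir / "expression_truth.tsv", sep="\t", index=False)
    outputs += [outdir / "expression_counts.tsv", outdir / "expression_genes.tsv",
                outdir / "expression_truth.tsv"]
    outputs.append(
        sio.write_sample_sheet(expression_samples(spec), outdir / "expression_samples.tsv")
    )

    orthologs = simulate_orthologs(spec)
    orthologs.to_csv(outdir / "orthologs.tsv", sep="\t", index=False)
    outputs.append(outdir / "orthologs.tsv")
    return outputs


def stage_coverage(config: PipelineConfig, outdir: Path) -> list[Path]:
    sites_path = _require(outdir, "sites_lab.tsv", "simulate")
    layout = sio.read_layout(_require(outdir, "layout.tsv", "simulate"))
    samples = sio.read_sample_sheet(_require(outdir, "samples.tsv", "simulate"))
    sites = sio.read_site_counts(sites_path)
    cov = coverage_table(sites, samples, layout, pseudocount=config.pseudocount)
    out = outdir / "coverage_lab.tsv"
    cov.to_csv(out, sep="\t", index=False)
    _write_manifest(outdir, "coverage", config, [sites_path], [out])
    return [out]


def stage_snpdensity(config: PipelineConfig, outdir: Path) -> list[Path]:
    samples = sio.read_sample_sheet(_require(outdir, "samples.tsv", "simulate"))
    genes = pd.read_csv(_require(outdir, "genes.tsv", "simulate"), sep="\t")
    populations = sorted({s.population for s in samples})
    by_pop = {p: [s for s in samples if s.population == p] for p in populations}
    datasets = {
        p: (sio.read_site_counts(_require(outdir, f"sites_{p}.tsv", "simulate")),
            by_pop[p])
        for p in populations
    }
    lab = density_table(
        datasets["lab"][0], datasets["lab"][1], genes,
        min_cov=config.min_cov, minor_frac=config.minor_frac,
        pseudocount=config.pseudocount,
    )
    out_lab = outdir / "snp_density_lab.tsv"
    lab.to_csv(out_lab, sep="\t", index=False)

    table = population_table(
        datasets, genes, min_cov=config.min_cov, minor_frac=config.minor_frac,
        pseudocount=config.pseudocount,
    )
    out_table = outdir / "snp_density_populations.tsv"
    table.to_csv(out_table, sep="\t", index=False)
    _write_manifest(outdir, "snpdensity", config,
                    [outdir / f"sites_{p}.tsv" for p in populations],
                    [out_lab, out_table])
    return [out_lab, out_table]


def stage_expression(config: PipelineConfig, outdir: Path) -> list[Path]:
    counts = pd.read_csv(
        _require(outdir, "expression_counts.tsv", "simulate"), sep="\t", index_col=0
    )
    genes = pd.read_csv(_require(outdir, "expression_genes.tsv", "simulate"), sep="\t")
    samples = sio.read_sample_sheet(
        _require(outdir, "expression_samples.tsv", "simulate")
    )
    lengths = genes.set_index("gene_id")["length"]
    mat = rpkm(counts, lengths)
    kept = expression_filter(mat, samples, threshold=config.fpkm_threshold)
    summary = expression_contrast(mat.loc[kept], samples,
                                  pseudocount=config.pseudocount)
    summary = summary.merge(genes[["gene_id", "chromosome", "pos"]], on="gene_id")
    summary = summary.sort_values(["chromosome", "pos"]).reset_index(drop=True)
    out = outdir / "expression_summary.tsv"
    summary.to_csv(out, sep="\t", index=False)
    _write_manifest(outdir, "expression", config,
                    [outdir / "expression_counts.tsv"], [out])
    return [out]


def _scan_tables(config: PipelineConfig, outdir: Path, table: pd.DataFrame,
                 value_col: str, statistic: str, layout: GenomeLayout,
                 label: str) -> tuple[list, list[Path], float]:
    sex_chrom = layout.sex_chromosome
    autosomal = table.loc[table["chromosome"] != sex_chrom, value_col].to_numpy()
    rng = np.random.default_rng(config.seed + hash_stable(label))
    from .windows import autosomal_bootstrap_ci

    band = autosomal_bootstrap_ci(autosomal, window=config.window,
                                  reps=config.reps, alpha=config.alpha, seed=rng)
    outputs = []
    calls = []
    fractions = []
    for chrom in sorted(table["chromosome"].unique()):
        sub = table[table["chromosome"] == chrom].sort_values("pos")
        if len(sub) < config.window:
            log.info("chromosome %s has fewer units than the window; skipped", chrom)
            continue
        track = scan_chromosome(
            chrom, sub["pos"].to_numpy(), sub[value_col].to_numpy(),
            autosomal, window=config.window, band=band,
        )
        path = outdir / f"track_{label}_{chrom}.bed"
        sio.write_track(track, path)
        outputs.append(path)
        fractions.append(track)
        if chrom == sex_chrom:
            calls.extend(call_strata(track, statistic, min_run=config.min_run))
    return calls, outputs, significant_fraction(fractions)


def hash_stable(label: str) -> int:
    import zlib

    return zlib.crc32(label.encode())


def stage_scan(config: PipelineConfig, outdir: Path) -> list[Path]:
    layout = sio.read_layout(_require(outdir, "layout.tsv", "simulate"))
    cov = pd.read_csv(_require(outdir, "coverage_lab.tsv", "coverage"), sep="\t")
    snp = pd.read_csv(_require(outdir, "snp_density_lab.tsv", "snpdensity"), sep="\t")
    cov_calls, cov_out, cov_frac = _scan_tables(
        config, outdir, cov, "log2_mf", "coverage", layout, "coverage"
    )
    snp_calls, snp_out, snp_frac = _scan_tables(
        config, outdir, snp, "log2_mf", "snp_density", layout, "snp"
    )
    calls = calls_to_frame(cov_calls + snp_calls)
    out = outdir / "strata.tsv"
    calls.to_csv(out, sep="\t", index=False)
    frac = {"coverage_significant_fraction": cov_frac,
            "snp_significant_fraction": snp_frac}
    with open(outdir / "scan_summary.json", "w") as fh:
        json.dump(frac, fh, indent=2)
    _write_manifest(outdir, "scan", config,
                    [outdir / "coverage_lab.tsv", outdir / "snp_density_lab.tsv"],
                    cov_out + snp_out + [out])
    return [out]


def stage_converge(config: PipelineConfig, outdir: Path) -> list[Path]:
    layout = sio.read_layout(_require(outdir, "layout.tsv", "simulate"))
    table = pd.read_csv(
        _require(outdir, "snp_density_populations.tsv", "snpdensity"), sep="\t"
    )
    rivers = sorted({c[:-3] for c in table.columns if c.endswith("_up")}
                    & {c[:-5] for c in table.columns if c.endswith("_down")})
    result = convergence_permutation(
        table, layout, rivers,
        region=config.region, window_mb=config.window_mb,
        reps=config.reps, alpha=config.alpha, seed=config.seed,
        band_window=config.window,
    )
    out = outdir / "convergence.json"
    with open(out, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)
    _write_manifest(outdir, "converge", config,
                    [outdir / "snp_density_populations.tsv"], [out])
    return [out]


def stage_fasterx(config: PipelineConfig, outdir: Path) -> list[Path]:
    rows = read_ortholog_table(_require(outdir, "orthologs.tsv", "simulate"))
    rows = filter_orthologs(rows, min_len=config.min_len, max_ds=config.max_ds)
    x_cats = [c for c in rows["category"].unique() if c.startswith("X")]
    x_all = rows.copy()
    x_all.loc[x_all["category"].isin(x_cats), "category"] = "X_all"
    report = divergence_report(rows, reps=config.reps, alpha=config.alpha,
                               seed=config.seed)
    report_all = divergence_report(x_all, categories=["X_all", "autosome"],
                                   reps=config.reps, alpha=config.alpha,
                                   seed=config.seed)
    tests = {
        "omega_X_vs_A_one_tailed": category_permutation_test(
            x_all, "X_all", "autosome", "omega", reps=config.reps,
            tail="one_tailed_a_greater", seed=config.seed
        ),
        "dN_X_vs_A_two_tailed": category_permutation_test(
            x_all, "X_all", "autosome", "dN", reps=config.reps,
            tail="two_tailed", seed=config.seed + 1
        ),
        "dS_X_vs_A_two_tailed": category_permutation_test(
            x_all, "X_all", "autosome", "dS", reps=config.reps,
            tail="two_tailed", seed=config.seed + 2
        ),
    }
    out_tsv = outdir / "fasterx_divergence.tsv"
    pd.concat([report, report_all], ignore_index=True).to_csv(
        out_tsv, sep="\t", index=False
    )
    out_json = outdir / "fasterx_tests.json"
    with open(out_json, "w") as fh:
        json.dump(tests, fh, indent=2)
    _write_manifest(outdir, "fasterx", config, [outdir / "orthologs.tsv"],
                    [out_tsv, out_json])
    return [out_tsv, out_json]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "coverage": stage_coverage,
    "snpdensity": stage_snpdensity,
    "expression": stage_expression,
    "scan": stage_scan,
    "converge": stage_converge,
    "fasterx": stage_fasterx,
}


def run_stage(name: str, config: PipelineConfig) -> list[Path]:
    if name not in _STAGE_FUNCS:
        raise ValidationError(f"unknown stage {name!r}; valid stages: {STAGES}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    outputs = _STAGE_FUNCS[name](config, outdir)
    if name == "simulate":
        _write_manifest(outdir, "simulate", config, [], outputs)
    log.info("stage %s finished in %.1f s", name, time.time() - t0)
    return outputs


def _boundary_error_bp(calls: pd.DataFrame, evidence: str,
                       truth_ivals: list[tuple[int, int]]) -> dict[str, Any]:
    sub = calls[calls["evidence"] == evidence]
    if sub.empty or not truth_ivals:
        return {"detected": len(sub) > 0, "expected": len(truth_ivals) > 0}
    # match each truth interval to the closest call
    errors = []
    for t_start, t_end in truth_ivals:
        centre = 0.5 * (t_start + t_end)
        best = min(sub.itertuples(),
                   key=lambda c: abs(0.5 * (c.start + c.end) - centre))
        errors.append({"truth": [t_start, t_end],
                       "call": [int(best.start), int(best.end)],
                       "start_error_bp": int(best.start - t_start),
                       "end_error_bp": int(best.end - t_end)})
    return {"detected": True, "expected": True, "matches": errors}


def run_all(config: PipelineConfig) -> dict[str, Any]:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"seed": config.seed, "stages_run": []}
    for name in STAGES:
        if name not in config.stages:
            report[name] = "skipped"
            continue
        try:
            run_stage(name, config)
        except Exception as e:
            raise RuntimeError(f"stage {name!r} failed: {e}") from e
        report["stages_run"].append(name)

    # recovery scoring against the simulation truth table
    if "scan" in config.stages and "simulate" in config.stages:
        truth = pd.read_csv(outdir / "truth.tsv", sep="\t")
        lab_truth = truth[truth["population"] == "lab"]
        calls = pd.read_csv(outdir / "strata.tsv", sep="\t")
        window_span_bp = int(config.window * config.scaffold_kb * 1e3)
        report["stratum_recovery"] = {
            "window_span_bp": window_span_bp,
            "coverage_deficit": _boundary_error_bp(
                calls, "coverage_deficit", truth_intervals(lab_truth, "coverage_deficit")
            ),
            "snp_excess": _boundary_error_bp(
                calls, "snp_excess", truth_intervals(lab_truth, "snp_excess")
            ),
        }
        with open(outdir / "scan_summary.json") as fh:
            report["scan_summary"] = json.load(fh)
    if "converge" in config.stages:
        with open(outdir / "convergence.json") as fh:
            report["convergence"] = json.load(fh)
    if "fasterx" in config.stages:
        with open(outdir / "fasterx_tests.json") as fh:
            report["fasterx_tests"] = json.load(fh)
        report["fasterx_divergence"] = pd.read_csv(
            outdir / "fasterx_divergence.tsv", sep="\t"
        ).to_dict(orient="records")
    if "expression" in config.stages and "simulate" in config.stages:
        est = pd.read_csv(outdir / "expression_summary.tsv", sep="\t")
        truth_e = pd.read_csv(outdir / "expression_truth.tsv", sep="\t")
        merged = est.merge(truth_e, on="gene_id")
        if merged["true_log2_mf"].abs().sum() > 0:
            slope = float(np.polyfit(merged["true_log2_mf"],
                                     merged["log2_mf"], 1)[0])
        else:
            slope = float("nan")
        report["expression_recovery_slope"] = slope

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
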