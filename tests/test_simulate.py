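import numpy as np
import pandas as pd
import pytest

from stratascan.model import ValidationError, coverage_of
from stratascan.simulate import (
    OrthologSpec,
    PopulationSpec,
    StratumSpec,
    default_layout,
    default_sim_spec,
    effective_strata,
    expected_log2_mf_coverage,
    null_sim_spec,
    simulate_expression,
    simulate_orthologs,
    simulate_populations,
    simulate_site_counts,
    truth_intervals,
)

from conftest import small_spec


def _sex_mean_coverage(counts, samples, mask=None):
    df = counts if mask is None else counts[mask]
    cov = df.assign(coverage=coverage_of(df)).groupby("sample")["coverage"].mean()
    by_sex = {s.sample_id: s.sex for s in samples}
    out = cov.groupby(by_sex).mean()
    return out["male"], out["female"]


class TestSiteCounts:
    def test_same_seed_is_byte_identical(self):
        a, _, _ = simulate_site_counts(small_spec(7), "lab")
        b, _, _ = simulate_site_counts(small_spec(7), "lab")
        pd.testing.assert_frame_equal(a, b)

    def test_null_model_is_sex_symmetric(self):
        spec = small_spec(1, strata=[], sites_per_scaffold=60, n_per_sex=4)
        counts, samples, _ = simulate_site_counts(spec, "lab")
        m, f = _sex_mean_coverage(counts, samples)
        # both sexes share the NB(depth) model; 64k sites per sex
        assert m == pytest.approx(f, rel=0.02)
        assert m == pytest.approx(spec.depth, rel=0.02)

    def test_y_loss_halves_y_coverage(self):
        # δ=0.5 over a whole-chromosome stratum: male:female coverage -> 0.75.
        # Oracle: analytic expectation (1 − δ/2), Monte Carlo over >=1e5 sites.
        spec = small_spec(
            3,
            strata=[StratumSpec(0, 26_000_000, y_loss=0.5, name="s")],
            sites_per_scaffold=400,
            n_per_sex=3,
        )
        counts, samples, _ = simulate_site_counts(spec, "lab")
        on_x = counts["scaffold"].str.startswith("chrX")
        assert int(on_x.sum()) >= 1e5
        m, f = _sex_mean_coverage(counts, samples, on_x)
        assert m / f == pytest.approx(0.75, abs=0.01)

    def test_xy_divergence_creates_male_only_het(self):
        spec = small_spec(4, sites_per_scaffold=100, n_per_sex=2)
        counts, samples, truth = simulate_site_counts(spec, "lab")
        sexes = {s.sample_id: s.sex for s in samples}
        on_x = counts["scaffold"].str.startswith("chrX")
        x = counts[on_x].copy()
        x["cov"] = coverage_of(x)
        x["second"] = np.partition(
            x[["A", "C", "G", "T"]].to_numpy(), 2, axis=1
        )[:, 2]
        x["het"] = x["second"] >= 0.3 * x["cov"]
        het_rate = x.groupby(x["sample"].map(sexes))["het"].mean()
        assert het_rate["male"] > 2 * het_rate["female"]

    def test_unknown_population_rejected(self):
        with pytest.raises(ValidationError):
            simulate_site_counts(small_spec(0), "nonesuch")

    def test_stream_independence_across_populations(self):
        # adding a population never perturbs another population's stream
        base = small_spec(11)
        more = small_spec(
            11,
            populations=base.populations + [PopulationSpec("Quare_up"),
                                            PopulationSpec("Quare_down")],
        )
        a, _, _ = simulate_site_counts(base, "lab")
        b, _, _ = simulate_site_counts(more, "lab")
        pd.testing.assert_frame_equal(a, b)


class TestTruth:
    def test_truth_records_analytic_expectations(self):
        spec = small_spec(0)
        _, _, truth = simulate_site_counts(spec, "lab")
        s1 = truth[truth["region"] == "stratum1"].iloc[0]
        assert s1["expected_log2_mf_coverage"] == pytest.approx(
            expected_log2_mf_coverage(spec.depth, 0.5)
        )
        assert expected_log2_mf_coverage(20, 0.5) == pytest.approx(
            np.log2(16 / 21)
        )

    def test_truth_intervals_merge_adjacent_snp_strata(self):
        _, _, truth = simulate_site_counts(small_spec(0), "lab")
        assert truth_intervals(truth, "coverage_deficit") == [(22_000_000, 25_000_000)]
        assert truth_intervals(truth, "snp_excess") == [(15_000_000, 25_000_000)]


class TestPopulations:
    def test_bookkeeping_three_pairs_plus_lab(self):
        spec = default_sim_spec(0, sites_per_scaffold=5, n_per_sex=1)
        datasets, truth = simulate_populations(spec)
        assert len(datasets) == 7 and "lab" in datasets
        assert set(truth["population"]) == set(datasets)

    def test_missing_pair_member_rejected(self):
        spec = small_spec(0, populations=[PopulationSpec("lab"),
                                          PopulationSpec("Yarra_up")])
        with pytest.raises(ValidationError, match="pair"):
            simulate_populations(spec)

    def test_upstream_stratum_extends_further(self):
        spec = default_sim_spec(0, sites_per_scaffold=5, n_per_sex=1)
        up = effective_strata(spec, "Yarra_up")
        down = effective_strata(spec, "Yarra_down")
        s2_up = next(s for s in up if s.name == "stratum2")
        s2_down = next(s for s in down if s.name == "stratum2")
        assert s2_up.end > s2_down.end
        assert s2_up.xy_divergence == 2 * s2_down.xy_divergence

    def test_null_spec_has_no_effects(self):
        spec = null_sim_spec(0, sites_per_scaffold=5, n_per_sex=1)
        for pop in ("lab", "Yarra_up"):
            for s in effective_strata(spec, pop):
                assert s.y_loss == 0 and s.xy_divergence == 0


class TestExpression:
    def test_zero_bias_means_flat_truth(self):
        spec = small_spec(0)
        spec.expression = type(spec.expression)(n_genes=200, bias_magnitude=0.0)
        _, _, truth = simulate_expression(spec)
        assert (truth["true_log2_mf"] == 0).all()

    def test_seed_reproducibility(self):
        a, _, _ = simulate_expression(small_spec(5))
        b, _, _ = simulate_expression(small_spec(5))
        pd.testing.assert_frame_equal(a, b)

    def test_biased_genes_confined_to_strata(self):
        _, _, truth = simulate_expression(small_spec(2))
        biased = truth[truth["true_log2_mf"] != 0]
        assert (biased["chromosome"] == "chrX").all()
        assert biased["pos"].between(15_000_000, 25_000_000).all()

    def test_invalid_gene_count_rejected(self):
        with pytest.raises(ValidationError):
            OrthologSpec(n_per_category=0)
        with pytest.raises(ValidationError):
            type(small_spec(0).expression)(n_genes=0)


class TestOrthologs:
    def test_rate_recovery_within_3_mc_se(self):
        # Poisson oracle: SE(ΣDN/ΣN) = sqrt(dN/ΣN) at 500 genes/category
        spec = small_spec(9)
        rows = simulate_orthologs(spec)
        for cat, dn_true in spec.orthologs.dn.items():
            sub = rows[rows["category"] == cat]
            dn_hat = sub["DN"].sum() / sub["N"].sum()
            se = np.sqrt(dn_true / sub["N"].sum())
            assert abs(dn_hat - dn_true) < 3 * se

    def test_zero_ds_rejected(self):
        with pytest.raises(ValidationError, match="undefined"):
            OrthologSpec(ds={"autosome": 0.0, "X_stratum1": 0.1, "X_stratum2": 0.1})

    def test_seed_reproducibility(self):
        pd.testing.assert_frame_equal(
            simulate_orthologs(small_spec(3)), simulate_orthologs(small_spec(3))
        )


def test_default_layout_flags_one_sex_chromosome():
    layout = default_layout(n_autosomes=3)
    assert layout.sex_chromosome == "chrX"
    assert len(layout.autosomes) == 3
    spans = [s for s in layout.scaffolds if s.chromosome == "chrX"]
    assert spans[0].chrom_start == 1 and spans[-1].chrom_end == layout.chromosome_length("chrX")
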