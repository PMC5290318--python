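import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stratascan.model import SampleInfo, ValidationError
from stratascan.sexdiff import (
    call_snp_sites,
    expression_contrast,
    expression_filter,
    gene_snp_density,
    mf_log2_ratio,
    normalize_by_x_median,
    relative_to_reference,
    rpkm,
    scaffold_coverage,
    snp_density_contrast,
)

from conftest import make_counts


class TestScaffoldCoverage:
    def test_arithmetic_mean_over_sequenced_sites(self):
        df = make_counts([("s1", i + 1, "M1", c, 0, 0, 0)
                          for i, c in enumerate([10, 20, 30])])
        out = scaffold_coverage(df)
        assert out["mean_coverage"].iloc[0] == 20

    def test_single_site(self):
        out = scaffold_coverage(make_counts([("s1", 1, "M1", 7, 0, 0, 0)]))
        assert out["mean_coverage"].iloc[0] == 7

    def test_zero_coverage_sites_excluded_from_denominator(self):
        df = make_counts([("s1", 1, "M1", 10, 0, 0, 0), ("s1", 2, "M1", 0, 0, 0, 0)])
        assert scaffold_coverage(df)["mean_coverage"].iloc[0] == 10

    def test_fully_unsequenced_scaffold_missing(self):
        df = make_counts([("s1", 1, "M1", 0, 0, 0, 0)])
        assert scaffold_coverage(df).empty


class TestMFLog2Ratio:
    @pytest.mark.parametrize("m, f, expected", [(5, 5, 0.0), (3, 1, 1.0), (0, 0, 0.0)])
    def test_examples(self, m, f, expected):
        assert mf_log2_ratio(m, f) == pytest.approx(expected)

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            mf_log2_ratio(-1, 2)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    def test_antisymmetry(self, m, f):
        assert mf_log2_ratio(m, f) == pytest.approx(-mf_log2_ratio(f, m), abs=1e-9)


class TestSNPCalling:
    @pytest.mark.parametrize(
        "counts, retained, is_snp",
        [
            ((5, 5, 0, 0), True, True),  # minor 5 >= 0.3*10
            ((8, 2, 0, 0), True, False),  # 2 < 3
            ((6, 3, 0, 0), False, False),  # coverage 9 < 10: site excluded
            ((7, 3, 0, 0), True, True),  # boundary: 3 >= 3
        ],
    )
    def test_call_rule(self, counts, retained, is_snp):
        df = make_counts([("s1", 1, "M1", *counts)])
        out = call_snp_sites(df)
        assert bool(out["retained"].iloc[0]) is retained
        assert bool(out["is_snp"].iloc[0]) is is_snp

    def test_parameter_validation(self):
        df = make_counts([("s1", 1, "M1", 5, 5, 0, 0)])
        with pytest.raises(ValidationError):
            call_snp_sites(df, min_cov=0)
        with pytest.raises(ValidationError):
            call_snp_sites(df, minor_frac=0.6)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(10, 60), st.integers(0, 30))
    def test_monotone_in_minor_count(self, major, minor):
        """At fixed coverage, raising the minor-allele count never un-calls."""
        cov = major + minor
        df = make_counts([
            ("s1", 1, "M1", major, minor, 0, 0),
            ("s1", 2, "M1", major - 1, minor + 1, 0, 0),
        ])
        out = call_snp_sites(df)
        if minor + 1 <= (cov) / 2:  # still the minor allele
            assert (not out["is_snp"].iloc[0]) or out["is_snp"].iloc[1]


GENES = pd.DataFrame(
    {"gene_id": ["gA"], "scaffold": ["s1"], "start": [1], "end": [1000]}
)


class TestGeneDensity:
    def test_density_is_snps_over_filtered_sites(self):
        rows = [("s1", i + 1, "M1", 20, 0, 0, 0) for i in range(198)]
        rows += [("s1", 300, "M1", 10, 10, 0, 0), ("s1", 301, "M1", 12, 8, 0, 0)]
        flagged = call_snp_sites(make_counts(rows))
        dens = gene_snp_density(flagged, GENES)
        assert dens["snp_density"].iloc[0] == pytest.approx(2 / 200)

    def test_zero_filtered_sites_drops_gene(self):
        flagged = call_snp_sites(make_counts([("s1", 1, "M1", 3, 0, 0, 0)]))
        assert gene_snp_density(flagged, GENES).empty

    def test_sites_outside_genes_ignored(self):
        flagged = call_snp_sites(make_counts([("s1", 2000, "M1", 20, 0, 0, 0)]))
        assert gene_snp_density(flagged, GENES).empty

    def test_contrast_zero_density_maps_to_zero_log(self):
        rows = [("s1", i + 1, s, 20, 0, 0, 0) for i in range(50)
                for s in ("M1", "F1")]
        flagged = call_snp_sites(make_counts(rows))
        dens = gene_snp_density(flagged, GENES)
        samples = [SampleInfo("M1", "male", "lab"), SampleInfo("F1", "female", "lab")]
        out = snp_density_contrast(dens, samples)
        assert out["log2_mf"].iloc[0] == 0.0

    def test_pooled_vs_mean_of_individuals(self):
        # individuals with different filtered-site counts make the two
        # definitions differ; the default is the mean of individual densities
        rows = [("s1", i + 1, "M1", 10, 10, 0, 0) for i in range(10)]  # dens 1.0
        rows += [("s1", i + 1, "M2", 20, 0, 0, 0) for i in range(30)]  # dens 0.0
        rows += [("s1", i + 1, "F1", 20, 0, 0, 0) for i in range(10)]
        flagged = call_snp_sites(make_counts(rows))
        dens = gene_snp_density(flagged, GENES)
        samples = [SampleInfo("M1", "male", "lab"), SampleInfo("M2", "male", "lab"),
                   SampleInfo("F1", "female", "lab")]
        mean_based = snp_density_contrast(dens, samples)
        pooled = snp_density_contrast(dens, samples, pooled=True)
        assert mean_based["male_density"].iloc[0] == pytest.approx(0.5)
        assert pooled["male_density"].iloc[0] == pytest.approx(10 / 40)


class TestNormalization:
    def test_x_median_subtraction(self):
        vals = pd.Series({"x1": 1.0, "x2": 2.0, "x3": 3.0, "a1": 5.0})
        out = normalize_by_x_median(vals, ["x1", "x2", "x3"])
        assert out["x2"] == 0.0
        assert out["a1"] == 3.0
        assert np.median(out[["x1", "x2", "x3"]]) == 0.0

    def test_requires_x_genes(self):
        with pytest.raises(ValidationError):
            normalize_by_x_median(pd.Series({"a": 1.0}), [])

    def test_reference_to_self_is_zero(self):
        vals = pd.Series({"g1": 0.3, "g2": -0.1})
        out = relative_to_reference(vals, vals)
        assert (out == 0).all()

    def test_reference_intersection(self):
        pop = pd.Series({"g1": 1.0, "g2": 2.0})
        ref = pd.Series({"g2": 0.5, "g3": 9.0})
        out = relative_to_reference(pop, ref)
        assert list(out.index) == ["g2"] and out["g2"] == 1.5
        with pytest.raises(ValidationError):
            relative_to_reference(pop, pd.Series({"zz": 1.0}))


class TestExpression:
    def _mat(self, data, samples):
        return pd.DataFrame(data, index=[f"g{i}" for i in range(len(data))],
                            columns=samples)

    def test_rpkm_examples(self):
        counts = self._mat([[10], [0], [20]], ["s1"])
        lengths = pd.Series([1000, 1000, 500], index=counts.index)
        libs = pd.Series([1e6], index=["s1"])
        out = rpkm(counts, lengths, libs)
        assert list(out["s1"]) == [10.0, 0.0, 20.0 / 0.5]
        out2 = rpkm(counts, lengths, pd.Series([2e6], index=["s1"]))
        assert out2["s1"].iloc[2] == pytest.approx(20 / (0.5 * 2))

    def test_zero_library_size_rejected(self):
        counts = self._mat([[10]], ["s1"])
        with pytest.raises(ValidationError):
            rpkm(counts, pd.Series([1000], index=counts.index),
                 pd.Series([0.0], index=["s1"]))

    def _samples(self):
        return ([SampleInfo(f"M{i}", "male", "lab", "rna") for i in range(1, 5)]
                + [SampleInfo(f"F{i}", "female", "lab", "rna") for i in range(1, 5)])

    def test_filter_half_of_either_sex(self):
        cols = [f"M{i}" for i in range(1, 5)] + [f"F{i}" for i in range(1, 5)]
        mat = pd.DataFrame(
            [
                [2.0, 2.0, 0, 0, 0, 0, 0, 0],  # 2 of 4 males at threshold: kept
                [1.9] * 8,  # below threshold everywhere: removed
                [0, 0, 0, 0, 2.0, 2.0, 0, 0],  # 2 of 4 females: kept
                [2.0, 0, 0, 0, 0, 0, 0, 0],  # 1 of 4 males only: removed
            ],
            index=["keep_m", "drop_low", "keep_f", "drop_one"],
            columns=cols,
        )
        kept = expression_filter(mat, self._samples(), threshold=2.0)
        assert set(kept) == {"keep_m", "keep_f"}

    def test_filter_requires_both_sexes(self):
        mat = pd.DataFrame([[5.0]], index=["g"], columns=["M1"])
        with pytest.raises(ValidationError):
            expression_filter(mat, [SampleInfo("M1", "male", "lab", "rna")])

    def test_contrast_means_and_ratio(self):
        cols = [f"M{i}" for i in range(1, 5)] + [f"F{i}" for i in range(1, 5)]
        mat = pd.DataFrame([[3.0] * 4 + [1.0] * 4], index=["g"], columns=cols)
        out = expression_contrast(mat, self._samples())
        assert out["log2_mf"].iloc[0] == pytest.approx(1.0)  # log2(4)-log2(2)
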