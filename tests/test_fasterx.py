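from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from stratascan.fasterx import (
    aggregate_divergence,
    bootstrap_ci_divergence,
    category_permutation_test,
    divergence_report,
    filter_orthologs,
    read_ortholog_table,
    validate_orthologs,
)
from stratascan.model import ValidationError


def make_rows(specs):
    """Rows from (category, DN, DS, N, S) tuples."""
    rows = []
    for i, (cat, dn, ds, n, s) in enumerate(specs):
        rows.append({"gene_id": f"g{i}", "category": cat, "DN": dn, "DS": ds,
                     "N": n, "S": s, "branch_ds": ds / s, "aln_len": n + s})
    return pd.DataFrame(rows)


class TestFilter:
    def test_saturated_ds_excluded(self):
        rows = make_rows([("autosome", 1, 250, 300, 100)])  # branch dS = 2.5
        assert filter_orthologs(rows).empty

    def test_short_alignment_excluded(self):
        rows = make_rows([("autosome", 1, 5, 150, 100)])  # aln 250 bp
        assert filter_orthologs(rows).empty

    def test_boundaries_retained(self):
        rows = make_rows([("autosome", 1, 200, 200, 100)])  # dS = 2.0, aln 300
        assert len(filter_orthologs(rows)) == 1


class TestAggregate:
    def test_sum_then_divide(self):
        rows = make_rows([("autosome", 2, 1, 100, 50), ("autosome", 4, 1, 300, 50)])
        cd = aggregate_divergence(rows, "autosome")
        assert cd.dN == pytest.approx(6 / 400)
        assert cd.dS == pytest.approx(2 / 100)
        assert cd.omega == pytest.approx((6 / 400) / (2 / 100))

    def test_single_row_equals_per_gene_ratio(self):
        rows = make_rows([("X_all", 3, 2, 100, 50)])
        cd = aggregate_divergence(rows, "X_all")
        assert cd.omega == pytest.approx((3 / 100) / (2 / 50))

    def test_duplication_invariance(self):
        rows = make_rows([("a", 2, 1, 100, 50), ("a", 4, 3, 300, 70)])
        doubled = pd.concat([rows, rows], ignore_index=True)
        a, b = aggregate_divergence(rows, "a"), aggregate_divergence(doubled, "a")
        assert (a.dN, a.dS, a.omega) == (b.dN, b.dS, b.omega)

    def test_empty_category_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_divergence(make_rows([("a", 1, 1, 10, 10)]), "b")

    def test_zero_ds_flags_omega_undefined(self):
        cd = aggregate_divergence(make_rows([("a", 1, 0, 10, 10)]), "a")
        assert np.isnan(cd.omega)

    def test_matches_independent_oracle_from_reparsed_table(self, tmp_path, rng):
        n = 200
        df = make_rows([
            ("a", int(rng.poisson(5)), int(rng.poisson(10)),
             int(rng.integers(100, 900)), int(rng.integers(50, 300)))
            for _ in range(n)
        ])
        path = tmp_path / "orth.tsv"
        df.to_csv(path, sep="\t", index=False)
        cd = aggregate_divergence(read_ortholog_table(path), "a")
        # oracle: independent line-by-line sums over the raw text
        dn = ds = nn = ss = 0
        for line in path.read_text().splitlines()[1:]:
            f = line.split("\t")
            dn += int(f[2]); ds += int(f[3]); nn += int(f[4]); ss += int(f[5])
        assert cd.dN == pytest.approx(dn / nn, abs=1e-12)
        assert cd.dS == pytest.approx(ds / ss, abs=1e-12)
        assert cd.omega == pytest.approx((dn / nn) / (ds / ss), abs=1e-12)


class TestReader:
    def test_accepts_rates_instead_of_counts(self, tmp_path):
        path = tmp_path / "rates.tsv"
        pd.DataFrame({"gene_id": ["g"], "category": ["a"], "dn": [0.01],
                      "ds": [0.1], "N": [500], "S": [100]}).to_csv(
            path, sep="\t", index=False)
        df = read_ortholog_table(path)
        assert df["DN"].iloc[0] == pytest.approx(5.0)
        assert df["DS"].iloc[0] == pytest.approx(10.0)

    def test_invalid_sites_rejected(self):
        with pytest.raises(ValidationError):
            validate_orthologs(make_rows([("a", 1, 1, 0, 10)]))


def exact_label_permutation_p(rows, cat_a, cat_b, statistic):
    """Full enumeration of label splits at tiny n (oracle)."""
    pool = rows.reset_index(drop=True)
    n_a = int((pool["category"] == cat_a).sum())

    def stat(sub):
        dN = sub["DN"].sum() / sub["N"].sum()
        dS = sub["DS"].sum() / sub["S"].sum()
        return {"dN": dN, "dS": dS, "omega": dN / dS}[statistic]

    obs = stat(pool[pool["category"] == cat_a]) - stat(pool[pool["category"] == cat_b])
    deltas = []
    for idx in combinations(range(len(pool)), n_a):
        a = pool.iloc[list(idx)]
        b = pool.drop(index=list(idx))
        deltas.append(stat(a) - stat(b))
    return float(np.mean(np.array(deltas) >= obs))


class TestPermutation:
    def test_converges_to_exact_enumeration_on_tiny_input(self):
        rows = make_rows([
            ("a", 9, 2, 100, 50), ("a", 7, 3, 120, 60), ("a", 8, 2, 90, 40),
            ("b", 1, 2, 110, 55), ("b", 2, 3, 100, 55), ("b", 0, 2, 95, 55),
        ])
        exact = exact_label_permutation_p(rows, "a", "b", "omega")
        reps = 20_000
        p = category_permutation_test(rows, "a", "b", "omega", reps=reps,
                                      tail="one_tailed_a_greater", seed=0)
        assert p == pytest.approx((exact * reps + 1) / (reps + 1), abs=0.01)

    def test_same_seed_identical(self):
        rows = make_rows([("a", i, 2, 100, 50) for i in range(6)]
                         + [("b", i, 2, 100, 50) for i in range(6)])
        kw = dict(statistic="dN", reps=200, seed=3)
        assert category_permutation_test(rows, "a", "b", **kw) == \
            category_permutation_test(rows, "a", "b", **kw)

    def test_add_one_never_zero(self):
        rows = make_rows([("a", 50, 2, 100, 50)] * 3 + [("b", 0, 2, 100, 50)] * 3)
        p = category_permutation_test(rows, "a", "b", "dN", reps=100, seed=1)
        assert p >= 1 / 101

    def test_validation(self):
        rows = make_rows([("a", 1, 1, 10, 10), ("b", 1, 1, 10, 10)])
        with pytest.raises(ValidationError):
            category_permutation_test(rows, "a", "b", "dN", reps=0)
        with pytest.raises(ValidationError):
            category_permutation_test(rows, "a", "c", "dN")
        with pytest.raises(ValidationError):
            category_permutation_test(rows, "a", "b", "gc_content")


class TestBootstrap:
    def test_single_row_degenerate_ci(self):
        rows = make_rows([("a", 4, 2, 100, 50)])
        ci = bootstrap_ci_divergence(rows, "a", reps=100, seed=0)
        assert ci["omega"][0] == ci["omega"][1] == pytest.approx((4 / 100) / (2 / 50))

    def test_ci_contains_point_estimate(self, rng):
        rows = make_rows([
            ("a", int(rng.poisson(5)), int(rng.poisson(10)),
             int(rng.integers(200, 800)), int(rng.integers(80, 250)))
            for _ in range(150)
        ])
        cd = aggregate_divergence(rows, "a")
        ci = bootstrap_ci_divergence(rows, "a", reps=500, seed=1)
        for stat, val in (("dN", cd.dN), ("dS", cd.dS), ("omega", cd.omega)):
            assert ci[stat][0] <= val <= ci[stat][1]

    def test_ci_width_shrinks_with_sample_size(self, rng):
        def width(n, seed):
            rows = make_rows([
                ("a", int(rng.poisson(5)), int(rng.poisson(10)), 500, 150)
                for _ in range(n)
            ])
            lo, hi = bootstrap_ci_divergence(rows, "a", reps=400, seed=seed)["dN"]
            return hi - lo
        w100 = np.mean([width(100, s) for s in range(3)])
        w400 = np.mean([width(400, s) for s in range(3)])
        assert w400 < 0.7 * w100  # ~1/2 expected from 1/sqrt(n)

    def test_report_covers_all_categories(self):
        rows = make_rows([("a", 1, 2, 100, 50), ("b", 2, 2, 100, 50)])
        rep = divergence_report(rows, reps=50)
        assert set(rep["category"]) == {"a", "b"}
        assert {"omega_ci_low", "omega_ci_high"} <= set(rep.columns)
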