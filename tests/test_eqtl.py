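"""Association model: MAF, inverse-normal transform, OLS, BH, run semantics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spatialeqtl.eqtl import (
    ConstantExpressionError,
    DegenerateFitError,
    MonomorphicError,
    SpatialEQTL,
    bh_adjust,
    compute_maf,
    export_manhattan,
    inverse_normal_transform,
    test_association as ols_association,
)


class TestMaf:
    @pytest.mark.parametrize(
        "dosages, expected",
        [([0, 0, 1, 1, 2], 0.4), ([0, 0, 0], 0.0), ([2, 2, 2], 0.0), ([1, 1], 0.5)],
    )
    def test_examples(self, dosages, expected):
        assert compute_maf(np.array(dosages)) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_maf(np.array([]))

    def test_missing_dropped(self):
        assert compute_maf(np.array([0, 2, np.nan])) == pytest.approx(0.5)


class TestInverseNormal:
    def test_quantile_values(self):
        out = inverse_normal_transform(np.array([10.0, 20.0, 30.0]))
        assert out == pytest.approx([-0.967422, 0.0, 0.967422], abs=1e-5)

    def test_monotone_and_zero_mean(self):
        x = np.random.default_rng(0).normal(size=101)
        y = inverse_normal_transform(x)
        assert (np.diff(y[np.argsort(x)]) > 0).all()
        assert abs(y.mean()) < 1e-10

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        perm = rng.permutation(50)
        assert np.allclose(inverse_normal_transform(x)[perm],
                           inverse_normal_transform(x[perm]))

    def test_constant_input_flagged(self):
        with pytest.raises(ConstantExpressionError):
            inverse_normal_transform(np.full(10, 3.0))


class TestAssociation:
    def test_perfect_fit_flagged_degenerate(self):
        g = np.array([0., 1, 2] * 4)
        with pytest.raises(DegenerateFitError):
            ols_association(g, 3 + 2 * g)

    def test_monomorphic_flagged(self):
        with pytest.raises(MonomorphicError):
            ols_association(np.zeros(20), np.random.default_rng(0).normal(size=20))

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            ols_association(np.arange(5.0), np.arange(5.0))

    def test_planted_beta_within_3se(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(2, 0.3, size=200).astype(float)
        y = 1.0 + 1.0 * g + rng.normal(size=200)
        beta, se, p = ols_association(g, y)
        assert abs(beta - 1.0) < 3 * se

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(1000):
            g = rng.binomial(2, 0.3, size=60).astype(float)
            if np.ptp(g) == 0:
                continue
            ps.append(ols_association(g, rng.normal(size=60))[2])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


def textbook_bh_rejections(p: np.ndarray, alpha: float) -> np.ndarray:
    """Classic step-up rule, implemented independently of the package."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    k = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= i * alpha / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


class TestBH:
    def test_hand_computed_example(self):
        out = bh_adjust(np.array([0.005, 0.01, 0.03]))
        assert out == pytest.approx([0.015, 0.015, 0.03])

    def test_equal_pvalues_rank_cancellation(self):
        out = bh_adjust(np.full(10, 0.04))
        assert out == pytest.approx(np.full(10, 0.04))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.1, 1.5]))

    def test_adjusted_never_below_raw_and_capped(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()

    def test_rejection_set_matches_textbook_step_up(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            m = int(rng.integers(1, 40))
            p = rng.uniform(size=m) ** rng.uniform(0.5, 3)
            assert ((bh_adjust(p) < 0.05) == textbook_bh_rejections(p, 0.05)).all()

    def test_permutation_leaves_significant_set_unchanged(self):
        rng = np.random.default_rng(6)
        p = np.concatenate([rng.uniform(0, 1e-4, 5), rng.uniform(size=50)])
        perm = rng.permutation(len(p))
        sig = bh_adjust(p) < 0.05
        assert ((bh_adjust(p[perm]) < 0.05) == sig[perm]).all()


def _toy_run(n=40, seed=0, beta=0.0, maf=0.3, tissues=("tissue1",), missing_gene=False):
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, maf, size=n).astype(float)
    pairs = pd.DataFrame(
        {"rsid": ["rs1"], "gene_id": ["g1"], "category": ["cis"],
         "distance": [100.0], "n_libraries": [1], "libraries": ["hic1"]}
    )
    samples = pd.Index([f"S{i}" for i in range(n)], name="sample")
    dosages = pd.DataFrame({"rs1": g}, index=samples)
    expr = {}
    for t in tissues:
        y = beta * g + rng.normal(size=n)
        cols = {} if missing_gene else {"g1": y}
        cols["g2"] = rng.normal(size=n)
        expr[t] = pd.DataFrame(cols, index=samples)
    return pairs, dosages, expr


class TestModelRun:
    def test_maf_filter_removes_rare_variants(self):
        pairs, dosages, expr = _toy_run(n=100, maf=0.02, seed=7)
        res = SpatialEQTL(pairs, dosages, expr, maf_min=0.05).fit()
        assert res.n_tests == 0
        assert res.n_maf_filtered == 1
        pairs, dosages, expr = _toy_run(n=100, maf=0.4, seed=7)
        res = SpatialEQTL(pairs, dosages, expr, maf_min=0.05).fit()
        assert (res.table["maf"] >= 0.05).all()

    def test_missing_gene_counted_as_skipped(self):
        pairs, dosages, expr = _toy_run(missing_gene=True)
        res = SpatialEQTL(pairs, dosages, expr).fit()
        assert res.n_tests == 0 and res.n_skipped == 1
        assert "missing" in res.skipped["reason"].iloc[0]

    def test_significance_flag_consistent(self, focal_study):
        from spatialeqtl.spatial import map_spatial_pairs

        pairs = map_spatial_pairs(
            focal_study.variants, focal_study.genes, focal_study.library,
            focal_study.contacts,
        )
        res = SpatialEQTL(pairs, focal_study.dosages, focal_study.expression).fit()
        t = res.table
        assert ((t["p_adj"] < res.alpha) == t["significant"]).all()
        assert (t["p_adj"] >= t["p"] - 1e-12).all()
        assert t["p"].between(0, 1).all()
        # results sorted by p
        assert (np.diff(t["p"]) >= 0).all()

    def test_power_monotone_in_beta_and_n(self):
        def detection_rate(beta, n, reps=150):
            rng = np.random.default_rng(42)
            hits = 0
            for _ in range(reps):
                g = rng.binomial(2, 0.3, size=n).astype(float)
                if np.ptp(g) == 0:
                    continue
                y = beta * g + rng.normal(size=n)
                hits += ols_association(g, y)[2] < 0.05
            return hits / reps

        by_beta = [detection_rate(b, 100) for b in (0.1, 0.4, 1.0)]
        assert by_beta[0] <= by_beta[1] <= by_beta[2]
        by_n = [detection_rate(0.4, n) for n in (20, 60, 200)]
        assert by_n[0] <= by_n[1] <= by_n[2]

    def test_per_tissue_family_option(self):
        pairs, dosages, expr = _toy_run(tissues=("tissue1", "tissue2"), seed=9)
        pooled = SpatialEQTL(pairs, dosages, expr).fit(bh_family="pooled")
        per = SpatialEQTL(pairs, dosages, expr).fit(bh_family="per_tissue")
        assert pooled.n_tests == per.n_tests == 2
        assert per.table["p_adj"].notna().all()


class TestManhattanExport:
    def test_min_p_and_threshold_flags(self):
        results = pd.DataFrame(
            {"rsid": ["rs1"] * 3, "gene_id": ["g"] * 3,
             "tissue_id": ["t1", "t2", "t3"], "p": [0.2, 1e-6, 0.01]}
        )
        variants = pd.DataFrame(
            {"rsid": ["rs1"], "chromosome": ["chr1"], "position": [42]}
        )
        out = export_manhattan(results, variants)
        assert len(out) == 1
        assert out["p_min"].iloc[0] == 1e-6
        assert bool(out["below_blue_line_1e-5"].iloc[0]) is True
        assert bool(out["below_red_line_5e-8"].iloc[0]) is False

    def test_no_flags_when_all_p_one(self):
        results = pd.DataFrame(
            {"rsid": ["rs1", "rs2"], "gene_id": ["g", "g"],
             "tissue_id": ["t1", "t1"], "p": [1.0, 1.0]}
        )
        out = export_manhattan(results)
        assert not out["below_red_line_5e-8"].any()
        assert not out["below_blue_line_1e-5"].any()

    def test_row_count_equals_distinct_snps(self, focal_study):
        from spatialeqtl.spatial import map_spatial_pairs

        pairs = map_spatial_pairs(
            focal_study.variants, focal_study.genes, focal_study.library,
            focal_study.contacts, focal_gene=focal_study.manifest["focal_gene"],
        )
        res = SpatialEQTL(pairs, focal_study.dosages, focal_study.expression).fit()
        out = export_manhattan(res.table, focal_study.variants)
        assert len(out) == res.table["rsid"].nunique()
        assert out["chromosome"].notna().all()

    def test_empty_results_give_empty_frame_with_header(self):
        out = export_manhattan(pd.DataFrame(columns=["rsid", "p"]))
        assert len(out) == 0 and "p_min" in out.columns
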