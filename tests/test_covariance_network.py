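import numpy as np
import pandas as pd
import pytest
from scipy import stats

import graynet as gn
from graynet.covariance_network import correlation_pvalues
from graynet.errors import InputError


def make_table(values, ages=None, regions=None):
    values = np.asarray(values, dtype=float)
    n_sub, n_reg = values.shape
    regions = regions or [f"r{j}" for j in range(n_reg)]
    cov = pd.DataFrame({"age": ages}) if ages is not None else None
    return gn.ThicknessTable([f"s{i}" for i in range(n_sub)], regions, values, cov)


def r_from_p(p, n_subjects):
    """Invert the one-sided r-to-t transform to hit a target p-value."""
    df = n_subjects - 2
    t = stats.t.isf(p, df)
    return t / np.sqrt(df + t**2)


class TestResidualize:
    def test_constant_covariate_mean_centers(self):
        rng = np.random.default_rng(0)
        values = rng.normal(2.5, 0.3, size=(8, 3))
        t = make_table(values, ages=[50.0] * 8)
        # a constant covariate is collinear with the intercept
        with pytest.raises(InputError, match="collinear"):
            gn.residualize(t, ["age"])
        resid = gn.residualize(t, []).values
        assert np.allclose(resid, values - values.mean(axis=0))

    def test_perfect_fit_gives_zero_residuals(self):
        ages = np.array([40.0, 45.0, 50.0, 55.0, 60.0])
        values = np.column_stack([2 * ages + 5, -0.5 * ages + 1])
        resid = gn.residualize(make_table(values, ages=ages), ["age"]).values
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_age(self):
        rng = np.random.default_rng(42)
        ages = rng.uniform(35, 64, 21)
        values = 0.3 * ages[:, None] + rng.normal(0, 0.2, size=(21, 5))
        resid = gn.residualize(make_table(values, ages=ages), ["age"]).values
        centered_age = ages - ages.mean()
        for j in range(5):
            assert abs(np.dot(resid[:, j], centered_age)) < 1e-8
            assert abs(resid[:, j].sum()) < 1e-8

    def test_mean_overall_thickness_derived(self):
        rng = np.random.default_rng(1)
        values = rng.normal(2.5, 0.3, size=(10, 4))
        resid = gn.residualize(make_table(values), ["mean_overall_thickness"]).values
        global_mean = values.mean(axis=1)
        centered = global_mean - global_mean.mean()
        for j in range(4):
            assert abs(np.dot(resid[:, j], centered)) < 1e-8

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        ages = rng.uniform(35, 64, 15)
        values = rng.normal(2.5, 0.3, size=(15, 6)) + 0.01 * ages[:, None]
        t = make_table(values, ages=ages)
        once = gn.residualize(t, ["age"])
        twice = gn.residualize(once, ["age"])
        assert np.allclose(once.values, twice.values, atol=1e-10)

    def test_too_few_subjects(self):
        with pytest.raises(InputError):
            gn.residualize(make_table(np.ones((2, 3)) + np.eye(2, 3), ages=[40, 50]), ["age"])


class TestPearsonMatrix:
    def test_duplicated_region_r_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=6)
        c = gn.pearson_matrix(make_table(np.column_stack([x, x, rng.normal(size=6)])))
        assert c.R[0, 1] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        c = gn.pearson_matrix(make_table(np.column_stack([x, -x + 10])))
        assert c.R[0, 1] == pytest.approx(-1.0)

    def test_textbook_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 4.0, 3.0])
        c = gn.pearson_matrix(make_table(np.column_stack([x, y])))
        xm, ym = x - x.mean(), y - y.mean()
        expected = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
        assert c.R[0, 1] == pytest.approx(expected)

    def test_zero_variance_region_named(self):
        values = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(InputError, match="r0"):
            gn.pearson_matrix(make_table(values))

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(3)
        c = gn.pearson_matrix(make_table(rng.normal(size=(9, 7))))
        assert np.array_equal(c.R, c.R.T)
        assert np.all(np.abs(c.R) <= 1.0)
        assert np.allclose(np.diag(c.R), 1.0)


class TestFdrBinarize:
    def test_all_nonpositive_empty_graph(self):
        R = np.full((4, 4), -0.5)
        np.fill_diagonal(R, 1.0)
        c = gn.CorrelationMatrix([f"r{i}" for i in range(4)], R, 21)
        assert gn.fdr_binarize(c, q=0.2).m == 0

    def test_hand_benjamini_hochberg(self):
        # 4 positive pairs with p = .01, .02, .5, .9; BH at q=.2 keeps 2
        n_sub = 21
        ps = [0.01, 0.02, 0.5, 0.9]
        rs = [r_from_p(p, n_sub) for p in ps]
        R = np.eye(4)
        R[0, 1] = R[1, 0] = rs[0]
        R[0, 2] = R[2, 0] = rs[1]
        R[0, 3] = R[3, 0] = rs[2]
        R[1, 2] = R[2, 1] = rs[3]
        R[1, 3] = R[3, 1] = -0.3
        R[2, 3] = R[3, 2] = 0.0
        c = gn.CorrelationMatrix([f"r{i}" for i in range(4)], R, n_sub)
        g = gn.fdr_binarize(c, q=0.2)
        assert g.m == 2
        assert set(g.edges()) == {(0, 1), (0, 2)}

    def test_monotone_in_q(self):
        rng = np.random.default_rng(11)
        for seed in range(5):
            t = make_table(np.random.default_rng(seed).normal(size=(21, 10)))
            c = gn.pearson_matrix(t)
            strict = set(gn.fdr_binarize(c, q=0.05).edges())
            loose = set(gn.fdr_binarize(c, q=0.2).edges())
            assert strict <= loose

    def test_perfect_correlation_p_zero(self):
        x = np.arange(5.0)
        values = np.column_stack([x, 2 * x + 1, np.random.default_rng(0).normal(size=5)])
        c = gn.pearson_matrix(make_table(values))
        p = correlation_pvalues(c)
        assert p[0, 1] == 0.0
        g = gn.fdr_binarize(c, q=0.2)
        assert g.A[0, 1] == 1

    def test_bad_q(self):
        c = gn.pearson_matrix(make_table(np.random.default_rng(0).normal(size=(6, 3))))
        for q in (0.0, 1.0, -0.1):
            with pytest.raises(InputError):
                gn.fdr_binarize(c, q=q)


class TestThresholdSweep:
    @staticmethod
    def corr(seed=0, n_sub=21, n_reg=8):
        return gn.pearson_matrix(
            make_table(np.random.default_rng(seed).normal(size=(n_sub, n_reg)))
        )

    def test_near_one_threshold_all_singletons(self):
        c = self.corr()
        rec = gn.threshold_sweep(c, [0.999999])[-1]
        assert rec["edges"] == 0
        assert rec["isolated_groups"] == c.n_regions

    def test_fully_positive_low_threshold_one_component(self):
        base = np.random.default_rng(4).normal(size=10)
        values = base[:, None] + np.random.default_rng(5).normal(0, 0.1, size=(10, 5))
        c = gn.pearson_matrix(make_table(values))
        min_pos = min(c.R[i, j] for i in range(5) for j in range(i + 1, 5))
        assert min_pos > 0
        rec = gn.threshold_sweep(c, [min_pos / 2])[0]
        assert rec["isolated_groups"] == 1

    def test_two_block_gap_gives_two_groups(self):
        spec = gn.CohortSpec(
            n_subjects=200, regions=tuple(f"r{i}" for i in range(10)),
            blocks=((0, 1, 2, 3, 4), (5, 6, 7, 8, 9)),
            rho_in=0.9, rho_out=0.05, seed=12,
        )
        table, _, _ = gn.generate_cohort(spec)
        c = gn.pearson_matrix(table)
        rec = gn.threshold_sweep(c, [0.5])[0]
        assert rec["isolated_groups"] == 2

    def test_monotone_counts(self):
        c = self.corr(seed=9)
        recs = gn.threshold_sweep(c, [0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        edges = [r["edges"] for r in recs]
        comps = [r["isolated_groups"] for r in recs]
        assert edges == sorted(edges, reverse=True)
        assert comps == sorted(comps)
        for r in recs:
            assert r["density"] + r["sparsity"] == pytest.approx(1.0)


class TestPipelineRecovery:
    def test_blocks_recovered_as_components(self):
        hits = 0
        for seed in range(10):
            spec = gn.CohortSpec(
                n_subjects=21, regions=tuple(f"r{i}" for i in range(12)),
                blocks=(tuple(range(6)), tuple(range(6, 12))),
                rho_in=0.9, rho_out=0.0, age_slope=0.01, seed=seed,
            )
            table, _, _ = gn.generate_cohort(spec)
            resid = gn.residualize(table, ["age", "mean_overall_thickness"])
            graph = gn.fdr_binarize(gn.pearson_matrix(resid), q=0.2)
            comps = {frozenset(c) for c in gn.connected_components(graph) if len(c) > 1}
            planted = {frozenset(range(6)), frozenset(range(6, 12))}
            hits += comps == planted
        assert hits >= 8
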