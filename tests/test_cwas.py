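import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import deltaconn as dc
from deltaconn.cwas import (
    EdgeModelSpec,
    bh_adjust,
    count_significant,
    fit_cross_sectional,
    fit_edge_models,
    rowwise_bh,
)

from conftest import make_cohort_from_edges


def oracle_ols(y, x):
    """Independent per-edge normal-equations OLS (beta, se, t, p, df)."""
    beta = np.linalg.solve(x.T @ x, x.T @ y)
    df = len(y) - x.shape[1]
    resid = y - x @ beta
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(x.T @ x)))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta, se, t, p, df


def zscore(v):
    return (v - v.mean()) / v.std(ddof=1)


class TestFitEdgeModels:
    def test_df_686_at_n_690(self):
        cfg = dc.SimulationConfig(seed=0, n_subjects=690, n_cortical=8, n_subcortical=2)
        ds, _ = dc.simulate_cohort(cfg)
        res = fit_edge_models(ds)
        assert res.df_resid == 686  # n - (3 regressors + intercept)
        assert res.terms == ["delta", "rsfc_tp1_same_edge", "sex", "intercept"]

    def test_noise_free_interpolation(self, tiny_scheme):
        # symptoms constructed to equal the delta value at edge 0 exactly
        rng = np.random.default_rng(1)
        n, e = 6, tiny_scheme.n_edges
        tp1 = rng.uniform(-0.3, 0.3, (n, e))
        delta = rng.uniform(-0.2, 0.2, (n, e))
        ds = make_cohort_from_edges(
            tiny_scheme, tp1, tp1 + delta, symptoms_tp2=delta[:, 0].copy()
        )
        spec = EdgeModelSpec(covariates=(), standardize=False)
        res = fit_edge_models(ds, spec)
        assert res.beta[0, 0] == pytest.approx(1.0, abs=1e-10)
        assert res.beta[0, 1] == pytest.approx(0.0, abs=1e-10)  # intercept
        assert res.se[0, 0] == pytest.approx(0.0, abs=1e-8)  # residual variance 0

    def test_oracle_equivalence_50_edges(self):
        cfg = dc.SimulationConfig(seed=7, n_subjects=200, n_cortical=26, n_subcortical=4)
        ds, _ = dc.simulate_cohort(cfg)
        assert ds.scheme.n_rois == 30
        res = fit_edge_models(ds)
        y = zscore(ds.symptoms_tp2)
        edges = np.random.default_rng(7).choice(ds.n_edges, 50, replace=False)
        for e in edges:
            x = np.column_stack(
                [zscore(ds.delta[:, e]), zscore(ds.rsfc_tp1[:, e]),
                 ds.sex.astype(float), np.ones(ds.n_subjects)]
            )
            beta, se, t, p, df = oracle_ols(y, x)
            assert res.df_resid == df
            np.testing.assert_allclose(res.beta[e], beta, atol=1e-8, rtol=0)
            np.testing.assert_allclose(res.t[e], t, atol=1e-8, rtol=0)
            np.testing.assert_allclose(res.p[e], p, atol=1e-8, rtol=0)

    def test_matches_statsmodels(self, null_cohort):
        import statsmodels.api as sm

        ds, _ = null_cohort
        res = fit_edge_models(ds)
        e = 17
        x = sm.add_constant(
            np.column_stack(
                [zscore(ds.delta[:, e]), zscore(ds.rsfc_tp1[:, e]), ds.sex]
            ),
            prepend=False,
        )
        fit = sm.OLS(zscore(ds.symptoms_tp2), x).fit()
        np.testing.assert_allclose(res.beta[e], fit.params, atol=1e-10)
        np.testing.assert_allclose(res.se[e], fit.bse, atol=1e-10)
        np.testing.assert_allclose(res.p[e], fit.pvalues, atol=1e-10)
        assert res.df_resid == fit.df_resid

    def test_affine_invariance_raw_scale(self, null_cohort):
        # x -> a*x + b leaves t and p unchanged; beta scales by 1/a
        ds, _ = null_cohort
        spec = EdgeModelSpec(standardize=False)
        res = fit_edge_models(ds, spec)
        a = 3.7
        scaled = make_cohort_from_edges(
            ds.scheme,
            ds.rsfc_tp1,
            ds.rsfc_tp1 + a * ds.delta,
            symptoms_tp2=ds.symptoms_tp2,
            symptoms_tp1=ds.symptoms_tp1,
            sex=ds.sex,
        )
        res2 = fit_edge_models(scaled, spec)
        np.testing.assert_allclose(res2.t[:, 0], res.t[:, 0], rtol=1e-9)
        np.testing.assert_allclose(res2.p[:, 0], res.p[:, 0], rtol=1e-9)
        np.testing.assert_allclose(res2.beta[:, 0], res.beta[:, 0] / a, rtol=1e-9)

    def test_degenerate_edge_flagged_not_dropped(self, tiny_scheme):
        rng = np.random.default_rng(2)
        n, e = 30, tiny_scheme.n_edges
        tp1 = rng.uniform(-0.3, 0.3, (n, e))
        tp2 = tp1 + rng.uniform(-0.2, 0.2, (n, e))
        tp2[:, 2] = tp1[:, 2]  # zero-variance delta at edge 2
        ds = make_cohort_from_edges(
            tiny_scheme, tp1, tp2, symptoms_tp2=rng.standard_normal(n)
        )
        res = fit_edge_models(ds)
        assert res.degenerate[2]
        assert np.isnan(res.beta[2, 0])
        assert res.n_edges == e  # still present
        res = rowwise_bh(res, 0.05)
        assert np.isnan(res.p_adj_a[2]) and np.isnan(res.p_adj_b[2])

    def test_too_few_subjects_rejected(self, tiny_scheme):
        rng = np.random.default_rng(3)
        n, e = 4, tiny_scheme.n_edges
        tp1 = rng.uniform(-0.3, 0.3, (n, e))
        ds = make_cohort_from_edges(
            tiny_scheme, tp1, tp1 + rng.uniform(-0.1, 0.1, (n, e)),
            symptoms_tp2=rng.standard_normal(n),
        )
        with pytest.raises(ValueError, match="not enough subjects"):
            fit_edge_models(ds)


class TestCrossSectional:
    def test_single_edge_equals_direct_regression(self):
        import pandas as pd

        scheme = dc.make_parcellation(
            pd.DataFrame(
                {
                    "roi_name": ["c0", "s0"],
                    "hemisphere": ["L", "bilateral"],
                    "roi_class": ["cortical", "subcortical"],
                    "network": ["n", "bg"],
                }
            )
        )
        rng = np.random.default_rng(4)
        n = 40
        tp1 = rng.uniform(-0.5, 0.5, (n, 1))
        ds = make_cohort_from_edges(
            scheme, tp1, tp1 + rng.uniform(-0.1, 0.1, (n, 1)),
            symptoms_tp2=rng.standard_normal(n),
        )
        res = fit_cross_sectional(ds, "TP1")
        x = np.column_stack(
            [zscore(ds.rsfc_tp1[:, 0]), ds.sex.astype(float), np.ones(n)]
        )
        beta, se, t, p, df = oracle_ols(zscore(ds.symptoms_tp1), x)
        np.testing.assert_allclose(res.beta[0], beta, atol=1e-10)
        np.testing.assert_allclose(res.p[0], p, atol=1e-10)

    def test_permutation_null_rate(self, null_cohort):
        ds, _ = null_cohort
        rng = np.random.default_rng(99)
        fracs = []
        for _ in range(20):
            perm = make_cohort_from_edges(
                ds.scheme, ds.rsfc_tp1, ds.rsfc_tp2,
                symptoms_tp2=rng.permutation(ds.symptoms_tp2),
                symptoms_tp1=rng.permutation(ds.symptoms_tp1),
                sex=ds.sex,
            )
            res = fit_cross_sectional(perm, "TP2")
            fracs.append(np.mean(res.p[:, 0] <= 0.05))
        frac = np.mean(fracs)
        mc_se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(frac - 0.05) <= max(3 * mc_se, 0.02)

    def test_tp2_planted_effect_larger_at_tp2(self, sim_scheme):
        # effects planted in delta show up in TP2 levels but not TP1
        sub = int(sim_scheme.subcortical_ids[0])
        planted = tuple((c, sub, 0.35) for c in range(4))
        betas_tp1, betas_tp2 = [], []
        for seed in range(10):
            cfg = dc.SimulationConfig(
                seed=seed, n_subjects=250, scheme=sim_scheme, planted_edges=planted
            )
            ds, truth = dc.simulate_cohort(cfg)
            ids = truth.planted_edge_ids
            betas_tp1.append(np.abs(fit_cross_sectional(ds, "TP1").beta[ids, 0]).mean())
            betas_tp2.append(np.abs(fit_cross_sectional(ds, "TP2").beta[ids, 0]).mean())
        assert np.mean(betas_tp2) > np.mean(betas_tp1)


def brute_force_bh(p):
    """Textbook BH: sort, scale by m/i, enforce monotone from the top."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = min(prev, 1.0)
    return adj


class TestBH:
    def test_hand_example_all_tied_at_max(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(bh_adjust(p), [0.04, 0.04, 0.04, 0.04])

    def test_hand_example_mixed(self):
        p = np.array([0.005, 0.1, 0.9])
        np.testing.assert_allclose(bh_adjust(p), [0.015, 0.15, 0.9])

    def test_all_equal_fixed_point(self):
        p = np.full(7, 0.2)
        np.testing.assert_allclose(bh_adjust(p), p)

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000), m=st.integers(1, 500))
    def test_matches_brute_force(self, seed, m):
        p = np.random.default_rng(seed).uniform(size=m)
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12, rtol=0)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for m in (1, 5, 100):
            p = rng.uniform(size=m)
            _, adj, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(bh_adjust(p), adj, atol=1e-12)


class TestRowwiseBH:
    @pytest.fixture()
    def fitted(self, planted_cohort):
        ds, _ = planted_cohort
        return rowwise_bh(fit_edge_models(ds), 0.05)

    def test_every_edge_has_two_padj(self, fitted):
        valid = ~fitted.degenerate
        assert np.all(np.isfinite(fitted.p_adj_a[valid]))
        assert np.all(np.isfinite(fitted.p_adj_b[valid]))

    def test_padj_ge_raw_p(self, fitted):
        col = fitted.term_column(fitted.tested_term)
        valid = ~fitted.degenerate
        assert np.all(fitted.p_adj_a[valid] >= fitted.p[valid, col] - 1e-15)
        assert np.all(fitted.p_adj_b[valid] >= fitted.p[valid, col] - 1e-15)

    def test_row_equals_direct_bh(self, fitted):
        col = fitted.term_column(fitted.tested_term)
        for roi in (0, 5, fitted.scheme.n_rois - 1):
            edges = fitted.row_edges(roi)
            expected = bh_adjust(fitted.p[edges, col])
            np.testing.assert_allclose(fitted.row_padj(roi), expected, atol=1e-15)
            assert len(edges) == fitted.scheme.n_rois - 1

    def test_monotone_in_q(self, fitted):
        ds_flags = {q: rowwise_bh(fitted, q).sig_a for q in (0.01, 0.05, 0.2)}
        assert np.all(ds_flags[0.01] <= ds_flags[0.05])
        assert np.all(ds_flags[0.05] <= ds_flags[0.2])

    def test_q_out_of_range(self, fitted):
        with pytest.raises(ValueError, match="q must be"):
            rowwise_bh(fitted, 1.5)

    def test_covariate_term_adjustable(self, planted_cohort):
        ds, _ = planted_cohort
        res = rowwise_bh(fit_edge_models(ds), 0.05, term="rsfc_tp1_same_edge")
        assert res.tested_term == "rsfc_tp1_same_edge"
        assert np.isfinite(res.p_adj_a[~res.degenerate]).all()


class TestCountSignificant:
    def test_no_flags_zero(self, null_cohort):
        ds, _ = null_cohort
        res = rowwise_bh(fit_edge_models(ds), 1e-6)
        roi = int(ds.scheme.subcortical_ids[0])
        if not res.row_flags(roi).any():
            assert count_significant(res, roi) == 0

    def test_planted_positive_edges_counted(self, sim_scheme):
        sub = int(sim_scheme.subcortical_ids[0])
        planted = tuple((c, sub, 0.38) for c in range(5))
        cfg = dc.SimulationConfig(
            seed=21, n_subjects=600, scheme=sim_scheme, planted_edges=planted
        )
        ds, truth = dc.simulate_cohort(cfg)
        res = rowwise_bh(fit_edge_models(ds), 0.05)
        assert count_significant(res, sub, "positive") == 5
        assert count_significant(res, sub, "negative") == 0
        assert count_significant(res, sub, "both") == 5

    def test_unknown_roi_rejected(self, null_cohort):
        ds, _ = null_cohort
        res = rowwise_bh(fit_edge_models(ds), 0.05)
        with pytest.raises(KeyError):
            count_significant(res, 999)

    def test_bad_sign_rejected(self, null_cohort):
        ds, _ = null_cohort
        res = rowwise_bh(fit_edge_models(ds), 0.05)
        with pytest.raises(ValueError, match="sign"):
            count_significant(res, 0, "up")


def test_long_export_columns(planted_cohort, tmp_path):
    ds, _ = planted_cohort
    res = rowwise_bh(fit_edge_models(ds), 0.05)
    df = res.to_long_frame()
    assert set(df.columns) >= {
        "edge_id", "roi_row", "term", "beta", "se", "t", "p", "p_adj", "significant",
    }
    # two ROI rows x len(terms) rows per edge
    assert len(df) == res.n_edges * 2 * len(res.terms)
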