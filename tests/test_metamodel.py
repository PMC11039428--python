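import json
import subprocess
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import symmeta as sm
from symmeta.metamodel import (
    FitError,
    MetaFit,
    ModelSpec,
    VarianceComponents,
    build_design,
    fit_reml,
    make_spec,
    marginal_covariance,
    reml_loglik,
    wald_tests,
)

from _oracles import dense_reml_loglik, wls_fit


def simple_spec(y, v, X=None, **kw):
    y = np.asarray(y, float)
    if X is None:
        X = np.ones((len(y), 1))
    return ModelSpec(y=y, v=v, X=X, column_names=["intercept"], **kw)


class TestBuildDesign:
    def test_three_level_factor(self):
        df = pd.DataFrame({"mod": ["b", "a", "c", "a", "b", "c"]})
        d = build_design(df, "mod")
        assert d.X.shape == (6, 3)
        assert d.column_names == ["intercept", "mod[b]", "mod[c]"]
        assert d.moderator_block == [1, 2]

    def test_no_moderator_is_intercept_only(self):
        d = build_design(pd.DataFrame(index=range(4)), None)
        np.testing.assert_array_equal(d.X, np.ones((4, 1)))
        assert d.moderator_block == []

    def test_continuous_moderator_centered_df1(self):
        df = pd.DataFrame({"gt": [1.0, 2.0, 6.0]})
        d = build_design(df, "gt")
        assert d.moderator_block == [1]
        assert d.X[:, 1].sum() == pytest.approx(0.0)

    def test_single_level_rejected(self):
        with pytest.raises(FitError, match="single"):
            build_design(pd.DataFrame({"mod": ["a", "a"]}), "mod")

    def test_missing_values_dropped_with_warning(self):
        df = pd.DataFrame({"mod": ["a", None, "b", "a"]})
        with pytest.warns(UserWarning, match="dropped 1"):
            d = build_design(df, "mod")
        assert d.kept.sum() == 3


class TestMarginalCovariance:
    def test_all_zero_components_is_diag_v(self):
        spec = simple_spec([0, 0], v=[1.0, 2.0])
        np.testing.assert_allclose(
            marginal_covariance(VarianceComponents(), spec), np.diag([1.0, 2.0])
        )

    def test_shared_study_block(self):
        spec = simple_spec([0, 0], v=[1.0, 1.0], study=np.array(["s1", "s1"]))
        M = marginal_covariance(VarianceComponents(study=2.0), spec)
        np.testing.assert_allclose(M, [[3.0, 2.0], [2.0, 3.0]])

    def test_random_spec_symmetric_and_choleskyable(self, small_dataset):
        df, tree, truth = small_dataset
        spec = make_spec(df, corr=sm.bm_correlation(tree))
        M = marginal_covariance(
            VarianceComponents(study=0.7, within=0.3, phylo=0.9), spec
        )
        assert np.abs(M - M.T).max() < 1e-12
        np.linalg.cholesky(M)


class TestRemlLoglik:
    def test_two_point_closed_form(self):
        # M = I, X = (1,1)': ll = -0.5*(log 2 + log 2*pi)
        spec = simple_spec([0.0, 0.0], v=[1.0, 1.0])
        expected = -0.5 * (np.log(2.0) + np.log(2.0 * np.pi))
        assert reml_loglik(VarianceComponents(), spec) == pytest.approx(
            expected, abs=1e-12
        )

    def test_invariant_to_shifting_y_with_intercept(self, small_dataset):
        df, tree, _ = small_dataset
        spec = make_spec(df, corr=sm.bm_correlation(tree))
        vc = VarianceComponents(study=0.5, within=0.4, phylo=0.2)
        ll = reml_loglik(vc, spec)
        spec_shift = ModelSpec(
            y=spec.y + 10.0, v=spec.v, X=spec.X, column_names=spec.column_names,
            study=spec.study, R=spec.R, tip_index=spec.tip_index,
        )
        assert reml_loglik(vc, spec_shift) == pytest.approx(ll, abs=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        y = rng.normal(size=n)
        v = rng.uniform(0.2, 1.0, n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        study = rng.integers(0, 4, n)
        A = rng.normal(size=(5, 5))
        R = A @ A.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        tip = rng.integers(0, 5, n)
        vc = tuple(rng.uniform(0.1, 1.0, 3))
        spec = ModelSpec(
            y=y, v=v, X=X, column_names=["intercept", "x"],
            study=study, R=R, tip_index=tip,
        )
        got = reml_loglik(
            VarianceComponents(study=vc[0], within=vc[1], phylo=vc[2]), spec
        )
        want = dense_reml_loglik(
            y, v, X, study=study, R_records=R[np.ix_(tip, tip)], vc=vc
        )
        assert got == pytest.approx(want, abs=1e-8)


class TestFitReml:
    def test_fixed_effect_limit_is_inverse_variance_weighting(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 0.1, 8)
        v = rng.uniform(0.5, 2.0, 8)
        spec = simple_spec(y, v=v)
        from symmeta.metamodel import _loglik_core

        _, beta, cov, _ = _loglik_core(VarianceComponents(), spec, want_grad=False)
        w = 1.0 / v
        assert beta[0] == pytest.approx(np.sum(w * y) / np.sum(w), rel=1e-10)
        assert np.sqrt(cov[0, 0]) == pytest.approx(np.sum(w) ** -0.5, rel=1e-10)

    def test_equal_variance_closed_form_reml(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0, 2.0, 30)
        v0 = 0.5
        spec = simple_spec(y, v=np.full(30, v0))
        fit = fit_reml(spec)
        expected_within = max(np.var(y, ddof=1) - v0, 0.0)
        assert fit.vc.within == pytest.approx(expected_within, rel=1e-5)
        assert fit.beta[0] == pytest.approx(y.mean(), rel=1e-8)
        assert fit.converged

    def test_needs_more_records_than_coefficients(self):
        with pytest.raises(FitError, match="more records"):
            fit_reml(simple_spec([1.0], v=[1.0]))

    def test_phylo_component_at_zero_matches_no_matrix_fit(self, small_dataset):
        df, tree, _ = small_dataset
        corr = sm.bm_correlation(tree)
        spec_R = make_spec(df, corr=corr)
        spec_no = make_spec(df)
        vc = VarianceComponents(study=0.8, within=0.4, phylo=0.0)
        assert reml_loglik(vc, spec_R) == pytest.approx(
            reml_loglik(vc, spec_no), abs=1e-10
        )
        from symmeta.metamodel import _loglik_core

        _, bR, _, _ = _loglik_core(vc, spec_R, want_grad=False)
        _, b0, _, _ = _loglik_core(vc, spec_no, want_grad=False)
        assert bR[0] == pytest.approx(b0[0], abs=1e-8)

    def test_permutation_equivariance(self, small_dataset):
        df, tree, _ = small_dataset
        corr = sm.bm_correlation(tree)
        fit1 = fit_reml(make_spec(df, moderator="mod", corr=corr))
        perm = df.sample(frac=1.0, random_state=5)
        fit2 = fit_reml(make_spec(perm, moderator="mod", corr=corr))
        np.testing.assert_allclose(fit1.beta, fit2.beta, atol=1e-6)
        assert fit1.vc.study == pytest.approx(fit2.vc.study, abs=1e-5)
        assert fit1.vc.phylo == pytest.approx(fit2.vc.phylo, abs=1e-5)

    def test_interior_gradient_small_at_optimum(self, small_dataset):
        df, tree, _ = small_dataset
        fit = fit_reml(make_spec(df, corr=sm.bm_correlation(tree)))
        assert fit.converged
        for comp, g in fit.optimizer["gradient"].items():
            if comp not in fit.optimizer["active_bounds"]:
                assert abs(g) < 1e-3

    def test_zero_sampling_variances_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            spec = simple_spec([0.1, 0.2, 0.3], v=[0.0, 1.0, 1.0])
        assert spec.v[0] == pytest.approx(1e-10)

    def test_missing_tip_mapping_rejected(self, small_dataset):
        df, tree, _ = small_dataset
        corr = sm.bm_correlation(tree)
        df = df.copy()
        df.loc[df.index[0], "tip_label"] = "not_a_tip"
        with pytest.raises(FitError, match="not_a_tip"):
            make_spec(df, corr=corr)


class TestWaldTests:
    def _fit(self, beta, cov, block):
        beta = np.asarray(beta, float)
        cov = np.asarray(cov, float)
        se = np.sqrt(np.diag(cov))
        z = beta / se
        from scipy import stats

        return MetaFit(
            beta=beta, cov_beta=cov, se=se, z=z,
            p=2 * stats.norm.sf(np.abs(z)),
            vc=VarianceComponents(), reml_loglik=0.0, converged=True,
            n=10, n_fixed=len(beta),
            column_names=[f"b{i}" for i in range(len(beta))],
            moderator_block=block,
        )

    def test_zero_block_gives_qm_zero_p_one(self):
        fit = self._fit([1.0, 0.0, 0.0], np.eye(3), [1, 2])
        w = wald_tests(fit, [1, 2])
        assert w.qm == 0.0
        assert w.qm_p == 1.0

    def test_scalar_block_qm_equals_z_squared(self):
        fit = self._fit([1.0, 0.7], np.diag([1.0, 0.25]), [1])
        w = wald_tests(fit, [1])
        assert w.qm == pytest.approx(fit.z[1] ** 2, rel=1e-12)
        assert w.qm_p == pytest.approx(fit.p[1], rel=1e-10)

    def test_matches_dense_quadratic_form(self, small_dataset):
        df, tree, _ = small_dataset
        fit = fit_reml(make_spec(df, moderator="mod", corr=sm.bm_correlation(tree)))
        b = fit.beta[[1, 2]]
        V = fit.cov_beta[np.ix_([1, 2], [1, 2])]
        assert fit.qm == pytest.approx(float(b @ np.linalg.inv(V) @ b), abs=1e-10)

    def test_empty_block_rejected(self):
        fit = self._fit([1.0], np.eye(1), [])
        with pytest.raises(FitError, match="empty"):
            wald_tests(fit, [])


class TestMetaforCrossCheck:
    """Independent oracle: R metafor rma.mv on the identical model."""

    def test_full_three_component_moderator_fit(self, small_dataset, tmp_path):
        df, tree, _ = small_dataset
        corr = sm.bm_correlation(tree)
        fit = fit_reml(make_spec(df, moderator="mod", corr=corr))

        data_csv = tmp_path / "dat.csv"
        r_csv = tmp_path / "R.csv"
        out_json = tmp_path / "out.json"
        df.to_csv(data_csv, index=False)
        corr.to_csv(r_csv)
        script = Path(__file__).parent / "metafor_oracle.R"
        subprocess.run(
            ["Rscript", str(script), str(data_csv), str(r_csv), "mod", str(out_json)],
            check=True, capture_output=True, text=True,
        )
        ref = json.loads(out_json.read_text())

        np.testing.assert_allclose(fit.beta, ref["beta"], atol=1e-4)
        np.testing.assert_allclose(fit.se, ref["se"], atol=1e-4)
        np.testing.assert_allclose(
            [fit.vc.study, fit.vc.within, fit.vc.phylo], ref["sigma2"], atol=2e-3
        )
        assert fit.qm == pytest.approx(ref["QM"], rel=1e-3)
        assert fit.qm_p == pytest.approx(ref["QMp"], rel=1e-3)
        # metafor's restricted likelihood carries a +0.5*log|X'X| constant
        offset = 0.5 * np.linalg.slogdet(fit_design(df))[1]
        assert fit.reml_loglik + offset == pytest.approx(ref["loglik"], abs=1e-4)


def fit_design(df):
    d = build_design(df, "mod")
    return d.X.T @ d.X
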