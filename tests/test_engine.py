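"""Unit and property tests for the PLS path-modeling engine."""

import itertools

import numpy as np
import pandas as pd
import pytest

import cephpls as c
from cephpls.engine import (
    NonConvergenceWarning,
    PLSPMError,
    SingularBlockError,
    ZeroVarianceError,
)


class TestStandardize:
    def test_symmetric_three_point_column(self):
        out = c.standardize(pd.DataFrame({"v": [1.0, 2.0, 3.0]}))
        assert np.allclose(out["v"], [-1.0, 0.0, 1.0])

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"v": rng.standard_normal(50)})
        once = c.standardize(X)
        twice = c.standardize(once)
        assert np.allclose(once, twice, atol=1e-12)

    def test_hand_arithmetic(self):
        # direct formula oracle: mean 30, sample variance 1000/3
        x = np.array([10.0, 20.0, 40.0, 50.0])
        expected = (x - 30.0) / np.sqrt(1000.0 / 3.0)
        out = c.standardize(pd.DataFrame({"v": x}))
        assert np.allclose(out["v"], expected, atol=1e-12)

    def test_zero_variance_names_column(self):
        X = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [4.0, 4.0, 4.0]})
        with pytest.raises(ZeroVarianceError, match="flat"):
            c.standardize(X)


class TestDegenerateModel:
    """Single-MV reflective blocks reduce the whole machinery to a
    Pearson correlation — the engine's sharpest external oracle."""

    def test_identical_columns_give_unit_path(self, single_mv_model):
        blocks, inner = single_mv_model
        v = np.array([1.0, 2.0, 5.0, 3.0, -1.0])
        X = pd.DataFrame({"x": v, "y": v.copy()})
        res = c.fit(X, blocks, inner)
        assert res.path_coefficients["B"]["A"] == pytest.approx(1.0, abs=1e-12)
        assert res.r_squared["B"] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("scheme", ["centroid", "factorial", "path"])
    def test_path_equals_pearson_r(self, single_mv_model, correlated_pair,
                                   scheme):
        blocks, inner = single_mv_model
        r = float(np.corrcoef(correlated_pair["x"], correlated_pair["y"])[0, 1])
        res = c.fit(correlated_pair, blocks, inner, scheme=scheme)
        assert res.path_coefficients["B"]["A"] == pytest.approx(r, abs=1e-10)
        assert res.r_squared["B"] == pytest.approx(r * r, abs=1e-10)


class TestPathCoefficients:
    def test_single_predecessor_is_correlation(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(200)
        b = 0.4 * a + rng.standard_normal(200)
        scores = c.standardize(pd.DataFrame({"A": a, "B": b}))
        inner = c.InnerSpec(("A", "B"), (("A", "B"),))
        paths, r2 = c.path_coefficients(scores, inner)
        r = float(np.corrcoef(scores["A"], scores["B"])[0, 1])
        assert paths["B"]["A"] == pytest.approx(r, abs=1e-12)
        assert r2["B"] == pytest.approx(r * r, abs=1e-12)

    def test_orthogonal_predictors(self):
        n = 8
        a = c.standardize(pd.DataFrame({"v": np.sin(np.arange(n))}))["v"]
        b = c.standardize(pd.DataFrame({"v": np.cos(2 * np.arange(n))}))["v"]
        a = a - a @ b / (b @ b) * b  # exact orthogonalisation
        a = a / a.std(ddof=1)
        y = 0.5 * a + 0.25 * b
        scores = pd.DataFrame({
            "A": a, "B": b, "Y": (y - y.mean()) / y.std(ddof=1)})
        inner = c.InnerSpec(("A", "B", "Y"), (("A", "Y"), ("B", "Y")))
        paths, r2 = c.path_coefficients(scores, inner)
        r1 = float(np.corrcoef(scores["A"], scores["Y"])[0, 1])
        r2a = float(np.corrcoef(scores["B"], scores["Y"])[0, 1])
        assert paths["Y"]["A"] == pytest.approx(r1, abs=1e-10)
        assert paths["Y"]["B"] == pytest.approx(r2a, abs=1e-10)
        assert r2["Y"] == pytest.approx(r1 * r1 + r2a * r2a, abs=1e-10)

    def test_matches_explicit_normal_equation_solve(self):
        rng = np.random.default_rng(4)
        Z = rng.standard_normal((300, 3))
        Z[:, 1] = 0.7 * Z[:, 0] + 0.3 * Z[:, 1]
        y = Z @ np.array([0.5, -0.2, 0.3]) + rng.standard_normal(300)
        scores = c.standardize(
            pd.DataFrame({"P1": Z[:, 0], "P2": Z[:, 1], "P3": Z[:, 2], "Y": y})
        )
        inner = c.InnerSpec(
            ("P1", "P2", "P3", "Y"),
            (("P1", "Y"), ("P2", "Y"), ("P3", "Y")),
        )
        paths, r2 = c.path_coefficients(scores, inner)
        P = scores[["P1", "P2", "P3"]].to_numpy()
        beta = np.linalg.solve(P.T @ P, P.T @ scores["Y"].to_numpy())
        assert np.allclose(paths["Y"].to_numpy(), beta, atol=1e-12)

    def test_collinear_predecessors_error(self):
        v = np.random.default_rng(5).standard_normal(50)
        scores = c.standardize(pd.DataFrame({"A": v, "B": v, "Y": v}))
        inner = c.InnerSpec(("A", "B", "Y"), (("A", "Y"), ("B", "Y")))
        with pytest.raises(PLSPMError, match="collinear"):
            c.path_coefficients(scores, inner)


class TestOlsFromCorrelation:
    def test_orthogonal_predictors_return_rxy(self):
        corr = pd.DataFrame(
            [[1.0, 0.3, 0.4], [0.3, 1.0, 0.0], [0.4, 0.0, 1.0]],
            index=["y", "p", "q"], columns=["y", "p", "q"],
        )
        beta, r2, cond = c.ols_from_correlation(corr, "y", ["p", "q"])
        assert beta["p"] == pytest.approx(0.3, abs=1e-12)
        assert beta["q"] == pytest.approx(0.4, abs=1e-12)
        assert r2 == pytest.approx(0.09 + 0.16, abs=1e-12)
        assert cond == pytest.approx(1.0, abs=1e-12)

    def test_published_single_predictor_bridge(self, table4):
        beta, r2, _ = c.ols_from_correlation(table4, "LV_overall", ["LV_10"])
        assert beta["LV_10"] == pytest.approx(0.9908, abs=0.005)
        assert r2 == pytest.approx(0.9818, abs=0.005)

    def test_published_sink_r2_despite_ill_conditioning(self, table4):
        beta, r2, cond = c.ols_from_correlation(
            table4, "LV_setback", ["LV_10", "LV_overall", "LV_1"]
        )
        assert cond > 100  # rounded near-collinear system
        assert r2 == pytest.approx(0.8731, abs=0.01)
        # cross-check against an independent full-precision solve
        Rxx = table4.loc[["LV_10", "LV_overall", "LV_1"],
                         ["LV_10", "LV_overall", "LV_1"]].to_numpy()
        rxy = table4.loc[["LV_10", "LV_overall", "LV_1"],
                         "LV_setback"].to_numpy()
        assert r2 == pytest.approx(float(rxy @ np.linalg.solve(Rxx, rxy)),
                                   abs=1e-12)

    def test_rejects_non_unit_diagonal(self):
        corr = pd.DataFrame([[1.0, 0.2], [0.2, 0.9]],
                            index=["y", "p"], columns=["y", "p"])
        with pytest.raises(PLSPMError, match="diagonal"):
            c.ols_from_correlation(corr, "y", ["p"])

    def test_rejects_singular_predictors(self):
        corr = pd.DataFrame(
            [[1.0, 0.5, 0.5], [0.5, 1.0, 1.0], [0.5, 1.0, 1.0]],
            index=["y", "p", "q"], columns=["y", "p", "q"],
        )
        with pytest.raises(PLSPMError):
            c.ols_from_correlation(corr, "y", ["p", "q"])


class TestQualityIndices:
    def test_loading_to_communality(self):
        # 0.991^2 = 0.982081, the printed 0.9819 to table precision
        assert 0.991**2 == pytest.approx(0.9819, abs=5e-4)

    def test_redundancy_product(self):
        # communality 0.9639 x R2 0.9818 -> printed 0.9463
        assert 0.9639 * 0.9818 == pytest.approx(0.9463, abs=5e-4)

    def test_identities_on_fitted_model(self, reflective_three_lv_spec):
        spec = reflective_three_lv_spec
        X, _ = c.simulate_latent(spec, seed=2)
        res = c.fit(X, spec.engine_blocks(), spec.inner)
        comm, red = c.quality_indices(res)
        for lv in res.inner.lv_names:
            assert np.allclose(res.communalities[lv],
                               res.loadings[lv] ** 2, atol=1e-12)
            assert np.allclose(comm[lv], res.communalities[lv], atol=1e-12)
            r2 = res.r_squared.get(lv, 0.0)
            assert np.allclose(res.redundancies[lv],
                               res.communalities[lv] * r2, atol=1e-12)
            assert (np.abs(res.loadings[lv]) <= 1 + 1e-12).all()


class TestGoodnessOfFit:
    def test_perfect_model(self):
        assert c.goodness_of_fit([1.0, 1.0], [1.0]) == pytest.approx(1.0)

    def test_closed_form(self):
        assert c.goodness_of_fit([0.25] * 4, [1.0, 1.0]) == pytest.approx(0.5)

    def test_empty_errors(self):
        with pytest.raises(PLSPMError):
            c.goodness_of_fit([], [0.5])


class TestLvCorrelationMatrix:
    def test_self_correlation_and_labels(self, reflective_three_lv_spec):
        spec = reflective_three_lv_spec
        X, _ = c.simulate_latent(spec, seed=3)
        res = c.fit(X, spec.engine_blocks(), spec.inner)
        R = res.lv_correlations
        assert list(R.index) == list(spec.inner.lv_names)
        assert np.allclose(np.diag(R), 1.0, atol=1e-12)
        assert np.allclose(R, R.T, atol=1e-12)

    def test_independent_columns_nearly_uncorrelated(self):
        rng = np.random.default_rng(8)
        scores = pd.DataFrame(
            {"A": rng.standard_normal(10000), "B": rng.standard_normal(10000)}
        )
        R = c.lv_correlation_matrix(scores)
        assert abs(R.loc["A", "B"]) < 0.05


class TestFitContracts:
    def test_scores_standardized(self, reflective_three_lv_spec):
        spec = reflective_three_lv_spec
        X, _ = c.simulate_latent(spec, seed=5)
        res = c.fit(X, spec.engine_blocks(), spec.inner)
        assert res.converged
        assert float(np.abs(res.lv_scores.mean()).max()) < 1e-10
        assert float(np.abs(res.lv_scores.var(ddof=1) - 1).max()) < 1e-10

    def test_scheme_agreement_on_well_separated_data(
        self, reflective_three_lv_spec
    ):
        spec = reflective_three_lv_spec
        X, _ = c.simulate_latent(spec, seed=9)
        ests = {}
        for scheme in ("centroid", "factorial", "path"):
            r = c.fit(X, spec.engine_blocks(), spec.inner, scheme=scheme)
            ests[scheme] = r.path_coefficients["C"]
        for s1, s2 in itertools.combinations(ests, 2):
            assert np.allclose(ests[s1], ests[s2], atol=0.02)

    def test_row_permutation_invariance(self, reflective_three_lv_spec):
        spec = reflective_three_lv_spec
        X, _ = c.simulate_latent(spec, seed=6)
        perm = np.random.default_rng(0).permutation(X.shape[0])
        r1 = c.fit(X, spec.engine_blocks(), spec.inner)
        r2 = c.fit(X.iloc[perm], spec.engine_blocks(), spec.inner)
        for lv in r1.inner.endogenous():
            assert np.allclose(r1.path_coefficients[lv],
                               r2.path_coefficients[lv], atol=1e-12)
        for lv in r1.inner.lv_names:
            assert np.allclose(r1.outer_weights[lv], r2.outer_weights[lv],
                               atol=1e-12)
        assert r1.gof == pytest.approx(r2.gof, abs=1e-12)

    def test_mv_reordering_within_block(self, reflective_three_lv_spec):
        spec = reflective_three_lv_spec
        X, _ = c.simulate_latent(spec, seed=7)
        blocks = spec.engine_blocks()
        swapped = tuple(
            c.BlockSpec(b.lv_name, tuple(reversed(b.mv_names)), mode=b.mode)
            if b.lv_name == "A" else b
            for b in blocks
        )
        r1 = c.fit(X, blocks, spec.inner)
        r2 = c.fit(X, swapped, spec.inner)
        assert np.allclose(
            r1.outer_weights["A"].sort_index(),
            r2.outer_weights["A"].sort_index(), atol=1e-12,
        )
        assert np.allclose(r1.lv_scores, r2.lv_scores, atol=1e-12)

    def test_negating_non_dominant_mv_flips_only_that_mv(
        self, reflective_three_lv_spec
    ):
        spec = reflective_three_lv_spec
        X, _ = c.simulate_latent(spec, seed=11)
        r1 = c.fit(X, spec.engine_blocks(), spec.inner)
        # a2 is not block A's dominant loading under this spec
        assert r1.loadings["A"].abs().idxmax() != "a2"
        X2 = X.copy()
        X2["a2"] = -X2["a2"]
        r2 = c.fit(X2, spec.engine_blocks(), spec.inner)
        assert r2.loadings["A"]["a2"] == pytest.approx(
            -r1.loadings["A"]["a2"], abs=1e-9)
        assert r2.loadings["A"]["a1"] == pytest.approx(
            r1.loadings["A"]["a1"], abs=1e-9)
        assert np.allclose(r1.lv_scores, r2.lv_scores, atol=1e-9)
        for lv in r1.inner.endogenous():
            assert np.allclose(r1.path_coefficients[lv],
                               r2.path_coefficients[lv], atol=1e-9)

    def test_orientation_rule_dominant_loading_positive(
        self, reflective_three_lv_spec
    ):
        spec = reflective_three_lv_spec
        X, _ = c.simulate_latent(spec, seed=12)
        res = c.fit(X, spec.engine_blocks(), spec.inner)
        for lv in res.inner.lv_names:
            lam = res.loadings[lv]
            assert lam[lam.abs().idxmax()] > 0

    def test_nonconvergence_flagged_and_warned(self, reflective_three_lv_spec):
        spec = reflective_three_lv_spec
        X, _ = c.simulate_latent(spec, seed=19)
        with pytest.warns(NonConvergenceWarning):
            res = c.fit(X, spec.engine_blocks(), spec.inner, tol=1e-12,
                        max_iter=1)
        assert not res.converged

    def test_singular_formative_block_named(self):
        v = np.random.default_rng(13).standard_normal(30)
        X = pd.DataFrame({"x1": v, "x2": 2 * v, "y": v + 1})
        blocks = (
            c.BlockSpec("F", ("x1", "x2"), mode="formative"),
            c.BlockSpec("Y", ("y",)),
        )
        inner = c.InnerSpec(("F", "Y"), (("F", "Y"),))
        with pytest.raises(SingularBlockError, match="F"):
            c.fit(X, blocks, inner)

    def test_too_few_rows_for_formative_block(self):
        X = pd.DataFrame(
            np.random.default_rng(14).standard_normal((3, 4)),
            columns=["a", "b", "c", "y"],
        )
        blocks = (
            c.BlockSpec("F", ("a", "b", "c"), mode="formative"),
            c.BlockSpec("Y", ("y",)),
        )
        inner = c.InnerSpec(("F", "Y"), (("F", "Y"),))
        with pytest.raises(PLSPMError, match="too small"):
            c.fit(X, blocks, inner)

    def test_block_inner_mismatch(self, correlated_pair):
        blocks = (c.BlockSpec("A", ("x",)), c.BlockSpec("B", ("y",)))
        inner = c.InnerSpec(("A", "Z"), (("A", "Z"),))
        with pytest.raises(PLSPMError, match="do not match"):
            c.fit(correlated_pair, blocks, inner)

    def test_gof_identity_both_variants(self, reflective_three_lv_spec):
        spec = reflective_three_lv_spec
        X, _ = c.simulate_latent(spec, seed=15)
        res = c.fit(X, spec.engine_blocks(), spec.inner)
        comm = [float(v) for lv in res.inner.lv_names
                for v in res.communalities[lv]]
        r2 = [res.r_squared[lv] for lv in res.inner.endogenous()]
        assert res.gof_all_mvs == pytest.approx(
            float(np.sqrt(np.mean(comm) * np.mean(r2))), abs=1e-12)
        assert res.gof == res.gof_all_mvs  # default variant


class TestInnerSpec:
    def test_rejects_cycles(self):
        with pytest.raises(PLSPMError, match="cycle"):
            c.InnerSpec(("A", "B"), (("A", "B"), ("B", "A")))

    def test_rejects_unknown_endpoints(self):
        with pytest.raises(PLSPMError, match="unknown"):
            c.InnerSpec(("A", "B"), (("A", "C"),))

    def test_endogenous_exogenous_partition(self):
        inner = c.InnerSpec(("A", "B", "C"), (("A", "C"), ("B", "C")))
        assert inner.endogenous() == ("C",)
        assert inner.exogenous() == ("A", "B")
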