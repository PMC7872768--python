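"""AUC, permutation testing, FDR and partial correlation."""

import itertools

import numpy as np
import pytest
from scipy import integrate, stats

from scnkit import inference
from scnkit.data_io import ValidationError
from scnkit.inference import (
    auc_trapezoid,
    bh_fdr,
    metric_curve_extractor,
    partial_correlation,
    permutation_test,
)
from scnkit.scn import default_sparsities


class TestAuc:
    def test_constant_curve(self):
        s = default_sparsities()
        assert auc_trapezoid(np.full(len(s), 3.0), s) == pytest.approx(0.45 * 3.0)

    def test_linear_ramp_any_grid(self, rng):
        grid = np.sort(rng.uniform(0, 1, 20))
        grid[0], grid[-1] = 0.0, 1.0
        assert auc_trapezoid(grid.copy(), grid) == pytest.approx(0.5)

    def test_matches_scipy_quadrature(self, rng):
        s = default_sparsities()
        vals = rng.normal(size=len(s))
        assert auc_trapezoid(vals, s) == pytest.approx(
            integrate.trapezoid(vals, s), abs=1e-12
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            auc_trapezoid([1.0, 2.0], [0.1, 0.2, 0.3])


def _split_residuals(rng, n1=6, n2=6, n_roi=8, shift=0.0):
    res1 = rng.normal(size=(n1, n_roi)) + shift
    res2 = rng.normal(size=(n2, n_roi))
    return res1, res2


class TestPermutationTest:
    SPARSITIES = np.arange(20, 51) / 100  # denser graphs keep tiny cases connected

    def _extractor(self):
        return metric_curve_extractor("degree", self.SPARSITIES)

    def test_p_matches_add_one_tail_count(self, rng):
        res1, res2 = _split_residuals(rng, 8, 8, 10)
        ext = metric_curve_extractor("clustering", self.SPARSITIES)
        res = permutation_test(res1, res2, ext, self.SPARSITIES, n_perm=50, rng=rng)
        expected = (np.sum(np.abs(res.null_diffs) >= abs(res.observed_diff)) + 1) / 51
        assert res.p == pytest.approx(expected)
        assert 1 / 51 <= res.p <= 1

    def test_exact_enumeration_matches_brute_force(self, rng):
        res1, res2 = _split_residuals(rng, 3, 3, 6)
        ext = metric_curve_extractor("clustering", self.SPARSITIES)
        res = permutation_test(res1, res2, ext, self.SPARSITIES, rng=rng, exact=True)
        pooled = np.vstack([res1, res2])
        diffs = []
        for idx in itertools.combinations(range(6), 3):
            m = np.zeros(6, dtype=bool)
            m[list(idx)] = True
            diffs.append(
                auc_trapezoid(ext(pooled[m]), self.SPARSITIES)
                - auc_trapezoid(ext(pooled[~m]), self.SPARSITIES)
            )
        diffs = np.asarray(diffs)
        assert len(diffs) == 20
        np.testing.assert_allclose(np.sort(res.null_diffs), np.sort(diffs), atol=1e-12)
        expected_p = (np.sum(np.abs(diffs) >= abs(res.observed_diff)) + 1) / 21
        assert res.p == pytest.approx(expected_p)

    def test_group_swap_negates_diff_and_keeps_p(self, rng):
        res1, res2 = _split_residuals(rng, 3, 3, 6, shift=1.0)
        ext = metric_curve_extractor("clustering", self.SPARSITIES)
        a = permutation_test(res1, res2, ext, self.SPARSITIES, exact=True)
        b = permutation_test(res2, res1, ext, self.SPARSITIES, exact=True)
        assert b.observed_diff == pytest.approx(-a.observed_diff)
        assert b.p == pytest.approx(a.p)

    def test_exact_p_bound_for_extreme_effect(self, rng):
        # effect so large every mixed assignment dilutes it: only the two
        # pure assignments tie the observed magnitude
        res1 = rng.normal(size=(3, 6)) + 0.0
        res2 = rng.normal(size=(3, 6))
        res1[:, :3] = res1[:, :3] * 0.01 + np.arange(3)[:, None] * 10  # tight coupling
        ext = metric_curve_extractor("clustering", self.SPARSITIES)
        res = permutation_test(res1, res2, ext, self.SPARSITIES, exact=True)
        tail = np.sum(np.abs(res.null_diffs) >= abs(res.observed_diff))
        assert res.p == pytest.approx((tail + 1) / (len(res.null_diffs) + 1))

    def test_p_invariant_under_odd_monotone_transform_of_diffs(self, rng):
        res1, res2 = _split_residuals(rng, 8, 8, 10)
        ext = metric_curve_extractor("clustering", self.SPARSITIES)
        res = permutation_test(res1, res2, ext, self.SPARSITIES, n_perm=99, rng=rng)
        h = lambda d: np.sign(d) * np.abs(d) ** 3  # strictly monotone, odd
        p_t = (np.sum(np.abs(h(res.null_diffs)) >= abs(h(res.observed_diff))) + 1) / 100
        assert p_t == pytest.approx(res.p)

    def test_nodal_metric_gets_fdr_q(self, rng):
        res1, res2 = _split_residuals(rng, 8, 8, 10)
        res = permutation_test(
            res1, res2, self._extractor(), self.SPARSITIES, n_perm=30, rng=rng,
            labels=[f"r{k}" for k in range(10)],
        )
        assert res.q is not None and res.q.shape == (10,)
        assert np.all(res.q >= res.p - 1e-12)
        frame = res.to_frame()
        assert list(frame["node"]) == [f"r{k}" for k in range(10)]

    def test_invalid_repetition_count_rejected(self, rng):
        res1, res2 = _split_residuals(rng)
        with pytest.raises(ValidationError):
            permutation_test(res1, res2, self._extractor(), self.SPARSITIES, n_perm=0)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2] * 5), 0.2)

    def test_matches_step_up_definition(self, rng):
        def brute_force_bh(p):
            m = len(p)
            order = np.argsort(p)
            q = np.empty(m)
            running_min = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running_min = min(running_min, p[i] * m / rank)
                q[i] = running_min
            return q

        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 13))
            np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.2])


class TestPartialCorrelation:
    def test_no_covariates_reduces_to_pearson(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = partial_correlation(x, y)
        r, p = stats.pearsonr(x, y)
        assert res.r == pytest.approx(r)
        assert res.p == pytest.approx(p)
        assert res.df == 28

    def test_identical_variables_correlate_to_one(self, rng):
        x = rng.normal(size=20)
        Z = rng.normal(size=(20, 2))
        res = partial_correlation(x, x, Z)
        assert res.r == pytest.approx(1.0)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        x, y = rng.normal(size=40), rng.normal(size=40)
        z1, z2 = rng.normal(size=40), rng.normal(size=40)
        df = pd.DataFrame({"x": x, "y": y, "z1": z1, "z2": z2})
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["z1", "z2"])
        res = partial_correlation(x, y, np.column_stack([z1, z2]))
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert res.p == pytest.approx(float(ref[pcol].iloc[0]), abs=1e-10)

    def test_missing_rows_dropped(self, rng):
        x = rng.normal(size=25)
        y = x + rng.normal(size=25) * 0.1
        y[3] = np.nan
        res = partial_correlation(x, y)
        assert res.n == 24

    def test_rank_deficient_covariates_rejected(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        z = rng.normal(size=20)
        with pytest.raises(ValidationError):
            partial_correlation(x, y, np.column_stack([z, 2 * z]))


def test_degree_extractor_matches_explicit_graph_series(rng, small_cohort):
    """Fast batched degree curves equal per-graph degree sums."""
    from scnkit import graphmetrics, preprocess, scn

    _, volumes, cohort, _ = small_cohort
    model = preprocess.regress_confounds(volumes, cohort)
    res = model.residuals_for_group(cohort, "patient")
    s = default_sparsities()
    fast = metric_curve_extractor("degree", s)(res)
    net = scn.build_covariance_network(res)
    series = scn.build_graph_series(net, s)
    slow = np.array([graphmetrics.degree_sequence(series.graph(k)) for k in range(len(s))])
    np.testing.assert_array_equal(fast, slow)


@pytest.mark.parametrize("metric", ["clustering", "path_length", "global_efficiency",
                                    "nodal_efficiency", "local_efficiency", "betweenness"])
def test_extractors_match_per_graph_functions(rng, metric):
    """Every batched extractor agrees with the public per-graph metrics."""
    from scnkit import graphmetrics, scn

    res = rng.normal(size=(15, 12))
    s = np.arange(10, 51, 5) / 100
    curve = metric_curve_extractor(metric, s)(res)
    net = scn.build_covariance_network(res)
    series = scn.build_graph_series(net, s)
    per_graph = {
        "clustering": lambda a: graphmetrics.clustering_coefficients(a)[1],
        "path_length": graphmetrics.characteristic_path_length,
        "global_efficiency": graphmetrics.global_efficiency,
        "nodal_efficiency": graphmetrics.nodal_efficiency,
        "local_efficiency": lambda a: graphmetrics.local_efficiency(a)[1],
        "betweenness": graphmetrics.betweenness_centrality,
    }[metric]
    expected = np.array([per_graph(series.graph(k)) for k in range(len(s))])
    np.testing.assert_allclose(curve, expected, atol=1e-6)
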