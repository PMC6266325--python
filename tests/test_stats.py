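"""Tests for covariate adjustment, permutation tests and FDR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conntopo import stats as S
from conntopo.build import build_sparsity_grid
from conntopo.pipeline import compute_cohort_curves
from conntopo.synthetic import SyntheticConfig, generate_cohort

import oracles


class TestAdjustCovariates:
    def test_exact_linear_dependence_gives_zero_residuals(self):
        rng = np.random.default_rng(0)
        age = rng.normal(40, 10, 20)
        cov = np.column_stack([age, rng.integers(0, 2, 20), rng.normal(8, 3, 20)])
        resid = S.adjust_covariates(2.0 * age, cov)
        assert np.allclose(resid, 0.0, atol=1e-9)

    def test_constant_covariate_errors(self):
        y = np.arange(6, dtype=float)
        with pytest.raises(ValueError, match="rank deficient"):
            S.adjust_covariates(y, np.ones((6, 1)))

    def test_matches_ols_closed_form(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        resid = S.adjust_covariates(y, X)
        Xi = np.column_stack([np.ones(30), X])
        beta = np.linalg.solve(Xi.T @ Xi, Xi.T @ y)  # normal equations oracle
        assert np.allclose(resid, y - Xi @ beta, atol=1e-10)
        assert abs(resid.sum()) < 1e-8
        assert np.all(np.abs(X.T @ resid) < 1e-8)


class TestPermutationTest:
    def test_exact_enumeration_123_456(self):
        obs, p = S.permutation_test([1, 2, 3], [4, 5, 6], n_perm=1000)
        assert obs == pytest.approx(-3.0)
        assert p == pytest.approx(2 / 20)  # the two extreme splits of C(6,3)

    def test_identical_groups_p_one(self):
        _, p = S.permutation_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], n_perm=500)
        assert p == pytest.approx(1.0)

    def test_reproducible_with_seed(self):
        a = np.random.default_rng(0).normal(size=12)
        b = np.random.default_rng(1).normal(size=12)
        r1 = S.permutation_test(a, b, 2000, np.random.default_rng(5))
        r2 = S.permutation_test(a, b, 2000, np.random.default_rng(5))
        assert r1 == r2

    def test_label_swap_flips_sign_keeps_p(self):
        a = [1.0, 3.0, 2.5, 4.0]
        b = [2.0, 5.0, 6.0]
        o1, p1 = S.permutation_test(a, b, 1000)
        o2, p2 = S.permutation_test(b, a, 1000)
        assert o1 == pytest.approx(-o2)
        assert p1 == pytest.approx(p2)

    def test_sampled_agrees_with_exact(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 4)
        b = rng.normal(1, 1, 4)
        _, p_exact = S.permutation_test(a, b, n_perm=100)  # C(8,4)=70 -> exact
        _, p_samp = S.permutation_test(a, b, n_perm=50000, rng=rng)
        assert abs(p_exact - p_samp) < 0.02

    def test_nan_column_yields_nan_p(self):
        V = np.column_stack([np.arange(8.0), np.full(8, np.nan)])
        obs, p = S.permutation_test_many(V, np.arange(8) < 4, n_perm=200)
        assert np.isfinite(p[0])
        assert np.isnan(p[1])


class TestBhFdr:
    def test_stepup_example_all_rejected(self):
        p_adj, reject = S.bh_fdr([0.005, 0.01, 0.03, 0.04], q=0.05)
        assert reject.all()

    def test_none_rejected(self):
        _, reject = S.bh_fdr([0.2, 0.3], q=0.05)
        assert not reject.any()

    def test_matches_handwritten_stepup(self):
        rng = np.random.default_rng(2)
        p = rng.random(25)
        p_adj, reject = S.bh_fdr(p, q=0.1)
        adj_o, rej_o = oracles.bh_stepup(p.tolist(), 0.1)
        assert np.allclose(p_adj, adj_o, atol=1e-12)
        assert list(reject) == rej_o

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=20))
    def test_adjusted_p_monotone_in_raw_p(self, pvals):
        p = np.array(pvals)
        p_adj, _ = S.bh_fdr(p, q=0.05)
        order = np.argsort(p)
        assert (np.diff(p_adj[order]) >= -1e-12).all()

    def test_invalid_p_errors(self):
        with pytest.raises(ValueError):
            S.bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            S.bh_fdr([0.5, 1.2])


def _cohort_inputs(cfg, grid, n_random, rng):
    subjects, parts, _ = generate_cohort(cfg)
    curves, nodal = compute_cohort_curves(
        [s.weights for s in subjects], grid, n_random, rng, nodal=True
    )
    is_patient = (parts["group"] == "patient").to_numpy()
    cov = parts[list(S.COVARIATE_COLUMNS)].to_numpy(dtype=float)
    return curves, nodal, is_patient, cov


class TestCohortComparisons:
    def test_planted_global_reduction_flags_efficiency(self):
        # all patient edges weakened: Eg must come out lower in patients
        cfg = SyntheticConfig(
            n_regions=30, n_per_group=(12, 12), lattice_neighbors=3,
            subject_noise_cv=0.2, seed=9,
            planted_edge_set=tuple(
                (i, (i + d) % 30) for d in (1, 2, 3) for i in range(30)
            ),
            planted_factor=0.6,
        )
        grid = build_sparsity_grid(0.14, 0.18, 0.02)
        rng = np.random.default_rng(4)
        curves, _, is_patient, cov = _cohort_inputs(cfg, grid, 0, rng)
        curves = {m: curves[m] for m in ("Cp", "Lp", "Eg", "Eloc")}
        primary, secondary = S.compare_global_metrics(
            curves, is_patient, cov, grid, n_perm=500, rng=rng
        )
        eg = primary.set_index("metric").loc["Eg"]
        assert eg["observed_diff"] < 0
        assert eg["p"] < 0.05
        assert set(secondary["metric"]) == set(curves)

    def test_empty_group_errors(self):
        V = np.arange(5.0)[:, None]
        with pytest.raises(ValueError, match="non-empty"):
            S.permutation_test_many(V, np.zeros(5, dtype=bool), 100)

    def test_nodal_comparison_shapes_and_fdr_family(self):
        cfg = SyntheticConfig(
            n_regions=20, n_per_group=(6, 6), lattice_neighbors=2,
            subject_noise_cv=0.3, seed=11,
        )
        grid = build_sparsity_grid(0.15, 0.25, 0.05)
        rng = np.random.default_rng(5)
        _, nodal, is_patient, cov = _cohort_inputs(cfg, grid, 0, rng)
        out = S.compare_nodal_metrics(
            nodal, is_patient, cov, grid, n_perm=300, rng=rng
        )
        for m in ("Ne", "Bc", "Dc"):
            assert len(out[m]) == 20
            ok = out[m]["p"].notna()
            assert (out[m].loc[ok & out[m]["rejected"], "p_fdr"] <= 0.05).all()


class TestHemisphereAnalysis:
    def _fake_comparison(self, pvals):
        import pandas as pd

        n = len(pvals)
        return {
            "Ne": pd.DataFrame(
                {
                    "node": np.arange(1, n + 1),
                    "label": [f"R{i // 2 + 1:02d}.{'L' if i % 2 == 0 else 'R'}"
                              for i in range(n)],
                    "observed_diff": np.zeros(n),
                    "p": pvals,
                    "p_fdr": pvals,
                    "rejected": np.zeros(n, dtype=bool),
                }
            )
        }

    def test_right_hemisphere_signal_stays_right(self):
        # small p only on odd (right) nodes
        p = np.where(np.arange(10) % 2 == 1, 1e-5, 0.8)
        hemis = ["L" if i % 2 == 0 else "R" for i in range(10)]
        tables, counts = S.hemisphere_analysis(self._fake_comparison(p), hemis)
        assert tables["R"]["rejected"].all()
        assert not tables["L"]["rejected"].any()
        right = counts[(counts["hemisphere"] == "R")]["n_significant"].iloc[0]
        left = counts[(counts["hemisphere"] == "L")]["n_significant"].iloc[0]
        assert (right, left) == (5, 0)

    def test_no_signal_no_rejections(self):
        p = np.full(10, 0.9)
        hemis = ["L" if i % 2 == 0 else "R" for i in range(10)]
        tables, counts = S.hemisphere_analysis(self._fake_comparison(p), hemis)
        assert counts["n_significant"].sum() == 0
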