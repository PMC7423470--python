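"""FPD combination, OLS oracle checks and bootstrap propagation."""

import numpy as np
import pandas as pd
import pytest

from fpdemog.distance import DistanceMatrix
from fpdemog.regression import (
    DistinctivenessRegression,
    a_grid,
    bootstrap_regression,
    combine_fpd,
    sweep_a,
)


def random_dm(rng, n, labels=None, scale=1.0):
    M = rng.uniform(0.1, 1.0, size=(n, n)) * scale
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0.0)
    labels = labels or tuple(f"L{i}_x" for i in range(n))
    return DistanceMatrix(labels, M)


class TestCombineFPD:
    def test_endpoints_reproduce_standardized_inputs(self):
        rng = np.random.default_rng(0)
        PD = random_dm(rng, 6, scale=7.0)
        FD = random_dm(rng, 6, labels=PD.labels)
        at1 = combine_fpd(PD, FD, 1.0)
        at0 = combine_fpd(PD, FD, 0.0)
        np.testing.assert_allclose(at1.values, PD.values / PD.max_offdiag(),
                                   atol=1e-12)
        np.testing.assert_allclose(at0.values, FD.values / FD.max_offdiag(),
                                   atol=1e-12)

    def test_hand_midpoint_value(self):
        labels = ("A_a", "B_b")
        PD = DistanceMatrix(labels, np.array([[0.0, 0.6], [0.6, 0.0]]))
        FD = DistanceMatrix(labels, np.array([[0.0, 0.8], [0.8, 0.0]]))
        out = combine_fpd(PD, FD, 0.5, standardization="none")
        assert out.values[0, 1] == pytest.approx(np.sqrt(0.5), abs=1e-9)

    def test_monotone_in_a(self):
        rng = np.random.default_rng(1)
        PD = random_dm(rng, 5, scale=3.0)
        FD = random_dm(rng, 5, labels=PD.labels)
        p = PD.values / PD.max_offdiag()
        f = FD.values / FD.max_offdiag()
        prev = None
        for a in np.linspace(0, 1, 11):
            cur = combine_fpd(PD, FD, float(a)).values
            if prev is not None:
                up = p > f
                down = p < f
                assert np.all(cur[up] >= prev[up] - 1e-12)
                assert np.all(cur[down] <= prev[down] + 1e-12)
            prev = cur

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        PD = random_dm(rng, 4)
        FD = random_dm(rng, 4, labels=tuple(f"M{i}_y" for i in range(4)))
        with pytest.raises(ValueError, match="label"):
            combine_fpd(PD, FD, 0.5)

    def test_grid_has_41_points(self):
        assert len(a_grid(0.025)) == 41
        with pytest.raises(ValueError):
            a_grid(0.03)


class TestDistinctivenessRegression:
    def test_perfect_fit_recovers_slope(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 1, 10)
        bm = rng.normal(size=10)
        y = 2.0 * x - 1.0
        res = DistinctivenessRegression(y, x, bm).fit()
        assert res.params["distinctiveness"] == pytest.approx(2.0, abs=1e-10)
        assert res.params["biomass"] == pytest.approx(0.0, abs=1e-10)
        assert res.adj_r2 == pytest.approx(1.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = 14
            d = rng.normal(size=n)
            bm = rng.normal(size=n)
            y = rng.normal(size=n)
            res = DistinctivenessRegression(y, d, bm).fit()
            bz = (bm - bm.mean()) / bm.std(ddof=1)
            X = np.column_stack([np.ones(n), d, bz])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            np.testing.assert_allclose(res.params.to_numpy(), beta, atol=1e-8)
            fitted = X @ beta
            ss_res = ((y - fitted) ** 2).sum()
            ss_tot = ((y - y.mean()) ** 2).sum()
            r2 = 1 - ss_res / ss_tot
            adj = 1 - (1 - r2) * (n - 1) / (n - 3)
            assert res.adj_r2 == pytest.approx(adj, abs=1e-8)

    def test_null_simulation_low_adj_r2(self):
        rng = np.random.default_rng(5)
        adj, pos = [], 0
        for _ in range(1000):
            y = rng.normal(size=14)
            d = rng.normal(size=14)
            bm = rng.normal(size=14)
            res = DistinctivenessRegression(y, d, bm).fit()
            adj.append(res.adj_r2)
            pos += res.params["distinctiveness"] > 0
        assert float(np.mean(adj)) < 0.05
        assert 0.4 < pos / 1000 < 0.6

    def test_small_n_and_constant_predictors_rejected(self):
        with pytest.raises(ValueError):
            DistinctivenessRegression([1, 2, 3], [1, 2, 3], [4, 5, 6])
        with pytest.raises(ValueError, match="non-constant"):
            DistinctivenessRegression(np.arange(5.0), np.ones(5), np.arange(5.0))

    def test_summary_mentions_coefficients(self):
        rng = np.random.default_rng(6)
        res = DistinctivenessRegression(rng.normal(size=8), rng.normal(size=8),
                                        rng.normal(size=8)).fit()
        s = res.summary()
        assert "distinctiveness" in s and "adj R^2" in s


class TestSweep:
    def make_world(self, seed=0, n=20):
        rng = np.random.default_rng(seed)
        PD = random_dm(rng, n, scale=12.0)
        FD = random_dm(rng, n, labels=PD.labels)
        focals = list(PD.labels[:8])
        communities = {
            sp: [x for x in PD.labels if x != sp][:10] for sp in focals
        }
        return rng, PD, FD, focals, communities

    def test_default_grid_41_rows(self):
        rng, PD, FD, focals, communities = self.make_world()
        eff = {sp: rng.normal() for sp in focals}
        bm = {sp: rng.uniform(1, 3) for sp in focals}
        sweep = sweep_a(PD, FD, communities, eff, bm, metric="MPD")
        assert len(sweep.table) == 41
        assert set(sweep.table.columns) >= {"a", "distinctiveness", "adj_r2"}

    def test_fd_equal_pd_makes_sweep_flat(self):
        rng, PD, _, focals, communities = self.make_world(seed=1)
        FD = DistanceMatrix(PD.labels, PD.values.copy())
        eff = {sp: rng.normal() for sp in focals}
        bm = {sp: rng.uniform(1, 3) for sp in focals}
        sweep = sweep_a(PD, FD, communities, eff, bm, metric="MPD")
        assert np.ptp(sweep.table["adj_r2"].to_numpy()) < 1e-9

    def test_endpoints_match_single_matrix_regressions(self):
        rng, PD, FD, focals, communities = self.make_world(seed=2)
        eff = {sp: rng.normal() for sp in focals}
        bm = {sp: rng.uniform(1, 3) for sp in focals}
        sweep = sweep_a(PD, FD, communities, eff, bm, metric="MPD", a_step=0.25)
        from fpdemog.distinct import focal_distinctiveness

        for a_val, M in ((1.0, PD), (0.0, FD)):
            dv = []
            for sp in focals:
                sub = M.submatrix([sp] + communities[sp])
                scaled = DistanceMatrix(sub.labels, sub.values / sub.max_offdiag())
                dv.append(focal_distinctiveness(scaled, sp, communities[sp],
                                                metric="MPD"))
            direct = DistinctivenessRegression(
                [eff[s] for s in focals], dv, [bm[s] for s in focals]
            ).fit()
            row = sweep.table[sweep.table["a"] == a_val].iloc[0]
            assert row["adj_r2"] == pytest.approx(direct.adj_r2, abs=1e-10)


class TestBootstrapRegression:
    def test_zero_variance_draws_collapse_to_point(self):
        rng = np.random.default_rng(7)
        n = 10
        d = rng.normal(size=n)
        bm = rng.uniform(1, 2, size=n)
        y = 1.5 - 0.4 * d + rng.normal(0, 0.1, size=n)
        E = np.tile(y[:, None], (1, 50))
        res = bootstrap_regression(E, d, bm, n_boot=50)
        point = DistinctivenessRegression(y, d, bm).fit()
        width = res.ci.loc["distinctiveness", "upper"] - res.ci.loc["distinctiveness", "lower"]
        assert width == pytest.approx(0.0, abs=1e-12)
        assert res.ci.loc["distinctiveness", "lower"] == pytest.approx(
            point.params["distinctiveness"], abs=1e-10
        )

    def test_deterministic_ci(self):
        rng = np.random.default_rng(8)
        n = 12
        d = rng.normal(size=n)
        bm = rng.uniform(1, 2, size=n)
        E = rng.normal(size=(n, 200))
        a = bootstrap_regression(E, d, bm, n_boot=200, seed=5)
        b = bootstrap_regression(E, d, bm, n_boot=200, seed=5)
        pd.testing.assert_frame_equal(a.ci, b.ci)

    def test_planted_slope_ci_excludes_zero(self):
        rng = np.random.default_rng(9)
        n = 14
        d = rng.uniform(0, 2, size=n)
        bm = rng.uniform(1, 2, size=n)
        true = 1.0 - 0.8 * d
        E = true[:, None] + rng.normal(0, 0.05, size=(n, 400))
        res = bootstrap_regression(E, d, bm, n_boot=400)
        assert res.ci.loc["distinctiveness", "upper"] < 0
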