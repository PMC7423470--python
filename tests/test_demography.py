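"""Projection models, growth rates and effect sizes against closed forms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fpdemog.demography import (
    IntegralProjectionModel,
    MatrixPopulationModel,
    ProjectionMatrix,
    SeedBankParams,
    SpeciesModelSpec,
    VitalRateCoefficients,
    bootstrap_effect_sizes,
    build_ipm_kernel,
    build_mpm,
    dominant_lambda,
    effect_size_of_competition,
    fit_vital_rates,
)


def mpm_records(rows):
    df = pd.DataFrame(rows, columns=["stage_t", "stage_t1", "repro_count"])
    df["individual_id"] = [f"i{k}" for k in range(len(df))]
    df["species"] = "S_x"
    df["treatment"] = "control"
    df["plot_id"] = "p0"
    df["year"] = 1
    return df


class TestBuildMPM:
    def test_hand_tally_half_survive(self):
        rows = [("A", "B", 0)] * 5 + [("A", "DEAD", 0)] * 5 + [("B", "DEAD", 0)] * 2
        m = build_mpm(mpm_records(rows), ["A", "B"], {})
        assert m.entries[1, 0] == pytest.approx(0.5)
        assert m.entries[:, 0].sum() == pytest.approx(0.5)

    def test_stasis_only_gives_lambda_one(self):
        rows = [("A", "A", 0)] * 4 + [("B", "B", 0)] * 4
        m = build_mpm(mpm_records(rows), ["A", "B"], {})
        np.testing.assert_allclose(m.entries, np.eye(2))
        assert dominant_lambda(m) == pytest.approx(1.0)

    def test_percapita_fecundity(self):
        rows = [("adult", "adult", 3), ("adult", "adult", 3),
                ("adult", "DEAD", 4), ("adult", "DEAD", 2),
                ("sdl", "sdl", 0)]
        m = build_mpm(mpm_records(rows), ["sdl", "adult"], {"adult": "sdl"})
        # 4 adults produce 12 recruits -> 3.0 per capita
        assert m.entries[0, 1] == pytest.approx(3.0)

    def test_empty_stage_named_in_error(self):
        rows = [("A", "A", 0)] * 3
        with pytest.raises(ValueError, match="B"):
            build_mpm(mpm_records(rows), ["A", "B"], {})

    def test_seed_bank_appended(self):
        rows = [("sdl", "adult", 0)] * 2 + [("adult", "adult", 10)] * 2
        bank = SeedBankParams(entry_prob=0.4, stasis_prob=0.5, germination_prob=0.2)
        m = build_mpm(mpm_records(rows), ["sdl", "adult"], {"adult": "sdl"}, bank)
        assert m.entries.shape == (3, 3)
        assert m.labels[-1] == "seedbank"
        assert m.entries[0, 1] == pytest.approx(0.6 * 10)   # direct recruitment
        assert m.entries[2, 1] == pytest.approx(0.4 * 10)   # into the bank
        assert m.entries[0, 2] == pytest.approx(0.2)        # germination
        assert m.entries[2, 2] == pytest.approx(0.5)        # stasis

    def test_pooling_equals_count_weighted_per_plot(self):
        rng = np.random.default_rng(5)
        stages = ["A", "B"]
        rows = []
        plots = []
        for plot in ("p1", "p2", "p3"):
            n = int(rng.integers(8, 20))
            for _ in range(n):
                st_t = stages[rng.integers(2)]
                st_t1 = ["A", "B", "DEAD"][rng.integers(3)]
                rows.append((st_t, st_t1, int(rng.integers(0, 4))))
                plots.append(plot)
        df = mpm_records(rows)
        df["plot_id"] = plots
        pooled = build_mpm(df, stages, {"B": "A"}).entries
        recon = np.zeros_like(pooled)
        tot = np.array([(df["stage_t"] == s).sum() for s in stages], float)
        for plot, grp in df.groupby("plot_id"):
            if any((grp["stage_t"] == s).sum() == 0 for s in stages):
                pytest.skip("degenerate plot draw")
            sub = build_mpm(grp, stages, {"B": "A"}).entries
            w = np.array([(grp["stage_t"] == s).sum() for s in stages], float) / tot
            recon += sub * w[None, :]
        np.testing.assert_allclose(pooled, recon, atol=1e-12)


class TestDominantLambda:
    def test_characteristic_polynomial_2x2(self):
        assert dominant_lambda(np.array([[0, 4], [0.5, 0]])) == pytest.approx(
            np.sqrt(2), abs=1e-10
        )

    def test_identity_and_diagonal(self):
        assert dominant_lambda(np.eye(3)) == pytest.approx(1.0)
        assert dominant_lambda(np.diag([0.5, 0.2])) == pytest.approx(0.5)

    def test_power_iteration_matches_eig(self):
        rng = np.random.default_rng(1)
        A = rng.uniform(0, 1, size=(700, 700)) / 700 + np.eye(700) * 0.3
        direct = float(np.max(np.abs(np.linalg.eigvals(A))))
        assert dominant_lambda(A) == pytest.approx(direct, abs=1e-8)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            dominant_lambda(np.array([[np.nan, 0], [0, 1.0]]))

    @given(st.integers(min_value=2, max_value=5), st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_substochastic_survival_lambda_below_one(self, n, seed):
        rng = np.random.default_rng(seed)
        A = rng.uniform(0, 1, size=(n, n))
        A = A / np.maximum(A.sum(axis=0), 1.0) * rng.uniform(0, 1)
        assert dominant_lambda(A) <= 1.0 + 1e-9

    @given(st.integers(0, 10_000), st.floats(1.0, 5.0))
    @settings(max_examples=40, deadline=None)
    def test_fecundity_scaling_monotone(self, seed, c):
        rng = np.random.default_rng(seed)
        T = rng.uniform(0, 0.3, size=(3, 3))
        F = np.zeros((3, 3))
        F[0, 2] = rng.uniform(0, 5)
        assert dominant_lambda(T + c * F) >= dominant_lambda(T + F) - 1e-9


class TestEffectSize:
    def test_identities(self):
        assert effect_size_of_competition(1.0, 1.0) == 0.0
        assert effect_size_of_competition(0.0, 0.0) == 0.0

    def test_hand_value(self):
        assert effect_size_of_competition(1.5, 0.5) == pytest.approx(
            np.log(2.0), abs=1e-12
        )

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            effect_size_of_competition(-0.1, 1.0)

    def test_ratio_of_logs_variant(self):
        want = np.log(1.5 + 0.5) / np.log(0.8 + 0.5)
        assert effect_size_of_competition(1.5, 0.8, variant="ratio_of_logs") == \
            pytest.approx(want, abs=1e-12)


def ipm_records(n, coeffs, seed=0, establishment_pool=True):
    rng = np.random.default_rng(seed)
    z = rng.normal(0.5, 0.8, size=n)
    p = 1 / (1 + np.exp(-(coeffs.surv_intercept + coeffs.surv_slope * z)))
    surv = rng.random(n) < p
    z1 = np.where(surv, rng.normal(coeffs.growth_intercept + coeffs.growth_slope * z,
                                   coeffs.growth_sd), np.nan)
    seeds = rng.poisson(np.exp(coeffs.fec_intercept + coeffs.fec_slope * z))
    df = pd.DataFrame({
        "individual_id": [f"i{k}" for k in range(n)],
        "species": "S_x", "treatment": "control", "plot_id": "p0",
        "stage_t": None, "stage_t1": None,
        "size_t": z, "size_t1": z1, "surv": surv.astype(float),
        "repro_count": seeds, "year": 1,
    })
    if establishment_pool:
        n_rec = int(rng.binomial(seeds.sum(), coeffs.establishment))
        rec = pd.DataFrame({
            "individual_id": [f"r{k}" for k in range(n_rec)],
            "species": "S_x", "treatment": "control", "plot_id": "p0",
            "stage_t": None, "stage_t1": None,
            "size_t": np.nan,
            "size_t1": rng.normal(coeffs.recruit_mean, coeffs.recruit_sd, n_rec),
            "surv": np.nan, "repro_count": 0, "year": 1,
        })
        df = pd.concat([df, rec], ignore_index=True)
    return df


TRUE_COEFFS = VitalRateCoefficients(
    surv_intercept=0.3, surv_slope=0.6,
    growth_intercept=0.4, growth_slope=0.9, growth_sd=0.3,
    fec_intercept=1.0, fec_slope=0.3, establishment=0.3,
    recruit_mean=-0.5, recruit_sd=0.3,
)


class TestFitVitalRates:
    def test_exact_growth_line_gives_sd_error(self):
        df = ipm_records(60, TRUE_COEFFS, seed=1)
        obs = df["size_t"].notna()
        df.loc[obs & (df["surv"] == 1), "size_t1"] = (
            0.9 * df.loc[obs & (df["surv"] == 1), "size_t"] + 1.0
        )
        with pytest.raises(ValueError, match="sd"):
            fit_vital_rates(df)

    def test_degenerate_survival_rejected(self):
        df = ipm_records(60, TRUE_COEFFS, seed=2)
        df.loc[df["size_t"].notna(), "surv"] = 1.0
        df.loc[df["size_t"].notna(), "size_t1"] = df.loc[df["size_t"].notna(), "size_t"]
        with pytest.raises(ValueError, match="degenerate survival"):
            fit_vital_rates(df)

    def test_separated_survival_handled(self):
        # survival perfectly determined by size: ridge fallback, no crash
        df = ipm_records(80, TRUE_COEFFS, seed=3)
        obs = df["size_t"].notna()
        df.loc[obs, "surv"] = (df.loc[obs, "size_t"] > 0.5).astype(float)
        df.loc[obs & (df["surv"] == 0), "size_t1"] = np.nan
        coeffs = fit_vital_rates(df)
        assert np.isfinite(coeffs.surv_intercept)
        assert coeffs.surv_slope > 0

    def test_logistic_matches_statsmodels(self):
        import statsmodels.api as sm

        df = ipm_records(300, TRUE_COEFFS, seed=4)
        coeffs = fit_vital_rates(df)
        obs = df[df["size_t"].notna()]
        X = sm.add_constant(obs["size_t"].to_numpy())
        ref = sm.Logit(obs["surv"].to_numpy(), X).fit(disp=0)
        assert coeffs.surv_intercept == pytest.approx(ref.params[0], abs=1e-6)
        assert coeffs.surv_slope == pytest.approx(ref.params[1], abs=1e-6)

    def test_parameter_recovery_within_three_se(self):
        import statsmodels.api as sm

        df = ipm_records(2000, TRUE_COEFFS, seed=5)
        coeffs = fit_vital_rates(df)
        obs = df[df["size_t"].notna()]
        X = sm.add_constant(obs["size_t"].to_numpy())
        logit = sm.Logit(obs["surv"].to_numpy(), X).fit(disp=0)
        for got, want, se in [
            (coeffs.surv_intercept, TRUE_COEFFS.surv_intercept, logit.bse[0]),
            (coeffs.surv_slope, TRUE_COEFFS.surv_slope, logit.bse[1]),
        ]:
            assert abs(got - want) < 3 * se
        grew = obs[(obs["surv"] == 1) & obs["size_t1"].notna()]
        ols = sm.OLS(grew["size_t1"].to_numpy(),
                     sm.add_constant(grew["size_t"].to_numpy())).fit()
        assert abs(coeffs.growth_intercept - TRUE_COEFFS.growth_intercept) < 3 * ols.bse[0]
        assert abs(coeffs.growth_slope - TRUE_COEFFS.growth_slope) < 3 * ols.bse[1]
        assert coeffs.growth_sd == pytest.approx(TRUE_COEFFS.growth_sd, rel=0.15)
        assert coeffs.establishment == pytest.approx(TRUE_COEFFS.establishment, rel=0.2)


class TestIPMKernel:
    def test_constant_survival_column_sums(self):
        # growth returns everyone to the domain centre: each column sums
        # to s and the kernel is rank-1 with lambda = s
        c = VitalRateCoefficients(
            surv_intercept=np.log(0.7 / 0.3), surv_slope=0.0,
            growth_intercept=5.0, growth_slope=0.0, growth_sd=0.5,
            fec_intercept=-np.inf, fec_slope=0.0, establishment=1.0,
            recruit_mean=5.0, recruit_sd=0.5,
        )
        m = build_ipm_kernel(c, (0.0, 10.0), meshpoints=500)
        sums = m.entries.sum(axis=0)
        np.testing.assert_allclose(sums, 0.7, atol=1e-6)
        assert dominant_lambda(m) == pytest.approx(0.7, abs=1e-6)

    def test_fecundity_only_rank_one_lambda(self):
        r = 2.3  # constant per-capita recruit mass
        c = VitalRateCoefficients(
            surv_intercept=-40.0, surv_slope=0.0,
            growth_intercept=5.0, growth_slope=0.0, growth_sd=0.5,
            fec_intercept=np.log(r), fec_slope=0.0, establishment=1.0,
            recruit_mean=5.0, recruit_sd=0.5,
        )
        m = build_ipm_kernel(c, (0.0, 10.0), meshpoints=500)
        z = m.mesh
        from scipy.stats import norm

        integral_c = norm.pdf(z, 5.0, 0.5).sum() * m.bin_width
        assert dominant_lambda(m) == pytest.approx(r * integral_c, abs=1e-6)

    def test_meshpoint_doubling_stability(self):
        l500 = dominant_lambda(build_ipm_kernel(TRUE_COEFFS, (-2.5, 4.0), 500))
        l1000 = dominant_lambda(build_ipm_kernel(TRUE_COEFFS, (-2.5, 4.0), 1000))
        assert abs(l500 - l1000) < 1e-4

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            build_ipm_kernel(TRUE_COEFFS, (2.0, 1.0), 100)
        with pytest.raises(ValueError):
            build_ipm_kernel(TRUE_COEFFS, (0.0, 1.0), 5)

    def test_model_class_summary(self):
        df = ipm_records(400, TRUE_COEFFS, seed=6)
        res = IntegralProjectionModel(df, meshpoints=120).fit()
        assert res.lambda_ > 0
        assert "lambda" in res.summary()
        assert res.matrix.model_kind == "IPM"


class TestBootstrap:
    SPEC = SpeciesModelSpec(kind="MPM", stages=("sdl", "juv", "adult"),
                            fecundity_map={"adult": "sdl"})

    @staticmethod
    def two_treatment_records(seed=0, n=150):
        rng = np.random.default_rng(seed)
        rows = []
        for trt, fec in (("control", 2.0), ("removal", 4.0)):
            for k in range(n):
                st = ["sdl", "juv", "adult"][rng.integers(3)]
                probs = {"sdl": [0.0, 0.3, 0.0], "juv": [0.0, 0.2, 0.5],
                         "adult": [0.0, 0.0, 0.6]}[st]
                u = rng.random()
                cum = np.cumsum(probs + [1 - sum(probs)])
                fate = ["sdl", "juv", "adult", "DEAD"][int(np.searchsorted(cum, u))]
                rows.append({
                    "individual_id": f"{trt}{k}", "species": "S_x",
                    "treatment": trt, "plot_id": f"{trt}-p{k % 4}",
                    "stage_t": st, "stage_t1": fate,
                    "size_t": np.nan, "size_t1": np.nan, "surv": float(fate != "DEAD"),
                    "repro_count": int(rng.poisson(fec)) if st == "adult" else 0,
                    "year": 1,
                })
        return pd.DataFrame(rows)

    def test_identity_resample_equals_point_estimate(self):
        df = self.two_treatment_records()
        from fpdemog.demography import point_effect_size

        point = point_effect_size(df, self.SPEC).value
        draws = bootstrap_effect_sizes(df, self.SPEC, n_boot=3, resample=False)
        np.testing.assert_allclose(draws, point)

    def test_deterministic_under_seed(self):
        df = self.two_treatment_records()
        a = bootstrap_effect_sizes(df, self.SPEC, n_boot=50, seed=4)
        b = bootstrap_effect_sizes(df, self.SPEC, n_boot=50, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_bootstrap_sd_matches_monte_carlo_oracle(self):
        # sd of bootstrap lambda should track the sd across fresh datasets
        from fpdemog.demography import _bootstrap_mpm_lambdas, treatment_lambdas

        lams_fresh = []
        for rep in range(200):
            df = self.two_treatment_records(seed=100 + rep)
            lams_fresh.append(
                treatment_lambdas(df, self.SPEC)["control"]
            )
        sd_fresh = float(np.std(lams_fresh, ddof=1))
        df0 = self.two_treatment_records(seed=55)
        rng = np.random.default_rng(9)
        boot = _bootstrap_mpm_lambdas(
            df0[df0["treatment"] == "control"].reset_index(drop=True),
            self.SPEC, 400, rng, 100,
        )
        sd_boot = float(np.std(boot, ddof=1))
        assert abs(sd_boot - sd_fresh) < 0.25 * sd_fresh


class TestIPMBootstrapFastPath:
    def test_array_path_matches_reference_path(self):
        """The vectorized bootstrap internals must reproduce the
        fit_vital_rates -> build_ipm_kernel -> dominant_lambda chain."""
        from fpdemog.demography import _ipm_lambda_from_arrays, size_bounds

        df = ipm_records(500, TRUE_COEFFS, seed=11)
        bounds = size_bounds(df)
        spec = SpeciesModelSpec(kind="IPM", meshpoints=120, bounds=bounds)
        coeffs = fit_vital_rates(df)
        ref = dominant_lambda(build_ipm_kernel(coeffs, bounds, 120))
        obs = df[df["size_t"].notna()]
        rec = df[df["size_t"].isna() & df["size_t1"].notna()]
        m = 120
        h = (bounds[1] - bounds[0]) / m
        mesh = bounds[0] + h * (np.arange(m) + 0.5)
        fast = _ipm_lambda_from_arrays(
            obs["size_t"].to_numpy(float), obs["surv"].to_numpy(float),
            obs["size_t1"].to_numpy(float), obs["repro_count"].to_numpy(float),
            rec["size_t1"].to_numpy(float), spec, mesh, h,
        )
        assert fast == pytest.approx(ref, abs=1e-10)

    def test_ipm_bootstrap_deterministic(self):
        df = ipm_records(300, TRUE_COEFFS, seed=12)
        df2 = df.copy()
        df2["treatment"] = "removal"
        both = pd.concat([df, df2], ignore_index=True)
        spec = SpeciesModelSpec(kind="IPM", meshpoints=60)
        a = bootstrap_effect_sizes(both, spec, n_boot=20, seed=1)
        b = bootstrap_effect_sizes(both, spec, n_boot=20, seed=1)
        np.testing.assert_array_equal(a, b)
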