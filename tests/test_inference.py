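import numpy as np
import pytest

from heatcase.ccmodel import FitResult, add_modifier_interaction, fit_ccpoisson
from heatcase.crossbasis import CrossBasisSpec, contrast_vector
from heatcase.inference import (
    PooledFit,
    edf,
    find_mmtp,
    marginal_curves,
    modifier_percentile_values,
    pool_rubin,
    rr_curve,
    run_main_analysis,
)


def fake_fit(coef, vcov):
    coef = np.atleast_1d(np.asarray(coef, dtype=float))
    vcov = np.atleast_2d(np.asarray(vcov, dtype=float))
    return FitResult(coef=coef, vcov=vcov, dispersion=1.0, deviance=0.0,
                     n_strata=1, n_obs=1, loglik=0.0, vcov_unscaled=vcov)


class TestPoolRubin:
    def test_identical_fits_have_zero_between_variance(self):
        fits = [fake_fit([1.0, 2.0], np.eye(2))] * 5
        pooled = pool_rubin(fits)
        assert np.allclose(pooled.between, 0.0)
        assert np.allclose(pooled.total, pooled.within)

    def test_closed_form_scalar_case(self):
        # m=2, coefs {0, 2}, each variance 1: pooled coef 1,
        # T = 1 + 1.5 * B with B = 2 -> 4
        fits = [fake_fit([0.0], [[1.0]]), fake_fit([2.0], [[1.0]])]
        pooled = pool_rubin(fits)
        assert pooled.coef[0] == pytest.approx(1.0)
        assert pooled.between[0, 0] == pytest.approx(2.0)
        assert pooled.total[0, 0] == pytest.approx(4.0)

    def test_matches_elementwise_matrix_oracle(self):
        rng = np.random.default_rng(0)
        m, p = 7, 3
        coefs = rng.normal(size=(m, p))
        vcovs = []
        for _ in range(m):
            a = rng.normal(size=(p, p))
            vcovs.append(a @ a.T)
        pooled = pool_rubin([fake_fit(c, v) for c, v in zip(coefs, vcovs)])
        w_oracle = sum(vcovs) / m
        b_oracle = np.cov(coefs.T, ddof=1)
        t_oracle = w_oracle + (1 + 1 / m) * b_oracle
        assert np.allclose(pooled.within, w_oracle)
        assert np.allclose(pooled.between, b_oracle)
        assert np.allclose(pooled.total, t_oracle)

    def test_total_never_below_within(self):
        rng = np.random.default_rng(1)
        fits = [fake_fit(rng.normal(size=4), np.eye(4)) for _ in range(6)]
        pooled = pool_rubin(fits)
        eig = np.linalg.eigvalsh(pooled.total - pooled.within)
        assert eig.min() >= -1e-12

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            pool_rubin([fake_fit([1.0], [[1.0]]), fake_fit([1.0, 2.0], np.eye(2))])


def coef_for_curve(spec, fn):
    """Least-squares coefficients whose cumulative contrast reproduces fn."""
    grid = np.linspace(0.5, 99.5, 199)
    C = np.array([contrast_vector(spec, p, 1.0) for p in grid])
    target = np.array([fn(p) for p in grid]) - fn(1.0)
    coef, *_ = np.linalg.lstsq(C, target, rcond=None)
    return coef


class TestFindMMTP:
    spec = CrossBasisSpec()

    def test_monotone_curve_puts_mmtp_at_1(self):
        coef = coef_for_curve(self.spec, lambda p: 0.002 * p)
        pooled = PooledFit(coef, np.eye(12), np.zeros((12, 12)), np.eye(12), 1)
        assert find_mmtp(pooled, self.spec) == 1.0

    def test_planted_minimum_at_40_recovered(self):
        coef = coef_for_curve(self.spec, lambda p: 0.0005 * (p - 40.0) ** 2)
        pooled = PooledFit(coef, np.eye(12), np.zeros((12, 12)), np.eye(12), 1)
        assert find_mmtp(pooled, self.spec) == pytest.approx(40.0, abs=2.0)

    def test_reference_invariance(self):
        rng = np.random.default_rng(2)
        coef = rng.normal(scale=0.01, size=12)
        pooled = PooledFit(coef, np.eye(12), np.zeros((12, 12)), np.eye(12), 1)
        grids = [np.arange(1.0, 100.0), np.arange(99.0, 0.0, -1.0)[::-1]]
        assert find_mmtp(pooled, self.spec, grid=grids[0]) == find_mmtp(
            pooled, self.spec, grid=grids[1]
        )


class TestRRCurve:
    spec = CrossBasisSpec()

    def test_rr_is_one_at_center_with_degenerate_ci(self):
        rng = np.random.default_rng(3)
        coef = rng.normal(scale=0.01, size=12)
        pooled = PooledFit(coef, np.eye(12) * 1e-4, np.zeros((12, 12)),
                           np.eye(12) * 1e-4, 1)
        curve = rr_curve(pooled, self.spec, center=37.0)
        row = curve.at(37.0)
        assert row["rr"] == 1.0 and row["lo"] == 1.0 and row["hi"] == 1.0

    def test_zero_coefficients_give_unit_curve(self):
        pooled = PooledFit(np.zeros(12), np.eye(12), np.zeros((12, 12)),
                           np.eye(12), 1)
        curve = rr_curve(pooled, self.spec, center=50.0)
        assert np.allclose(curve.table["rr"], 1.0)

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(4)
        coef = rng.normal(scale=0.02, size=12)
        v = np.eye(12) * 1e-4
        pooled = PooledFit(coef, v, np.zeros((12, 12)), v, 1)
        curve = rr_curve(pooled, self.spec, center=10.0)
        assert (curve.table["lo"] <= curve.table["rr"]).all()
        assert (curve.table["rr"] <= curve.table["hi"]).all()


class TestEDF:
    def _design(self, n_days=400, deaths_per_day=10, seed=5):
        from heatcase.exposure import panel_to_percentiles
        from heatcase.synthetic_data import (
            GeneratorConfig,
            gen_city_temperatures,
        )
        from heatcase.ccmodel import build_panel_design
        import pandas as pd

        cfg = GeneratorConfig(n_cities=1, n_days=n_days, seed=seed)
        panel = panel_to_percentiles(gen_city_temperatures(cfg))
        for s in panel.values():
            s.data["deaths"] = deaths_per_day
        return build_panel_design(panel, CrossBasisSpec())

    def test_zero_beta_gives_zero_edf_and_degenerate_ci(self):
        design = self._design()
        z = np.zeros((12, 12))
        pooled = PooledFit(np.zeros(12), z, z, z, 1)
        res = edf(pooled, design, mmtp=1.0, seed=0, n_sim=50)
        assert res.edf == 0.0 and res.lower == 0.0 and res.upper == 0.0

    def test_hand_computed_toy_value(self):
        # 100 days at 10 deaths/day, 5 hot days with constant eta = log(1.2)
        # across the lag window: EDF = 5*10*(1 - 1/1.2) / 1000 = 0.833...%
        import pandas as pd
        from heatcase.ccmodel import PanelDesign

        spec = CrossBasisSpec()
        n = 100
        expo = np.full(n, 50.0)
        expo[:5] = 96.0  # five days above the 95th percentile
        X = np.zeros((n, 12))
        y = np.full(n, 10.0)
        design = PanelDesign(
            y=y, X=X, strata=np.zeros(n, dtype=int),
            city_ids=np.repeat("a", n),
            dates=pd.date_range("2018-01-01", periods=n, freq="D"),
            exposure=expo, spec=spec,
        )
        eta = np.log(1.2)
        # encode eta directly through the design rows: the reference row
        # plus a rescaled contrast direction gives (x_t - ref) @ coef = eta
        cvec = contrast_vector(spec, 96.0, 50.0)
        ref_row = np.tile(spec.exposure_basis(np.array([50.0]))[0], spec.d_l)
        design.X[:] = ref_row
        design.X[:5] += cvec * eta / (cvec @ cvec)
        pooled = PooledFit(cvec, np.zeros((12, 12)),
                           np.zeros((12, 12)), np.zeros((12, 12)), 1)
        res = edf(pooled, design, mmtp=50.0, threshold=95.0, seed=0, n_sim=10)
        assert res.edf == pytest.approx(5 * 10 * (1 - 1 / 1.2) / 1000, rel=1e-6)

    def test_matches_day_by_day_loop_oracle(self):
        design = self._design(seed=6)
        rng = np.random.default_rng(7)
        coef = rng.normal(scale=2e-5, size=12)
        v = np.eye(12) * 1e-12
        pooled = PooledFit(coef, v, np.zeros((12, 12)), v, 1)
        mmtp = 30.0
        res = edf(pooled, design, mmtp=mmtp, threshold=95.0, seed=1, n_sim=20)
        # brute-force loop
        spec = design.spec
        ref = np.tile(spec.exposure_basis(np.array([mmtp]))[0], spec.d_l)
        num, den = 0.0, 0.0
        for t in range(len(design.y)):
            eta = (design.X[t] - ref) @ coef
            den += design.y[t]
            if design.exposure[t] >= 95.0:
                num += design.y[t] * (1.0 - np.exp(-eta))
        assert res.edf == pytest.approx(num / den, abs=1e-12)

    def test_invariant_to_count_rescaling(self):
        design = self._design(seed=8)
        rng = np.random.default_rng(9)
        coef = rng.normal(scale=2e-5, size=12)
        v = np.eye(12) * 1e-12
        pooled = PooledFit(coef, v, np.zeros((12, 12)), v, 1)
        r1 = edf(pooled, design, mmtp=20.0, seed=2, n_sim=10)
        design.y = design.y * 7.0
        r2 = edf(pooled, design, mmtp=20.0, seed=2, n_sim=10)
        assert r1.edf == pytest.approx(r2.edf, rel=1e-12)

    def test_bad_threshold_rejected(self):
        design = self._design(seed=10)
        pooled = PooledFit(np.zeros(12), np.eye(12), np.zeros((12, 12)),
                           np.eye(12), 1)
        with pytest.raises(ValueError, match="threshold"):
            edf(pooled, design, mmtp=1.0, threshold=100.0)


class TestMarginalCurves:
    spec = CrossBasisSpec()

    def _interaction_pooled(self, b_main, b_int, scale=1e-4):
        coef = np.concatenate([b_main, b_int])
        v = np.eye(24) * scale
        return PooledFit(coef, v, np.zeros((24, 24)), v, 1)

    def test_zero_interaction_gives_identical_curves(self):
        rng = np.random.default_rng(11)
        b_main = rng.normal(scale=0.01, size=12)
        pooled = self._interaction_pooled(b_main, np.zeros(12))
        lo, hi = marginal_curves(pooled, self.spec, center=1.0,
                                 z_values=(0.2, 1.8))
        assert np.allclose(lo.table["rr"], hi.table["rr"])

    def test_positive_interaction_orders_curves(self):
        # planted positive interaction: higher modifier -> steeper heat slope
        b_main = coef_for_curve(self.spec, lambda p: 0.001 * p)
        b_int = coef_for_curve(self.spec, lambda p: 0.0015 * p)
        pooled = self._interaction_pooled(b_main, b_int)
        lo, hi = marginal_curves(pooled, self.spec, center=1.0,
                                 z_values=(0.0, 2.0))
        upper = lo.table["pctl"] > 10
        assert (hi.table.loc[upper, "rr"].to_numpy()
                >= lo.table.loc[upper, "rr"].to_numpy()).all()

    def test_missing_interaction_block_rejected(self):
        pooled = PooledFit(np.zeros(12), np.eye(12), np.zeros((12, 12)),
                           np.eye(12), 1)
        with pytest.raises(ValueError, match="interaction"):
            marginal_curves(pooled, self.spec, center=1.0, z_values=(0.0, 1.0))

    def test_modifier_percentile_helper(self):
        vals = np.arange(101.0)
        lo, hi = modifier_percentile_values(vals)
        assert lo == pytest.approx(10.0) and hi == pytest.approx(90.0)


class TestPooledInference:
    def test_large_m_identical_data_converges_to_single_fit(self, small_panel):
        from heatcase.ccmodel import build_panel_design

        panel, _, _ = small_panel
        design = build_panel_design(panel, CrossBasisSpec())
        fit = fit_ccpoisson(design.y, design.X, design.strata)
        pooled = pool_rubin([fit] * 40)
        assert np.allclose(pooled.coef, fit.coef)
        assert np.allclose(pooled.total, fit.vcov)

    def test_main_analysis_recovers_strong_planted_curve(self, small_panel):
        panel, truth, _ = small_panel
        res = run_main_analysis(panel)
        # strong effect, dense counts: estimate within CI half-widths of truth
        for p in (50.0, 95.0):
            row = res.curve.at(p)
            true_rr = np.exp(truth.curve(p) - truth.curve(res.mmtp))
            assert row["lo"] * 0.95 < true_rr < row["hi"] * 1.05
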