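"""Causal estimators against independent oracles and their invariances."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from mrlipid.instruments import LDMatrix
from mrlipid.mr_core import (
    MREstimateError,
    egger,
    egger_correlated,
    ivw,
    ivw_correlated,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)
from mrlipid.synthetic_data import simulate_harmonized

from conftest import random_instrument_frame


class TestWaldRatio:
    def test_hand_computed_example(self):
        r = wald_ratio(
            {"rsid": "rs1", "beta_exposure": 0.5, "se_exposure": 0.0,
             "beta_outcome": 0.05, "se_outcome": 0.02}
        )
        assert r.ratio == pytest.approx(0.10)
        assert r.se_first == pytest.approx(0.04)

    def test_null_outcome_gives_zero_ratio_positive_se(self):
        r = wald_ratio(
            {"rsid": "rs1", "beta_exposure": 0.5, "se_exposure": 0.01,
             "beta_outcome": 0.0, "se_outcome": 0.02}
        )
        assert r.ratio == 0.0 and r.se_first > 0 and r.se_second > 0

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(MREstimateError, match="non-informative"):
            wald_ratio(
                {"rsid": "rs1", "beta_exposure": 0.0, "se_exposure": 0.01,
                 "beta_outcome": 0.1, "se_outcome": 0.02}
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_second_order_se_matches_expansion(self, seed):
        rng = np.random.default_rng(seed)
        bx, sx, by, sy = rng.uniform(0.01, 0.5, 4)
        r = wald_ratio(
            {"rsid": "rs1", "beta_exposure": bx, "se_exposure": sx,
             "beta_outcome": by, "se_outcome": sy}
        )
        expected = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
        assert r.se_second == pytest.approx(expected, abs=1e-14)
        assert r.se_second >= r.se_first


class TestIVW:
    @pytest.mark.parametrize("seed", range(5))
    def test_equals_zero_intercept_wls_oracle(self, seed):
        rng = np.random.default_rng(seed)
        inst = random_instrument_frame(rng)
        est = ivw(inst, effects_model="fixed")
        fit = sm.WLS(
            inst["beta_outcome"], inst[["beta_exposure"]],
            weights=inst["se_outcome"] ** -2.0,
        ).fit()
        assert est.beta_hat == pytest.approx(fit.params.iloc[0], abs=1e-10)

    def test_single_variant_reduces_to_wald_ratio(self):
        rng = np.random.default_rng(1)
        inst = random_instrument_frame(rng, j=1)
        with pytest.warns(UserWarning, match="Wald"):
            est = ivw(inst)
        r = wald_ratio(inst.iloc[0])
        assert est.beta_hat == pytest.approx(r.ratio)
        assert est.se_hat == pytest.approx(r.se_first)

    def test_random_effects_never_narrower_than_fixed(self):
        rng = np.random.default_rng(2)
        inst = random_instrument_frame(rng, 20)
        fixed = ivw(inst, effects_model="fixed")
        rand = ivw(inst, effects_model="multiplicative_random")
        assert rand.se_hat >= fixed.se_hat
        assert rand.scale_factor >= 1.0
        assert rand.beta_hat == pytest.approx(fixed.beta_hat)


class TestEgger:
    @pytest.mark.parametrize("seed", range(5))
    def test_equals_wls_with_intercept_oracle(self, seed):
        rng = np.random.default_rng(seed)
        inst = random_instrument_frame(rng)
        est = egger(inst)
        X = sm.add_constant(inst["beta_exposure"])
        fit = sm.WLS(inst["beta_outcome"], X, weights=inst["se_outcome"] ** -2.0).fit()
        assert est.intercept == pytest.approx(fit.params.iloc[0], abs=1e-10)
        assert est.beta_hat == pytest.approx(fit.params.iloc[1], abs=1e-10)

    def test_exact_line_recovered_with_phi_one(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        inst = pd.DataFrame(
            {
                "rsid": [f"rs{i}" for i in range(4)],
                "beta_exposure": bx,
                "se_exposure": 0.001,
                "beta_outcome": 0.03 + 0.5 * bx,
                "se_outcome": 0.01,
                "exclusion_flag": "none",
            }
        )
        est = egger(inst)
        assert est.intercept == pytest.approx(0.03, abs=1e-12)
        assert est.beta_hat == pytest.approx(0.5, abs=1e-12)
        assert est.scale_factor == 1.0

    def test_requires_increasing_allele_orientation(self):
        rng = np.random.default_rng(3)
        inst = random_instrument_frame(rng)
        inst.loc[0, "beta_exposure"] *= -1
        with pytest.raises(MREstimateError, match="orient"):
            egger(inst)

    def test_fewer_than_three_variants_rejected(self):
        inst = random_instrument_frame(np.random.default_rng(0), j=2)
        with pytest.raises(MREstimateError, match="at least 3"):
            egger(inst)

    def test_directional_pleiotropy_recovered(self):
        """Planted mean pleiotropy appears in the intercept, not the slope."""
        ints, slopes = [], []
        for r in range(200):
            h, _ = simulate_harmonized(
                30, 0.0, pleiotropy_mode="directional",
                pleiotropy_mean=0.05, pleiotropy_scale=0.02, seed=1000 + r,
            )
            est = egger(h)
            ints.append(est.intercept)
            slopes.append(est.beta_hat)
        assert np.mean(ints) == pytest.approx(0.05, abs=0.005)
        assert abs(np.mean(slopes)) < 3 * np.std(slopes) / np.sqrt(len(slopes)) + 0.02


class TestWeightedMedian:
    def test_uniform_weights_odd_count_midpoint(self):
        inst = pd.DataFrame(
            {
                "rsid": ["a", "b", "c"],
                "beta_exposure": [1.0, 1.0, 1.0],
                "se_exposure": [0.01] * 3,
                "beta_outcome": [1.0, 2.0, 9.0],
                "se_outcome": [1.0, 1.0, 1.0],
                "exclusion_flag": "none",
            }
        )
        est = weighted_median(inst, n_boot=100, seed=0)
        assert est.beta_hat == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_weighted_cdf_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        inst = random_instrument_frame(rng, 15)
        est = weighted_median(inst, n_boot=100, seed=0)
        ratios = (inst["beta_outcome"] / inst["beta_exposure"]).to_numpy()
        weights = (inst["beta_exposure"].abs() / inst["se_outcome"]).to_numpy() ** 2
        order = np.argsort(ratios)
        r, w = ratios[order], weights[order] / weights.sum()
        s = np.cumsum(w) - w / 2
        # brute-force scan of the weighted empirical CDF for the 50% point
        k = int(np.searchsorted(s, 0.5))
        if k == 0:
            expected = r[0]
        elif k == len(r):
            expected = r[-1]
        else:
            f = (0.5 - s[k - 1]) / (s[k] - s[k - 1])
            expected = r[k - 1] + f * (r[k] - r[k - 1])
        assert est.beta_hat == pytest.approx(expected, abs=1e-10)

    def test_breakdown_resists_minority_invalid_instruments(self):
        theta = float(np.log(1.1))
        wm, naive = [], []
        for r in range(50):
            h, _ = simulate_harmonized(
                30, theta, pleiotropy_mode="outlier",
                n_outliers=4, outlier_sigma=30.0, seed=2000 + r,
            )
            wm.append(weighted_median(h, n_boot=100, seed=r).beta_hat)
            naive.append(ivw(h).beta_hat)
        assert abs(np.mean(wm) - theta) < abs(np.mean(naive) - theta) / 3
        assert np.mean(wm) == pytest.approx(theta, abs=0.03)

    def test_seed_is_mandatory(self):
        inst = random_instrument_frame(np.random.default_rng(0))
        with pytest.raises(MREstimateError, match="seed"):
            weighted_median(inst)


class TestCorrelatedEstimators:
    @staticmethod
    def frame_and_ld(rng, j=10, decay=0.5):
        inst = random_instrument_frame(rng, j)
        idx = np.arange(j)
        rho = decay ** np.abs(idx[:, None] - idx[None, :])
        return inst, LDMatrix(list(inst["rsid"]), rho)

    def test_identity_ld_reduces_to_ivw_and_egger(self):
        rng = np.random.default_rng(4)
        inst = random_instrument_frame(rng, 12)
        ld = LDMatrix(list(inst["rsid"]), np.eye(12))
        assert ivw_correlated(inst, ld).beta_hat == pytest.approx(
            ivw(inst).beta_hat, abs=1e-9
        )
        ec, eu = egger_correlated(inst, ld), egger(inst)
        assert ec.beta_hat == pytest.approx(eu.beta_hat, abs=1e-9)
        assert ec.intercept == pytest.approx(eu.intercept, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_gls_matches_explicit_inverse_oracle(self, seed):
        rng = np.random.default_rng(seed)
        inst, ld = self.frame_and_ld(rng)
        sy = inst["se_outcome"].to_numpy()
        omega = np.outer(sy, sy) * ld.values
        omega += 1e-10 * np.mean(np.diag(omega)) * np.eye(len(sy))  # same conditioning
        oi = np.linalg.inv(omega)
        x = inst["beta_exposure"].to_numpy()
        y = inst["beta_outcome"].to_numpy()
        expected_ivw = (x @ oi @ y) / (x @ oi @ x)
        est = ivw_correlated(inst, ld)
        assert est.beta_hat == pytest.approx(expected_ivw, abs=1e-8)
        X = np.column_stack([np.ones(len(x)), x])
        expected_egger = np.linalg.solve(X.T @ oi @ X, X.T @ oi @ y)
        este = egger_correlated(inst, ld)
        assert este.intercept == pytest.approx(expected_egger[0], abs=1e-8)
        assert este.beta_hat == pytest.approx(expected_egger[1], abs=1e-8)

    def test_near_duplicate_variant_not_double_counted(self):
        rng = np.random.default_rng(7)
        inst = random_instrument_frame(rng, 5)
        single = ivw_correlated(
            inst, LDMatrix(list(inst["rsid"]), np.eye(5))
        )
        dup = pd.concat([inst, inst.iloc[[0]].assign(rsid="rs_dup")], ignore_index=True)
        rho = np.eye(6)
        rho[0, 5] = rho[5, 0] = 1 - 1e-9
        est = ivw_correlated(dup, LDMatrix(list(dup["rsid"]), rho))
        assert est.beta_hat == pytest.approx(single.beta_hat, rel=0.05)
        assert est.se_hat == pytest.approx(single.se_hat, rel=0.25)

    def test_exact_line_recovered_under_any_omega(self):
        rng = np.random.default_rng(8)
        inst, ld = self.frame_and_ld(rng, j=6, decay=0.7)
        inst["beta_outcome"] = 0.02 + 0.4 * inst["beta_exposure"]
        est = egger_correlated(inst, ld)
        assert est.intercept == pytest.approx(0.02, abs=1e-8)
        assert est.beta_hat == pytest.approx(0.4, abs=1e-8)


class TestScaleEquivariance:
    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_estimates_divide_by_exposure_rescaling(self, c):
        rng = np.random.default_rng(11)
        inst = random_instrument_frame(rng, 12)
        scaled = inst.assign(
            beta_exposure=inst["beta_exposure"] * c,
            se_exposure=inst["se_exposure"] * c,
        )
        assert ivw(scaled).beta_hat == pytest.approx(ivw(inst).beta_hat / c)
        assert egger(scaled).beta_hat == pytest.approx(egger(inst).beta_hat / c)
        wm0 = weighted_median(inst, n_boot=100, seed=0).beta_hat
        wm1 = weighted_median(scaled, n_boot=100, seed=0).beta_hat
        assert wm1 == pytest.approx(wm0 / c)


class TestOddsRatioScale:
    def test_zero_beta_is_unit_or(self):
        est = ivw(random_instrument_frame(np.random.default_rng(0)))
        est.beta_hat = 0.0
        assert to_odds_ratio(est)["odds_ratio"] == 1.0

    def test_presentation_rounding(self):
        rng = np.random.default_rng(1)
        inst = random_instrument_frame(rng)
        est = ivw(inst)
        est.beta_hat, est.ci_low, est.ci_high = 0.0862, 0.0862 - 1.96 * 0.037, 0.0862 + 1.96 * 0.037
        d = to_odds_ratio(est, decimals=2)
        assert (d["odds_ratio"], d["ci_low"], d["ci_high"]) == (1.09, 1.01, 1.17)

    def test_ci_brackets_or(self):
        for seed in range(5):
            est = ivw(random_instrument_frame(np.random.default_rng(seed)))
            d = to_odds_ratio(est)
            assert d["ci_low"] <= d["odds_ratio"] <= d["ci_high"]
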