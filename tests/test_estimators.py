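"""Causal estimators: Wald ratio, IVW, MR-Egger, medians, modes."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from tsmr import (
    IVW,
    MREgger,
    ModeEstimator,
    WeightedMedian,
    ivw,
    mode_estimators,
    mr_egger,
    wald_ratio,
    weighted_median,
)
from tsmr.estimators import _weighted_median
from tsmr.exceptions import (
    InsufficientInstrumentsError,
    UndefinedRatioError,
    ValidationError,
)

from conftest import make_harmonized


def _random_instance(rng, k=None):
    k = k or int(rng.integers(3, 12))
    bx = rng.uniform(0.02, 0.3, k) * rng.choice([-1, 1], k)
    sx = rng.uniform(0.002, 0.02, k)
    sy = rng.uniform(0.01, 0.1, k)
    by = 0.3 * bx + rng.normal(0, sy)
    return make_harmonized(bx, sx, by, sy)


class TestWaldRatio:
    def test_direct_division(self):
        est = wald_ratio(make_harmonized([0.1], [0.01], [0.05], [0.02]))
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)

    def test_zero_outcome_effect(self):
        assert wald_ratio(
            make_harmonized([0.1], [0.01], [0.0], [0.02])).beta == 0.0

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(make_harmonized([0.0], [0.01], [0.1], [0.02]))

    def test_delta_method_se_matches_monte_carlo(self, rng):
        """SE equals the sd of the simulated ratio within 5%."""
        bx, sy = 0.1, 0.02
        draws = (0.05 + sy * rng.standard_normal(100_000)) / bx
        est = wald_ratio(make_harmonized([bx], [0.001], [0.05], [sy]))
        assert est.se == pytest.approx(np.std(draws), rel=0.05)


class TestIVW:
    def test_hand_evaluated_two_snp_example(self):
        h = make_harmonized([0.1, 0.2], [0.01, 0.01], [0.02, 0.08],
                            [0.1, 0.1])
        est = ivw(h, model="fixed")
        assert est.beta == pytest.approx(0.36)
        assert est.se == pytest.approx(5 ** -0.5)

    def test_consensus_data(self):
        h = make_harmonized([0.1, 0.2, 0.3], [0.01] * 3,
                            [0.05, 0.10, 0.15], [0.02] * 3)
        m = IVW(model="auto").fit(h)
        assert m.beta_ == pytest.approx(0.5)
        assert m.q_ == pytest.approx(0.0, abs=1e-20)
        assert m.model_used_ == "fixed"

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_origin_wls_oracle(self, seed):
        """IVW is weighted least squares through the origin (1e-12)."""
        rng = np.random.default_rng(seed)
        h = _random_instance(rng)
        bx, by = h["beta_exp"].to_numpy(), h["beta_out"].to_numpy()
        sy = h["se_out"].to_numpy()
        sw = np.sqrt(1.0 / sy**2)
        slope = np.linalg.lstsq(
            (sw * bx)[:, None], sw * by, rcond=None)[0][0]
        assert ivw(h, model="fixed").beta == pytest.approx(slope, abs=1e-12)

    def test_point_estimate_model_invariant(self, rng):
        h = _random_instance(rng)
        fixed = ivw(h, model="fixed")
        random = ivw(h, model="random")
        assert fixed.beta == random.beta
        assert random.se >= fixed.se

    def test_needs_two_snps(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(make_harmonized([0.1], [0.01], [0.05], [0.02]))

    def test_rejects_zero_exposure_beta(self):
        with pytest.raises(UndefinedRatioError):
            ivw(make_harmonized([0.1, 0.0], [0.01] * 2, [0.05, 0.1],
                                [0.02] * 2))


class TestMREgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        h = make_harmonized(bx, [0.01] * 4, 0.01 + 0.3 * bx, [0.02] * 4)
        m = MREgger().fit(h)
        assert m.intercept_ == pytest.approx(0.01, abs=1e-12)
        assert m.beta_ == pytest.approx(0.3, abs=1e-12)
        assert m.rss_ == pytest.approx(0.0, abs=1e-18)

    def test_matches_statsmodels_wls(self, rng):
        """Slope/intercept/SEs agree with the statsmodels WLS oracle when
        the residual dispersion exceeds 1 (the floor is inactive)."""
        k = 15
        bx = rng.uniform(0.05, 0.3, k)
        sy = rng.uniform(0.01, 0.03, k)
        by = 0.02 + 0.4 * bx + rng.normal(0, 5 * sy)  # overdispersed
        h = make_harmonized(bx, [0.005] * k, by, sy)
        m = MREgger().fit(h)
        ref = sm.WLS(by, sm.add_constant(bx), weights=1 / sy**2).fit()
        assert m.scale_ > 1
        assert m.intercept_ == pytest.approx(ref.params[0], abs=1e-10)
        assert m.beta_ == pytest.approx(ref.params[1], abs=1e-10)
        assert m.intercept_se_ == pytest.approx(ref.bse[0], rel=1e-10)
        assert m.se_ == pytest.approx(ref.bse[1], rel=1e-10)

    def test_orientation_negates_negative_exposure_effects(self, rng):
        h = _random_instance(rng, k=10)
        flipped = h.copy()
        flipped["beta_exp"] = -flipped["beta_exp"]
        flipped["beta_out"] = -flipped["beta_out"]
        a, b = mr_egger(h), mr_egger(flipped)
        assert a.beta == pytest.approx(b.beta, abs=1e-14)
        assert a.intercept == pytest.approx(b.intercept, abs=1e-14)

    def test_singular_design_rejected(self):
        h = make_harmonized([0.1, 0.1, -0.1], [0.01] * 3,
                            [0.05, 0.06, -0.05], [0.02] * 3)
        with pytest.raises(ValidationError, match="singular"):
            mr_egger(h)

    def test_balanced_pleiotropy_intercept_type_i(self):
        """With a true zero intercept, the intercept test rejects ~5%."""
        rej = 0
        reps = 200
        for i in range(reps):
            rng = np.random.default_rng(10_000 + i)
            k = 25
            bx = rng.uniform(0.05, 0.3, k)
            sy = np.full(k, 0.02)
            by = 0.3 * bx + rng.normal(0, sy)
            m = MREgger().fit(make_harmonized(bx, [0.005] * k, by, sy))
            rej += m.intercept_pval_ < 0.05
        assert 0.01 <= rej / reps <= 0.11


class TestWeightedMedian:
    def test_middle_order_statistic(self):
        assert _weighted_median(np.array([0.1, 0.2, 0.3]),
                                np.ones(3)) == pytest.approx(0.2)

    def test_two_point_interpolation(self):
        # s = (0.25, 0.75); interpolating at 0.5 gives the midpoint
        assert _weighted_median(np.array([0.0, 1.0]),
                                np.ones(2)) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_interpolation(self, seed):
        rng = np.random.default_rng(seed)
        ratio = rng.normal(size=9)
        w = rng.uniform(0.1, 2.0, size=9)
        # independent oracle: explicit bracket search + linear interpolation
        order = np.argsort(ratio)
        r, ww = ratio[order], w[order]
        s = (np.cumsum(ww) - ww / 2) / ww.sum()
        expected = None
        for j in range(len(r) - 1):
            if s[j] <= 0.5 <= s[j + 1]:
                frac = (0.5 - s[j]) / (s[j + 1] - s[j])
                expected = r[j] + frac * (r[j + 1] - r[j])
                break
        if expected is None:
            expected = r[0] if 0.5 < s[0] else r[-1]
        assert _weighted_median(ratio, w) == pytest.approx(expected,
                                                           abs=1e-14)

    def test_equal_weights_equal_simple_median(self, rng):
        h = _random_instance(rng, k=9)
        est = weighted_median(h, weights="equal", n_boot=50, seed=1)
        ratio = h["beta_out"] / h["beta_exp"]
        assert est.beta == pytest.approx(np.median(ratio))
        assert est.method == "simple_median"

    def test_estimate_within_ratio_range(self, rng):
        h = _random_instance(rng)
        est = weighted_median(h, n_boot=50, seed=1)
        ratio = h["beta_out"] / h["beta_exp"]
        assert ratio.min() - 1e-12 <= est.beta <= ratio.max() + 1e-12

    def test_bootstrap_seeded(self, rng):
        h = _random_instance(rng)
        a = weighted_median(h, n_boot=200, seed=5)
        b = weighted_median(h, n_boot=200, seed=5)
        assert a.se == b.se


class TestModes:
    def test_degenerate_consensus(self):
        bx = np.array([0.1, 0.2, 0.4])
        h = make_harmonized(bx, [0.01] * 3, 0.4 * bx, [0.02] * 3)
        m = ModeEstimator(kind="simple", n_boot=10, seed=0).fit(h)
        assert m.beta_ == pytest.approx(0.4)
        assert m.se_ == 0.0 and m.degenerate_

    def test_mode_tracks_majority_not_mean(self):
        h = make_harmonized(np.ones(4), [0.01] * 4,
                            [0.1, 0.1, 0.1, 0.9], [0.1] * 4)
        est = mode_estimators(h, kind="simple", n_boot=50, seed=1)
        assert abs(est.beta - 0.1) < 0.05  # mean would be 0.3

    @pytest.mark.parametrize("kind", ["simple", "weighted"])
    def test_matches_density_grid_brute_force(self, rng, kind):
        h = _random_instance(rng, k=12)
        est = mode_estimators(h, kind=kind, n_boot=10, seed=1)
        ratio = (h["beta_out"] / h["beta_exp"]).to_numpy()
        from tsmr.estimators import _mode_bandwidth

        hbw = _mode_bandwidth(ratio, 1.0)
        w = (np.ones_like(ratio) if kind == "simple"
             else (h["beta_exp"] ** 2 / h["se_out"] ** 2).to_numpy())
        w = w / w.sum()
        grid = np.linspace(ratio.min() - 3 * hbw, ratio.max() + 3 * hbw,
                           20_001)
        dens = (w * np.exp(-0.5 * ((grid[:, None] - ratio) / hbw) ** 2)).sum(
            axis=1)
        assert est.beta == pytest.approx(grid[np.argmax(dens)],
                                         abs=2 * (grid[1] - grid[0]))

    def test_majority_valid_instruments_recovered(self):
        """30% invalid instruments: the mode stays near the true slope."""
        ok = 0
        reps = 20
        for i in range(reps):
            rng = np.random.default_rng(100 + i)
            k, theta = 30, 0.3
            bx = rng.uniform(0.05, 0.15, k)
            sy = np.full(k, 0.02)
            alpha = np.where(np.arange(k) < 9, 0.05, 0.0)
            by = theta * bx + alpha + rng.normal(0, sy)
            m = ModeEstimator(kind="weighted", n_boot=200, seed=i).fit(
                make_harmonized(bx, [0.004] * k, by, sy))
            ok += abs(m.beta_ - theta) <= 2 * m.se_
        assert ok >= 0.9 * reps


class TestEquivariance:
    @pytest.mark.parametrize("fit", [
        lambda h: ivw(h, model="fixed").beta,
        lambda h: mr_egger(h).beta,
        lambda h: weighted_median(h, n_boot=10, seed=0).beta,
        lambda h: mode_estimators(h, kind="weighted", n_boot=10, seed=0).beta,
    ], ids=["ivw", "egger", "wmedian", "wmode"])
    def test_sign_equivariance(self, rng, fit):
        h = _random_instance(rng, k=8)
        both = h.copy()
        both["beta_exp"] = -both["beta_exp"]
        both["beta_out"] = -both["beta_out"]
        only_out = h.copy()
        only_out["beta_out"] = -only_out["beta_out"]
        base = fit(h)
        assert fit(both) == pytest.approx(base, abs=1e-9)
        assert fit(only_out) == pytest.approx(-base, abs=1e-9)

    def test_egger_constrained_to_origin_is_ivw(self, rng):
        """The zero-intercept limit of the Egger regression is IVW."""
        h = _random_instance(rng)
        bx = h["beta_exp"].to_numpy()
        by = h["beta_out"].to_numpy()
        sy = h["se_out"].to_numpy()
        sw = 1.0 / sy
        slope = np.linalg.lstsq((sw * bx)[:, None], sw * by, rcond=None)[0][0]
        assert ivw(h, model="fixed").beta == pytest.approx(slope, abs=1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_ivw_oracle_property(seed):
    """Property form of the IVW/WLS identity over random instances."""
    rng = np.random.default_rng(seed)
    h = _random_instance(rng)
    bx, by = h["beta_exp"].to_numpy(), h["beta_out"].to_numpy()
    sw = 1.0 / h["se_out"].to_numpy()
    slope = np.linalg.lstsq((sw * bx)[:, None], sw * by, rcond=None)[0][0]
    assert abs(ivw(h, model="fixed").beta - slope) < 1e-12


def test_or_scale_consistent(rng):
    est = ivw(_random_instance(rng))
    assert est.odds_ratio == pytest.approx(np.exp(est.beta), rel=1e-12)
    assert est.ci_low < est.ci_high
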