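import math

import numpy as np
import pytest
import statsmodels.api as sm

from conftest import make_pair, make_ratios, random_ratios
from mrkit.estimators import (
    EstimationError,
    cochran_q,
    egger,
    estimate_all,
    ivw,
    penalized_weighted_median,
    ratio_estimates,
    weighted_median,
)


class TestRatioEstimates:
    @pytest.mark.parametrize(
        "bx,by,sy,theta,s",
        [
            (0.1, 0.05, 0.02, 0.5, 0.2),
            (1.0, 0.0, 0.3, 0.0, 0.3),
            (-0.2, 0.1, 0.04, -0.5, 0.2),
        ],
    )
    def test_wald_ratio_arithmetic(self, bx, by, sy, theta, s):
        (r,) = ratio_estimates([make_pair(bx=bx, by=by, sy=sy)])
        assert r.theta == pytest.approx(theta)
        assert r.s == pytest.approx(s)
        assert r.weight == pytest.approx(s**-2)

    def test_zero_exposure_effect_excluded(self):
        rs = ratio_estimates([make_pair(vid="a", bx=0.0), make_pair(vid="b")])
        assert [r.variant_id for r in rs] == ["b"]


class TestIvw:
    def test_single_instrument_returns_its_ratio(self):
        (est,) = [ivw(make_ratios([0.5], [0.2]))]
        assert est.beta_hat == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)

    def test_equal_weight_symmetry(self):
        est = ivw(make_ratios([0.4, 0.6], [0.1, 0.1]))
        assert est.beta_hat == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1 / math.sqrt(2))

    def test_equals_zero_intercept_wls(self, rng):
        """IVW must equal the slope of origin-constrained WLS of outcome
        betas on exposure betas weighted by se_outcome^-2."""
        for _ in range(20):
            j = int(rng.integers(2, 12))
            bx = rng.normal(0.1, 0.05, j)
            bx[np.abs(bx) < 1e-3] = 0.05
            by = rng.normal(0.02, 0.05, j)
            sy = rng.uniform(0.01, 0.1, j)
            pairs = [
                make_pair(vid=f"v{i}", bx=bx[i], by=by[i], sy=sy[i]) for i in range(j)
            ]
            est = ivw(ratio_estimates(pairs))
            wls = sm.WLS(by, bx[:, None], weights=sy**-2.0).fit()
            assert est.beta_hat == pytest.approx(wls.params[0], abs=1e-10)

    def test_random_effects_never_shrinks_se(self, rng):
        ratios = random_ratios(rng, 8)
        assert ivw(ratios, random_effects=True).se >= ivw(ratios).se

    def test_empty_input_rejected(self):
        with pytest.raises(EstimationError):
            ivw([])

    def test_ci_brackets_estimate(self, rng):
        est = ivw(random_ratios(rng))
        assert est.ci_low < est.beta_hat < est.ci_high
        assert est.ci_high - est.beta_hat == pytest.approx(1.959964 * est.se)
        orv, lo, hi = est.or_scale
        assert orv == pytest.approx(math.exp(est.beta_hat))


class TestCochranQ:
    def test_homogeneous_is_zero(self):
        q, df, per = cochran_q(make_ratios([0.3, 0.3, 0.3], [0.1, 0.2, 0.3]), 0.3)
        assert q == 0.0 and df == 2 and per == [0.0, 0.0, 0.0]

    def test_single_instrument_degenerate(self):
        q, df, _ = cochran_q(make_ratios([0.4], [0.1]), 0.4)
        assert q == 0.0 and df == 0

    def test_hand_computed_value(self):
        # weights 100 each, deviations 0.5 -> Q = 2 * 100 * 0.25 = 50
        q, _, per = cochran_q(make_ratios([0.0, 1.0], [0.1, 0.1]), 0.5)
        assert q == pytest.approx(50.0)
        assert per == [pytest.approx(25.0), pytest.approx(25.0)]


def _grid_oracle(theta, s, weights=None, passes=4, width=None):
    """Weighted-median oracle: locate the 0.5 crossing of the piecewise
    linear weighted-CDF midpoint function by iteratively refined grid
    search (independent of the searchsorted implementation)."""
    theta = np.asarray(theta, float)
    w = np.asarray(weights if weights is not None else 1.0 / np.asarray(s) ** 2, float)
    order = np.argsort(theta, kind="stable")
    th, wn = theta[order], w[order] / w.sum()
    p = np.cumsum(wn) - wn / 2.0
    lo, hi = th[0], th[-1]
    if p[0] > 0.5:
        return float(th[0])
    if p[-1] < 0.5:
        return float(th[-1])
    best = None
    for _ in range(passes):
        grid = np.linspace(lo, hi, 4001)
        vals = np.interp(grid, th, p)
        i = int(np.argmin(np.abs(vals - 0.5)))
        best = grid[i]
        span = (hi - lo) / 4000 * 4
        lo, hi = best - span, best + span
    return float(best)


class TestWeightedMedian:
    def test_symmetric_three_instruments(self):
        est = weighted_median(make_ratios([0.1, 0.5, 0.9], [0.1, 0.1, 0.1]), n_boot=50, seed=1)
        assert est.beta_hat == pytest.approx(0.5)

    def test_two_instruments_rejected(self):
        with pytest.raises(EstimationError):
            weighted_median(make_ratios([0.1, 0.2], [0.1, 0.1]))

    def test_even_split_interpolates_midpoint(self):
        est = weighted_median(
            make_ratios([0.0, 0.0, 1.0, 1.0], [0.1] * 4), n_boot=50, seed=1
        )
        assert est.beta_hat == pytest.approx(0.5)

    def test_equal_weights_match_plain_median_odd_j(self, rng):
        for _ in range(20):
            theta = rng.normal(size=5)
            est = weighted_median(make_ratios(theta, [0.1] * 5), n_boot=2, seed=0)
            assert est.beta_hat == pytest.approx(float(np.median(theta)))

    def test_matches_grid_oracle(self, rng):
        for _ in range(200):
            j = int(rng.integers(3, 15))
            theta = rng.normal(0.2, 1.0, j)
            s = rng.uniform(0.05, 0.5, j)
            est = weighted_median(make_ratios(theta, s), n_boot=2, seed=0)
            assert est.beta_hat == pytest.approx(_grid_oracle(theta, s), abs=1e-6)

    def test_bootstrap_is_seeded(self, rng):
        ratios = random_ratios(rng)
        a = weighted_median(ratios, n_boot=200, seed=7)
        b = weighted_median(ratios, n_boot=200, seed=7)
        assert a.se == b.se and a.beta_hat == b.beta_hat


class TestPenalizedWeightedMedian:
    def test_identical_ratios_leave_weights_unchanged(self):
        ratios = make_ratios([0.3] * 5, [0.1, 0.2, 0.1, 0.3, 0.2])
        pen = penalized_weighted_median(ratios, n_boot=50, seed=3)
        unpen = weighted_median(ratios, n_boot=50, seed=3)
        assert pen.beta_hat == unpen.beta_hat

    def test_large_penalty_scale_recovers_weighted_median(self, rng):
        # limit behaviour: min(1, scale * p) -> 1 whenever the chi-square
        # tail p is representable (> 0), so the penalty vanishes
        ratios = make_ratios(rng.normal(0.2, 0.3, 8), rng.uniform(0.2, 0.5, 8))
        pen = penalized_weighted_median(ratios, n_boot=2, seed=0, penalty_scale=1e300)
        unpen = weighted_median(ratios, n_boot=2, seed=0)
        assert pen.beta_hat == pytest.approx(unpen.beta_hat)

    def test_outlier_downweighted(self, rng):
        """19 concordant instruments near 0.2 plus one precise gross outlier:
        the penalized estimate must sit strictly closer to 0.2."""
        theta = list(rng.normal(0.2, 0.02, 19)) + [5.0]
        s = [0.1] * 19 + [0.02]  # outlier carries high weight
        ratios = make_ratios(theta, s)
        pen = penalized_weighted_median(ratios, n_boot=2, seed=0)
        unpen = weighted_median(ratios, n_boot=2, seed=0)
        assert abs(pen.beta_hat - 0.2) < abs(unpen.beta_hat - 0.2)


class TestEgger:
    def test_recovers_exact_line(self):
        bx = np.array([0.05, 0.08, 0.1, 0.12, 0.2])
        pairs = [
            make_pair(vid=f"v{i}", bx=b, by=0.01 + 0.3 * b, sy=0.02)
            for i, b in enumerate(bx)
        ]
        res = egger(pairs)
        assert res.intercept == pytest.approx(0.01, abs=1e-12)
        assert res.slope.beta_hat == pytest.approx(0.3, abs=1e-12)

    def test_singular_design_rejected(self):
        pairs = [make_pair(vid=f"v{i}", bx=0.1, by=0.05) for i in range(3)]
        with pytest.raises(EstimationError, match="singular"):
            egger(pairs)

    def test_too_few_instruments_rejected(self):
        with pytest.raises(EstimationError):
            egger([make_pair(vid="a"), make_pair(vid="b")])

    def test_orientation_makes_exposure_effects_nonnegative(self):
        """Flipping the signs of both betas of any instrument leaves the
        Egger fit unchanged (instruments are re-oriented internally)."""
        rng = np.random.default_rng(5)
        bx = rng.normal(0.1, 0.05, 6)
        by = 0.02 + 0.25 * bx + rng.normal(0, 0.01, 6)
        pairs = [make_pair(vid=f"v{i}", bx=bx[i], by=by[i]) for i in range(6)]
        flipped = [
            make_pair(vid=f"v{i}", bx=-bx[i], by=-by[i]) if i % 2 else pairs[i]
            for i in range(6)
        ]
        a, b = egger(pairs), egger(flipped)
        assert a.intercept == pytest.approx(b.intercept)
        assert a.slope.beta_hat == pytest.approx(b.slope.beta_hat)

    def test_matches_statsmodels_wls_coefficients(self, rng):
        bx = np.abs(rng.normal(0.1, 0.05, 8)) + 0.01
        by = rng.normal(0.02, 0.03, 8)
        sy = rng.uniform(0.01, 0.05, 8)
        pairs = [
            make_pair(vid=f"v{i}", bx=bx[i], by=by[i], sy=sy[i]) for i in range(8)
        ]
        res = egger(pairs)
        fit = sm.WLS(by, sm.add_constant(bx), weights=sy**-2.0).fit()
        assert res.intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert res.slope.beta_hat == pytest.approx(fit.params[1], abs=1e-10)


ESTIMATORS = {
    "ivw": lambda r: ivw(r).beta_hat,
    "weighted_median": lambda r: weighted_median(r, n_boot=2, seed=0).beta_hat,
    "penalized": lambda r: penalized_weighted_median(r, n_boot=2, seed=0).beta_hat,
}


class TestSharedInvariants:
    @pytest.mark.parametrize("name", list(ESTIMATORS))
    def test_input_order_invariance(self, name, rng):
        ratios = random_ratios(rng, 9)
        perm = [ratios[i] for i in rng.permutation(9)]
        assert ESTIMATORS[name](perm) == pytest.approx(ESTIMATORS[name](ratios))

    @pytest.mark.parametrize("name", list(ESTIMATORS))
    def test_scale_equivariance(self, name, rng):
        """Multiplying outcome betas and SEs by c scales every estimate by c."""
        j, c = 9, 3.7
        bx = np.abs(rng.normal(0.1, 0.05, j)) + 0.01
        by = rng.normal(0.02, 0.05, j)
        sy = rng.uniform(0.01, 0.1, j)
        base = ratio_estimates(
            [make_pair(vid=f"v{i}", bx=bx[i], by=by[i], sy=sy[i]) for i in range(j)]
        )
        scaled = ratio_estimates(
            [make_pair(vid=f"v{i}", bx=bx[i], by=c * by[i], sy=c * sy[i]) for i in range(j)]
        )
        assert ESTIMATORS[name](scaled) == pytest.approx(c * ESTIMATORS[name](base))

    def test_sign_flip_invariance(self, rng):
        """Simultaneously negating (beta_exposure, beta_outcome) of any
        instrument leaves every estimator unchanged."""
        j = 9
        bx = rng.normal(0.1, 0.05, j)
        by = rng.normal(0.02, 0.05, j)
        sy = rng.uniform(0.01, 0.1, j)
        pairs = [make_pair(vid=f"v{i}", bx=bx[i], by=by[i], sy=sy[i]) for i in range(j)]
        flipped = [
            make_pair(vid=f"v{i}", bx=-bx[i], by=-by[i], sy=sy[i])
            if i in (1, 4, 7)
            else pairs[i]
            for i in range(j)
        ]
        for name, fn in ESTIMATORS.items():
            assert fn(ratio_estimates(flipped)) == pytest.approx(
                fn(ratio_estimates(pairs))
            ), name


class TestEstimateAll:
    def test_single_instrument_only_ivw_defined(self):
        table = estimate_all([make_pair()], n_boot=10, seed=0)
        assert table.estimates["ivw"] is not None
        assert table.estimates["weighted_median"] is None
        assert table.estimates["egger_slope"] is None
        df = table.to_frame(outcome="x")
        assert (df.loc[df.method != "ivw", "status"] == "not_estimable").all()

    def test_full_table_has_four_methods(self, rng):
        bx = np.abs(rng.normal(0.1, 0.03, 6)) + 0.02
        by = 0.14 * bx + rng.normal(0, 0.01, 6)
        pairs = [make_pair(vid=f"v{i}", bx=bx[i], by=by[i]) for i in range(6)]
        table = estimate_all(pairs, n_boot=20, seed=0)
        assert all(table.estimates[m] is not None for m in table.estimates)
        assert table.q_df == 5
        assert table.egger is not None
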