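"""Estimator unit tests against independent oracles, plus invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mr2sample.errors import (
    DegenerateInstrumentsError,
    InsufficientInstrumentsError,
    UndefinedRatioError,
)
from mr2sample.estimators import (
    cochran_q,
    egger,
    ivw,
    max_likelihood,
    ratio_estimates,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)
from mr2sample.summary_io import HarmonizedPair


def wls_origin_oracle(bx, by, sy):
    """Explicit-summation weighted LS through the origin (pure python)."""
    num = sum(b * y / s**2 for b, y, s in zip(bx, by, sy))
    den = sum(b * b / s**2 for b, s in zip(bx, sy))
    return num / den, den**-0.5


def wls_intercept_oracle(bx, by, sy):
    """Explicit-summation weighted LS with intercept (pure python)."""
    w = [1.0 / s**2 for s in sy]
    sw = sum(w)
    mx = sum(wi * b for wi, b in zip(w, bx)) / sw
    my = sum(wi * y for wi, y in zip(w, by)) / sw
    sxx = sum(wi * (b - mx) ** 2 for wi, b in zip(w, bx))
    sxy = sum(wi * (b - mx) * (y - my) for wi, b, y in zip(w, bx, by))
    slope = sxy / sxx
    intercept = my - slope * mx
    return slope, intercept


class TestWaldRatio:
    def test_hand_arithmetic_on_tag_snp_inputs(self):
        """-0.056/0.285 and 0.017/0.285, computed by hand."""
        pair = HarmonizedPair("rs356182", 0.285, 0.012, -0.056, 0.017)
        est = wald_ratio(pair, se_order="first")
        assert est.theta == pytest.approx(-0.056 / 0.285, abs=1e-12)
        assert est.theta == pytest.approx(-0.19649, abs=5e-6)
        assert est.se == pytest.approx(0.017 / 0.285, abs=1e-12)
        assert est.se == pytest.approx(0.05965, abs=5e-6)

    def test_second_order_se_adds_exposure_term(self):
        pair = HarmonizedPair("rs1", 0.285, 0.012, -0.056, 0.017)
        first = wald_ratio(pair, se_order="first").se
        second = wald_ratio(pair, se_order="second").se
        expected = math.sqrt(
            0.017**2 / 0.285**2 + 0.056**2 * 0.012**2 / 0.285**4
        )
        assert second == pytest.approx(expected, abs=1e-12)
        assert second >= first

    def test_zero_numerator_gives_null_or(self):
        est = wald_ratio(HarmonizedPair("rs1", 0.2, 0.01, 0.0, 0.02))
        assert est.theta == 0.0 and est.or_ == 1.0

    def test_identity_ratio(self):
        est = wald_ratio(HarmonizedPair("rs1", 0.2, 0.01, 0.2, 0.01))
        assert est.theta == pytest.approx(1.0)

    def test_zero_exposure_effect_is_error(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(HarmonizedPair("rs1", 0.0, 0.01, 0.1, 0.02))


class TestIVW:
    def test_matches_explicit_summation_oracle(self, random_dataset):
        for seed in range(5):
            ds = random_dataset(5, seed=seed)
            theta, se = wls_origin_oracle(ds.beta_x, ds.beta_y, ds.se_y)
            est = ivw(ds, model="fixed")
            assert est.theta == pytest.approx(theta, abs=1e-10)
            assert est.se == pytest.approx(se, abs=1e-10)

    def test_single_variant_reduces_to_first_order_wald(self, make_dataset):
        ds = make_dataset([0.285], [0.012], [-0.056], [0.017])
        est = ivw(ds, model="fixed")
        wald = wald_ratio(ds[0], se_order="first")
        assert est.theta == pytest.approx(wald.theta, abs=1e-12)
        assert est.se == pytest.approx(wald.se, abs=1e-12)

    def test_default_model_resolution(self, random_dataset):
        assert ivw(random_dataset(3), model="default").model == "fixed"
        assert ivw(random_dataset(4), model="default").model == "random"

    def test_fixed_and_random_share_theta_random_se_not_smaller(self, random_dataset):
        ds = random_dataset(10, seed=3)
        fixed, random = ivw(ds, "fixed"), ivw(ds, "random")
        assert fixed.theta == random.theta
        assert random.se >= fixed.se

    def test_noiseless_recovery_of_theta(self, make_dataset):
        rng = np.random.default_rng(1)
        bx = rng.uniform(0.05, 0.3, 10)
        ds = make_dataset(bx, [1e-6] * 10, 0.3 * bx, [0.02] * 10)
        assert ivw(ds, "fixed").theta == pytest.approx(0.3, abs=1e-9)

    def test_all_zero_exposure_is_degenerate(self, make_dataset):
        ds = make_dataset([0.0, 0.0], [0.01, 0.01], [0.1, 0.1], [0.02, 0.02])
        with pytest.raises(DegenerateInstrumentsError):
            ivw(ds)


class TestEgger:
    def test_matches_explicit_summation_oracle(self, random_dataset):
        for seed in range(5):
            ds = random_dataset(5, seed=seed)
            slope, intercept = wls_intercept_oracle(ds.beta_x, ds.beta_y, ds.se_y)
            got_slope, got_int = egger(ds)
            assert got_slope.theta == pytest.approx(slope, abs=1e-10)
            assert got_int.theta == pytest.approx(intercept, abs=1e-10)

    def test_exact_proportional_data_gives_zero_intercept(self, make_dataset):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        ds = make_dataset(bx, [0.01] * 4, 0.7 * bx, [0.02] * 4)
        slope, intercept = egger(ds)
        assert slope.theta == pytest.approx(0.7, abs=1e-10)
        assert intercept.theta == pytest.approx(0.0, abs=1e-10)

    def test_constant_directional_pleiotropy_lands_in_intercept(self, make_dataset):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        ds = make_dataset(bx, [0.01] * 4, 0.5 * bx + 0.05, [0.02] * 4)
        slope, intercept = egger(ds)
        assert intercept.theta == pytest.approx(0.05, abs=1e-10)
        assert slope.theta == pytest.approx(0.5, abs=1e-10)

    def test_requires_three_variants_and_spread(self, make_dataset):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_dataset([0.1, 0.2], [0.01] * 2, [0.0, 0.0], [0.02] * 2))
        flat = make_dataset([0.1, 0.1, -0.1], [0.01] * 3, [0.0, 0.0, 0.0], [0.02] * 3)
        with pytest.raises(DegenerateInstrumentsError):
            egger(flat)


class TestWeightedMedian:
    def test_equal_weights_interpolates_central_ratio(self, make_dataset):
        # ratios {1, 2, 3} with equal weights: midpoint p2 = 0.5 exactly
        ds = make_dataset([0.1] * 3, [1e-4] * 3, [0.1, 0.2, 0.3], [0.01] * 3)
        est = weighted_median(ds, n_boot=100, seed=1, se_order="first")
        assert est.theta == pytest.approx(2.0, abs=1e-10)

    def test_identical_ratios_return_common_ratio(self, make_dataset):
        bx = np.array([0.1, 0.2, 0.4])
        ds = make_dataset(bx, [0.01] * 3, 0.25 * bx, [0.01, 0.03, 0.02])
        est = weighted_median(ds, n_boot=100, seed=1)
        assert est.theta == pytest.approx(0.25, abs=1e-12)

    def test_point_estimate_independent_of_seed(self, random_dataset):
        ds = random_dataset(8, seed=5)
        a = weighted_median(ds, n_boot=100, seed=1)
        b = weighted_median(ds, n_boot=100, seed=99)
        assert a.theta == b.theta
        assert a.se != b.se  # bootstrap stream differs

    def test_se_reproducible_for_fixed_seed(self, random_dataset):
        ds = random_dataset(8, seed=5)
        assert (
            weighted_median(ds, n_boot=150, seed=7).se
            == weighted_median(ds, n_boot=150, seed=7).se
        )

    def test_needs_three_variants(self, make_dataset):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(
                make_dataset([0.1, 0.2], [0.01] * 2, [0.0, 0.0], [0.02] * 2)
            )


class TestMaxLikelihood:
    def test_negligible_exposure_noise_matches_fixed_ivw(self, pd_ad, make_dataset):
        ds = make_dataset(pd_ad.beta_x, pd_ad.se_x * 1e-6, pd_ad.beta_y, pd_ad.se_y)
        ml = max_likelihood(ds)
        fixed = ivw(ds, model="fixed")
        assert ml.theta == pytest.approx(fixed.theta, abs=5e-5)
        assert round(ml.theta, 4) == round(fixed.theta, 4)

    def test_single_noiseless_instrument_equals_wald(self, make_dataset):
        ds = make_dataset([0.285], [1e-9], [-0.056], [0.017])
        ml = max_likelihood(ds)
        assert ml.theta == pytest.approx(-0.056 / 0.285, abs=1e-6)
        assert ml.converged

    def test_se_at_least_fixed_ivw_se(self, pd_ad):
        # profiling out the latent effects can only lose information
        assert max_likelihood(pd_ad).se >= ivw(pd_ad, model="fixed").se - 1e-12


class TestCochranQ:
    def test_proportional_data_has_zero_q(self, make_dataset):
        bx = np.array([0.1, 0.2, 0.3])
        ds = make_dataset(bx, [0.01] * 3, 0.4 * bx, [0.02] * 3)
        q, df, p = cochran_q(ds)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 2 and p == pytest.approx(1.0)

    def test_matches_term_by_term_summation_oracle(self, pd_ad):
        q, df, _ = cochran_q(pd_ad)
        theta, _ = wls_origin_oracle(pd_ad.beta_x, pd_ad.beta_y, pd_ad.se_y)
        oracle = sum(
            (b / s) ** 2 * (y / b - theta) ** 2
            for b, y, s in zip(pd_ad.beta_x, pd_ad.beta_y, pd_ad.se_y)
        )
        assert q == pytest.approx(oracle, rel=1e-10)
        assert df == 38

    def test_duplicating_every_variant_doubles_q(self, random_dataset, make_dataset):
        ds = random_dataset(6, seed=2)
        q1, _, _ = cochran_q(ds)
        dup = make_dataset(
            np.r_[ds.beta_x, ds.beta_x],
            np.r_[ds.se_x, ds.se_x],
            np.r_[ds.beta_y, ds.beta_y],
            np.r_[ds.se_y, ds.se_y],
        )
        q2, _, _ = cochran_q(dup)
        assert q2 == pytest.approx(2 * q1, rel=1e-10)


class TestToOddsRatio:
    def test_null_effect_centers_at_one(self):
        or_, lo, hi = to_odds_ratio(0.0, 0.1)
        assert or_ == 1.0 and lo < 1.0 < hi

    def test_back_calculates_printed_snca_interval(self):
        # OR 1.33 (1.30-1.36): se recovered from the printed CI width
        se = (math.log(1.36) - math.log(1.30)) / (2 * 1.96)
        or_, lo, hi = to_odds_ratio(math.log(1.33), se)
        assert (round(lo, 2), round(hi, 2)) == (1.30, 1.36)

    def test_back_calculated_ivw_interval(self):
        # inputs back-calculated from a printed interval, so ~1e-3 slack
        or_, lo, hi = to_odds_ratio(-0.0856, 0.0814)
        assert lo == pytest.approx(0.782, abs=2e-3)
        assert hi == pytest.approx(1.076, abs=2e-3)


# ---------------------------------------------------------------------------
# invariant suite (shared across estimators)


def _build(bx, sx, by, sy):
    from mr2sample.summary_io import HarmonizedDataset

    return HarmonizedDataset(
        [
            HarmonizedPair(f"rs{i + 1}", float(bx[i]), float(sx[i]), float(by[i]), float(sy[i]))
            for i in range(len(bx))
        ]
    )


def _run_all(ds):
    return {
        "ivw": ivw(ds, model="fixed"),
        "egger": egger(ds)[0],
        "wmed": weighted_median(ds, n_boot=100, seed=3),
        "ml": max_likelihood(ds),
    }


@pytest.fixture(scope="module")
def base():
    rng = np.random.default_rng(11)
    from mr2sample.summary_io import HarmonizedDataset, HarmonizedPair

    bx = rng.uniform(0.05, 0.4, 8)
    pairs = [
        HarmonizedPair(
            f"rs{i}", float(bx[i]), float(rng.uniform(0.005, 0.03)),
            float(0.2 * bx[i] + rng.normal(0, 0.01)), float(rng.uniform(0.01, 0.05)),
        )
        for i in range(8)
    ]
    return HarmonizedDataset(pairs)


class TestInvariants:
    def test_permutation_invariance(self, base):
        from mr2sample.summary_io import HarmonizedDataset

        shuffled = HarmonizedDataset(list(reversed(base.pairs)))
        for k, est in _run_all(base).items():
            other = _run_all(shuffled)[k]
            assert est.theta == pytest.approx(other.theta, abs=1e-9), k

    def test_orientation_invariance_single_flip(self, base, make_dataset):
        bx, by = base.beta_x.copy(), base.beta_y.copy()
        bx[2], by[2] = -bx[2], -by[2]
        flipped = make_dataset(bx, base.se_x, by, base.se_y)
        for k, est in _run_all(base).items():
            other = _run_all(flipped)[k]
            assert est.theta == pytest.approx(other.theta, abs=1e-7), k
            if k != "wmed":  # bootstrap draws are seed-, not orientation-, tied
                assert est.se == pytest.approx(other.se, rel=1e-6), k

    def test_sign_equivariance(self, base, make_dataset):
        negated = make_dataset(base.beta_x, base.se_x, -base.beta_y, base.se_y)
        for k, est in _run_all(base).items():
            other = _run_all(negated)[k]
            assert other.theta == pytest.approx(-est.theta, abs=1e-7), k
            if k != "wmed":
                assert other.pval == pytest.approx(est.pval, rel=1e-6), k

    def test_scale_equivariance(self, base, make_dataset):
        c = 2.5
        scaled = make_dataset(c * base.beta_x, c * base.se_x, base.beta_y, base.se_y)
        for k, est in _run_all(base).items():
            other = _run_all(scaled)[k]
            assert other.theta == pytest.approx(est.theta / c, abs=1e-7), k

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(0.02, 0.5),
                st.floats(0.005, 0.05),
                st.floats(-0.2, 0.2),
                st.floats(0.01, 0.08),
            ),
            min_size=2,
            max_size=6,
        )
    )
    def test_random_se_never_below_fixed(self, data):
        bx, sx, by, sy = map(list, zip(*data))
        ds = _build(bx, sx, by, sy)
        assert ivw(ds, "random").se >= ivw(ds, "fixed").se

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.floats(0.02, 0.5), st.floats(-0.2, 0.2), st.floats(0.01, 0.08)),
            min_size=1,
            max_size=5,
        )
    )
    def test_ivw_matches_oracle_everywhere(self, data):
        bx, by, sy = map(list, zip(*data))
        ds = _build(bx, [0.01] * len(bx), by, sy)
        theta, se = wls_origin_oracle(bx, by, sy)
        est = ivw(ds, model="fixed")
        assert est.theta == pytest.approx(theta, abs=1e-10)

    def test_second_order_ratio_se_dominates_first(self, pd_ad):
        for r in ratio_estimates(pd_ad):
            assert r.se_second_order >= r.se_first_order
            assert r.weight > 0
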