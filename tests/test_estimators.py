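"""IVW, weighted-median and MR-Egger estimators against independent oracles."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from mrkit import HarmonizedSet, egger, ivw, weighted_median
from mrkit.estimators import WeightedMedianEstimator, weighted_median_point


def wls_origin_oracle(bx, by, sey):
    """Independent WLS-through-origin fit (statsmodels)."""
    fit = sm.WLS(by, bx[:, None], weights=1 / sey**2).fit()
    return float(fit.params[0]), float(fit.bse[0] / np.sqrt(fit.scale))


def wls_intercept_oracle(bx, by, sey):
    """Independent WLS-with-intercept fit; returns params and unscaled SEs."""
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1 / sey**2).fit()
    se_unscaled = fit.bse / np.sqrt(fit.scale)
    return fit.params, se_unscaled, float(fit.scale * fit.df_resid)


def test_ivw_perfectly_proportional(proportional_set):
    est = ivw(proportional_set)
    fixed = ivw(proportional_set, mode="fixed")
    assert est.beta == pytest.approx(0.2, abs=1e-14)
    assert est.se == pytest.approx(fixed.se)  # Q = 0 -> mRE collapses to fixed


def test_single_snp_wald_ratio():
    data = HarmonizedSet(
        pair_label="wald",
        snp_id=np.array(["rs1"], dtype=object),
        beta_x=[0.1],
        se_x=[0.01],
        beta_y=[0.05],
        se_y=[0.01],
        eaf_x=[0.3],
    )
    est = ivw(data)
    assert est.method == "ivw_fixed"
    assert est.beta == pytest.approx(0.5)
    assert est.se == pytest.approx(0.1)  # first-order delta: se_y / |beta_x|


@pytest.mark.parametrize("seed", range(10))
def test_ivw_matches_wls_oracle(random_set_factory, seed):
    data = random_set_factory(j=10, seed=seed)
    beta_oracle, se_oracle = wls_origin_oracle(data.beta_x, data.beta_y, data.se_y)
    fixed = ivw(data, mode="fixed")
    assert fixed.beta == pytest.approx(beta_oracle, abs=1e-10)
    assert fixed.se == pytest.approx(se_oracle, abs=1e-10)
    mre = ivw(data)
    assert mre.beta == pytest.approx(beta_oracle, abs=1e-10)
    assert mre.se >= fixed.se - 1e-15  # overdispersion floored at 1


@pytest.mark.parametrize("seed", range(5))
def test_ivw_fixed_equals_weighted_mean_of_wald_ratios(random_set_factory, seed):
    """Algebraic identity: origin-forced WLS = IV-weighted mean of ratios."""
    data = random_set_factory(j=12, seed=seed)
    ratios = data.beta_y / data.beta_x
    weights = data.beta_x**2 / data.se_y**2
    expected = np.sum(weights * ratios) / np.sum(weights)
    assert ivw(data, mode="fixed").beta == pytest.approx(expected, abs=1e-12)


def test_weighted_median_symmetric_three_snps():
    data = HarmonizedSet(
        pair_label="wm3",
        snp_id=np.array(["a", "b", "c"], dtype=object),
        beta_x=[0.1, 0.1, 0.1],
        se_x=[0.01] * 3,
        beta_y=[0.01, 0.02, 0.03],  # ratios 0.1, 0.2, 0.3, equal weights
        se_y=[0.01] * 3,
        eaf_x=[0.3] * 3,
    )
    est = weighted_median(data, n_boot=200, seed=1)
    assert est.beta == pytest.approx(0.2)


def test_weighted_median_degenerate_limit():
    """All ratios identical: estimate exact; bootstrap SE -> 0 as se_y -> 0."""
    ses = []
    for sy in (1e-3, 1e-5):
        data = HarmonizedSet(
            pair_label="wm-lim",
            snp_id=np.array(["a", "b", "c", "d"], dtype=object),
            beta_x=[0.1, 0.2, 0.3, 0.4],
            se_x=[1e-8] * 4,
            beta_y=[0.02, 0.04, 0.06, 0.08],
            se_y=[sy] * 4,
            eaf_x=[0.3] * 4,
        )
        est = weighted_median(data, n_boot=300, seed=3)
        assert est.beta == pytest.approx(0.2, abs=1e-6)
        ses.append(est.se)
    assert ses[1] < ses[0] / 10


def test_weighted_median_equals_sample_median_equal_weights():
    rng = np.random.default_rng(5)
    for j in (5, 7, 11):
        ratios = rng.normal(0.2, 0.1, j)
        assert weighted_median_point(ratios, np.ones(j)) == pytest.approx(
            np.median(ratios), abs=1e-12
        )


def test_weighted_median_robust_to_invalid_minority():
    """6 valid SNPs (ratio ~ 0.2) vs 5 invalid (ratio ~ 1.0); the valid
    majority of weight pins the estimate near 0.2."""
    rng = np.random.default_rng(11)
    bx = np.full(11, 0.1)  # equal weights: valid SNPs carry 6/11 of weight
    sy = np.full(11, 0.004)
    by = np.where(np.arange(11) < 6, 0.2 * bx, 1.0 * bx) + rng.normal(0, 0.002, 11)
    data = HarmonizedSet(
        pair_label="wm-rob",
        snp_id=np.array([f"rs{i}" for i in range(11)], dtype=object),
        beta_x=bx,
        se_x=np.full(11, 0.005),
        beta_y=by,
        se_y=sy,
        eaf_x=np.full(11, 0.3),
    )
    est = weighted_median(data, n_boot=500, seed=7)
    assert est.ci_low <= 0.2 <= est.ci_high
    assert abs(est.beta - 0.2) < 0.1


def test_weighted_median_requires_seed(random_set_factory):
    data = random_set_factory(j=5, seed=0)
    with pytest.raises(ValueError, match="random_state"):
        WeightedMedianEstimator().fit(data.beta_x, data.beta_y, data.se_x, data.se_y)


def test_weighted_median_zero_beta_x_names_snp(random_set_factory):
    data = random_set_factory(j=5, seed=0)
    data.beta_x[2] = 0.0
    with pytest.raises(ZeroDivisionError, match="index 2"):
        weighted_median(data, seed=1)


def test_egger_proportional_data(proportional_set):
    slope, intercept = egger(proportional_set)
    assert slope.beta == pytest.approx(0.2, abs=1e-12)
    assert intercept.beta == pytest.approx(0.0, abs=1e-12)


def test_egger_recovers_intercept_and_slope():
    """Data generated as beta_y = 0.01 + 0.2 beta_x with tiny noise."""
    rng = np.random.default_rng(3)
    bx = rng.uniform(0.05, 0.3, 20)
    by = 0.01 + 0.2 * bx + rng.normal(0, 1e-5, 20)
    data = HarmonizedSet(
        pair_label="egger",
        snp_id=np.array([f"rs{i}" for i in range(20)], dtype=object),
        beta_x=bx,
        se_x=np.full(20, 0.01),
        beta_y=by,
        se_y=rng.uniform(0.005, 0.02, 20),
        eaf_x=np.full(20, 0.3),
    )
    slope, intercept = egger(data)
    params, se_unscaled, _ = wls_intercept_oracle(bx, by, data.se_y)
    assert slope.beta == pytest.approx(float(params[1]), abs=1e-10)
    assert intercept.beta == pytest.approx(float(params[0]), abs=1e-10)
    assert slope.beta == pytest.approx(0.2, abs=1e-3)
    assert intercept.beta == pytest.approx(0.01, abs=1e-4)


@pytest.mark.parametrize("seed", range(5))
def test_egger_matches_wls_oracle_with_overdispersion(random_set_factory, seed):
    data = random_set_factory(j=10, seed=seed, noise=0.02)
    sign = np.where(data.beta_x < 0, -1.0, 1.0)
    x, y = data.beta_x * sign, data.beta_y * sign
    params, se_unscaled, rss_w = wls_intercept_oracle(x, y, data.se_y)
    phi = max(1.0, rss_w / (10 - 2))
    slope, intercept = egger(data)
    assert slope.beta == pytest.approx(float(params[1]), abs=1e-10)
    assert slope.se == pytest.approx(float(se_unscaled[1]) * np.sqrt(phi), abs=1e-10)
    assert intercept.se == pytest.approx(float(se_unscaled[0]) * np.sqrt(phi), abs=1e-10)


def test_egger_orientation_invariance(random_set_factory):
    data = random_set_factory(j=8, seed=2)
    slope1, intercept1 = egger(data)
    flipped = data.subset(np.arange(8))
    flipped.beta_x[3] *= -1
    flipped.beta_y[3] *= -1
    slope2, intercept2 = egger(flipped)
    assert slope2.beta == pytest.approx(slope1.beta, abs=1e-14)
    assert intercept2.beta == pytest.approx(intercept1.beta, abs=1e-14)


def _random_set(j=9, seed=4, theta=0.2, noise=0.01):
    rng = np.random.default_rng(seed)
    bx = rng.uniform(0.03, 0.2, j) * rng.choice([-1, 1], j)
    return HarmonizedSet(
        pair_label=f"rand-{seed}",
        snp_id=np.array([f"rs{i}" for i in range(j)], dtype=object),
        beta_x=bx,
        se_x=rng.uniform(0.002, 0.01, j),
        beta_y=theta * bx + rng.normal(0, noise, j),
        se_y=rng.uniform(0.005, 0.02, j),
        eaf_x=rng.uniform(0.05, 0.45, j),
    )


@given(perm_seed=st.integers(0, 1000))
@settings(max_examples=20, deadline=None)
def test_estimators_invariant_to_snp_order(perm_seed):
    data = _random_set(j=9, seed=4)
    perm = np.random.default_rng(perm_seed).permutation(9)
    shuffled = data.subset(perm)
    assert ivw(shuffled).beta == pytest.approx(ivw(data).beta, abs=1e-12)
    assert egger(shuffled)[0].beta == pytest.approx(egger(data)[0].beta, abs=1e-12)
    wm_a = weighted_median(data, n_boot=50, seed=9).beta
    wm_b = weighted_median(shuffled, n_boot=50, seed=9).beta
    # the point estimate (not the bootstrap draw) is order-invariant
    assert weighted_median_point(
        shuffled.beta_y / shuffled.beta_x, shuffled.beta_x**2 / shuffled.se_y**2
    ) == pytest.approx(
        weighted_median_point(data.beta_y / data.beta_x, data.beta_x**2 / data.se_y**2),
        abs=1e-12,
    )
    assert wm_a == pytest.approx(wm_b, abs=1e-12)


def test_preconditions():
    tiny = HarmonizedSet(
        pair_label="tiny",
        snp_id=np.array(["a", "b"], dtype=object),
        beta_x=[0.1, 0.2],
        se_x=[0.01, 0.01],
        beta_y=[0.02, 0.04],
        se_y=[0.01, 0.01],
        eaf_x=[0.3, 0.3],
    )
    with pytest.raises(ValueError):
        egger(tiny)
    with pytest.raises(ValueError):
        weighted_median(tiny, seed=1)
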