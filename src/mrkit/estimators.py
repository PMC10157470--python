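"""Causal estimators for two-sample MR summary data.

Three estimators are provided, each as a scikit-learn-style estimator class
plus a thin functional wrapper consuming a :class:`~mrkit.harmonize.HarmonizedSet`:

* **IVW** — inverse-variance-weighted regression of outcome effects on
  exposure effects through the origin. The multiplicative random-effects
  variant (the primary analysis) inflates the fixed-effects standard error
  by ``sqrt(max(1, Q/(J-1)))`` so that heterogeneity widens, and never
  narrows, the interval.
* **Weighted median** — the weighted median of per-SNP Wald ratios,
  consistent when instruments carrying at least half the weight are valid;
  standard error by parametric bootstrap.
* **MR-Egger** — weighted regression with a free intercept; the slope
  estimates the causal effect under the InSIDE assumption and the
  intercept the average directional pleiotropy.

All p-values are two-sided: standard normal for IVW and the weighted
median, Student t with J-2 degrees of freedom for Egger.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .harmonize import HarmonizedSet

__all__ = [
    "MREstimate",
    "IVWEstimator",
    "WeightedMedianEstimator",
    "EggerRegression",
    "ivw",
    "weighted_median",
    "egger",
]

_P_FLOOR = 1e-300  # keep p-values inside (0, 1]


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate with its uncertainty.

    ``beta`` is in outcome units per exposure unit. ``method`` is one of
    ``ivw_mre``, ``ivw_fixed``, ``weighted_median``, ``egger_slope``,
    ``egger_intercept``.
    """

    method: str
    beta: float
    se: float
    pvalue: float
    n_snps: int
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if not self.se > 0:
            raise ValueError(f"se must be positive, got {self.se}")
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("confidence interval must bracket the estimate")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"pvalue must lie in (0,1], got {self.pvalue}")


def _normal_p(z: float) -> float:
    return float(np.clip(2.0 * stats.norm.sf(abs(z)), _P_FLOOR, 1.0))


def _as_arrays(*arrs):
    out = tuple(np.asarray(a, dtype=float) for a in arrs)
    n = {a.shape for a in out}
    if len(n) != 1 or out[0].ndim != 1:
        raise ValueError("inputs must be equal-length 1-d arrays")
    return out


# ---------------------------------------------------------------------------
# closed-form IVW machinery (shared with the sensitivity module)
# ---------------------------------------------------------------------------

def ivw_sums(beta_x, beta_y, se_y):
    """Weighted cross-products ``(Sxx, Sxy, Syy)`` with weights 1/se_y^2."""
    w = 1.0 / se_y**2
    return (
        float(np.sum(w * beta_x**2)),
        float(np.sum(w * beta_x * beta_y)),
        float(np.sum(w * beta_y**2)),
    )


def ivw_closed_form(beta_x, beta_y, se_y):
    """Fixed-effects IVW estimate, SE and Cochran's Q from the sums.

    Returns ``(beta, se_fixed, q_stat)``. Q here is the weighted residual
    sum of squares of the origin-forced regression at its solution, which
    equals Cochran's Q computed from Wald ratios with weights
    ``beta_x^2 / se_y^2`` (algebraic identity).
    """
    sxx, sxy, syy = ivw_sums(beta_x, beta_y, se_y)
    beta = sxy / sxx
    se_fixed = float(np.sqrt(1.0 / sxx))
    q = max(0.0, syy - sxy**2 / sxx)
    return beta, se_fixed, q


def ivw_leave_one_out(beta_x, beta_y, se_y):
    """Vectorized leave-one-out fixed-effects IVW.

    Returns ``(beta_loo, se_fixed_loo, q_loo)`` arrays of length J, where
    entry j is the fit with SNP j removed.
    """
    w = 1.0 / se_y**2
    sxx = np.sum(w * beta_x**2) - w * beta_x**2
    sxy = np.sum(w * beta_x * beta_y) - w * beta_x * beta_y
    syy = np.sum(w * beta_y**2) - w * beta_y**2
    beta = sxy / sxx
    se = np.sqrt(1.0 / sxx)
    q = np.maximum(0.0, syy - sxy**2 / sxx)
    return beta, se, q


def _mre_inflation(q: float, j: int) -> float:
    """Multiplicative random-effects SE inflation factor, floored at 1."""
    if j < 2:
        return 1.0
    return float(np.sqrt(max(1.0, q / (j - 1))))


# ---------------------------------------------------------------------------
# estimator classes
# ---------------------------------------------------------------------------

class IVWEstimator(BaseEstimator):
    """Inverse-variance-weighted causal estimate.

    Parameters
    ----------
    mode : {"multiplicative_random", "fixed"}
        Fixed-effects IVW uses ``se = sqrt(1/sum(w beta_x^2))``; the
        multiplicative random-effects mode multiplies it by
        ``sqrt(max(1, Q/(J-1)))``.

    Attributes (after :meth:`fit`)
    ------------------------------
    estimate_, se_, pvalue_, ci_low_, ci_high_, n_snps_, method_,
    q_stat_, q_df_ : fitted causal estimate and heterogeneity statistics.
    """

    def __init__(self, mode: str = "multiplicative_random"):
        self.mode = mode

    def fit(self, beta_x, beta_y, se_y):
        if self.mode not in ("multiplicative_random", "fixed"):
            raise ValueError(f"unknown IVW mode {self.mode!r}")
        beta_x, beta_y, se_y = _as_arrays(beta_x, beta_y, se_y)
        j = len(beta_x)
        if j == 0:
            raise ValueError("IVW requires at least one SNP")
        if j == 1:
            # Wald ratio with first-order delta-method SE
            if beta_x[0] == 0:
                raise ZeroDivisionError("Wald ratio undefined for beta_x = 0")
            self.estimate_ = float(beta_y[0] / beta_x[0])
            self.se_ = float(se_y[0] / abs(beta_x[0]))
            self.q_stat_, self.q_df_ = 0.0, 0
            self.method_ = "ivw_fixed"
        else:
            beta, se_fixed, q = ivw_closed_form(beta_x, beta_y, se_y)
            self.estimate_ = beta
            self.q_stat_, self.q_df_ = q, j - 1
            if self.mode == "multiplicative_random":
                self.se_ = se_fixed * _mre_inflation(q, j)
                self.method_ = "ivw_mre"
            else:
                self.se_ = se_fixed
                self.method_ = "ivw_fixed"
        z = self.estimate_ / self.se_
        self.pvalue_ = _normal_p(z)
        half = stats.norm.ppf(0.975) * self.se_
        self.ci_low_ = self.estimate_ - half
        self.ci_high_ = self.estimate_ + half
        self.n_snps_ = j
        return self

    def result(self) -> MREstimate:
        return MREstimate(
            method=self.method_,
            beta=self.estimate_,
            se=self.se_,
            pvalue=self.pvalue_,
            n_snps=self.n_snps_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
        )


def weighted_median_point(ratios, weights):
    """Weighted median with midpoint cumulative weights and interpolation.

    Standardized cumulative weights ``s_j = (cumsum(w)_j - w_j/2)/sum(w)``
    over ratios sorted ascending; the estimate interpolates ratio against
    ``s`` at 0.5, clamping to the extreme ratios outside ``[s_1, s_J]``.
    """
    ratios = np.asarray(ratios, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, r))


def _weighted_median_rows(ratios, weights):
    """Row-wise weighted median for (n_boot, J) arrays."""
    order = np.argsort(ratios, axis=1)
    r = np.take_along_axis(ratios, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    s = (np.cumsum(w, axis=1) - 0.5 * w) / np.sum(w, axis=1, keepdims=True)
    out = np.empty(len(r))
    for i in range(len(r)):
        out[i] = np.interp(0.5, s[i], r[i])
    return out


class WeightedMedianEstimator(BaseEstimator):
    """Weighted median of Wald ratios with parametric-bootstrap SE.

    Ratios ``r_j = beta_y/beta_x`` are weighted by the inverse variance of
    the first-order ratio, ``beta_x^2/se_y^2``. The bootstrap redraws both
    effect vectors from normals at their observed values with their
    standard errors; ``random_state`` must be supplied for reproducibility.
    """

    def __init__(self, n_boot: int = 1000, random_state: int | None = None):
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, beta_x, beta_y, se_x, se_y):
        beta_x, beta_y, se_x, se_y = _as_arrays(beta_x, beta_y, se_x, se_y)
        j = len(beta_x)
        if j < 3:
            raise ValueError(f"weighted median requires >= 3 SNPs, got {j}")
        if np.any(beta_x == 0):
            bad = np.nonzero(beta_x == 0)[0][0]
            raise ZeroDivisionError(f"Wald ratio undefined at SNP index {bad} (beta_x = 0)")
        if self.random_state is None:
            raise ValueError("random_state must be set for the bootstrap SE")
        ratios = beta_y / beta_x
        weights = beta_x**2 / se_y**2
        self.estimate_ = weighted_median_point(ratios, weights)

        rng = np.random.default_rng(self.random_state)
        bx = rng.normal(beta_x, se_x, size=(self.n_boot, j))
        by = rng.normal(beta_y, se_y, size=(self.n_boot, j))
        bx = np.where(bx == 0, np.finfo(float).tiny, bx)
        boots = _weighted_median_rows(by / bx, bx**2 / se_y**2)
        se = float(np.std(boots, ddof=1))
        self.se_ = max(se, np.finfo(float).tiny)
        z = self.estimate_ / self.se_
        self.pvalue_ = _normal_p(z)
        half = stats.norm.ppf(0.975) * self.se_
        self.ci_low_ = self.estimate_ - half
        self.ci_high_ = self.estimate_ + half
        self.n_snps_ = j
        self.method_ = "weighted_median"
        return self

    def result(self) -> MREstimate:
        return MREstimate(
            method="weighted_median",
            beta=self.estimate_,
            se=self.se_,
            pvalue=self.pvalue_,
            n_snps=self.n_snps_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
        )


class EggerRegression(BaseEstimator):
    """MR-Egger: weighted regression of beta_y on beta_x with intercept.

    SNPs are first oriented so every exposure effect is non-negative
    (negating both effects where needed), which makes the fit invariant to
    the arbitrary choice of effect allele. Weights are ``1/se_y^2``;
    standard errors carry a multiplicative overdispersion factor
    ``sqrt(max(1, RSS_w/(J-2)))`` and p-values use t(J-2).
    """

    def fit(self, beta_x, beta_y, se_y):
        beta_x, beta_y, se_y = _as_arrays(beta_x, beta_y, se_y)
        j = len(beta_x)
        if j < 3:
            raise ValueError(
                f"MR-Egger needs >= 3 SNPs (intercept + slope + residual df), got {j}"
            )
        sign = np.where(beta_x < 0, -1.0, 1.0)
        x = beta_x * sign
        y = beta_y * sign
        w = 1.0 / se_y**2
        # weighted normal equations for [intercept, slope]
        sw, swx = np.sum(w), np.sum(w * x)
        swxx, swy, swxy = np.sum(w * x * x), np.sum(w * y), np.sum(w * x * y)
        det = sw * swxx - swx**2
        intercept = (swxx * swy - swx * swxy) / det
        slope = (sw * swxy - swx * swy) / det
        resid = y - intercept - slope * x
        rss_w = float(np.sum(w * resid**2))
        phi = max(1.0, rss_w / (j - 2))
        var_intercept = swxx / det * phi
        var_slope = sw / det * phi

        self.slope_ = float(slope)
        self.slope_se_ = float(np.sqrt(var_slope))
        self.intercept_ = float(intercept)
        self.intercept_se_ = float(np.sqrt(var_intercept))
        tdist = stats.t(df=j - 2)
        self.slope_pvalue_ = float(
            np.clip(2 * tdist.sf(abs(self.slope_ / self.slope_se_)), _P_FLOOR, 1.0)
        )
        self.intercept_pvalue_ = float(
            np.clip(2 * tdist.sf(abs(self.intercept_ / self.intercept_se_)), _P_FLOOR, 1.0)
        )
        self.tcrit_ = float(tdist.ppf(0.975))
        self.n_snps_ = j
        self.overdispersion_ = phi
        return self

    def result(self) -> tuple[MREstimate, MREstimate]:
        slope = MREstimate(
            method="egger_slope",
            beta=self.slope_,
            se=self.slope_se_,
            pvalue=self.slope_pvalue_,
            n_snps=self.n_snps_,
            ci_low=self.slope_ - self.tcrit_ * self.slope_se_,
            ci_high=self.slope_ + self.tcrit_ * self.slope_se_,
        )
        intercept = MREstimate(
            method="egger_intercept",
            beta=self.intercept_,
            se=self.intercept_se_,
            pvalue=self.intercept_pvalue_,
            n_snps=self.n_snps_,
            ci_low=self.intercept_ - self.tcrit_ * self.intercept_se_,
            ci_high=self.intercept_ + self.tcrit_ * self.intercept_se_,
        )
        return slope, intercept


# ---------------------------------------------------------------------------
# functional wrappers over HarmonizedSet
# ---------------------------------------------------------------------------

def ivw(data: HarmonizedSet, mode: str = "multiplicative_random") -> MREstimate:
    """IVW causal estimate for a harmonized set (Wald ratio when J = 1)."""
    if data.n_snps == 0:
        raise ValueError(f"empty harmonized set for {data.pair_label!r}")
    return IVWEstimator(mode=mode).fit(data.beta_x, data.beta_y, data.se_y).result()


def weighted_median(data: HarmonizedSet, n_boot: int = 1000, seed: int | None = None) -> MREstimate:
    """Weighted-median causal estimate with bootstrap SE (J >= 3)."""
    est = WeightedMedianEstimator(n_boot=n_boot, random_state=seed)
    return est.fit(data.beta_x, data.beta_y, data.se_x, data.se_y).result()


def egger(data: HarmonizedSet) -> tuple[MREstimate, MREstimate]:
    """MR-Egger (slope, intercept) estimates for a harmonized set (J >= 3)."""
    return EggerRegression().fit(data.beta_x, data.beta_y, data.se_y).result()
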