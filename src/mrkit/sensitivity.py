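"""Sensitivity analyses for a single exposure-outcome MR pair.

Covers heterogeneity (Cochran's Q, funnel data), horizontal pleiotropy
(MR-Egger intercept test), pleiotropic outliers (MR-PRESSO global /
outlier / distortion tests) and influence (leave-one-out IVW).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    EggerRegression,
    IVWEstimator,
    MREstimate,
    ivw_closed_form,
    ivw_leave_one_out,
    _mre_inflation,
    _normal_p,
)
from .harmonize import HarmonizedSet

__all__ = [
    "SensitivityReport",
    "PressoResult",
    "cochran_q",
    "egger_intercept_test",
    "mr_presso",
    "leave_one_out",
    "funnel_data",
    "run_sensitivity",
]


def cochran_q(data: HarmonizedSet) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity test over per-SNP Wald ratios.

    ``Q = sum_j w_j (r_j - beta_fixed)^2`` with ``r_j = beta_y/beta_x`` and
    ``w_j = beta_x^2/se_y^2``; the reference estimate is the fixed-effects
    IVW, and p comes from chi-square with J-1 degrees of freedom.
    """
    j = data.n_snps
    if j < 2:
        raise ValueError(f"Cochran's Q needs >= 2 SNPs, got {j}")
    ratios = data.beta_y / data.beta_x
    weights = data.beta_x**2 / data.se_y**2
    beta_fixed = float(np.sum(weights * ratios) / np.sum(weights))
    q = float(np.sum(weights * (ratios - beta_fixed) ** 2))
    p = float(np.clip(stats.chi2.sf(q, df=j - 1), 1e-300, 1.0))
    return q, j - 1, p


def egger_intercept_test(data: HarmonizedSet) -> tuple[float, float, float]:
    """MR-Egger intercept (average directional pleiotropy): value, SE, p."""
    fitted = EggerRegression().fit(data.beta_x, data.beta_y, data.se_y)
    return fitted.intercept_, fitted.intercept_se_, fitted.intercept_pvalue_


@dataclass
class PressoResult:
    """MR-PRESSO outcome for one pair.

    ``global_pvalue`` is an upper bound (``1/n_sim``) when no simulated
    residual sum exceeded the observed one; ``global_pvalue_text`` then
    reads ``"<1/n_sim"``. ``outliers`` lists ``(snp_id, corrected_p)``.
    """

    global_pvalue: float
    global_pvalue_text: str
    outliers: list[tuple[str, float]]
    distortion_pvalue: float | None
    cleaned: HarmonizedSet


def mr_presso(
    data: HarmonizedSet,
    n_sim: int = 1000,
    seed: int | None = None,
    outlier_alpha: float = 0.05,
    bonferroni: bool = True,
    n_perm_distortion: int = 1000,
) -> PressoResult:
    """MR-PRESSO pleiotropy residual-sum and outlier test.

    The observed statistic is the weighted residual sum of squares of each
    SNP against its *leave-one-out* IVW prediction,
    ``RSS = sum_j w_j (beta_yj - beta_ivw(-j) beta_xj)^2`` with
    ``w_j = 1/se_yj^2``. The null distribution comes from ``n_sim``
    parametric simulations drawing ``beta_x* ~ N(beta_x, se_x)`` and
    ``beta_y* ~ N(beta_ivw(-j) beta_x, se_y)``. Per-SNP residual
    contributions give one-sided outlier p-values, Bonferroni-corrected
    over J by default; SNPs below ``outlier_alpha`` are removed to form
    ``cleaned``. When outliers are found, a permutation distortion test
    compares the observed change in the IVW estimate after outlier removal
    with the change from removing random same-size SNP subsets.
    """
    j = data.n_snps
    if j < 4:
        raise ValueError(f"MR-PRESSO needs >= 4 SNPs, got {j}")
    if n_sim < 100:
        import warnings

        warnings.warn(f"n_sim={n_sim} is very small for MR-PRESSO", stacklevel=2)
    if seed is None:
        raise ValueError("seed must be set: MR-PRESSO is simulation-based")
    rng = np.random.default_rng(seed)

    bx, by, sx, sy = data.beta_x, data.beta_y, data.se_x, data.se_y
    w = 1.0 / sy**2
    beta_loo, _, _ = ivw_leave_one_out(bx, by, sy)
    obs_contrib = w * (by - beta_loo * bx) ** 2
    rss_obs = float(np.sum(obs_contrib))

    # parametric null: redraw both effect vectors around leave-one-out fits
    bx_sim = rng.normal(bx, sx, size=(n_sim, j))
    by_sim = rng.normal(beta_loo * bx, sy, size=(n_sim, j))
    w_row = w[None, :]
    sxx = np.sum(w_row * bx_sim**2, axis=1, keepdims=True) - w_row * bx_sim**2
    sxy = np.sum(w_row * bx_sim * by_sim, axis=1, keepdims=True) - w_row * bx_sim * by_sim
    beta_loo_sim = sxy / sxx
    contrib_sim = w_row * (by_sim - beta_loo_sim * bx_sim) ** 2
    rss_sim = np.sum(contrib_sim, axis=1)

    exceed = int(np.sum(rss_sim >= rss_obs))
    if exceed == 0:
        global_p = 1.0 / n_sim
        global_text = f"<1/{n_sim}"
    else:
        global_p = exceed / n_sim
        global_text = f"{global_p:.6g}"

    outlier_p = np.mean(contrib_sim >= obs_contrib[None, :], axis=0)
    corrected = np.minimum(1.0, outlier_p * j) if bonferroni else outlier_p
    flagged = corrected < outlier_alpha
    outliers = [(str(data.snp_id[i]), float(corrected[i])) for i in np.nonzero(flagged)[0]]

    distortion_p: float | None = None
    n_out = int(np.sum(flagged))
    if n_out and j - n_out >= 2:
        beta_all, _, _ = ivw_closed_form(bx, by, sy)
        keep = ~flagged
        beta_clean, _, _ = ivw_closed_form(bx[keep], by[keep], sy[keep])
        if beta_clean != 0:
            obs_dist = (beta_all - beta_clean) / abs(beta_clean)
            perm_dist = np.empty(n_perm_distortion)
            idx = np.arange(j)
            for k in range(n_perm_distortion):
                drop = rng.choice(idx, size=n_out, replace=False)
                m = np.ones(j, dtype=bool)
                m[drop] = False
                b_sub, _, _ = ivw_closed_form(bx[m], by[m], sy[m])
                perm_dist[k] = (beta_all - b_sub) / abs(b_sub) if b_sub != 0 else np.inf
            distortion_p = float(np.mean(np.abs(perm_dist) >= abs(obs_dist)))

    cleaned = data.subset(~flagged) if n_out else data
    return PressoResult(
        global_pvalue=float(global_p),
        global_pvalue_text=global_text,
        outliers=outliers,
        distortion_pvalue=distortion_p,
        cleaned=cleaned,
    )


def leave_one_out(
    data: HarmonizedSet, significance_threshold: float = 0.05
) -> tuple[list[tuple[str, MREstimate]], bool]:
    """Leave-one-out multiplicative random-effects IVW.

    Refits the primary IVW with each SNP removed in turn. The analysis
    passes when every leave-one-out p-value stays below
    ``significance_threshold`` and every estimate keeps the sign of the
    full-set estimate — i.e. no single SNP drives the result.
    """
    j = data.n_snps
    if j < 3:
        raise ValueError(f"leave-one-out needs >= 3 SNPs, got {j}")
    full = IVWEstimator().fit(data.beta_x, data.beta_y, data.se_y)
    beta, se_fixed, q = ivw_leave_one_out(data.beta_x, data.beta_y, data.se_y)
    results: list[tuple[str, MREstimate]] = []
    z975 = stats.norm.ppf(0.975)
    ok = True
    for i in range(j):
        se = se_fixed[i] * _mre_inflation(q[i], j - 1)
        p = _normal_p(beta[i] / se)
        est = MREstimate(
            method="ivw_mre" if j - 1 >= 2 else "ivw_fixed",
            beta=float(beta[i]),
            se=float(se),
            pvalue=p,
            n_snps=j - 1,
            ci_low=float(beta[i] - z975 * se),
            ci_high=float(beta[i] + z975 * se),
        )
        results.append((str(data.snp_id[i]), est))
        if p >= significance_threshold or np.sign(beta[i]) != np.sign(full.estimate_):
            ok = False
    return results, ok


def funnel_data(data: HarmonizedSet) -> pd.DataFrame:
    """Per-SNP funnel-plot coordinates: Wald ratio vs precision.

    ``ratio = beta_y/beta_x`` and ``precision = |beta_x|/se_y``, the
    reciprocal of the first-order ratio SE. Asymmetry of the funnel around
    the pooled estimate indicates directional pleiotropy.
    """
    if np.any(data.beta_x == 0):
        bad = data.snp_id[data.beta_x == 0][0]
        raise ZeroDivisionError(f"Wald ratio undefined for {bad} (beta_x = 0)")
    return pd.DataFrame(
        {
            "snp_id": data.snp_id,
            "ratio": data.beta_y / data.beta_x,
            "precision": np.abs(data.beta_x) / data.se_y,
        }
    )


def funnel_plot(data: HarmonizedSet, ax=None):
    """Render the funnel plot (convenience helper, not a tested contract)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    tab = funnel_data(data)
    est = IVWEstimator().fit(data.beta_x, data.beta_y, data.se_y)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(tab["ratio"], tab["precision"], s=14)
    ax.axvline(est.estimate_, color="crimson", lw=1, label="IVW")
    ax.set_xlabel("Wald ratio")
    ax.set_ylabel(r"precision $|\beta_x|/\mathrm{se}_y$")
    ax.legend()
    return ax


@dataclass
class SensitivityReport:
    """Q, Egger intercept, MR-PRESSO and leave-one-out outcomes for one pair."""

    pair_label: str
    q_stat: float
    q_df: int
    q_pvalue: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_pvalue: float
    loo_results: list[tuple[str, MREstimate]]
    loo_pass: bool
    funnel: pd.DataFrame
    presso: PressoResult | None = None
    notes: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        """One row in the layout of a significant/nominal results table."""
        return {
            "q_p": self.q_pvalue,
            "intercept_p": self.egger_intercept_pvalue,
            "loo": "Yes" if self.loo_pass else "No",
        }


def run_sensitivity(
    data: HarmonizedSet,
    loo_threshold: float = 0.05,
    presso: PressoResult | None = None,
) -> SensitivityReport:
    """Assemble the full sensitivity battery for a harmonized pair (J >= 3)."""
    q, q_df, q_p = cochran_q(data)
    icpt, icpt_se, icpt_p = egger_intercept_test(data)
    loo, loo_ok = leave_one_out(data, significance_threshold=loo_threshold)
    return SensitivityReport(
        pair_label=data.pair_label,
        q_stat=q,
        q_df=q_df,
        q_pvalue=q_p,
        egger_intercept=icpt,
        egger_intercept_se=icpt_se,
        egger_intercept_pvalue=icpt_p,
        loo_results=loo,
        loo_pass=loo_ok,
        funnel=funnel_data(data),
        presso=presso,
    )
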