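"""Study orchestration: many exposures by many outcomes, with
multiple-testing correction and a three-tier significance classification.

A pair is **significant** when the primary (multiplicative random-effects)
IVW p-value beats the Bonferroni-corrected level threshold, the weighted
median is itself significant at 0.05, the weighted-median and MR-Egger
estimates agree in direction with the IVW, no heterogeneity or horizontal
pleiotropy is detected (Cochran's Q and Egger-intercept p at or above
0.05), and the leave-one-out analysis passes. A pair is **nominal** when
the IVW p-value is below 0.05 without meeting all of the above; otherwise
**null**. The heterogeneity/pleiotropy gates can be switched off to obtain
the consistency-only reading of the rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .estimators import MREstimate, egger, ivw, weighted_median
from .harmonize import HarmonizedSet, harmonize
from .select import LDTable, SelectionConfig, select_instruments
from .sensitivity import SensitivityReport, leave_one_out, mr_presso, run_sensitivity
from .sumstats import SummaryRecord, read_summary_stats

__all__ = [
    "StudyConfig",
    "PairResult",
    "bonferroni_threshold",
    "classify_pair",
    "analyze_pair",
    "run_study",
]

log = logging.getLogger(__name__)


def bonferroni_threshold(family_alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected per-test threshold, ``family_alpha / n_tests``."""
    if not (0.0 < family_alpha < 1.0):
        raise ValueError(f"family_alpha must be in (0,1), got {family_alpha}")
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return family_alpha / n_tests


@dataclass
class StudyConfig:
    """Thresholds and settings for a full MR study.

    Regional tests are Bonferroni-corrected over ``n_regional_tests``
    (34 atlas regions x two measures = 68 by default) and global tests
    over ``n_global_tests`` (surface area and thickness). The
    heterogeneity/pleiotropy gates on the significant tier follow the
    strict reading of the classification rule; set
    ``require_sensitivity_gates=False`` for the consistency-only reading.
    """

    family_alpha: float = 0.05
    n_regional_tests: int = 68
    n_global_tests: int = 2
    wm_alpha: float = 0.05
    heterogeneity_alpha: float = 0.05
    pleiotropy_alpha: float = 0.05
    loo_alpha: float = 0.05
    require_sensitivity_gates: bool = True
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    n_boot: int = 1000
    presso_n_sim: int = 1000
    presso_outlier_alpha: float = 0.05
    apply_presso: bool = True
    seed: int = 0
    assumed_sample_overlap: float | None = None  # recorded in report metadata only

    @property
    def regional_alpha(self) -> float:
        return bonferroni_threshold(self.family_alpha, self.n_regional_tests)

    @property
    def global_alpha(self) -> float:
        return bonferroni_threshold(self.family_alpha, self.n_global_tests)


@dataclass
class PairResult:
    """Classification and evidence for one exposure-outcome pair."""

    exposure: str
    outcome: str
    level: str  # "regional" | "global"
    tier: str  # "significant" | "nominal" | "null" | "not_evaluable"
    reasons: list[tuple[str, bool, str]]
    estimates: dict[str, MREstimate] = field(default_factory=dict)
    sensitivity: SensitivityReport | None = None

    def to_row(self) -> dict:
        iv = self.estimates.get("ivw")
        row = {
            "exposure": self.exposure,
            "outcome": self.outcome,
            "level": self.level,
            "tier": self.tier,
            "beta": iv.beta if iv else np.nan,
            "se": iv.se if iv else np.nan,
            "ivw_p": iv.pvalue if iv else np.nan,
            "n_snps": iv.n_snps if iv else 0,
        }
        if self.sensitivity is not None:
            row.update(self.sensitivity.to_row())
        else:
            row.update({"q_p": np.nan, "intercept_p": np.nan, "loo": ""})
        for m in ("weighted_median", "egger_slope"):
            e = self.estimates.get(m)
            row[f"{m}_beta"] = e.beta if e else np.nan
            row[f"{m}_p"] = e.pvalue if e else np.nan
        row["reasons"] = "; ".join(
            f"{name}={'ok' if ok else 'fail'} ({detail})" for name, ok, detail in self.reasons
        )
        return row


def classify_pair(
    estimates: Mapping[str, MREstimate],
    sensitivity: SensitivityReport | None,
    config: StudyConfig,
    level: str = "regional",
) -> tuple[str, list[tuple[str, bool, str]]]:
    """Apply the three-tier significance rule to one pair.

    ``estimates`` must contain ``"ivw"`` and, for sets of three or more
    instruments, ``"weighted_median"`` and ``"egger_slope"``. Pairs
    estimated from fewer than three instruments (Wald ratio or two-SNP
    IVW) lack the consistency estimators and can reach at most the nominal
    tier. Returns ``(tier, reasons)`` where reasons list every criterion
    with its outcome.
    """
    if level not in ("regional", "global"):
        raise ValueError(f"level must be 'regional' or 'global', got {level!r}")
    ivw_est = estimates.get("ivw")
    if ivw_est is None:
        raise ValueError("estimates must contain an 'ivw' entry")
    threshold = config.regional_alpha if level == "regional" else config.global_alpha
    reasons: list[tuple[str, bool, str]] = []

    ivw_sig = ivw_est.pvalue < threshold
    reasons.append(
        ("ivw_p_below_level_threshold", ivw_sig, f"p={ivw_est.pvalue:.3g} vs {threshold:.3g}")
    )

    wm = estimates.get("weighted_median")
    eg = estimates.get("egger_slope")
    if wm is None or eg is None:
        if ivw_est.n_snps >= 3:
            raise ValueError(
                "weighted_median and egger_slope estimates are required for pairs with >= 3 SNPs"
            )
        reasons.append(
            ("consistency_estimators", False, f"unavailable with {ivw_est.n_snps} SNP(s)")
        )
        ok_consistency = False
    else:
        wm_sig = wm.pvalue < config.wm_alpha
        concordant = np.sign(wm.beta) == np.sign(ivw_est.beta) == np.sign(eg.beta)
        reasons.append(("wm_p_below_0.05", wm_sig, f"p={wm.pvalue:.3g}"))
        reasons.append(
            (
                "wm_egger_direction_concordant",
                bool(concordant),
                f"ivw={ivw_est.beta:.3g}, wm={wm.beta:.3g}, egger={eg.beta:.3g}",
            )
        )
        ok_consistency = wm_sig and concordant

    gates_ok = True
    if sensitivity is None:
        reasons.append(("sensitivity_battery", False, "unavailable"))
        gates_ok = False
    else:
        loo_ok = sensitivity.loo_pass
        reasons.append(("leave_one_out", loo_ok, "Yes" if loo_ok else "No"))
        gates_ok = loo_ok
        if config.require_sensitivity_gates:
            q_ok = sensitivity.q_pvalue >= config.heterogeneity_alpha
            pl_ok = sensitivity.egger_intercept_pvalue >= config.pleiotropy_alpha
            reasons.append(("no_heterogeneity", q_ok, f"Q p={sensitivity.q_pvalue:.3g}"))
            reasons.append(
                ("no_pleiotropy", pl_ok, f"intercept p={sensitivity.egger_intercept_pvalue:.3g}")
            )
            gates_ok = gates_ok and q_ok and pl_ok

    if ivw_sig and ok_consistency and gates_ok:
        return "significant", reasons
    if ivw_est.pvalue < 0.05:
        reasons.append(("ivw_p_below_0.05", True, f"p={ivw_est.pvalue:.3g}"))
        return "nominal", reasons
    reasons.append(("ivw_p_below_0.05", False, f"p={ivw_est.pvalue:.3g}"))
    return "null", reasons


def analyze_pair(
    data: HarmonizedSet,
    config: StudyConfig,
    level: str = "regional",
    seed: int | None = None,
    exposure: str = "",
    outcome: str = "",
    apply_presso: bool | None = None,
) -> PairResult:
    """Estimate, run sensitivity analyses and classify one harmonized pair.

    Order follows the study design: MR-PRESSO outlier removal first (when
    enabled and at least four instruments are available), then the three
    estimators and the sensitivity battery on the cleaned set. For the
    significant tier the leave-one-out analysis is additionally evaluated
    at the level's Bonferroni threshold.
    """
    seed = config.seed if seed is None else seed
    if apply_presso is None:
        apply_presso = config.apply_presso
    notes: list[str] = []

    work = data
    presso = None
    if apply_presso and work.n_snps >= 4:
        presso = mr_presso(
            work,
            n_sim=config.presso_n_sim,
            seed=seed,
            outlier_alpha=config.presso_outlier_alpha,
        )
        if presso.outliers:
            notes.append(
                "MR-PRESSO removed: " + ", ".join(s for s, _ in presso.outliers)
            )
            work = presso.cleaned

    estimates: dict[str, MREstimate] = {"ivw": ivw(work, mode="multiplicative_random")}
    sensitivity = None
    if work.n_snps >= 3:
        estimates["weighted_median"] = weighted_median(work, n_boot=config.n_boot, seed=seed)
        slope, intercept = egger(work)
        estimates["egger_slope"] = slope
        estimates["egger_intercept"] = intercept
        sensitivity = run_sensitivity(work, loo_threshold=config.loo_alpha, presso=presso)
        sensitivity.notes.extend(notes)

    tier, reasons = classify_pair(estimates, sensitivity, config, level=level)
    if tier == "significant":
        # re-evaluate leave-one-out stability at the level threshold
        threshold = config.regional_alpha if level == "regional" else config.global_alpha
        _, strict_ok = leave_one_out(work, significance_threshold=threshold)
        reasons.append(
            ("leave_one_out_at_level_threshold", strict_ok, f"threshold={threshold:.3g}")
        )
        if not strict_ok:
            tier = "nominal"
    return PairResult(
        exposure=exposure,
        outcome=outcome,
        level=level,
        tier=tier,
        reasons=reasons,
        estimates=estimates,
        sensitivity=sensitivity,
    )


def _load_records(source) -> list[SummaryRecord]:
    if isinstance(source, (str, Path)):
        return read_summary_stats(source).records
    return list(source)


def run_study(
    exposures: Mapping[str, object],
    outcomes: Mapping[str, object],
    ld=None,
    exclusions: Mapping[str, str] | None = None,
    config: StudyConfig | None = None,
    outcome_levels: Mapping[str, str] | None = None,
    out_dir=None,
) -> list[PairResult]:
    """Run the full study grid.

    ``exposures`` and ``outcomes`` map names to either file paths of
    tab-delimited summary statistics or in-memory record lists.
    ``outcome_levels`` assigns each outcome to the ``"regional"`` (default)
    or ``"global"`` test family. Per exposure: instruments are selected
    once; per outcome: harmonize, MR-PRESSO, estimate, sensitivity,
    classify. Pairs that cannot be evaluated (no shared SNPs, no surviving
    instruments...) are reported with tier ``"not_evaluable"`` and the
    cause, never silently dropped. Writes ``results_long.tsv``,
    ``table1_style.tsv`` and ``audit.log`` when ``out_dir`` is given; rows
    are ordered by exposure then outcome name.
    """
    config = config or StudyConfig()
    if exclusions:
        config = replace(
            config, selection=replace(config.selection, exclusion_list=dict(exclusions))
        )
    if ld is not None and not isinstance(ld, LDTable):
        ld = LDTable.from_file(ld) if isinstance(ld, (str, Path)) else LDTable(ld)
    outcome_levels = dict(outcome_levels or {})
    audit_lines: list[str] = []
    if config.assumed_sample_overlap is not None:
        audit_lines.append(
            f"metadata: assumed exposure-outcome sample overlap = {config.assumed_sample_overlap}"
        )

    results: list[PairResult] = []
    outcome_records = {name: _load_records(src) for name, src in sorted(outcomes.items())}
    for e_idx, (exp_name, exp_src) in enumerate(sorted(exposures.items())):
        exp_records = _load_records(exp_src)
        try:
            instruments, strengths, audit = select_instruments(exp_records, ld, config.selection)
        except ValueError as err:
            audit_lines.append(f"{exp_name}: instrument selection failed: {err}")
            for out_name in outcome_records:
                results.append(
                    PairResult(
                        exposure=exp_name,
                        outcome=out_name,
                        level=outcome_levels.get(out_name, "regional"),
                        tier="not_evaluable",
                        reasons=[("instrument_selection", False, str(err))],
                    )
                )
            continue
        audit_lines.append(
            f"{exp_name}: selection audit " + ", ".join(f"{s}={n}" for s, n in audit)
        )
        for o_idx, (out_name, out_recs) in enumerate(sorted(outcome_records.items())):
            level = outcome_levels.get(out_name, "regional")
            pair_seed = int(
                np.random.SeedSequence([config.seed, e_idx, o_idx]).generate_state(1)[0]
                % (2**31 - 1)
            )
            try:
                hset = harmonize(instruments, out_recs, pair_label=f"{exp_name} x {out_name}")
                result = analyze_pair(
                    hset, config, level=level, seed=pair_seed, exposure=exp_name, outcome=out_name
                )
            except (ValueError, ZeroDivisionError) as err:
                result = PairResult(
                    exposure=exp_name,
                    outcome=out_name,
                    level=level,
                    tier="not_evaluable",
                    reasons=[("evaluation", False, str(err))],
                )
            results.append(result)
            audit_lines.append(f"{exp_name} x {out_name}: tier={result.tier}")

    results.sort(key=lambda r: (r.exposure, r.outcome))
    if out_dir is not None:
        _write_reports(results, audit_lines, Path(out_dir))
    return results


def _write_reports(results: list[PairResult], audit_lines: list[str], out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    long_df = pd.DataFrame([r.to_row() for r in results])
    long_df.to_csv(out_dir / "results_long.tsv", sep="\t", index=False)
    table1 = long_df[long_df["tier"].isin(["significant", "nominal"])]
    table1 = table1[["exposure", "outcome", "beta", "se", "ivw_p", "q_p", "intercept_p", "loo"]]
    table1.to_csv(out_dir / "table1_style.tsv", sep="\t", index=False)
    (out_dir / "audit.log").write_text("\n".join(audit_lines) + "\n")
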