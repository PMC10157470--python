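"""Instrument selection: significance, LD independence, confounder
exclusion and instrument strength.

Selection proceeds in a fixed order — p-value filter, greedy LD clumping
against a user-supplied pairwise r-squared table, removal of SNPs on a
confounder exclusion list, then F-statistic screening — each stage only
ever removing SNPs, with an audit trail of counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .sumstats import SummaryRecord

__all__ = [
    "SelectionConfig",
    "InstrumentStrength",
    "LDTable",
    "filter_by_pvalue",
    "ld_clump",
    "compute_strength",
    "apply_exclusions",
    "select_instruments",
    "read_exclusions",
]

log = logging.getLogger(__name__)

#: genome-wide significance, the default instrument threshold
GENOME_WIDE_P = 5e-8
#: relaxed threshold used when strict screening leaves too few instruments
RELAXED_P = 5e-6


@dataclass
class SelectionConfig:
    """Thresholds governing instrument selection.

    ``p_threshold`` is the exposure-association cutoff (genome-wide 5e-8 by
    default; 5e-6 is the conventional relaxation for sparse exposures, kept
    only together with the F > ``f_min`` floor). ``clump_r2``/``clump_kb``
    define LD independence; ``f_min`` flags weak instruments.
    """

    p_threshold: float = GENOME_WIDE_P
    clump_r2: float = 0.001
    clump_kb: float = 10000.0
    f_min: float = 10.0
    exclusion_list: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError(f"p_threshold must be in (0,1), got {self.p_threshold}")
        if not (0.0 <= self.clump_r2 <= 1.0):
            raise ValueError(f"clump_r2 must be in [0,1], got {self.clump_r2}")
        if not self.clump_kb > 0:
            raise ValueError(f"clump_kb must be positive, got {self.clump_kb}")


@dataclass(frozen=True)
class InstrumentStrength:
    """Strength statistics for one instrument within a set of k instruments.

    ``r2`` is the proportion of exposure variance the SNP explains,
    ``2*MAF*(1-MAF)*beta^2`` when the allele frequency is known and the
    ``beta^2/(beta^2 + se^2*n)`` fallback otherwise; ``f_stat`` is
    ``(r2/(1-r2)) * (n-k-1)/k``. ``f_stat_single`` reports the same SNP
    treated as a one-instrument set (k = 1).
    """

    snp_id: str
    r2: float
    f_stat: float
    f_stat_single: float
    formula_used: str  # "maf_formula" | "se_formula"

    def __post_init__(self):
        if self.f_stat < 0 or not (0.0 <= self.r2 < 1.0):
            raise ValueError("invalid strength statistics")


class LDTable:
    """Sparse pairwise r-squared lookup; absent pairs count as r2 = 0."""

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._r2: dict[frozenset, float] = {}
        for (a, b), v in (pairs or {}).items():
            self.set(a, b, v)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 must lie in [0,1], got {r2} for ({a},{b})")
        if a != b:
            self._r2[frozenset((a, b))] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_file(cls, path) -> "LDTable":
        """Read either a 3-column (snp_a, snp_b, r2) table or a square
        matrix with snp_ids as header row and first column."""
        df = pd.read_csv(path, sep="\t")
        table = cls()
        first_col = {str(v) for v in df.iloc[:, 0]}
        is_square = df.shape[1] > 1 and all(str(c) in first_col for c in df.columns[1:])
        if df.shape[1] == 3 and not is_square:
            a_col, b_col, r_col = df.columns
            for a, b, r in zip(df[a_col], df[b_col], df[r_col]):
                table.set(str(a), str(b), float(r))
        else:
            ids = [str(c) for c in df.columns[1:]]
            for _, row in df.iterrows():
                a = str(row.iloc[0])
                for b, v in zip(ids, row.iloc[1:]):
                    if a != b and float(v) > 0:
                        table.set(a, b, float(v))
        return table


def filter_by_pvalue(records: list[SummaryRecord], p_threshold: float) -> list[SummaryRecord]:
    """Keep records with exposure p-value below ``p_threshold`` (order preserved)."""
    kept = [r for r in records if r.pvalue < p_threshold]
    if not kept:
        log.warning("p-value filter at %.3g left no records", p_threshold)
    return kept


def ld_clump(
    records: list[SummaryRecord],
    ld_r2: LDTable | Mapping[tuple[str, str], float],
    config: SelectionConfig,
) -> list[SummaryRecord]:
    """Greedy LD clumping.

    Repeatedly takes the remaining SNP with the smallest p-value as an
    index SNP (ties broken by lexicographically smaller snp_id, so the
    result is independent of input order) and removes every remaining SNP
    on the same chromosome within ``clump_kb`` of it whose r-squared with
    the index is at least ``clump_r2``. Index SNPs are returned sorted by
    chromosome and position.
    """
    if not isinstance(ld_r2, LDTable):
        ld_r2 = LDTable(ld_r2)
    remaining = sorted(records, key=lambda r: (r.pvalue, r.snp_id))
    window = config.clump_kb * 1000.0
    index_snps: list[SummaryRecord] = []
    while remaining:
        index = remaining.pop(0)
        index_snps.append(index)
        remaining = [
            r
            for r in remaining
            if not (
                r.chrom == index.chrom
                and abs(r.pos - index.pos) <= window
                and ld_r2.r2(index.snp_id, r.snp_id) >= config.clump_r2
            )
        ]
    return sorted(index_snps, key=lambda r: (r.chrom, r.pos, r.snp_id))


def compute_strength(record: SummaryRecord, k: int) -> InstrumentStrength:
    """Instrument strength for one SNP within a k-instrument set.

    Uses the allele-frequency formula for explained variance when eaf is
    available and the SE-based fallback otherwise; the F-statistic then
    scales the variance-explained odds by ``(n-k-1)/k``.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if record.n <= k + 1:
        raise ValueError(
            f"degenerate sample: n={record.n} must exceed k+1={k + 1} for {record.snp_id}"
        )
    if record.maf is not None:
        r2 = 2.0 * record.maf * (1.0 - record.maf) * record.beta**2
        formula = "maf_formula"
    else:
        r2 = record.beta**2 / (record.beta**2 + record.se**2 * record.n)
        formula = "se_formula"
    r2 = min(r2, 1.0 - 1e-12)

    def f_for(kk: int) -> float:
        return (r2 / (1.0 - r2)) * ((record.n - kk - 1) / kk)

    return InstrumentStrength(
        snp_id=record.snp_id,
        r2=float(r2),
        f_stat=float(f_for(k)),
        f_stat_single=float(f_for(1)) if record.n > 2 else 0.0,
        formula_used=formula,
    )


def apply_exclusions(
    records: list[SummaryRecord], exclusion_list: Mapping[str, str]
) -> tuple[list[SummaryRecord], list[tuple[str, str]]]:
    """Remove confounder-associated SNPs; returns (kept, removal log).

    The removal log carries each excluded SNP's stated reason (e.g.
    ``"second phenotype: obesity"``); exclusion ids absent from the input
    are logged as ``"not found"`` and leave the kept list unchanged.
    """
    present = {r.snp_id for r in records}
    removed = [(snp, reason) for snp, reason in exclusion_list.items() if snp in present]
    removed += [
        (snp, f"not found ({reason})")
        for snp, reason in exclusion_list.items()
        if snp not in present
    ]
    kept = [r for r in records if r.snp_id not in exclusion_list]
    return kept, removed


def read_exclusions(path) -> dict[str, str]:
    """Read a 2-column tab-delimited (snp_id, reason) exclusion list."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    id_col, reason_col = df.columns[:2]
    return {str(s): str(r) for s, r in zip(df[id_col], df[reason_col])}


def select_instruments(
    exposure: list[SummaryRecord],
    ld_r2: LDTable | Mapping[tuple[str, str], float] | None,
    config: SelectionConfig,
) -> tuple[list[SummaryRecord], list[InstrumentStrength], list[tuple[str, int]]]:
    """Full instrument-selection pipeline for one exposure.

    Stages, in order: p-value filter, LD clumping, confounder exclusions,
    strength computation, and removal of weak instruments (per-SNP
    F-statistic below ``config.f_min``). The weak-instrument screen uses
    each SNP judged on its own (k = 1), the convention under which the
    F < 10 rule is calibrated; the returned strength statistics also carry
    the F recomputed with k equal to the final set size. Returns the
    instruments, their strength statistics and an audit log of
    ``(stage, count)`` entries.

    Raises a ``ValueError`` when no instrument survives.
    """
    audit: list[tuple[str, int]] = [("input", len(exposure))]
    sig = filter_by_pvalue(exposure, config.p_threshold)
    audit.append(("p_filter", len(sig)))
    clumped = ld_clump(sig, ld_r2 if ld_r2 is not None else LDTable(), config)
    audit.append(("ld_clump", len(clumped)))
    kept, removal_log = apply_exclusions(clumped, config.exclusion_list)
    audit.append(("exclusions", len(kept)))
    for snp, reason in removal_log:
        log.info("excluded %s: %s", snp, reason)
    if not kept:
        raise ValueError("no instruments survive selection (before strength screening)")

    single = [compute_strength(r, 1) for r in kept]
    strong = [r for r, s in zip(kept, single) if s.f_stat_single >= config.f_min]
    for r, s in zip(kept, single):
        if s.f_stat_single < config.f_min:
            log.info("weak IV %s dropped (F=%.2f < %.1f)", r.snp_id, s.f_stat_single, config.f_min)
    audit.append(("weak_iv", len(strong)))
    if not strong:
        raise ValueError("no instruments survive the weak-instrument screen")
    final_strengths = [compute_strength(r, len(strong)) for r in strong]
    return strong, final_strengths, audit
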