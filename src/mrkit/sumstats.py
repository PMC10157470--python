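"""Reading, validating and writing GWAS summary statistics.

The on-disk format is a tab-delimited table with one row per SNP and a
header row. Column names are configurable through a ``column_map``; the
defaults follow the common ``SNP / CHR / BP / EA / OA / EAF / BETA / SE /
P / N`` convention. Only biallelic single-nucleotide variants are accepted:
indels and multi-allelic records are rejected at read time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

__all__ = [
    "SummaryRecord",
    "ReadResult",
    "DEFAULT_COLUMN_MAP",
    "SummaryStatsError",
    "ColumnMapError",
    "read_summary_stats",
    "write_summary_stats",
]

VALID_ALLELES = frozenset("ACGT")

#: canonical field -> default header name
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "n": "N",
}

_REQUIRED_FIELDS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pvalue",
    "n",
)
_NUMERIC_FIELDS = ("pos", "eaf", "beta", "se", "pvalue", "n")


class SummaryStatsError(ValueError):
    """Raised for unrecoverable problems in a summary-statistics file."""


class ColumnMapError(SummaryStatsError):
    """A required column cannot be resolved from the header."""


@dataclass(frozen=True)
class SummaryRecord:
    """One SNP's association statistics in one GWAS.

    ``beta`` is the per effect-allele effect (log-odds for binary traits,
    trait units otherwise), ``se`` its standard error, ``eaf`` the
    effect-allele frequency (``None`` when unreported) and ``n`` the GWAS
    sample size.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float
    n: int

    @property
    def maf(self) -> float | None:
        """Minor-allele frequency, ``min(eaf, 1 - eaf)``; ``None`` if eaf is missing."""
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants, whose strand is ambiguous."""
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})

    def violations(self) -> list[str]:
        """Return the list of violated record invariants (empty when valid)."""
        problems: list[str] = []
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            problems.append("indel-or-multiallelic")
        elif self.effect_allele == self.other_allele:
            problems.append("identical alleles")
        if not self.se > 0:
            problems.append("nonpositive se")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            problems.append("eaf outside [0,1]")
        if self.pos < 1:
            problems.append("nonpositive position")
        if not (0.0 < self.pvalue <= 1.0):
            problems.append("pvalue outside (0,1]")
        if self.n <= 0:
            problems.append("nonpositive sample size")
        return problems


class ReadResult(NamedTuple):
    """Validated records plus per-row rejections ``(row, snp_id, reason)``."""

    records: list[SummaryRecord]
    dropped: list[tuple[int, str, str]]


def _resolve_columns(header: Sequence[str], column_map: Mapping[str, str]) -> dict[str, str]:
    resolved: dict[str, str] = {}
    for field in _REQUIRED_FIELDS:
        name = column_map.get(field, DEFAULT_COLUMN_MAP[field])
        if name not in header:
            raise ColumnMapError(
                f"required column {name!r} (field {field!r}) not found in header {list(header)}"
            )
        resolved[field] = name
    eaf_name = column_map.get("eaf", DEFAULT_COLUMN_MAP["eaf"])
    if eaf_name in header:
        resolved["eaf"] = eaf_name
    return resolved


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
) -> ReadResult:
    """Read a tab-delimited GWAS summary-statistics file.

    Rows violating record invariants (nonpositive SE, non-ACGT alleles,
    out-of-range frequencies or p-values ...) are returned in ``dropped``
    with their 1-based data-row number and a reason. Duplicate ``snp_id``
    entries keep the record with the smallest p-value; the rest are dropped
    with reason ``"duplicate-snp"``. Alleles are upper-cased on read.

    Raises
    ------
    ColumnMapError
        when a required column is absent from the header.
    SummaryStatsError
        when numeric columns contain unparseable values (the offending row
        numbers are listed in the message).
    """
    column_map = dict(column_map or {})
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = _resolve_columns(df.columns, column_map)

    # parse numerics up front so unparseable rows can be reported together;
    # Python's float() is used for exact round-trip of written values
    def _parse(text: str) -> float:
        try:
            return float(text)
        except ValueError:
            return None  # type: ignore[return-value]

    parsed: dict[str, pd.Series] = {}
    bad_rows: set[int] = set()
    for field in _NUMERIC_FIELDS:
        if field not in cols:
            continue
        raw = df[cols[field]].str.strip()
        blank = raw == ""
        num = raw.map(_parse)
        unparseable = num.isna() & ~blank if field == "eaf" else num.isna()
        bad_rows.update(int(i) + 1 for i in df.index[unparseable])
        parsed[field] = num.astype(float)
    if bad_rows:
        raise SummaryStatsError(
            f"unparseable numeric values in rows {sorted(bad_rows)} of {path}"
        )

    records: list[SummaryRecord] = []
    dropped: list[tuple[int, str, str]] = []
    rownums: list[int] = []
    for i in df.index:
        row = i + 1  # 1-based data-row number
        snp = str(df.at[i, cols["snp_id"]]).strip()
        eaf = None
        if "eaf" in cols and not pd.isna(parsed["eaf"].iat[i]):
            eaf = float(parsed["eaf"].iat[i])
        rec = SummaryRecord(
            snp_id=snp,
            chrom=str(df.at[i, cols["chrom"]]).strip(),
            pos=int(parsed["pos"].iat[i]),
            effect_allele=str(df.at[i, cols["effect_allele"]]).strip().upper(),
            other_allele=str(df.at[i, cols["other_allele"]]).strip().upper(),
            eaf=eaf,
            beta=float(parsed["beta"].iat[i]),
            se=float(parsed["se"].iat[i]),
            pvalue=float(parsed["pvalue"].iat[i]),
            n=int(parsed["n"].iat[i]),
        )
        problems = rec.violations()
        if problems:
            dropped.append((row, snp, "; ".join(problems)))
        else:
            records.append(rec)
            rownums.append(row)

    records, rownums, dup_dropped = _dedupe(records, rownums)
    dropped.extend(dup_dropped)
    return ReadResult(records, dropped)


def _dedupe(
    records: list[SummaryRecord], rownums: list[int]
) -> tuple[list[SummaryRecord], list[int], list[tuple[int, str, str]]]:
    """Keep the smallest-p record per snp_id (first wins on ties)."""
    best: dict[str, int] = {}
    for idx, rec in enumerate(records):
        cur = best.get(rec.snp_id)
        if cur is None or rec.pvalue < records[cur].pvalue:
            best[rec.snp_id] = idx
    keep = set(best.values())
    dropped = [
        (rownums[i], r.snp_id, "duplicate-snp")
        for i, r in enumerate(records)
        if i not in keep
    ]
    kept = [r for i, r in enumerate(records) if i in keep]
    kept_rows = [rn for i, rn in enumerate(rownums) if i in keep]
    return kept, kept_rows, dropped


def write_summary_stats(
    records: Iterable[SummaryRecord],
    path,
    column_map: Mapping[str, str] | None = None,
) -> None:
    """Write records as a tab-delimited table using ``column_map`` headers."""
    column_map = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    rows = []
    for r in records:
        rows.append(
            {
                column_map["snp_id"]: r.snp_id,
                column_map["chrom"]: r.chrom,
                column_map["pos"]: r.pos,
                column_map["effect_allele"]: r.effect_allele,
                column_map["other_allele"]: r.other_allele,
                column_map["eaf"]: "" if r.eaf is None else repr(r.eaf),
                column_map["beta"]: repr(r.beta),
                column_map["se"]: repr(r.se),
                column_map["pvalue"]: repr(r.pvalue),
                column_map["n"]: r.n,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def reoriented(record: SummaryRecord) -> SummaryRecord:
    """Return the record expressed on its other allele (sign-flipped beta)."""
    return replace(
        record,
        effect_allele=record.other_allele,
        other_allele=record.effect_allele,
        eaf=None if record.eaf is None else 1.0 - record.eaf,
        beta=-record.beta,
    )
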