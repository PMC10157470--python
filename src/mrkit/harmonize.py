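"""Harmonizing exposure and outcome summary statistics.

Two-sample MR needs every SNP's exposure and outcome effects expressed for
the *same* effect allele. Outcome records are re-oriented onto the
exposure's effect allele: a swapped allele pair flips the sign of the
outcome beta, a strand-complemented pair is complemented first, and
palindromic (A/T, C/G) variants — where allele letters cannot resolve the
strand — are oriented by allele frequency or dropped when the frequency is
too close to 0.5 to be informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import SummaryRecord

__all__ = ["HarmonizedSet", "harmonize", "EmptyIntersectionError"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default MAF ceiling below which a palindromic SNP's strand is considered
#: resolvable by frequency (prevailing two-sample MR practice)
DEFAULT_PALINDROME_EAF_LIMIT = 0.42


class EmptyIntersectionError(ValueError):
    """Exposure and outcome share no SNPs."""


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs on a common effect-allele orientation.

    Arrays are aligned: element ``j`` of every array describes the same SNP,
    with effects expressed for the exposure's effect allele. ``eaf_x`` is
    NaN where the exposure frequency is unreported. ``dropped`` lists
    ``(snp_id, reason)`` for every shared SNP that could not be harmonized.
    """

    pair_label: str
    snp_id: np.ndarray
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    eaf_x: np.ndarray
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        for name in ("beta_x", "se_x", "beta_y", "se_y", "eaf_x"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if len({len(getattr(self, a)) for a in ("snp_id", "beta_x", "se_x", "beta_y", "se_y", "eaf_x")}) > 1:
            raise ValueError("harmonized arrays must have equal length")
        if len(set(self.snp_id)) != len(self.snp_id):
            raise ValueError("duplicate snp_id in harmonized set")
        if np.any(self.se_x <= 0) or np.any(self.se_y <= 0):
            raise ValueError("all standard errors must be positive")

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)

    def subset(self, mask) -> "HarmonizedSet":
        """Return a new set restricted to ``mask`` (boolean or index array)."""
        mask = np.asarray(mask)
        return HarmonizedSet(
            pair_label=self.pair_label,
            snp_id=self.snp_id[mask],
            beta_x=self.beta_x[mask],
            se_x=self.se_x[mask],
            beta_y=self.beta_y[mask],
            se_y=self.se_y[mask],
            eaf_x=self.eaf_x[mask],
            dropped=list(self.dropped),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_id,
                "beta_x": self.beta_x,
                "se_x": self.se_x,
                "beta_y": self.beta_y,
                "se_y": self.se_y,
                "eaf_x": self.eaf_x,
            }
        )

    def write(self, path, drop_path=None) -> None:
        """Write the harmonized table; optionally a drop-reason side file."""
        self.to_frame().to_csv(path, sep="\t", index=False)
        if drop_path is not None:
            pd.DataFrame(self.dropped, columns=["snp_id", "drop_reason"]).to_csv(
                drop_path, sep="\t", index=False
            )


def _match_orientation(exp: SummaryRecord, out: SummaryRecord) -> str | None:
    """How the outcome alleles map onto the exposure's: keep/flip/None."""
    ex = (exp.effect_allele, exp.other_allele)
    oy = (out.effect_allele, out.other_allele)
    comp = (_COMPLEMENT[out.effect_allele], _COMPLEMENT[out.other_allele])
    if oy == ex:
        return "keep"
    if oy == (ex[1], ex[0]):
        return "flip"
    if comp == ex:
        return "keep-complement"
    if comp == (ex[1], ex[0]):
        return "flip-complement"
    return None


def harmonize(
    exposure: list[SummaryRecord],
    outcome: list[SummaryRecord],
    palindrome_eaf_limit: float = DEFAULT_PALINDROME_EAF_LIMIT,
    pair_label: str = "exposure x outcome",
) -> HarmonizedSet:
    """Align outcome effects onto the exposure's effect alleles.

    Every SNP shared between the two inputs ends up exactly once in either
    the harmonized records or ``dropped``. Outcome betas are only ever
    sign-flipped, never rescaled. Palindromic SNPs are oriented by
    frequency: kept when both effect-allele frequencies fall on the same
    side of 0.5 and both minor-allele frequencies are below
    ``palindrome_eaf_limit``, dropped as ``"palindromic-ambiguous"``
    otherwise. SNPs whose alleles cannot be reconciled are dropped as
    ``"allele-mismatch"``; when the exposure or outcome frequency is
    missing, only exact or swapped (same-strand) allele matches are
    accepted.
    """
    exp_by_id = {r.snp_id: r for r in exposure}
    out_by_id = {r.snp_id: r for r in outcome}
    shared = [r.snp_id for r in exposure if r.snp_id in out_by_id]
    if not shared:
        raise EmptyIntersectionError(
            f"no shared SNPs between exposure ({len(exposure)} records) and "
            f"outcome ({len(outcome)} records) for {pair_label!r}"
        )

    ids: list[str] = []
    bx: list[float] = []
    sx: list[float] = []
    by: list[float] = []
    sy: list[float] = []
    fx: list[float] = []
    dropped: list[tuple[str, str]] = []

    for snp in shared:
        exp = exp_by_id[snp]
        out = out_by_id[snp]
        if exp.is_palindromic:
            # same-letter check: a palindromic pair only ever matches itself
            if {out.effect_allele, out.other_allele} != {exp.effect_allele, exp.other_allele}:
                dropped.append((snp, "allele-mismatch"))
                continue
            if exp.eaf is None or out.eaf is None:
                dropped.append((snp, "palindromic-ambiguous"))
                continue
            if (
                min(exp.eaf, 1 - exp.eaf) >= palindrome_eaf_limit
                or min(out.eaf, 1 - out.eaf) >= palindrome_eaf_limit
            ):
                dropped.append((snp, "palindromic-ambiguous"))
                continue
            # allele letters cannot resolve strand; orient by frequency:
            # the outcome's effect allele is taken to be the exposure's
            # when both frequencies fall on the same side of 0.5
            flip = (exp.eaf - 0.5) * (out.eaf - 0.5) < 0
        else:
            action = _match_orientation(exp, out)
            if action is None:
                dropped.append((snp, "allele-mismatch"))
                continue
            if action.endswith("complement") and (exp.eaf is None or out.eaf is None):
                # without frequencies a strand flip cannot be distinguished
                # from genotyping on the opposite strand; be conservative
                dropped.append((snp, "allele-mismatch"))
                continue
            flip = action.startswith("flip")
        ids.append(snp)
        bx.append(exp.beta)
        sx.append(exp.se)
        by.append(-out.beta if flip else out.beta)
        sy.append(out.se)
        fx.append(np.nan if exp.eaf is None else exp.eaf)

    return HarmonizedSet(
        pair_label=pair_label,
        snp_id=np.array(ids, dtype=object),
        beta_x=np.array(bx),
        se_x=np.array(sx),
        beta_y=np.array(by),
        se_y=np.array(sy),
        eaf_x=np.array(fx),
        dropped=dropped,
    )
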