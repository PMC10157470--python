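"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the statistical structure of summary-level GWAS
inputs to a two-sample MR study: per-SNP effect/SE pairs whose standard
errors follow the ``1/sqrt(2 maf (1-maf) n)`` approximation, a true causal
effect ``theta`` linking exposure and outcome effects, optional pleiotropy
regimes (balanced, directional, InSIDE-violating), planted outlier SNPs,
and optional LD blocks with an emitted pairwise r-squared table. Allele
columns are assigned so that configurable fractions of SNPs are
palindromic and are flipped between the two files, exercising
harmonization.

Default sample sizes follow the scale of large disease and imaging GWAS
meta-analyses (tens of thousands of subjects); the exposure is treated as
a continuous unit-variance trait, so effect sizes are interchangeable with
log-odds labels at the summary level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

from .harmonize import HarmonizedSet, harmonize
from .sumstats import SummaryRecord, write_summary_stats

__all__ = [
    "SimulationConfig",
    "simulate_effects",
    "simulate_harmonized",
    "simulate_pair",
    "simulate_study",
]

_PLEIOTROPY_MODES = ("none", "balanced", "directional", "inside_violating")


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic exposure-outcome pair.

    Each instrument's explained exposure variance is drawn uniformly from
    ``exposure_h2_range`` (per-SNP chi-square is about ``h2 * n_exposure``),
    emulating the wide effect-size dispersion of real instrument panels —
    a few major loci plus many moderate ones; with the defaults every
    instrument is genome-wide significant and strong (F >> 10), and the
    spread keeps exposure-side measurement error from diluting slope-based
    estimators. ``theta`` is the true causal effect in outcome units per
    exposure SD. Pleiotropy adds a direct SNP-outcome effect ``a_j``:
    ``balanced`` draws mean-zero, ``directional`` mean ``pleiotropy_mean``,
    ``inside_violating`` makes ``a_j`` proportional to the instrument
    effect (``a_j = pleiotropy_mean * b_j`` plus noise), violating InSIDE;
    ``pleiotropy_fraction`` restricts the regime to the first matching
    share of SNPs (invalid instruments). ``n_outliers`` SNPs have their
    outcome effect displaced by ``outlier_scale`` outcome-SEs.
    """

    n_snps: int = 50
    theta: float = 0.0
    n_exposure: int = 60000
    n_outcome: int = 51665
    maf_range: tuple[float, float] = (0.05, 0.40)
    exposure_h2_range: tuple[float, float] = (0.0005, 0.02)
    pleiotropy: str = "none"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_fraction: float = 1.0
    n_outliers: int = 0
    outlier_scale: float = 10.0
    ld_blocks: tuple[int, float] | None = None  # (n_blocks, within-block r2)
    palindromic_fraction: float = 0.1
    flipped_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.n_exposure <= 2 or self.n_outcome <= 2:
            raise ValueError("sample sizes must exceed 2")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie inside (0, 0.5], got {self.maf_range}")
        h_lo, h_hi = self.exposure_h2_range
        if not (0.0 < h_lo <= h_hi < 1.0):
            raise ValueError(
                f"exposure_h2_range must lie inside (0, 1), got {self.exposure_h2_range}"
            )
        if self.pleiotropy not in _PLEIOTROPY_MODES:
            raise ValueError(f"pleiotropy must be one of {_PLEIOTROPY_MODES}")
        if self.pleiotropy_sd < 0 or not (0.0 <= self.pleiotropy_fraction <= 1.0):
            raise ValueError("invalid pleiotropy parameters")


def _block_assignment(config: SimulationConfig) -> np.ndarray:
    """Contiguous block index per SNP (all singletons when LD is off)."""
    if config.ld_blocks is None:
        return np.arange(config.n_snps)
    n_blocks, _ = config.ld_blocks
    return np.minimum(np.arange(config.n_snps) * n_blocks // config.n_snps, n_blocks - 1)


def _correlated_noise(rng, blocks: np.ndarray, r: float, size: int) -> np.ndarray:
    """Unit-variance noise with equicorrelation ``r`` within each block."""
    shared = rng.standard_normal(blocks.max() + 1)[blocks]
    own = rng.standard_normal(size)
    return np.sqrt(r) * shared + np.sqrt(1 - r) * own


def simulate_effects(config: SimulationConfig, rng=None) -> dict:
    """Draw all latent and observed per-SNP quantities.

    Returns a truth record with, per SNP: ``maf``, true instrument effect
    ``b`` (positive: effect alleles are exposure-increasing), pleiotropic
    effect ``a``, true outcome effect ``c = theta*b + a`` (plus outlier
    displacement), standard errors, observed effects and p-values, and the
    masks describing outliers, LD blocks, palindromic alleles and
    between-file flips.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    j = config.n_snps
    maf = rng.uniform(*config.maf_range, size=j)
    het = 2.0 * maf * (1.0 - maf)
    h2 = rng.uniform(*config.exposure_h2_range, size=j)
    b = np.sqrt(h2 / het)
    se_x = 1.0 / np.sqrt(het * config.n_exposure)
    se_y = 1.0 / np.sqrt(het * config.n_outcome)

    a = np.zeros(j)
    n_aff = int(round(config.pleiotropy_fraction * j))
    affected = np.zeros(j, dtype=bool)
    affected[:n_aff] = True
    if config.pleiotropy == "balanced":
        a[affected] = rng.normal(0.0, config.pleiotropy_sd, size=n_aff)
    elif config.pleiotropy == "directional":
        a[affected] = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=n_aff)
    elif config.pleiotropy == "inside_violating":
        a[affected] = b[affected] * (
            config.pleiotropy_mean + rng.normal(0.0, config.pleiotropy_sd, size=n_aff)
        )

    c = config.theta * b + a
    outlier_idx = np.array([], dtype=int)
    if config.n_outliers:
        outlier_idx = rng.choice(j, size=config.n_outliers, replace=False)
        signs = rng.choice([-1.0, 1.0], size=config.n_outliers)
        c = c.copy()
        c[outlier_idx] += signs * config.outlier_scale * se_y[outlier_idx]

    blocks = _block_assignment(config)
    if config.ld_blocks is not None:
        r = float(np.sqrt(config.ld_blocks[1]))
        noise_x = _correlated_noise(rng, blocks, r, j)
        noise_y = _correlated_noise(rng, blocks, r, j)
    else:
        noise_x = rng.standard_normal(j)
        noise_y = rng.standard_normal(j)
    beta_x = b + se_x * noise_x
    beta_y = c + se_y * noise_y

    palindromic = rng.random(j) < config.palindromic_fraction
    flipped = rng.random(j) < config.flipped_fraction

    return {
        "theta": config.theta,
        "maf": maf,
        "b": b,
        "a": a,
        "c": c,
        "se_x": se_x,
        "se_y": se_y,
        "beta_x": beta_x,
        "beta_y": beta_y,
        "p_x": np.clip(2 * stats.norm.sf(np.abs(beta_x / se_x)), 1e-300, 1.0),
        "p_y": np.clip(2 * stats.norm.sf(np.abs(beta_y / se_y)), 1e-300, 1.0),
        "outlier_idx": outlier_idx,
        "blocks": blocks,
        "affected": affected,
        "palindromic": palindromic,
        "flipped": flipped,
    }


def simulate_harmonized(config: SimulationConfig, pair_label: str = "sim") -> tuple[HarmonizedSet, dict]:
    """Fast path: the harmonized set implied by a draw, skipping allele
    bookkeeping (exact equivalent of simulating files and harmonizing when
    every SNP is resolvable)."""
    truth = simulate_effects(config)
    j = config.n_snps
    hset = HarmonizedSet(
        pair_label=pair_label,
        snp_id=np.array([f"rs{k + 1}" for k in range(j)], dtype=object),
        beta_x=truth["beta_x"],
        se_x=truth["se_x"],
        beta_y=truth["beta_y"],
        se_y=truth["se_y"],
        eaf_x=truth["maf"],
    )
    return hset, truth


def _records_from_truth(
    truth: dict,
    config: SimulationConfig,
    snp_ids: list[str],
    chroms: list[str],
    positions: list[int],
) -> tuple[list[SummaryRecord], list[SummaryRecord]]:
    """Materialize exposure and outcome SummaryRecords with allele columns."""
    exposure: list[SummaryRecord] = []
    outcome: list[SummaryRecord] = []
    for k in range(config.n_snps):
        pal = bool(truth["palindromic"][k])
        ea, oa = ("A", "T") if pal else ("A", "G")
        eaf = float(truth["maf"][k])  # effect allele is the minor, exposure-increasing allele
        exposure.append(
            SummaryRecord(
                snp_id=snp_ids[k],
                chrom=chroms[k],
                pos=positions[k],
                effect_allele=ea,
                other_allele=oa,
                eaf=eaf,
                beta=float(truth["beta_x"][k]),
                se=float(truth["se_x"][k]),
                pvalue=float(truth["p_x"][k]),
                n=config.n_exposure,
            )
        )
        flip = bool(truth["flipped"][k])
        outcome.append(
            SummaryRecord(
                snp_id=snp_ids[k],
                chrom=chroms[k],
                pos=positions[k],
                effect_allele=oa if flip else ea,
                other_allele=ea if flip else oa,
                eaf=1.0 - eaf if flip else eaf,
                beta=float(-truth["beta_y"][k] if flip else truth["beta_y"][k]),
                se=float(truth["se_y"][k]),
                pvalue=float(truth["p_y"][k]),
                n=config.n_outcome,
            )
        )
    return exposure, outcome


def _positions(config: SimulationConfig, start_snp: int = 0) -> tuple[list[str], list[int]]:
    """Chromosome/position layout: independent SNPs far apart, LD-block
    members within 100 kb of each other."""
    blocks = _block_assignment(config)
    chroms: list[str] = []
    positions: list[int] = []
    within: dict[int, int] = {}
    for k in range(config.n_snps):
        blk = int(blocks[k]) + start_snp
        chroms.append(str(blk % 22 + 1))
        offset = within.get(blk, 0)
        within[blk] = offset + 1
        positions.append(1 + (blk // 22) * 20_000_000 + offset * 50_000)
    return chroms, positions


def ld_pairs_from_truth(truth: dict, config: SimulationConfig, snp_ids: list[str]) -> dict:
    """Within-block pairwise r-squared entries implied by the LD config."""
    if config.ld_blocks is None:
        return {}
    r2 = config.ld_blocks[1]
    pairs = {}
    blocks = truth["blocks"]
    for i in range(config.n_snps):
        for j in range(i + 1, config.n_snps):
            if blocks[i] == blocks[j]:
                pairs[(snp_ids[i], snp_ids[j])] = r2
    return pairs


def simulate_pair(
    config: SimulationConfig,
) -> tuple[list[SummaryRecord], list[SummaryRecord], dict]:
    """Simulate one exposure GWAS and one outcome GWAS over shared SNPs.

    Returns ``(exposure_records, outcome_records, truth)``; the truth dict
    records every latent quantity (see :func:`simulate_effects`) plus the
    snp ids. Re-harmonizing the two record lists recovers the generated
    effect pairs exactly for every resolvable SNP.
    """
    truth = simulate_effects(config)
    snp_ids = [f"rs{k + 1}" for k in range(config.n_snps)]
    chroms, positions = _positions(config)
    exposure, outcome = _records_from_truth(truth, config, snp_ids, chroms, positions)
    truth = {**truth, "snp_id": snp_ids}
    return exposure, outcome, truth


def simulate_study(
    n_exposures: int,
    n_outcomes: int,
    planted_effects: dict[tuple[int, int], float],
    config: SimulationConfig,
    out_dir=None,
    overwrite: bool = False,
) -> dict:
    """Simulate a full exposure-by-outcome study grid.

    Each exposure gets its own disjoint instrument panel; each outcome file
    contains every panel's SNPs, with a nonzero causal effect only at the
    cells named in ``planted_effects`` (keys are 0-based
    ``(exposure_index, outcome_index)``). When ``out_dir`` is given, writes
    ``exposure_<i>.tsv``, ``outcome_<j>.tsv``, ``truth.yaml`` and — when LD
    blocks are enabled — ``ld.tsv``. Returns a manifest with the theta
    grid, file names and per-cell truth.
    """
    for (i, jj) in planted_effects:
        if not (0 <= i < n_exposures and 0 <= jj < n_outcomes):
            raise ValueError(f"planted cell {(i, jj)} outside the {n_exposures}x{n_outcomes} grid")
    out_path = None
    if out_dir is not None:
        out_path = Path(out_dir)
        if out_path.exists() and any(out_path.iterdir()) and not overwrite:
            raise FileExistsError(f"{out_path} exists and is not empty (pass overwrite=True)")
        out_path.mkdir(parents=True, exist_ok=True)

    root = np.random.default_rng(config.seed)
    theta_grid = np.zeros((n_exposures, n_outcomes))
    for (i, jj), th in planted_effects.items():
        theta_grid[i, jj] = th

    exposures: dict[str, list[SummaryRecord]] = {}
    outcomes: dict[str, list[SummaryRecord]] = {str(jj): [] for jj in range(n_outcomes)}
    ld_pairs: dict = {}
    manifest: dict = {
        "n_exposures": n_exposures,
        "n_outcomes": n_outcomes,
        "theta": theta_grid.tolist(),
        "seed": config.seed,
        "exposures": {},
        "outcomes": {},
    }

    for i in range(n_exposures):
        # one latent instrument panel per exposure, shared across outcomes
        panel_seed = int(root.integers(2**31 - 1))
        panel_rng = np.random.default_rng(panel_seed)
        base = simulate_effects(
            SimulationConfig(**{**asdict(config), "theta": 0.0, "seed": panel_seed}), panel_rng
        )
        snp_ids = [f"rs{i + 1}_{k + 1}" for k in range(config.n_snps)]
        chroms, positions = _positions(config, start_snp=i * max(config.n_snps, 1))
        cfg_i = SimulationConfig(**{**asdict(config), "theta": 0.0, "seed": panel_seed})
        exp_records, _ = _records_from_truth(base, cfg_i, snp_ids, chroms, positions)
        exposures[str(i)] = exp_records
        ld_pairs.update(ld_pairs_from_truth(base, cfg_i, snp_ids))
        manifest["exposures"][str(i)] = {"file": f"exposure_{i}.tsv", "n_snps": config.n_snps}

        for jj in range(n_outcomes):
            th = float(theta_grid[i, jj])
            c = th * base["b"] + base["a"]
            beta_y = c + base["se_y"] * panel_rng.standard_normal(config.n_snps)
            out_truth = {
                **base,
                "beta_y": beta_y,
                "c": c,
                "p_y": np.clip(2 * stats.norm.sf(np.abs(beta_y / base["se_y"])), 1e-300, 1.0),
            }
            _, out_records = _records_from_truth(out_truth, cfg_i, snp_ids, chroms, positions)
            outcomes[str(jj)].extend(out_records)

    if out_path is not None:
        for i in range(n_exposures):
            write_summary_stats(exposures[str(i)], out_path / f"exposure_{i}.tsv")
        for jj in range(n_outcomes):
            write_summary_stats(outcomes[str(jj)], out_path / f"outcome_{jj}.tsv")
            manifest["outcomes"][str(jj)] = {"file": f"outcome_{jj}.tsv"}
        if ld_pairs:
            with open(out_path / "ld.tsv", "w") as fh:
                fh.write("snp_a\tsnp_b\tr2\n")
                for (a, b), v in sorted(ld_pairs.items()):
                    fh.write(f"{a}\t{b}\t{v}\n")
            manifest["ld_file"] = "ld.tsv"
        with open(out_path / "truth.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
    else:
        for jj in range(n_outcomes):
            manifest["outcomes"][str(jj)] = {"file": None}

    manifest["exposure_records"] = exposures
    manifest["outcome_records"] = outcomes
    manifest["ld_pairs"] = ld_pairs
    return manifest
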