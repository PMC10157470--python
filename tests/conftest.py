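import numpy as np
import pytest

from mrkit import HarmonizedSet, SummaryRecord


def make_record(
    snp_id="rs1",
    chrom="1",
    pos=1000,
    ea="A",
    oa="G",
    eaf=0.3,
    beta=0.1,
    se=0.01,
    pvalue=1e-10,
    n=60000,
):
    return SummaryRecord(
        snp_id=snp_id,
        chrom=chrom,
        pos=pos,
        effect_allele=ea,
        other_allele=oa,
        eaf=eaf,
        beta=beta,
        se=se,
        pvalue=pvalue,
        n=n,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def proportional_set():
    """Three SNPs exactly on the line beta_y = 0.2 * beta_x (Q = 0)."""
    return HarmonizedSet(
        pair_label="prop",
        snp_id=np.array(["rs1", "rs2", "rs3"], dtype=object),
        beta_x=np.array([0.1, 0.2, 0.3]),
        se_x=np.array([0.01, 0.01, 0.01]),
        beta_y=np.array([0.02, 0.04, 0.06]),
        se_y=np.array([0.01, 0.01, 0.01]),
        eaf_x=np.array([0.2, 0.3, 0.4]),
    )


@pytest.fixture
def random_set_factory():
    """Random harmonized sets of a given size, seeded."""

    def _make(j=10, seed=0, theta=0.2, noise=0.01):
        rng = np.random.default_rng(seed)
        bx = rng.uniform(0.03, 0.2, j) * rng.choice([-1, 1], j)
        sy = rng.uniform(0.005, 0.02, j)
        by = theta * bx + rng.normal(0, noise, j)
        return HarmonizedSet(
            pair_label=f"rand-{seed}",
            snp_id=np.array([f"rs{i}" for i in range(j)], dtype=object),
            beta_x=bx,
            se_x=rng.uniform(0.002, 0.01, j),
            beta_y=by,
            se_y=sy,
            eaf_x=rng.uniform(0.05, 0.45, j),
        )

    return _make
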