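"""Instrument selection: p-filter, clumping, strength, exclusions."""

import numpy as np
import pytest

from mrkit import (
    LDTable,
    SelectionConfig,
    apply_exclusions,
    compute_strength,
    filter_by_pvalue,
    ld_clump,
    select_instruments,
)


def test_pvalue_filter_strict_and_relaxed(record_factory):
    records = [
        record_factory(snp_id="rs1", pvalue=1e-9),
        record_factory(snp_id="rs2", pvalue=4e-8),
        record_factory(snp_id="rs3", pvalue=6e-8),
    ]
    assert [r.snp_id for r in filter_by_pvalue(records, 5e-8)] == ["rs1", "rs2"]
    # the relaxed threshold used for sparse exposures keeps all three
    assert [r.snp_id for r in filter_by_pvalue(records, 5e-6)] == ["rs1", "rs2", "rs3"]
    assert filter_by_pvalue([], 5e-8) == []


def test_greedy_clump_example(record_factory):
    a = record_factory(snp_id="rsA", pos=1_000_000, pvalue=1e-10)
    b = record_factory(snp_id="rsB", pos=1_050_000, pvalue=1e-9)  # 50 kb from A
    c = record_factory(snp_id="rsC", pos=1_080_000, pvalue=1e-8)  # 80 kb from A
    ld = LDTable({("rsA", "rsB"): 0.5, ("rsA", "rsC"): 0.0001})
    kept = ld_clump([a, b, c], ld, SelectionConfig())
    assert [r.snp_id for r in kept] == ["rsA", "rsC"]


def test_clump_ignores_other_chromosomes(record_factory):
    a = record_factory(snp_id="rsA", chrom="1", pos=1000, pvalue=1e-10)
    b = record_factory(snp_id="rsB", chrom="2", pos=1000, pvalue=1e-9)
    ld = LDTable({("rsA", "rsB"): 0.99})
    kept = ld_clump([a, b], ld, SelectionConfig())
    assert {r.snp_id for r in kept} == {"rsA", "rsB"}


def test_clump_against_brute_force_checker(record_factory):
    """On block-structured r2, no retained pair may violate the joint
    (distance, r2) rule and every removed SNP must trace to a retained
    index with a smaller p-value."""
    rng = np.random.default_rng(42)
    n = 20
    records = []
    for i in range(n):
        records.append(
            record_factory(
                snp_id=f"rs{i:02d}",
                chrom="1",
                pos=1 + i * 500_000,  # all within one 10 Mb window of neighbours
                pvalue=float(rng.uniform(1e-12, 1e-8)),
            )
        )
    pairs = {}
    for i in range(n):
        for j in range(i + 1, n):
            if i // 5 == j // 5:  # 4 blocks of 5
                pairs[(f"rs{i:02d}", f"rs{j:02d}")] = 0.8
    ld = LDTable(pairs)
    cfg = SelectionConfig()
    kept = ld_clump(records, ld, cfg)
    kept_ids = {r.snp_id for r in kept}
    by_id = {r.snp_id: r for r in records}
    window = cfg.clump_kb * 1000

    for a in kept:
        for b in kept:
            if a.snp_id < b.snp_id:
                violates = (
                    a.chrom == b.chrom
                    and abs(a.pos - b.pos) <= window
                    and ld.r2(a.snp_id, b.snp_id) >= cfg.clump_r2
                )
                assert not violates, (a.snp_id, b.snp_id)
    for r in records:
        if r.snp_id not in kept_ids:
            culprits = [
                k
                for k in kept
                if k.chrom == r.chrom
                and abs(k.pos - r.pos) <= window
                and ld.r2(k.snp_id, r.snp_id) >= cfg.clump_r2
                and (k.pvalue, k.snp_id) < (r.pvalue, r.snp_id)
            ]
            assert culprits, r.snp_id


def test_clump_order_invariant(record_factory):
    rng = np.random.default_rng(7)
    records = [
        record_factory(snp_id=f"rs{i}", pos=1 + i * 100_000, pvalue=float(rng.uniform(1e-10, 1e-8)))
        for i in range(12)
    ]
    ld = LDTable({(f"rs{i}", f"rs{j}"): 0.3 for i in range(12) for j in range(i + 1, 12)})
    ref = [r.snp_id for r in ld_clump(records, ld, SelectionConfig())]
    for seed in range(3):
        shuffled = list(records)
        np.random.default_rng(seed).shuffle(shuffled)
        assert [r.snp_id for r in ld_clump(shuffled, ld, SelectionConfig())] == ref


def test_strength_maf_formula(record_factory):
    # direct arithmetic from the two printed formulas:
    # R2 = 2*0.5*0.5*0.01 = 0.005 ; F = (0.005/0.995) * 9998
    rec = record_factory(eaf=0.5, beta=0.1, n=10000)
    s = compute_strength(rec, k=1)
    assert s.formula_used == "maf_formula"
    assert s.r2 == pytest.approx(0.005)
    assert s.f_stat == pytest.approx((0.005 / 0.995) * 9998, rel=1e-12)
    assert s.f_stat == pytest.approx(50.24, abs=0.01)


def test_strength_se_fallback(record_factory):
    rec = record_factory(eaf=None, beta=0.1, se=0.01, n=1000)
    s = compute_strength(rec, k=1)
    assert s.formula_used == "se_formula"
    assert s.r2 == pytest.approx(0.01 / (0.01 + 0.0001 * 1000))
    assert s.r2 == pytest.approx(0.0909, abs=1e-4)


def test_strength_zero_effect(record_factory):
    s = compute_strength(record_factory(eaf=0.3, beta=0.0), k=1)
    assert s.r2 == 0.0 and s.f_stat == 0.0


def test_strength_monotone_in_effect_size(record_factory):
    """F strictly increases with |beta| under both formulas."""
    betas = [0.01, 0.05, 0.1, 0.2]
    for eaf in (0.3, None):
        fs = [compute_strength(record_factory(eaf=eaf, beta=b), k=3).f_stat for b in betas]
        assert all(x < y for x, y in zip(fs, fs[1:]))


def test_strength_degenerate_sample(record_factory):
    with pytest.raises(ValueError, match="degenerate"):
        compute_strength(record_factory(n=3), k=2)


def test_exclusions_including_confounder_snps(record_factory):
    # rsIDs associated with second phenotypes are removed with reasons
    records = [
        record_factory(snp_id="rs6062496"),
        record_factory(snp_id="rs4276914"),
        record_factory(snp_id="rs999"),
    ]
    exclusions = {
        "rs6062496": "second phenotype: obesity",
        "rs4276914": "second phenotype: hypertension",
    }
    kept, removed = apply_exclusions(records, exclusions)
    assert [r.snp_id for r in kept] == ["rs999"]
    assert dict(removed)["rs6062496"] == "second phenotype: obesity"

    kept2, removed2 = apply_exclusions(records, {})
    assert kept2 == records and removed2 == []

    kept3, removed3 = apply_exclusions(records, {"rs_missing": "obesity"})
    assert kept3 == records
    assert removed3 == [("rs_missing", "not found (obesity)")]


def test_select_instruments_no_attrition_when_no_rule_binds(record_factory):
    records = [
        record_factory(snp_id=f"rs{i:02d}", chrom=str(i % 22 + 1), pos=1 + i * 20_000_000, pvalue=1e-10)
        for i in range(30)
    ]
    instruments, strengths, audit = select_instruments(records, None, SelectionConfig())
    assert len(instruments) == 30
    counts = dict(audit)
    assert counts["p_filter"] == counts["ld_clump"] == counts["weak_iv"] == 30
    assert all(s.f_stat_single > 10 for s in strengths)


def test_select_instruments_drops_weak_snp(record_factory):
    """A SNP whose own F-statistic is below 10 is screened out."""
    strong = [
        record_factory(snp_id=f"rs{i:02d}", chrom=str(i % 22 + 1), pos=1 + i * 20_000_000)
        for i in range(29)
    ]
    # by-hand F for the weak SNP: R2 = 2*.3*.7*.01^2 = 4.2e-5,
    # F = (R2/(1-R2)) * (30-2)/1 ~ 1.2e-3 << 10
    weak = record_factory(snp_id="rs_weak", chrom="22", pos=5, beta=0.01, se=0.5, n=30, pvalue=1e-9)
    instruments, strengths, audit = select_instruments(strong + [weak], None, SelectionConfig())
    assert len(instruments) == 29
    assert "rs_weak" not in {r.snp_id for r in instruments}
    assert dict(audit)["weak_iv"] == 29


def test_select_instruments_exclusion_before_strength(record_factory):
    """k in the reported strengths reflects the post-exclusion set size."""
    records = [
        record_factory(snp_id=f"rs{i:02d}", chrom=str(i % 22 + 1), pos=1 + i * 20_000_000)
        for i in range(10)
    ]
    cfg = SelectionConfig(exclusion_list={"rs00": "second phenotype: smoking"})
    instruments, strengths, _ = select_instruments(records, None, cfg)
    assert len(instruments) == 9
    # scripted stage-by-stage oracle: strengths recomputed at k = 9
    expected = compute_strength(records[1], k=9)
    got = next(s for s in strengths if s.snp_id == "rs01")
    assert got.f_stat == pytest.approx(expected.f_stat)


def test_select_output_subset_of_input(record_factory):
    records = [
        record_factory(snp_id=f"rs{i}", chrom=str(i % 22 + 1), pos=1 + i * 20_000_000,
                       pvalue=1e-10 if i % 2 else 1e-6)
        for i in range(10)
    ]
    instruments, _, _ = select_instruments(records, None, SelectionConfig())
    assert {r.snp_id for r in instruments} <= {r.snp_id for r in records}


def test_ld_table_rejects_out_of_range_r2():
    with pytest.raises(ValueError):
        LDTable({("a", "b"): 1.5})


def test_ld_table_file_formats(tmp_path):
    three = tmp_path / "ld3.tsv"
    three.write_text("snp_a\tsnp_b\tr2\nrs1\trs2\t0.5\n")
    t = LDTable.from_file(three)
    assert t.r2("rs2", "rs1") == 0.5 and t.r2("rs1", "rs3") == 0.0

    square = tmp_path / "ldsq.tsv"
    square.write_text("id\trs1\trs2\nrs1\t1.0\t0.25\nrs2\t0.25\t1.0\n")
    t2 = LDTable.from_file(square)
    assert t2.r2("rs1", "rs2") == 0.25
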