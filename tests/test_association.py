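"""Carrier tables, odds ratios, max(T) permutation tests and subtype analysis."""

from itertools import combinations

import numpy as np
import pytest
import scipy.sparse as sp
from scipy import stats

from esocnv import (
    GenomicInterval,
    SampleMeta,
    carrier_table,
    classify_nested_carriers,
    gene_test,
    keep_one_per_family,
    max_t_carrier_permutation,
    odds_ratio_ci,
    segmental_test,
    subtype_chisq,
)
from esocnv.association import CarrierTable
from esocnv.core import AnnotatedRegion

from conftest import make_call, make_samples


# ---------------------------------------------------------------------------
# Carrier tables
# ---------------------------------------------------------------------------


def test_carrier_table_counts_planted_carriers():
    samples = make_samples(1614, 3922)
    locus = GenomicInterval("2", 87428677, 87965359)
    calls = [
        make_call(f"CASE{i:04d}", "2", 87430000, 87900000, 3, 100, 99) for i in range(23)
    ] + [make_call(f"CTRL{i:04d}", "2", 87500000, 87960000, 3, 100, 99) for i in range(4)]
    t = carrier_table(calls, samples, locus, "DUP")
    assert (t.a, t.b, t.c, t.d) == (23, 1591, 4, 3918)


def test_carrier_table_no_calls_and_distinct_counting():
    samples = make_samples(5, 5)
    locus = GenomicInterval("1", 1000, 2000)
    t = carrier_table([], samples, locus, "DUP")
    assert (t.a, t.b, t.c, t.d) == (0, 5, 0, 5)
    two = [
        make_call("CASE0000", "1", 900, 1500, 3, 10, 9),
        make_call("CASE0000", "1", 1600, 2400, 3, 10, 9),
    ]
    t = carrier_table(two, samples, locus, "DUP")
    assert t.a == 1  # one sample with two overlapping calls counts once
    # class matters: a deletion at the locus is not a duplication carrier
    t = carrier_table(two, samples, locus, "DEL")
    assert t.a == 0


def test_carrier_requires_at_least_one_bp_overlap():
    samples = make_samples(2, 2)
    locus = GenomicInterval("1", 1000, 2000)
    adjacent = [make_call("CASE0000", "1", 2001, 3000, 3, 10, 9)]
    assert carrier_table(adjacent, samples, locus, "DUP").a == 0
    touching = [make_call("CASE0000", "1", 2000, 3000, 3, 10, 9)]
    assert carrier_table(touching, samples, locus, "DUP").a == 1


# ---------------------------------------------------------------------------
# Odds ratios
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "cells,expected,digits",
    [
        ((23, 1591, 4, 3918), 14.16, 2),
        ((27, 1587, 6, 3916), 11.1, 1),
        ((64, 1550, 18, 3904), 8.96, 2),
        ((28, 1550, 18, 3904), 3.918, 3),
    ],
)
def test_reported_odds_ratios_from_carrier_counts(cells, expected, digits):
    res = odds_ratio_ci(CarrierTable(*cells))
    assert round(res.value, digits) == expected
    assert res.lower < res.value < res.upper
    assert not res.haldane


def test_balanced_table_or_one_with_symmetric_ci():
    res = odds_ratio_ci(CarrierTable(10, 10, 10, 10))
    assert res.value == pytest.approx(1.0)
    assert res.lower * res.upper == pytest.approx(1.0)  # symmetric on the log scale


def test_swapping_rows_gives_reciprocal_or():
    a = odds_ratio_ci(CarrierTable(23, 1591, 4, 3918))
    b = odds_ratio_ci(CarrierTable(4, 3918, 23, 1591))
    assert a.value == pytest.approx(1 / b.value)


def test_zero_cell_is_haldane_corrected_and_flagged():
    res = odds_ratio_ci(CarrierTable(5, 95, 0, 100))
    assert res.haldane and np.isfinite(res.value)
    assert res.value == pytest.approx((5.5 * 100.5) / (95.5 * 0.5))


# ---------------------------------------------------------------------------
# Exhaustive-enumeration oracles for the permutation machinery
# ---------------------------------------------------------------------------


def _exact_pointwise(carrier_sets, case_idx, n, locus):
    """Enumerate all case-label assignments; chi-square via scipy (independent
    of the production statistic path)."""

    def chi2(members, case_set):
        a = len(members & case_set)
        K = len(members)
        n1 = len(case_set)
        table = np.array([[a, n1 - a], [K - a, (n - n1) - (K - a)]])
        if min(table.sum(axis=0)) == 0 or min(table.sum(axis=1)) == 0:
            return 0.0
        return stats.chi2_contingency(table.T, correction=False)[0]

    observed = chi2(carrier_sets[locus], set(case_idx))
    n1 = len(case_idx)
    count = total = 0
    for combo in combinations(range(n), n1):
        t = chi2(carrier_sets[locus], set(combo))
        count += t >= observed - 1e-9
        total += 1
    return count / total


def test_segmental_pointwise_p_matches_enumeration_small_cohort():
    """4 cases (3 carriers) vs 4 controls (0 carriers): empirical p at 1e5
    permutations within 0.02 of the exact p over all 70 assignments."""
    samples = make_samples(4, 4)
    calls = [make_call(f"CASE000{i}", "1", 100_000, 200_000, 3, 20, 99) for i in range(3)]
    res = segmental_test(calls, samples, "DUP", n_perm=100_000, seed=3)
    assert len(res) == 1
    members = {0, 1, 2}
    exact = _exact_pointwise({0: members}, range(4), 8, 0)
    assert res[0].p_point == pytest.approx(exact, abs=0.02)
    assert res[0].table.a == 3 and res[0].table.c == 0


def test_balanced_carriers_are_null():
    samples = make_samples(4, 4)
    calls = [
        make_call(sid, "1", 100_000, 200_000, 3, 20, 99)
        for sid in ("CASE0000", "CASE0001", "CTRL0000", "CTRL0001")
    ]
    res = segmental_test(calls, samples, "DUP", n_perm=20_000, seed=0)
    assert res[0].p_point > 0.5


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_pointwise_p_matches_enumeration_random_cohorts(seed):
    """Random <=12-sample cohorts with several loci: pointwise p within
    binomial Monte-Carlo error of exact enumeration."""
    rng = np.random.default_rng(seed)
    n_case, n_ctrl = 6, 6
    samples = make_samples(n_case, n_ctrl)
    ids = [s.sample_id for s in samples]
    calls = []
    loci_pos = [(100_000, 200_000), (400_000, 500_000), (800_000, 950_000)]
    for lo, hi in loci_pos:
        for i in np.flatnonzero(rng.random(12) < 0.35):
            calls.append(make_call(ids[i], "1", lo, hi, 3, 20, 99))
    if not calls:
        pytest.skip("empty draw")
    n_perm = 40_000
    res = segmental_test(calls, samples, "DUP", n_perm=n_perm, seed=seed + 50)
    carrier_sets = {}
    for r in res:
        carrier_sets[r.name] = {
            i for i, s in enumerate(samples)
            if any(
                c.sample_id == s.sample_id and c.interval.start <= r.locus.end
                and c.interval.end >= r.locus.start for c in calls
            )
        }
    for r in res:
        exact = _exact_pointwise(carrier_sets, range(n_case), 12, r.name)
        tol = 4.5 * np.sqrt(exact * (1 - exact) / n_perm) + 2 / n_perm
        assert abs(r.p_point - exact) <= tol


def test_corrected_p_dominates_pointwise_everywhere():
    rng = np.random.default_rng(9)
    samples = make_samples(15, 15)
    ids = [s.sample_id for s in samples]
    calls = []
    for k in range(5):
        lo = 100_000 + 300_000 * k
        for i in np.flatnonzero(rng.random(30) < 0.3):
            calls.append(make_call(ids[i], "1", lo, lo + 150_000, 3, 20, 99))
    for seed in (0, 7):
        res = segmental_test(calls, samples, "DUP", n_perm=2000, seed=seed)
        assert res
        for r in res:
            assert r.p_corr >= r.p_point
            assert r.p_point >= 1 / 2001  # never below the attainable floor


def test_empty_class_returns_empty_result():
    samples = make_samples(3, 3)
    calls = [make_call("CASE0000", "1", 100_000, 200_000, 1, 20, 99)]  # deletions only
    assert segmental_test(calls, samples, "DUP", n_perm=100, seed=0) == []


def test_identical_carrier_sets_collapse_into_one_segment():
    samples = make_samples(5, 5)
    # two carriers with identical breakpoints: start and end positions share
    # one carrier set -> a single reported segment spanning both
    calls = [
        make_call("CASE0000", "1", 100_000, 200_000, 3, 20, 99),
        make_call("CASE0001", "1", 100_000, 200_000, 3, 20, 99),
    ]
    res = segmental_test(calls, samples, "DUP", n_perm=200, seed=0)
    assert len(res) == 1
    assert (res[0].locus.start, res[0].locus.end) == (100_000, 200_000)
    # breakpoint jitter splits the carrier sets into several segments
    calls.append(make_call("CASE0002", "1", 150_000, 260_000, 3, 20, 99))
    res = segmental_test(calls, samples, "DUP", n_perm=200, seed=0)
    assert len(res) == 3


def test_max_t_family_wise_error_control_under_global_null():
    """Top-locus corrected p >= 0.05 in >= 93% of 100 null cohorts."""
    n, n_case, L = 40, 20, 6
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(20_000 + seed)
        rows, cols = [], []
        for l in range(L):
            for i in np.flatnonzero(rng.random(n) < 0.25):
                rows.append(l)
                cols.append(i)
        carriers = sp.csr_matrix(
            (np.ones(len(rows), np.float32), (rows, cols)), shape=(L, n)
        )
        case_mask = np.zeros(n, bool)
        case_mask[:n_case] = True
        res = max_t_carrier_permutation(carriers, case_mask, n_perm=500, seed=seed)
        if res.p_corr.size and res.p_corr.min() >= 0.05:
            hits += 1
    assert hits >= 93


def test_minimum_attainable_p_reached_by_overwhelming_signal():
    samples = make_samples(200, 400)
    calls = [make_call(f"CASE{i:04d}", "1", 100_000, 300_000, 3, 40, 99) for i in range(40)]
    calls += [make_call("CTRL0000", "1", 700_000, 800_000, 3, 20, 99)]
    n_perm = 5000
    res = segmental_test(calls, samples, "DUP", n_perm=n_perm, seed=2)
    best = min(res, key=lambda r: r.p_corr)
    assert best.p_corr == pytest.approx(1 / (n_perm + 1))
    assert best.p_point == pytest.approx(1 / (n_perm + 1))


# ---------------------------------------------------------------------------
# Gene test
# ---------------------------------------------------------------------------


def _gene(chrom="4", lo=100_000, hi=200_000, exons=((100_000, 110_000), (180_000, 200_000))):
    return AnnotatedRegion(
        GenomicInterval(chrom, lo, hi), "G1",
        exons=[GenomicInterval(chrom, a, b) for a, b in exons],
    )


def test_gene_test_conditions_on_exonic_overlap():
    samples = make_samples(6, 6)
    gene = _gene()
    intronic = [make_call("CASE0000", "4", 120_000, 170_000, 3, 20, 99)]
    assert gene_test(intronic, samples, [gene], "DUP", 200, 0) == []
    exonic = [make_call("CASE0000", "4", 95_000, 105_000, 3, 20, 99)]  # exon 1 only
    res = gene_test(exonic, samples, [gene], "DUP", 200, 0)
    assert len(res) == 1 and res[0].name == "G1" and res[0].table.a == 1


def test_gene_without_exons_is_skipped(caplog):
    import logging

    samples = make_samples(3, 3)
    bare = AnnotatedRegion(GenomicInterval("4", 1000, 2000), "NOEXON")
    calls = [make_call("CASE0000", "4", 900, 2100, 3, 20, 99)]
    with caplog.at_level(logging.WARNING, logger="esocnv"):
        assert gene_test(calls, samples, [bare], "DUP", 100, 0) == []
    assert "NOEXON" in caplog.text


def test_gene_test_recovers_planted_exonic_risk_duplication():
    rng = np.random.default_rng(4)
    samples = make_samples(200, 400)
    gene = _gene()
    null_gene = _gene(lo=600_000, hi=700_000, exons=((600_000, 610_000),))
    null_gene.name = "G0"
    calls = []
    for i, s in enumerate(samples):
        p = 0.2 if s.is_case else 0.01
        if rng.random() < p:
            calls.append(make_call(s.sample_id, "4", 95_000, 115_000, 3, 20, 99))
        if rng.random() < 0.05:
            calls.append(make_call(s.sample_id, "4", 595_000, 620_000, 3, 20, 99))
    n_perm = 2000
    res = gene_test(calls, samples, [gene, null_gene], "DUP", n_perm, seed=0)
    by_name = {r.name: r for r in res}
    assert by_name["G1"].p_corr == pytest.approx(1 / (n_perm + 1))
    assert by_name["G0"].p_corr > 0.05


# ---------------------------------------------------------------------------
# Nested carriers, subtype chi-square, relatedness
# ---------------------------------------------------------------------------


def test_classify_nested_carriers_labels():
    full = GenomicInterval("10", 47049547, 47703870)
    distinguishing = GenomicInterval("10", 47049547, 47400000)
    samples = make_samples(3, 1)
    calls = [
        make_call("CASE0000", "10", 47049547, 47703870, 3, 100, 99),  # spans everything
        make_call("CASE0001", "10", 47420000, 47700000, 3, 50, 99),  # shared segment only
    ]
    labels = classify_nested_carriers(calls, samples, full, distinguishing)
    assert labels["CASE0000"] == "full"
    assert labels["CASE0001"] == "partial"
    assert labels["CASE0002"] == "none"
    assert labels["CTRL0000"] == "none"


def test_nested_partial_or_matches_reported_value():
    """Partial-vs-noncarrier table (28, 1550, 18, 3904) gives OR 3.92; the
    reference excludes full carriers (1614 - 36 - 28 = 1550)."""
    t = CarrierTable(28, 1614 - 36 - 28, 18, 3922 - 0 - 18)
    assert round(odds_ratio_ci(t).value, 2) == 3.92


def test_distinguishing_region_must_be_nested():
    full = GenomicInterval("10", 1000, 2000)
    with pytest.raises(ValueError, match="outside"):
        classify_nested_carriers([], [], full, GenomicInterval("10", 500, 1500))


def test_subtype_chisq_df_and_degenerate_cases():
    table_4x3 = np.array([[10, 5, 30], [8, 6, 20], [2, 4, 10], [6, 6, 16]])
    stat, df, p = subtype_chisq(table_4x3)
    assert df == 6
    # table proportional to its margins: statistic 0, p = 1
    outer = np.outer([1, 2, 3], [4, 5, 6])
    stat, df, p = subtype_chisq(outer)
    assert stat == pytest.approx(0.0, abs=1e-9)
    assert p == pytest.approx(1.0)


def test_subtype_chisq_closed_form_2x2():
    # margins 30/30 each way, expected 15 per cell: chi2 = 4 * 25/15
    stat, df, p = subtype_chisq([[10, 20], [20, 10]])
    assert df == 1
    assert stat == pytest.approx(4 * 25 / 15)
    assert p == pytest.approx(stats.chi2.sf(4 * 25 / 15, 1))


def test_subtype_chisq_zero_margin_is_error():
    with pytest.raises(ValueError, match="margin"):
        subtype_chisq([[0, 0], [5, 5]])
    with pytest.raises(ValueError, match="margin"):
        subtype_chisq([[0, 5], [0, 5]])


def test_keep_one_per_family_prefers_lowest_lrr_sd():
    s1 = SampleMeta("A", "case", "infantile", "FAM1", 0.99, 0.20, 0.0, 0.001)
    s2 = SampleMeta("B", "case", "infantile", "FAM1", 0.99, 0.12, 0.0, 0.001)
    s3 = SampleMeta("C", "case", "accommodative", "FAM2", 0.99, 0.15, 0.0, 0.001)
    s4 = SampleMeta("D", "control", "none", None, 0.99, 0.30, 0.0, 0.001)
    kept = keep_one_per_family([s1, s2, s3, s4])
    assert [s.sample_id for s in kept] == ["B", "C", "D"]


def test_association_survives_relative_removal():
    """A real signal carried consistently within families stays significant
    after keeping one sample per family."""
    rng = np.random.default_rng(6)
    samples = []
    calls = []
    for i in range(120):
        fam = f"F{i // 2:03d}"  # 60 families of 2
        s = SampleMeta(f"CASE{i:03d}", "case", "nonaccommodative", fam, 0.99,
                       float(rng.uniform(0.1, 0.25)), 0.0, 0.001)
        samples.append(s)
    for j in range(240):
        samples.append(SampleMeta(f"CTRL{j:03d}", "control", "none", None, 0.99, 0.15, 0.0, 0.001))
    carrier_fams = {f"F{k:03d}" for k in range(12)}  # 20% of case families carry
    for s in samples:
        if s.family_id in carrier_fams:
            calls.append(make_call(s.sample_id, "1", 100_000, 250_000, 3, 25, 99))
    full = segmental_test(calls, samples, "DUP", 2000, seed=1)
    subset = keep_one_per_family(samples)
    assert len([s for s in subset if s.is_case]) == 60
    ids = {s.sample_id for s in subset}
    res = segmental_test([c for c in calls if c.sample_id in ids], subset, "DUP", 2000, seed=1)
    assert min(r.p_corr for r in full) == pytest.approx(1 / 2001)
    assert min(r.p_corr for r in res) == pytest.approx(1 / 2001)
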