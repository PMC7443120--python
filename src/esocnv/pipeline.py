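"""End-to-end study pipeline on a synthetic cohort.

Runs the full chain the analysis is built from: intensity simulation ->
GC-wave adjustment -> dual-HMM calling -> fragment merging -> consensus
intersection -> sample QC -> call filtering -> control-frequency filtering ->
burden statistics -> segmental (and optionally gene-based) max(T) association.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .association import AssociationResult, gene_test, segmental_test
from .burden import BurdenComparison, BurdenSummary, compare_burden, summarize_burden
from .core import CnvCall, SampleMeta, logger, overlap_bp, GenomicInterval
from .curation import (
    FilterThresholds,
    QcThresholds,
    control_frequency_filter,
    filter_calls,
    intersect_two_callsets,
    merge_adjacent_fragments,
    per_sample_call_counts,
    sample_qc_filter,
)
from .hmm import caller_params, gc_adjust_lrr_batch, segment_with_profiles
from .simulate import CohortConfig, TruthCnv, generate_cohort, simulate_intensities_batch


@dataclass
class StudyResult:
    """Everything the downstream report needs from one pipeline run."""

    config: CohortConfig
    n_perm: int
    seed: int
    samples: list[SampleMeta]  # passing sample QC
    qc_report: dict[str, list[str]]
    truth: list[TruthCnv]
    consensus_calls: list[CnvCall]
    final_calls: list[CnvCall]
    removal_counts: dict[str, int]
    burden_summaries: list[BurdenSummary]
    burden: dict[str, BurdenComparison]
    segmental: dict[str, list[AssociationResult]]
    gene: dict[str, list[AssociationResult]] = field(default_factory=dict)


def run_study(
    config: CohortConfig,
    n_perm: int = 10_000,
    seed: int = 0,
    callers: Sequence[str] = ("callerA", "callerB"),
    classes: Sequence[str] = ("DUP", "DEL"),
    burden_metrics: Sequence[str] = ("total_len_dup", "total_len_del"),
    qc: QcThresholds = QcThresholds(),
    thresholds: FilterThresholds = FilterThresholds(),
    run_gene_test: bool = False,
    burden_n_perm: Optional[int] = None,
) -> StudyResult:
    """Simulate one cohort under ``config`` and run the complete analysis.

    ``seed`` drives the permutation streams (the cohort itself is drawn from
    ``config.seed``); deterministic given both.
    """
    t0 = time.time()
    mmap = config.marker_map()
    samples_all, truth = generate_cohort(config)
    ids = [s.sample_id for s in samples_all]
    lrr, baf = simulate_intensities_batch(samples_all, truth, mmap, config)
    lrr = gc_adjust_lrr_batch(lrr, mmap)
    logger.info("simulated %d samples x %d markers (%.1fs)", len(ids), len(mmap), time.time() - t0)

    raw_sets = segment_with_profiles(lrr, baf, ids, mmap, [caller_params(p) for p in callers])
    del lrr, baf
    merged: dict[str, list[CnvCall]] = {}
    for profile, raw in raw_sets.items():
        merged[profile] = merge_adjacent_fragments(raw, mmap, thresholds.merge_gap_frac)
        logger.info("%s: %d raw / %d merged calls (%.1fs)",
                    profile, len(raw), len(merged[profile]), time.time() - t0)

    if len(callers) == 2:
        consensus = intersect_two_callsets(merged[callers[0]], merged[callers[1]], mmap)
    else:
        consensus = merged[callers[0]]

    counts = per_sample_call_counts(consensus)
    passing, qc_report = sample_qc_filter(samples_all, counts, qc)
    passing_ids = {s.sample_id for s in passing}
    calls_qc = [c for c in consensus if c.sample_id in passing_ids]

    retained, removal = filter_calls(
        calls_qc, config.artifact_regions, config.common_catalog, thresholds, mmap
    )
    final = control_frequency_filter(retained, passing, thresholds)
    removal["control_frequency"] = len(retained) - len(final)
    removal["sample_qc"] = len(consensus) - len(calls_qc)
    logger.info("curation: %d consensus -> %d final calls %s (%.1fs)",
                len(consensus), len(final), removal, time.time() - t0)

    rng = np.random.default_rng(seed)

    summaries = summarize_burden(final, passing)
    burden_res: dict[str, BurdenComparison] = {}
    for metric in burden_metrics:
        burden_res[metric] = compare_burden(
            summaries, passing, metric,
            n_perm=burden_n_perm or min(n_perm, 10_000),
            seed=int(rng.integers(2**31)),
        )

    segmental: dict[str, list[AssociationResult]] = {}
    gene: dict[str, list[AssociationResult]] = {}
    for cls in classes:
        segmental[cls] = segmental_test(final, passing, cls, n_perm, int(rng.integers(2**31)))
        if run_gene_test and config.genes:
            gene[cls] = gene_test(final, passing, config.genes, cls, n_perm, int(rng.integers(2**31)))
    logger.info("association done (%.1fs)", time.time() - t0)

    return StudyResult(
        config=config, n_perm=n_perm, seed=seed, samples=passing, qc_report=qc_report,
        truth=truth, consensus_calls=consensus, final_calls=final, removal_counts=removal,
        burden_summaries=summaries, burden=burden_res, segmental=segmental, gene=gene,
    )


@dataclass
class RecoveryReport:
    recovered: list[str]
    missed: list[str]
    n_null_significant: int
    min_attainable_p: float


def evaluate_recovery(result: StudyResult, margin_bp: int = 15_000) -> RecoveryReport:
    """Which planted risk duplication loci reached the minimum attainable
    genome-wide corrected p, and whether any null locus did.

    A locus counts as recovered when some duplication segment overlapping it
    (within ``margin_bp``, covering breakpoint jitter) has corrected p equal
    to 1/(n_perm+1).  Significant segments overlapping no configured locus are
    null-locus false positives.
    """
    p_min = 1.0 / (result.n_perm + 1)
    eps = p_min * 1e-6
    config = result.config

    def expanded(iv: GenomicInterval) -> GenomicInterval:
        return GenomicInterval(iv.chrom, max(1, iv.start - margin_bp), iv.end + margin_bp)

    targets = [l for l in config.risk_loci if l.case_freq > l.control_freq]
    planted = [expanded(l.interval) for l in config.risk_loci]
    planted += [expanded(l.interval) for l in config.common_loci]

    dup_results = result.segmental.get("DUP", [])
    recovered, missed = [], []
    for locus in targets:
        hit = any(
            r.p_corr <= p_min + eps and r.locus is not None
            and overlap_bp(r.locus, expanded(locus.interval)) > 0
            for r in dup_results
        )
        (recovered if hit else missed).append(locus.name)

    n_null = 0
    for cls_results in result.segmental.values():
        for r in cls_results:
            if r.p_corr <= p_min + eps and r.locus is not None:
                if not any(overlap_bp(r.locus, iv) > 0 for iv in planted):
                    n_null += 1
    return RecoveryReport(recovered, missed, n_null, p_min)
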