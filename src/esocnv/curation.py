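"""Sample QC and the call-level filtering cascade.

Order of operations in the full pipeline:

1. ``sample_qc_filter``      -- exclude samples by intensity metrics / call count
2. ``merge_adjacent_fragments`` -- re-join CNVs artificially split by the HMM
3. ``intersect_two_callsets``   -- dual-caller consensus (intersection)
4. ``filter_calls``             -- size, marker, artifact, common-CNV and
                                   confidence filters (in that order)
5. ``control_frequency_filter`` -- drop events present in >1% of controls

Every filter is a contraction (output is a subset of input) and reports what
it removed.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .core import (
    AnnotatedRegion,
    CnvCall,
    GenomicInterval,
    MarkerMap,
    SampleMeta,
    intersect_interval,
    overlap_fraction,
)


@dataclass
class QcThresholds:
    """Sample-level exclusion thresholds (strict inequalities to pass)."""

    max_lrr_sd: float = 0.3
    max_abs_wf: float = 0.43
    max_baf_drift: float = 0.01
    min_call_rate: float = 0.98
    max_cnv_calls: int = 50

    def __post_init__(self):
        if min(self.max_lrr_sd, self.max_abs_wf, self.max_baf_drift, self.min_call_rate) <= 0:
            raise ValueError("QC thresholds must be positive")


@dataclass
class FilterThresholds:
    """Call-level filter parameters.

    Confidence cutoffs (25 for deletions, 10 for duplications) are expressed
    on this package's log-likelihood-ratio scale; they are configuration, not
    universal constants.
    """

    min_length_bp: int = 10_000
    min_markers: int = 10
    del_min_conf: float = 25.0
    dup_min_conf: float = 10.0
    artifact_overlap_frac: float = 0.5
    common_overlap_frac: float = 0.5
    common_freq: float = 0.10
    max_control_freq: float = 0.01
    presence_reciprocal_frac: float = 0.5
    merge_gap_frac: float = 0.2

    def __post_init__(self):
        for f in (
            self.artifact_overlap_frac,
            self.common_overlap_frac,
            self.presence_reciprocal_frac,
            self.merge_gap_frac,
        ):
            if not (0.0 < f <= 1.0):
                raise ValueError("overlap fractions must lie in (0, 1]")
        if self.min_length_bp <= 0 or self.min_markers < 1:
            raise ValueError("length/marker thresholds must be positive")


# ---------------------------------------------------------------------------
# Sample QC
# ---------------------------------------------------------------------------


def sample_qc_filter(
    samples: Sequence[SampleMeta],
    per_sample_call_counts: Mapping[str, int],
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[list[SampleMeta], dict[str, list[str]]]:
    """Split samples into passing and excluded, with per-sample failure reasons.

    A sample passes iff lrr_sd < 0.3 AND |wf| < 0.43 AND baf_drift < 0.01 AND
    call_rate >= 0.98 AND its CNV call count <= 50 (defaults).  A missing
    metric excludes with reason ``missing_metric``.
    """
    passing: list[SampleMeta] = []
    report: dict[str, list[str]] = {}
    for s in samples:
        reasons: list[str] = []
        metrics = {"lrr_sd": s.lrr_sd, "wf": s.wf, "baf_drift": s.baf_drift, "call_rate": s.call_rate}
        missing = [k for k, v in metrics.items() if v is None]
        if missing:
            reasons.append("missing_metric")
        else:
            if not s.lrr_sd < thresholds.max_lrr_sd:
                reasons.append("lrr_sd")
            if not abs(s.wf) < thresholds.max_abs_wf:
                reasons.append("wf")
            if not s.baf_drift < thresholds.max_baf_drift:
                reasons.append("baf_drift")
            if not s.call_rate >= thresholds.min_call_rate:
                reasons.append("call_rate")
        if per_sample_call_counts.get(s.sample_id, 0) > thresholds.max_cnv_calls:
            reasons.append("cnv_call_count")
        if reasons:
            report[s.sample_id] = reasons
        else:
            passing.append(s)
    return passing, report


# ---------------------------------------------------------------------------
# Fragment merging
# ---------------------------------------------------------------------------


def merge_adjacent_fragments(
    calls: Sequence[CnvCall],
    mmap: MarkerMap,
    gap_frac: float = 0.2,
    include_gap_in_denominator: bool = False,
) -> list[CnvCall]:
    """Re-join same-state fragments separated by a small marker gap.

    Two adjacent calls of the same sample, caller and copy state merge when
    the count of intervening markers is less than ``gap_frac`` times the total
    markers of the two segments (optionally including the gap in the
    denominator).  Iterated to a fixpoint; the merged call spans both
    fragments, counts the gap markers, and sums the two confidences.
    Overlapping same-group calls violate the caller contract and raise.
    """
    groups: dict[tuple, list[CnvCall]] = defaultdict(list)
    for c in calls:
        groups[(c.sample_id, c.caller, c.interval.chrom)].append(c)

    merged_all: list[CnvCall] = []
    for (sample_id, caller, chrom), group in groups.items():
        group = sorted(group, key=lambda c: c.interval.start)
        for a, b in zip(group, group[1:]):
            if b.interval.start <= a.interval.end:
                raise ValueError(
                    f"overlapping calls for sample {sample_id} caller {caller}: "
                    f"{a.interval} and {b.interval}"
                )
        positions = mmap.positions(chrom)
        changed = True
        while changed:
            changed = False
            out: list[CnvCall] = []
            i = 0
            while i < len(group):
                cur = group[i]
                if i + 1 < len(group):
                    nxt = group[i + 1]
                    if nxt.copy_state == cur.copy_state:
                        gap = int(
                            np.searchsorted(positions, nxt.interval.start, side="left")
                            - np.searchsorted(positions, cur.interval.end, side="right")
                        )
                        denom = cur.n_markers + nxt.n_markers
                        if include_gap_in_denominator:
                            denom += gap
                        if gap < gap_frac * denom:
                            cur = CnvCall(
                                sample_id=cur.sample_id,
                                interval=GenomicInterval(
                                    chrom, cur.interval.start, nxt.interval.end
                                ),
                                copy_state=cur.copy_state,
                                n_markers=cur.n_markers + nxt.n_markers + gap,
                                confidence=cur.confidence + nxt.confidence,
                                caller=cur.caller,
                            )
                            group[i + 1] = cur
                            i += 1
                            changed = True
                            continue
                out.append(cur)
                i += 1
            group = out
        merged_all.extend(group)
    merged_all.sort(key=lambda c: (c.sample_id, c.caller, c.interval))
    return merged_all


# ---------------------------------------------------------------------------
# Dual-caller consensus
# ---------------------------------------------------------------------------


def intersect_two_callsets(
    callsA: Sequence[CnvCall],
    callsB: Sequence[CnvCall],
    mmap: MarkerMap,
    strict_state: bool = False,
) -> list[CnvCall]:
    """Consensus by interval intersection of same-class overlapping calls.

    For every overlapping pair (one call from each caller, same sample) whose
    copy classes match (identical integer copy number when ``strict_state``),
    the shared span is emitted with marker count recomputed from the map,
    confidence = min of the pair, caller tag ``consensus``.  Calls present in
    only one callset contribute nothing.
    """

    def key(c: CnvCall):
        return (c.sample_id, c.interval.chrom)

    byA: dict[tuple, list[CnvCall]] = defaultdict(list)
    for c in callsA:
        byA[key(c)].append(c)
    byB: dict[tuple, list[CnvCall]] = defaultdict(list)
    for c in callsB:
        byB[key(c)].append(c)

    out: list[CnvCall] = []
    for k, la in byA.items():
        lb = byB.get(k)
        if not lb:
            continue
        for a in la:
            for b in lb:
                if strict_state:
                    if a.copy_state != b.copy_state:
                        continue
                elif a.copy_class != b.copy_class:
                    continue
                shared = intersect_interval(a.interval, b.interval)
                if shared is None:
                    continue
                n_markers = mmap.count_in(shared)
                if n_markers < 1:
                    continue
                # consensus copy state: agreement keeps it; disagreement within
                # a class takes the state closer to diploid (conservative)
                if a.copy_state == b.copy_state:
                    state = a.copy_state
                else:
                    state = max(a.copy_state, b.copy_state) if a.copy_class == "DEL" else min(
                        a.copy_state, b.copy_state
                    )
                out.append(
                    CnvCall(
                        sample_id=a.sample_id,
                        interval=shared,
                        copy_state=state,
                        n_markers=n_markers,
                        confidence=min(a.confidence, b.confidence),
                        caller="consensus",
                    )
                )
    out.sort(key=lambda c: (c.sample_id, c.interval))
    return out


# ---------------------------------------------------------------------------
# Call-level filters
# ---------------------------------------------------------------------------


def _region_tree(regions: Sequence[AnnotatedRegion]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for r in regions:
        iv = r.interval
        trees[iv.chrom].addi(iv.start, iv.end + 1, r)  # tree is half-open
    return trees


def _max_overlap_fraction(call: CnvCall, trees: Mapping[str, IntervalTree]) -> float:
    tree = trees.get(call.interval.chrom)
    if not tree:
        return 0.0
    best = 0.0
    for hit in tree.overlap(call.interval.start, call.interval.end + 1):
        best = max(best, overlap_fraction(call.interval, hit.data.interval, "of_a"))
    return best


def filter_calls(
    calls: Sequence[CnvCall],
    artifact_regions: Sequence[AnnotatedRegion],
    common_catalog: Sequence[AnnotatedRegion],
    thresholds: FilterThresholds = FilterThresholds(),
    mmap: Optional[MarkerMap] = None,
) -> tuple[list[CnvCall], dict[str, int]]:
    """Apply the call-level filter cascade and count removals per rule.

    Rules are applied sequentially in the order size, markers, artifact
    overlap, common-CNV overlap, confidence; a call is charged to the first
    rule it fails.  Catalog entries without a frequency are treated as common.
    """
    art_trees = _region_tree(artifact_regions)
    common = [
        r
        for r in common_catalog
        if (r.frequency if r.frequency is not None else 1.0) > thresholds.common_freq
    ]
    common_trees = _region_tree(common)

    removed = {"size": 0, "markers": 0, "artifact": 0, "common": 0, "confidence": 0}
    retained: list[CnvCall] = []
    for c in calls:
        if c.length < thresholds.min_length_bp:
            removed["size"] += 1
            continue
        if c.n_markers < thresholds.min_markers:
            removed["markers"] += 1
            continue
        if _max_overlap_fraction(c, art_trees) > thresholds.artifact_overlap_frac:
            removed["artifact"] += 1
            continue
        if _max_overlap_fraction(c, common_trees) > thresholds.common_overlap_frac:
            removed["common"] += 1
            continue
        min_conf = thresholds.del_min_conf if c.copy_class == "DEL" else thresholds.dup_min_conf
        if c.confidence < min_conf:
            removed["confidence"] += 1
            continue
        retained.append(c)
    return retained, removed


def cluster_calls_by_reciprocal_overlap(
    calls: Sequence[CnvCall], min_reciprocal: float = 0.5
) -> list[list[int]]:
    """Single-linkage clusters of same-class calls by reciprocal overlap.

    Returns clusters as lists of indices into ``calls``.
    """
    parent = list(range(len(calls)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    by_group: dict[tuple, list[int]] = defaultdict(list)
    for i, c in enumerate(calls):
        by_group[(c.interval.chrom, c.copy_class)].append(i)

    for idxs in by_group.values():
        idxs = sorted(idxs, key=lambda i: calls[i].interval.start)
        active: list[int] = []
        for i in idxs:
            ci = calls[i].interval
            active = [j for j in active if calls[j].interval.end >= ci.start]
            for j in active:
                if overlap_fraction(ci, calls[j].interval, "reciprocal") >= min_reciprocal:
                    union(i, j)
            active.append(i)

    clusters: dict[int, list[int]] = defaultdict(list)
    for i in range(len(calls)):
        clusters[find(i)].append(i)
    return list(clusters.values())


def control_frequency_filter(
    calls: Sequence[CnvCall],
    samples: Sequence[SampleMeta],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[CnvCall]:
    """Drop every call belonging to an event present in >1% of controls.

    Calls of the same class are clustered by reciprocal overlap (single
    linkage, >= ``presence_reciprocal_frac``); a cluster whose distinct
    control carriers exceed ``max_control_freq`` of all controls is removed
    entirely -- its case calls included.
    """
    controls = {s.sample_id for s in samples if s.group == "control"}
    n_controls = len(controls)
    if n_controls == 0:
        raise ValueError("control frequency filter requires at least one control sample")
    calls = list(calls)
    drop = set()
    for cluster in cluster_calls_by_reciprocal_overlap(calls, thresholds.presence_reciprocal_frac):
        carriers = {calls[i].sample_id for i in cluster} & controls
        if len(carriers) / n_controls > thresholds.max_control_freq:
            drop.update(cluster)
    return [c for i, c in enumerate(calls) if i not in drop]


def per_sample_call_counts(calls: Sequence[CnvCall]) -> Counter:
    return Counter(c.sample_id for c in calls)
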