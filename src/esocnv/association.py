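"""Locus-level case-control association with max(T) permutation correction.

The segmental (breakpoint) test evaluates carrier frequencies at every unique
call start/end position; the gene test counts carriers per gene, conditioned
on the call touching at least one exonic base pair.  Both use the Pearson
chi-square of the carrier 2x2 table as the per-locus statistic, with empirical
pointwise and genome-wide corrected p-values from label-swapping permutations:
each permutation re-assigns case/control labels (preserving group sizes), and
a locus's corrected p is the rank of its observed statistic within the
distribution of per-permutation maxima across all loci (max(T) family-wise
error control).  Empirical p-values use the (r+1)/(n+1) convention, so the
minimum attainable value is 1/(n_perm+1) -- 1e-6 at one million permutations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy import stats

from .core import (
    AnnotatedRegion,
    CnvCall,
    CnvClass,
    GenomicInterval,
    SampleMeta,
    logger,
    overlap_bp,
)

Alternative = Literal["two-sided", "case-enriched"]


# ---------------------------------------------------------------------------
# Carrier tables and odds ratios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CarrierTable:
    """2x2 carrier table: (a, b) case carriers/non-carriers, (c, d) controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("carrier table cells must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    @property
    def case_freq(self) -> float:
        return self.a / self.n_cases if self.n_cases else float("nan")

    @property
    def control_freq(self) -> float:
        return self.c / self.n_controls if self.n_controls else float("nan")


@dataclass(frozen=True)
class OddsRatio:
    value: float
    lower: float
    upper: float
    haldane: bool  # True when a 0.5 continuity correction was applied


def odds_ratio_ci(table: CarrierTable, level: float = 0.95) -> OddsRatio:
    """Odds ratio (a*d)/(b*c) with a Woolf (log-scale normal) confidence interval.

    Any zero cell triggers the Haldane-Anscombe 0.5 correction (flagged);
    degenerate tables are reported, never raised.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    haldane = min(a, b, c, d) == 0.0
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    return OddsRatio(or_, or_ * math.exp(-z * se), or_ * math.exp(z * se), haldane)


def carrier_table(
    calls: Sequence[CnvCall],
    samples: Sequence[SampleMeta],
    locus: GenomicInterval,
    cnv_class: CnvClass,
) -> CarrierTable:
    """Carrier counts at a locus: a sample carries iff it has >= 1 call of the
    class overlapping the locus by >= 1 bp (distinct samples counted once)."""
    carriers = {
        c.sample_id
        for c in calls
        if c.copy_class == cnv_class and overlap_bp(c.interval, locus) > 0
    }
    a = sum(1 for s in samples if s.is_case and s.sample_id in carriers)
    c_ = sum(1 for s in samples if not s.is_case and s.sample_id in carriers)
    n_cases = sum(1 for s in samples if s.is_case)
    n_controls = len(samples) - n_cases
    return CarrierTable(a, n_cases - a, c_, n_controls - c_)


# ---------------------------------------------------------------------------
# Permutation machinery
# ---------------------------------------------------------------------------


def _chi2_carrier_stat(
    a: np.ndarray, K: np.ndarray, n_case: int, n_total: int, alternative: Alternative
) -> np.ndarray:
    """Pearson chi-square of the carrier 2x2 from case-carrier counts ``a`` and
    total carrier counts ``K`` (margins fixed).  Vectorized; zero when a margin
    is empty.  For the one-sided variant, control-enriched tables score 0."""
    a = np.asarray(a, dtype=np.float64)
    K = np.asarray(K, dtype=np.float64)
    n_ctrl = n_total - n_case
    num = (a * n_total - n_case * K) ** 2 * n_total
    den = float(n_case) * n_ctrl * K * (n_total - K)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    if alternative == "case-enriched":
        t = np.where(a * n_total - n_case * K > 0, t, 0.0)
    return t


@dataclass
class MaxTResult:
    t_obs: np.ndarray
    p_point: np.ndarray
    p_corr: np.ndarray
    n_perm: int


def max_t_carrier_permutation(
    carriers: sp.csr_matrix,
    case_mask: np.ndarray,
    n_perm: int,
    seed: int,
    alternative: Alternative = "two-sided",
    batch: int = 2000,
) -> MaxTResult:
    """Label-swapping permutation test over a loci-by-samples carrier matrix.

    Permutations re-draw which samples are cases (group sizes preserved).
    Pointwise p at locus l = (#{perm: T*_l >= T_l} + 1) / (n_perm + 1);
    corrected p = (#{perm: max_l T*_l >= T_l} + 1) / (n_perm + 1).
    Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    case_mask = np.asarray(case_mask, dtype=bool)
    n = case_mask.size
    n_case = int(case_mask.sum())
    L = carriers.shape[0]
    K = np.asarray(carriers.sum(axis=1)).ravel()
    a_obs = carriers @ case_mask.astype(np.float64)
    t_obs = _chi2_carrier_stat(a_obs, K, n_case, n, alternative)
    if L == 0:
        return MaxTResult(t_obs, np.empty(0), np.empty(0), n_perm)

    rng = np.random.default_rng(seed)
    ge_point = np.zeros(L, dtype=np.int64)
    ge_corr = np.zeros(L, dtype=np.int64)
    base = np.zeros(n, dtype=np.float32)
    base[:n_case] = 1.0
    eps = 1e-9
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        labels = np.tile(base, (b, 1))
        rng.permuted(labels, axis=1, out=labels)
        a_star = carriers @ labels.T  # (L, b)
        t_star = _chi2_carrier_stat(a_star, K[:, None], n_case, n, alternative)
        ge_point += (t_star >= t_obs[:, None] - eps).sum(axis=1)
        col_max = t_star.max(axis=0)
        ge_corr += (col_max[None, :] >= t_obs[:, None] - eps).sum(axis=1)
        done += b
    p_point = (ge_point + 1) / (n_perm + 1)
    p_corr = (ge_corr + 1) / (n_perm + 1)
    return MaxTResult(t_obs, p_point, p_corr, n_perm)


# ---------------------------------------------------------------------------
# Segmental (breakpoint) and gene-based tests
# ---------------------------------------------------------------------------


@dataclass
class AssociationResult:
    """One tested locus: carrier counts, statistic and empirical p-values."""

    name: str
    locus: Optional[GenomicInterval]
    cnv_class: CnvClass
    statistic: float
    p_point: float
    p_corr: float
    table: CarrierTable

    def __post_init__(self):
        if self.p_corr < self.p_point - 1e-12:
            raise ValueError("corrected p cannot undercut the pointwise p")


def _sample_index(samples: Sequence[SampleMeta]) -> tuple[dict[str, int], np.ndarray]:
    index = {s.sample_id: i for i, s in enumerate(samples)}
    if len(index) != len(samples):
        raise ValueError("duplicate sample ids")
    case_mask = np.array([s.is_case for s in samples], dtype=bool)
    return index, case_mask


def _run_locus_test(
    loci: list[tuple[str, Optional[GenomicInterval], frozenset[int]]],
    samples: Sequence[SampleMeta],
    case_mask: np.ndarray,
    cnv_class: CnvClass,
    n_perm: int,
    seed: int,
    alternative: Alternative,
) -> list[AssociationResult]:
    if not loci:
        return []
    n = len(samples)
    rows, cols = [], []
    for li, (_, _, members) in enumerate(loci):
        rows.extend([li] * len(members))
        cols.extend(sorted(members))
    carriers = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.float32), (rows, cols)), shape=(len(loci), n)
    )
    res = max_t_carrier_permutation(carriers, case_mask, n_perm, seed, alternative)
    n_case = int(case_mask.sum())
    out = []
    for li, (name, locus, members) in enumerate(loci):
        a = sum(1 for i in members if case_mask[i])
        K = len(members)
        table = CarrierTable(a, n_case - a, K - a, (n - n_case) - (K - a))
        out.append(
            AssociationResult(
                name, locus, cnv_class,
                float(res.t_obs[li]), float(res.p_point[li]), float(res.p_corr[li]), table,
            )
        )
    return out


def segmental_test(
    calls: Sequence[CnvCall],
    samples: Sequence[SampleMeta],
    cnv_class: CnvClass,
    n_perm: int,
    seed: int,
    alternative: Alternative = "two-sided",
) -> list[AssociationResult]:
    """Breakpoint association test for one CNV class.

    Evaluation positions are the sorted unique call start/end positions; the
    carrier set at a position is every sample with a call covering it.
    Adjacent positions with identical carrier sets collapse into one reported
    segment.  Empty input returns an empty result.
    """
    index, case_mask = _sample_index(samples)
    cls_calls = [c for c in calls if c.copy_class == cnv_class and c.sample_id in index]
    if not cls_calls:
        return []

    by_chrom: dict[str, list[CnvCall]] = {}
    for c in cls_calls:
        by_chrom.setdefault(c.interval.chrom, []).append(c)

    loci: list[tuple[str, Optional[GenomicInterval], frozenset[int]]] = []
    for chrom in sorted(by_chrom):
        group = by_chrom[chrom]
        positions = sorted({p for c in group for p in (c.interval.start, c.interval.end)})
        carriers_at: list[set[int]] = [set() for _ in positions]
        pos_arr = np.array(positions)
        for c in group:
            lo = int(np.searchsorted(pos_arr, c.interval.start, side="left"))
            hi = int(np.searchsorted(pos_arr, c.interval.end, side="right"))
            si = index[c.sample_id]
            for k in range(lo, hi):
                carriers_at[k].add(si)
        # collapse adjacent positions with identical carrier sets
        start_k = 0
        for k in range(1, len(positions) + 1):
            if k == len(positions) or carriers_at[k] != carriers_at[start_k]:
                members = frozenset(carriers_at[start_k])
                if members:
                    iv = GenomicInterval(chrom, positions[start_k], positions[k - 1])
                    loci.append((str(iv), iv, members))
                start_k = k
    return _run_locus_test(loci, samples, case_mask, cnv_class, n_perm, seed, alternative)


def gene_test(
    calls: Sequence[CnvCall],
    samples: Sequence[SampleMeta],
    genes: Sequence[AnnotatedRegion],
    cnv_class: CnvClass,
    n_perm: int,
    seed: int,
    alternative: Alternative = "two-sided",
) -> list[AssociationResult]:
    """Gene-based association conditioned on exonic overlap.

    A call counts toward a gene iff it overlaps at least one exonic base pair;
    intron-only events are ignored.  Genes without exon models are skipped.
    """
    index, case_mask = _sample_index(samples)
    cls_calls = [c for c in calls if c.copy_class == cnv_class and c.sample_id in index]
    loci: list[tuple[str, Optional[GenomicInterval], frozenset[int]]] = []
    for gene in genes:
        if not gene.exons:
            logger.warning("gene %s has no exon model; skipped", gene.name)
            continue
        members = {
            index[c.sample_id]
            for c in cls_calls
            if any(overlap_bp(c.interval, ex) > 0 for ex in gene.exons)
        }
        if members:
            loci.append((gene.name, gene.interval, frozenset(members)))
    return _run_locus_test(loci, samples, case_mask, cnv_class, n_perm, seed, alternative)


# ---------------------------------------------------------------------------
# Nested-duplication carriers, subtype test, relatedness
# ---------------------------------------------------------------------------


def classify_nested_carriers(
    calls: Sequence[CnvCall],
    samples: Sequence[SampleMeta],
    full_locus: GenomicInterval,
    distinguishing_region: GenomicInterval,
    cnv_class: CnvClass = "DUP",
) -> dict[str, str]:
    """Label each sample ``full``, ``partial`` or ``none`` at a nested locus.

    ``full``: carries a call overlapping the distinguishing region (the part
    unique to the extended duplication); ``partial``: carries at the full
    locus but not the distinguishing region; ``none`` otherwise.
    """
    if not full_locus.contains(distinguishing_region):
        raise ValueError(
            f"distinguishing region {distinguishing_region} outside locus {full_locus}"
        )
    labels = {s.sample_id: "none" for s in samples}
    for c in calls:
        if c.copy_class != cnv_class or c.sample_id not in labels:
            continue
        if overlap_bp(c.interval, distinguishing_region) > 0:
            labels[c.sample_id] = "full"
        elif overlap_bp(c.interval, full_locus) > 0 and labels[c.sample_id] != "full":
            labels[c.sample_id] = "partial"
    return labels


def subtype_chisq(table) -> tuple[float, int, float]:
    """Pearson chi-square of a subtype-by-group count matrix.

    Returns (statistic, degrees of freedom, p).  A zero row or column margin
    is rejected with the offending margin named.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need a table with at least 2 rows and 2 columns")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    if (row_sums == 0).any():
        raise ValueError(f"zero row margin at row {int(np.argmin(row_sums))}")
    if (col_sums == 0).any():
        raise ValueError(f"zero column margin at column {int(np.argmin(col_sums))}")
    stat, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), int(df), float(p)


def keep_one_per_family(samples: Sequence[SampleMeta]) -> list[SampleMeta]:
    """Retain one sample per family: the one with the best (lowest) LRR_SD.

    Samples without a family id are always kept.  Mirrors the unrelated-subset
    re-test used to verify that association signals are not driven by
    relatedness.
    """
    best: dict[str, SampleMeta] = {}
    out: list[SampleMeta] = []
    for s in samples:
        if s.family_id is None:
            out.append(s)
            continue
        cur = best.get(s.family_id)
        if cur is None or (s.lrr_sd or np.inf) < (cur.lrr_sd or np.inf):
            best[s.family_id] = s
    out.extend(best.values())
    ids = {s.sample_id for s in out}
    return [s for s in samples if s.sample_id in ids]
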