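"""Per-sample rare-CNV burden summaries and case-control burden comparisons.

Burden differences are tested with two-sided label-swapping permutation tests
of the group mean difference (the same exchangeability framing as the
association stage), and size-partitioned risk is summarised as odds ratios of
"burden in bin" versus the rest of the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

from .association import CarrierTable, OddsRatio, odds_ratio_ci
from .core import CnvCall, SampleMeta


@dataclass
class BurdenSummary:
    """Counts, total and mean lengths (bp) of one sample's rare CNVs."""

    sample_id: str
    n_del: int = 0
    n_dup: int = 0
    total_len_del: int = 0
    total_len_dup: int = 0

    @property
    def mean_len_del(self) -> Optional[float]:
        return self.total_len_del / self.n_del if self.n_del else None

    @property
    def mean_len_dup(self) -> Optional[float]:
        return self.total_len_dup / self.n_dup if self.n_dup else None


BurdenMetric = Literal[
    "rate_del", "rate_dup", "total_len_del", "total_len_dup",
    "mean_len_del", "mean_len_dup", "pct_with_del", "pct_with_dup",
]


@dataclass
class BurdenComparison:
    metric: str
    case_mean: float
    control_mean: float
    p_value: float
    n_perm: int
    seed: int


def summarize_burden(
    calls: Sequence[CnvCall], samples: Sequence[SampleMeta]
) -> list[BurdenSummary]:
    """One summary per sample (zeros for samples without calls).

    A call referencing a sample not in ``samples`` is an error.
    """
    by_id = {s.sample_id: BurdenSummary(s.sample_id) for s in samples}
    for c in calls:
        summ = by_id.get(c.sample_id)
        if summ is None:
            raise ValueError(f"call references unknown sample {c.sample_id!r}")
        if c.copy_class == "DEL":
            summ.n_del += 1
            summ.total_len_del += c.length
        else:
            summ.n_dup += 1
            summ.total_len_dup += c.length
    return [by_id[s.sample_id] for s in samples]


def _metric_value(s: BurdenSummary, metric: str) -> Optional[float]:
    if metric == "rate_del":
        return float(s.n_del)
    if metric == "rate_dup":
        return float(s.n_dup)
    if metric == "total_len_del":
        return float(s.total_len_del)
    if metric == "total_len_dup":
        return float(s.total_len_dup)
    if metric == "mean_len_del":
        return s.mean_len_del
    if metric == "mean_len_dup":
        return s.mean_len_dup
    if metric == "pct_with_del":
        return float(s.n_del > 0)
    if metric == "pct_with_dup":
        return float(s.n_dup > 0)
    raise ValueError(f"unknown burden metric {metric!r}")


def compare_burden(
    summaries: Sequence[BurdenSummary],
    samples: Sequence[SampleMeta],
    metric: BurdenMetric,
    n_perm: int = 100_000,
    seed: int = 0,
    batch: int = 2000,
) -> BurdenComparison:
    """Two-sided label-swapping permutation test of the case-control mean
    difference for one burden metric.

    Samples for which the metric is undefined (mean length with zero calls)
    are excluded; the permutation swaps labels among the remaining samples,
    preserving group sizes.  Deterministic given ``seed``.
    """
    if len(summaries) != len(samples):
        raise ValueError("summaries and samples must align")
    vals, mask = [], []
    for summ, s in zip(summaries, samples):
        if summ.sample_id != s.sample_id:
            raise ValueError("summaries and samples must align by sample id")
        v = _metric_value(summ, metric)
        if v is not None:
            vals.append(v)
            mask.append(s.is_case)
    if not vals:
        raise ValueError(f"metric {metric!r} undefined for every sample")
    x = np.asarray(vals, dtype=np.float64)
    case = np.asarray(mask, dtype=bool)
    n1, n0 = int(case.sum()), int((~case).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("need at least 2 samples per group with a defined metric")

    total = x.sum()
    t_obs = x[case].mean() - x[~case].mean()

    rng = np.random.default_rng(seed)
    base = np.zeros(x.size, dtype=np.float64)
    base[:n1] = 1.0
    ge = 0
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        labels = np.tile(base, (b, 1))
        rng.permuted(labels, axis=1, out=labels)
        case_sums = labels @ x
        t_star = case_sums / n1 - (total - case_sums) / n0
        ge += int((np.abs(t_star) >= abs(t_obs) - 1e-12).sum())
        done += b
    p = (ge + 1) / (n_perm + 1)
    return BurdenComparison(metric, float(x[case].mean()), float(x[~case].mean()), p, n_perm, seed)


BinKind = Literal["total_dup", "total_del", "total_all", "count_dup", "count_del"]


@dataclass
class BurdenBinRow:
    """One burden bin: exposed-vs-rest 2x2 table with OR, Woolf CI, Fisher p."""

    lo: float
    hi: float  # inf for the open top bin
    table: CarrierTable
    odds: Optional[OddsRatio]
    fisher_p: float
    empty_exposed: bool


def _bin_value(s: BurdenSummary, kind: BinKind) -> float:
    if kind == "total_dup":
        return float(s.total_len_dup)
    if kind == "total_del":
        return float(s.total_len_del)
    if kind == "total_all":
        return float(s.total_len_del + s.total_len_dup)
    if kind == "count_dup":
        return float(s.n_dup)
    if kind == "count_del":
        return float(s.n_del)
    raise ValueError(f"unknown burden bin kind {kind!r}")


def burden_bin_odds(
    summaries: Sequence[BurdenSummary],
    samples: Sequence[SampleMeta],
    bins: Sequence[float],
    kind: BinKind = "total_dup",
) -> list[BurdenBinRow]:
    """Partition samples by burden and report per-bin case-control odds ratios.

    ``bins`` are strictly increasing thresholds; bin i spans [bins[i],
    bins[i+1]) and the last bin is open-ended.  Exposed = samples whose burden
    falls in the bin; reference = all other samples, so each row's table sums
    to the cohort size.  Zero-cell tables get the flagged Haldane-corrected
    odds ratio; an empty exposed set yields a flagged row without an OR.
    """
    edges = [float(b) for b in bins]
    if any(b2 <= b1 for b1, b2 in zip(edges, edges[1:])) or not edges:
        raise ValueError("bins must be non-empty and strictly increasing")
    by_id = {s.sample_id: summ for summ, s in zip(summaries, samples)}
    if len(by_id) != len(samples):
        raise ValueError("summaries and samples must align")
    values = np.array([_bin_value(summ, kind) for summ in summaries])
    case = np.array([s.is_case for s in samples])
    n_cases, n_controls = int(case.sum()), int((~case).sum())

    rows = []
    spans = list(zip(edges, edges[1:] + [np.inf]))
    for lo, hi in spans:
        exposed = (values >= lo) & (values < hi)
        a = int((exposed & case).sum())
        c = int((exposed & ~case).sum())
        table = CarrierTable(a, n_cases - a, c, n_controls - c)
        if a + c == 0:
            rows.append(BurdenBinRow(lo, hi, table, None, 1.0, True))
            continue
        odds = odds_ratio_ci(table)
        _, fisher_p = stats.fisher_exact([[a, n_cases - a], [c, n_controls - c]])
        rows.append(BurdenBinRow(lo, hi, table, odds, float(fisher_p), False))
    return rows
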