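"""Domain types, coordinate conventions and file I/O for SNP-array CNV analysis.

Conventions used throughout the package
---------------------------------------
* Genomic coordinates are **1-based inclusive**: an interval ``chrom:start-end``
  has ``length = end - start + 1``.  BED input/output converts at the boundary
  (BED is 0-based half-open).
* Chromosome labels are plain strings without a ``chr`` prefix; readers strip a
  leading ``chr`` (case-insensitive).
* Copy states are integers in ``{0, 1, 3, 4}``; the diploid state 2 never
  appears in a call.  States 0/1 form the deletion class (``DEL``), 3/4 the
  duplication class (``DUP``).

All tabular formats are plain TSV with a header row; see the reader docstrings
for the column contracts.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("esocnv")

DEL_STATES = frozenset({0, 1})
DUP_STATES = frozenset({3, 4})
VALID_STATES = DEL_STATES | DUP_STATES

CnvClass = Literal["DEL", "DUP"]


def copy_class(copy_state: int) -> CnvClass:
    """Map an integer copy state to its deletion/duplication class."""
    if copy_state in DEL_STATES:
        return "DEL"
    if copy_state in DUP_STATES:
        return "DUP"
    raise ValueError(f"copy state {copy_state!r} is not a CNV state (expected 0, 1, 3 or 4)")


def normalize_chrom(label: object) -> str:
    """Strip a leading 'chr' prefix and return the bare chromosome label."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if not s:
        raise ValueError("empty chromosome label")
    return s


def chrom_sort_key(chrom: str):
    """Natural ordering: numeric chromosomes first, then X, Y, others."""
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome-anchored 1-based inclusive span; the unit of overlap algebra."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"interval end {self.end} precedes start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @classmethod
    def parse(cls, text: str) -> "GenomicInterval":
        m = re.fullmatch(r"(\w+):(\d+)-(\d+)", text.strip())
        if m is None:
            raise ValueError(f"cannot parse interval {text!r} (expected chrom:start-end)")
        return cls(m.group(1), int(m.group(2)), int(m.group(3)))


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Base pairs shared by two 1-based inclusive intervals (0 when disjoint)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def overlap_fraction(
    a: GenomicInterval, b: GenomicInterval, mode: Literal["of_a", "reciprocal"] = "of_a"
) -> float:
    """Overlap of ``a`` and ``b`` as a fraction.

    ``of_a``       : shared bp / length(a) -- the ">50% of the call" rule.
    ``reciprocal`` : min(shared/len(a), shared/len(b)) -- the symmetric
                     criterion for treating two calls as the same event.
    """
    ov = overlap_bp(a, b)
    if ov == 0:
        return 0.0
    if mode == "of_a":
        return ov / a.length
    if mode == "reciprocal":
        return min(ov / a.length, ov / b.length)
    raise ValueError(f"unknown overlap mode {mode!r}")


def intersect_interval(a: GenomicInterval, b: GenomicInterval) -> Optional[GenomicInterval]:
    """The shared span of two intervals, or None when disjoint."""
    if overlap_bp(a, b) == 0:
        return None
    return GenomicInterval(a.chrom, max(a.start, b.start), min(a.end, b.end))


class MarkerMap:
    """Ordered SNP-array marker grid: (marker_id, chrom, pos, gc).

    Markers are stored sorted by (chromosome, position); positions are strictly
    increasing within a chromosome and marker ids are unique.
    """

    REQUIRED = ("marker_id", "chrom", "pos", "gc")

    def __init__(self, df: pd.DataFrame):
        df = df.loc[:, list(self.REQUIRED)].copy()
        df["chrom"] = df["chrom"].map(normalize_chrom)
        df["pos"] = df["pos"].astype(np.int64)
        df["gc"] = df["gc"].astype(float)
        if ((df["gc"] < 0) | (df["gc"] > 1)).any():
            raise ValueError("gc fractions must lie in [0, 1]")
        if df["marker_id"].duplicated().any():
            dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r}")
        order = sorted(range(len(df)), key=lambda i: (chrom_sort_key(df["chrom"].iat[i]), df["pos"].iat[i]))
        if order != list(range(len(df))):
            logger.warning("marker map not sorted by (chrom, pos); sorting")
            df = df.iloc[order]
        df = df.reset_index(drop=True)
        for chrom, sub in df.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                i = int(np.flatnonzero(np.diff(pos) <= 0)[0])
                raise ValueError(
                    f"duplicate or non-increasing position on chromosome {chrom} near {pos[i]}"
                )
        self.df = df
        self._slices: dict[str, slice] = {}
        start = 0
        for chrom, sub in df.groupby("chrom", sort=False):
            self._slices[chrom] = slice(start, start + len(sub))
            start += len(sub)
        self._pos = df["pos"].to_numpy()
        self._gc = df["gc"].to_numpy()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, int, float]]) -> "MarkerMap":
        df = pd.DataFrame(records, columns=list(cls.REQUIRED))
        return cls(df)

    # -- basic accessors ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_markers(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> list[str]:
        return list(self._slices)

    def chrom_slice(self, chrom: str) -> slice:
        return self._slices[normalize_chrom(chrom)]

    def positions(self, chrom: str) -> np.ndarray:
        return self._pos[self.chrom_slice(chrom)]

    def gc(self, chrom: str | None = None) -> np.ndarray:
        if chrom is None:
            return self._gc
        return self._gc[self.chrom_slice(chrom)]

    @property
    def marker_ids(self) -> pd.Series:
        return self.df["marker_id"]

    # -- coordinate lookups -------------------------------------------------

    def global_range(self, interval: GenomicInterval) -> tuple[int, int]:
        """Global row indices [i, j) of markers with start <= pos <= end."""
        sl = self._slices.get(interval.chrom)
        if sl is None:
            return (0, 0)
        pos = self._pos[sl]
        i = int(np.searchsorted(pos, interval.start, side="left"))
        j = int(np.searchsorted(pos, interval.end, side="right"))
        return (sl.start + i, sl.start + j)

    def count_in(self, interval: GenomicInterval) -> int:
        i, j = self.global_range(interval)
        return j - i

    def interval_from_indices(self, chrom: str, first: int, last: int) -> GenomicInterval:
        """Interval spanning marker indices first..last (chromosome-local)."""
        pos = self.positions(chrom)
        return GenomicInterval(chrom, int(pos[first]), int(pos[last]))


@dataclass
class IntensityProfile:
    """Per-marker LRR and BAF for one sample, aligned to a MarkerMap's order."""

    sample_id: str
    lrr: np.ndarray
    baf: np.ndarray

    def __post_init__(self):
        self.lrr = np.asarray(self.lrr, dtype=float)
        self.baf = np.asarray(self.baf, dtype=float)
        if self.lrr.shape != self.baf.shape or self.lrr.ndim != 1:
            raise ValueError("lrr and baf must be 1-D arrays of equal length")
        if np.any((self.baf < 0) | (self.baf > 1)):
            raise ValueError("BAF values must lie in [0, 1]")

    @property
    def n_markers(self) -> int:
        return self.lrr.size


Subtype = Literal["accommodative", "infantile", "nonaccommodative", "none"]


@dataclass
class SampleMeta:
    """Phenotype labels plus the intensity QC metrics used for sample exclusion."""

    sample_id: str
    group: Literal["case", "control"]
    subtype: Subtype = "none"
    family_id: Optional[str] = None
    call_rate: Optional[float] = None
    lrr_sd: Optional[float] = None
    wf: Optional[float] = None
    baf_drift: Optional[float] = None

    def __post_init__(self):
        if self.group not in ("case", "control"):
            raise ValueError(f"group must be 'case' or 'control', got {self.group!r}")
        if self.group == "control" and self.subtype != "none":
            raise ValueError("controls carry no esotropia subtype")

    @property
    def is_case(self) -> bool:
        return self.group == "case"


@dataclass(frozen=True)
class CnvCall:
    """One called CNV segment for one sample.

    ``confidence`` is a log-likelihood-ratio style score (called state versus
    diploid); ``caller`` tags the calling pass that produced the segment.
    """

    sample_id: str
    interval: GenomicInterval
    copy_state: int
    n_markers: int
    confidence: float
    caller: str

    def __post_init__(self):
        if self.copy_state not in VALID_STATES:
            raise ValueError(
                f"copy state {self.copy_state} invalid for a CNV call (must be 0, 1, 3 or 4)"
            )
        if self.n_markers < 1:
            raise ValueError("a call must span at least one marker")

    @property
    def copy_class(self) -> CnvClass:
        return copy_class(self.copy_state)

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class AnnotatedRegion:
    """A named genomic region: artifact zone, common-CNV catalog entry or gene model."""

    interval: GenomicInterval
    name: str
    frequency: Optional[float] = None
    exons: Optional[list[GenomicInterval]] = None

    def __post_init__(self):
        if self.frequency is not None and not (0.0 <= self.frequency <= 1.0):
            raise ValueError(f"frequency {self.frequency} outside [0, 1]")
        if self.exons:
            for ex in self.exons:
                if not self.interval.contains(ex):
                    raise ValueError(f"exon {ex} lies outside gene interval {self.interval}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_marker_map(path: str | os.PathLike) -> MarkerMap:
    """Read a marker map TSV with columns marker_id, chrom, pos, gc.

    Unsorted input is sorted (with a log entry); duplicate positions on a
    chromosome are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str})
    missing = [c for c in MarkerMap.REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for col in ("pos", "gc"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna() | df[col].isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(f"{path}: malformed {col!r} value at line {line}")
    return MarkerMap(df)


def write_marker_map(mmap: MarkerMap, path: str | os.PathLike) -> None:
    mmap.df.to_csv(path, sep="\t", index=False)


def read_bed_regions(
    path: str | os.PathLike, has_frequency: bool = False
) -> list[AnnotatedRegion]:
    """Read a BED file (0-based half-open) into 1-based inclusive regions.

    Column 4, when present, is the region name; column 5 (``has_frequency``)
    is a population frequency in [0, 1].
    """
    regions: list[AnnotatedRegion] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            if end0 <= start0:
                raise ValueError(f"{path}: line {lineno}: empty interval ({start0}, {end0})")
            name = parts[3] if len(parts) > 3 else f"region_{lineno}"
            freq = None
            if has_frequency:
                if len(parts) < 5:
                    raise ValueError(f"{path}: line {lineno}: frequency column missing")
                freq = float(parts[4])
                if not (0.0 <= freq <= 1.0):
                    raise ValueError(f"{path}: line {lineno}: frequency {freq} outside [0, 1]")
            regions.append(
                AnnotatedRegion(GenomicInterval(chrom, start0 + 1, end0), name, frequency=freq)
            )
    return regions


def write_bed_regions(
    regions: Sequence[AnnotatedRegion], path: str | os.PathLike, with_frequency: bool = False
) -> None:
    with open(path, "w") as fh:
        for r in regions:
            cols = [r.interval.chrom, str(r.interval.start - 1), str(r.interval.end), r.name]
            if with_frequency:
                cols.append(repr(r.frequency if r.frequency is not None else 0.0))
            fh.write("\t".join(cols) + "\n")


def read_gene_models(path: str | os.PathLike) -> list[AnnotatedRegion]:
    """Read gene models from BED12 (exon blocks in columns 10-12)."""
    genes: list[AnnotatedRegion] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}: line {lineno}: BED12 requires 12 columns")
            chrom, start0, end0, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            n_blocks = int(parts[9])
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            starts = [int(x) for x in parts[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{path}: line {lineno}: block count mismatch")
            exons = [
                GenomicInterval(chrom, start0 + bs + 1, start0 + bs + sz)
                for bs, sz in zip(starts, sizes)
            ]
            genes.append(
                AnnotatedRegion(GenomicInterval(chrom, start0 + 1, end0), name, exons=exons)
            )
    return genes


def write_gene_models(genes: Sequence[AnnotatedRegion], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            exons = g.exons or [iv]
            sizes = ",".join(str(ex.length) for ex in exons) + ","
            starts = ",".join(str(ex.start - iv.start) for ex in exons) + ","
            cols = [
                iv.chrom, str(iv.start - 1), str(iv.end), g.name, "0", "+",
                str(iv.start - 1), str(iv.end), "0", str(len(exons)), sizes, starts,
            ]
            fh.write("\t".join(cols) + "\n")


CALL_COLUMNS = [
    "sample_id", "chrom", "start", "end", "copy_state", "n_markers", "confidence", "caller",
]


def read_cnv_calls(path: str | os.PathLike) -> list[CnvCall]:
    """Read a CNV call TSV (1-based inclusive coordinates)."""
    df = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str, "chrom": str, "caller": str},
        float_precision="round_trip",
    )
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    calls = []
    for row in df.itertuples(index=False):
        calls.append(
            CnvCall(
                sample_id=row.sample_id,
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                copy_state=int(row.copy_state),
                n_markers=int(row.n_markers),
                confidence=float(row.confidence),
                caller=row.caller,
            )
        )
    return calls


def write_cnv_calls(calls: Sequence[CnvCall], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [
            (c.sample_id, c.interval.chrom, c.interval.start, c.interval.end,
             c.copy_state, c.n_markers, repr(float(c.confidence)), c.caller)
            for c in calls
        ],
        columns=CALL_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


SAMPLE_COLUMNS = [
    "sample_id", "group", "subtype", "family_id", "call_rate", "lrr_sd", "wf", "baf_drift",
]


def read_sample_sheet(path: str | os.PathLike) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "family_id": str})
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    samples = []
    for row in df.itertuples(index=False):
        fam = None if pd.isna(row.family_id) else str(row.family_id)

        def _num(v):
            return None if pd.isna(v) else float(v)

        samples.append(
            SampleMeta(
                sample_id=row.sample_id,
                group=row.group,
                subtype=row.subtype,
                family_id=fam,
                call_rate=_num(row.call_rate),
                lrr_sd=_num(row.lrr_sd),
                wf=_num(row.wf),
                baf_drift=_num(row.baf_drift),
            )
        )
    return samples


def write_sample_sheet(samples: Sequence[SampleMeta], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [
            (s.sample_id, s.group, s.subtype, s.family_id if s.family_id is not None else "",
             s.call_rate, s.lrr_sd, s.wf, s.baf_drift)
            for s in samples
        ],
        columns=SAMPLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_signal(path: str | os.PathLike, mmap: MarkerMap, sample_id: str) -> IntensityProfile:
    """Read a per-sample signal TSV (marker_id, lrr, baf) aligned to ``mmap``."""
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str})
    for col in ("marker_id", "lrr", "baf"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if len(df) != len(mmap) or not (df["marker_id"].to_numpy() == mmap.marker_ids.to_numpy()).all():
        df = df.set_index("marker_id").reindex(mmap.marker_ids)
        if df["lrr"].isna().any():
            raise ValueError(f"{path}: signal markers do not match the marker map")
    return IntensityProfile(sample_id, df["lrr"].to_numpy(), df["baf"].to_numpy())


def write_signal(profile: IntensityProfile, mmap: MarkerMap, path: str | os.PathLike) -> None:
    if profile.n_markers != len(mmap):
        raise ValueError("profile is not aligned to the marker map")
    df = pd.DataFrame(
        {"marker_id": mmap.marker_ids, "lrr": profile.lrr, "baf": profile.baf}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")
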