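"""Synthetic SNP-array cohort generator.

Emulates a case-control cohort with the statistical structure the downstream
analysis assumes: per-sample intensity QC metrics, LRR/BAF signal with embedded
copy-number variants, a case-enriched duplication-length burden, and planted
recurrent risk duplication loci with group-specific carrier frequencies.

Signal model
------------
The diploid LRR baseline is 0 with Gaussian noise at the sample's own LRR_SD
metric, plus an optional GC-correlated "waviness" term scaled by the sample's
WF metric.  Copy-state segments shift the LRR mean (CN0 -3.5, CN1 -0.55,
CN3 +0.35, CN4 +0.65 -- typical Illumina array behaviour) and redraw BAF from
state-specific cluster mixtures (diploid clusters near {0, 1/2, 1}; the
heterozygote band is absent in CN1; CN3 clusters near {0, 1/3, 2/3, 1}).
"""

from __future__ import annotations

import os
import shutil
import tempfile
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from .core import (
    AnnotatedRegion,
    GenomicInterval,
    IntensityProfile,
    MarkerMap,
    SampleMeta,
    logger,
    write_bed_regions,
    write_gene_models,
    write_marker_map,
    write_sample_sheet,
    write_signal,
)

# Mean LRR shift per copy state (diploid = 0).
LRR_STATE_SHIFT: dict[int, float] = {0: -3.5, 1: -0.55, 2: 0.0, 3: 0.35, 4: 0.65}

# BAF cluster mixtures per copy state: (centers, weights).  CN0 carries no DNA
# and its BAF is uniform noise (encoded as centers=None).  Homozygous clusters
# at {0, 1} appear in every state so that long homozygous runs stay
# uninformative about copy number.
BAF_STATE_MIXTURE: dict[int, Optional[tuple[tuple[float, ...], tuple[float, ...]]]] = {
    0: None,
    1: ((0.0, 1.0), (0.5, 0.5)),
    2: ((0.0, 0.5, 1.0), (0.33, 0.34, 0.33)),
    3: ((0.0, 1 / 3, 2 / 3, 1.0), (0.28, 0.22, 0.22, 0.28)),
    4: ((0.0, 0.25, 0.5, 0.75, 1.0), (0.26, 0.14, 0.20, 0.14, 0.26)),
}


@dataclass(frozen=True)
class TruthCnv:
    """Ground-truth CNV planted in a synthetic sample."""

    sample_id: str
    interval: GenomicInterval
    copy_state: int
    origin: str  # "common" | "background_rare" | "risk_locus:<name>"


@dataclass
class RiskLocus:
    """A planted recurrent duplication locus with group-specific carrier rates.

    ``nested``, when given, is a smaller sub-locus carried (with its own
    frequencies) by samples that do NOT carry the full-span duplication --
    the nested-duplication structure seen at recurrent loci where a shorter
    shared segment is common to both carrier groups.
    """

    name: str
    interval: GenomicInterval
    case_freq: float
    control_freq: float
    copy_state: int = 3
    nested: Optional["RiskLocus"] = None

    def __post_init__(self):
        for f in (self.case_freq, self.control_freq):
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"carrier frequency {f} outside [0, 1] at locus {self.name}")
        if self.nested is not None and not self.interval.contains(self.nested.interval):
            raise ValueError(f"nested locus {self.nested.name} outside {self.name}")


@dataclass
class CommonLocus:
    """A polymorphic CNV locus present at the same frequency in both groups."""

    name: str
    interval: GenomicInterval
    copy_state: int
    pop_freq: float


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Background rates and group mean total lengths default to the cohort-level
    values the analysis is calibrated against: ~0.8 deletions and ~1.1
    duplications per person; mean total deletion length 220.7 kb (cases) vs
    177.8 kb (controls); mean total duplication length 419.6 kb vs 258 kb.
    Event lengths are log-normal (an assumption, recorded in the manifest).
    """

    n_cases: int
    n_controls: int
    seed: int = 0
    background_del_rate: float = 0.8
    background_dup_rate: float = 1.1
    case_del_total_kb: float = 220.7
    control_del_total_kb: float = 177.8
    case_dup_total_kb: float = 419.6
    control_dup_total_kb: float = 258.0
    length_log_sd: float = 0.6
    min_background_markers: int = 12
    # Background events are kept this many markers away from every configured
    # risk locus.  On a real genome the chance of a background CNV landing
    # within ~0.5 Mb of a given locus is negligible; on a compressed toy
    # genome it is not, and a nearby background event can merge with a
    # carrier's locus call and chain it into recurrent background clusters.
    risk_zone_margin_markers: int = 100
    risk_loci: list[RiskLocus] = field(default_factory=list)
    common_loci: list[CommonLocus] = field(default_factory=list)
    subtype_probs: tuple[float, float, float] = (0.139, 0.196, 0.665)
    lrr_sd: float = 0.16
    baf_sd: float = 0.03
    wave_gain: float = 1.0
    qc_fail_fraction: float = 0.0
    family_fraction: float = 0.0
    markers: Optional[MarkerMap] = None
    artifact_regions: list[AnnotatedRegion] = field(default_factory=list)
    common_catalog: list[AnnotatedRegion] = field(default_factory=list)
    genes: list[AnnotatedRegion] = field(default_factory=list)

    def __post_init__(self):
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        if abs(sum(self.subtype_probs) - 1.0) > 1e-9:
            raise ValueError("subtype probabilities must sum to 1")

    def marker_map(self) -> MarkerMap:
        if self.markers is None:
            self.markers = toy_marker_map()
        return self.markers


# ---------------------------------------------------------------------------
# Toy genome and the scaled study configuration
# ---------------------------------------------------------------------------

_TOY_CHROMS = ("1", "2", "4", "10")
_TOY_MARKERS_PER_CHROM = 1000
_TOY_SPACING = 5000
_TOY_START = 50_000


def toy_marker_map(
    chroms: Sequence[str] = _TOY_CHROMS,
    markers_per_chrom: int = _TOY_MARKERS_PER_CHROM,
    spacing: int = _TOY_SPACING,
) -> MarkerMap:
    """Regular toy marker grid with a smooth deterministic GC field."""
    records = []
    for chrom in chroms:
        idx = np.arange(markers_per_chrom)
        pos = _TOY_START + spacing * idx
        gc = 0.45 + 0.10 * np.sin(2 * np.pi * idx / 600) + 0.05 * np.sin(2 * np.pi * idx / 97)
        for i in range(markers_per_chrom):
            records.append((f"rs{chrom}_{i:05d}", chrom, int(pos[i]), float(gc[i])))
    return MarkerMap.from_records(records)


def _toy_interval(chrom: str, first_idx: int, last_idx: int) -> GenomicInterval:
    return GenomicInterval(
        chrom, _TOY_START + _TOY_SPACING * first_idx, _TOY_START + _TOY_SPACING * last_idx
    )


def study_risk_loci() -> list[RiskLocus]:
    """The three recurrent duplication loci of the emulated study.

    Carrier frequencies are the reported carrier counts over the analysis
    cohort (1614 cases / 3922 controls): 23 vs 4, 27 vs 6 and, at the nested
    locus, 36 vs 0 full-span carriers plus 28 vs 18 carriers of the smaller
    shared duplication.  Spans are expressed on the toy marker grid.
    """
    return [
        RiskLocus("dup2", _toy_interval("2", 380, 486), 23 / 1614, 4 / 3922),
        RiskLocus("dup4", _toy_interval("4", 700, 729), 27 / 1614, 6 / 3922),
        RiskLocus(
            "dup10_full",
            _toy_interval("10", 500, 630),
            36 / 1614,
            0.0,
            nested=RiskLocus("dup10_small", _toy_interval("10", 571, 630), 28 / 1614, 18 / 3922),
        ),
        # An equal-frequency locus carried by ~2% of both groups: exercises the
        # >1%-of-controls frequency filter inside the full pipeline.
        RiskLocus("ctrl_common", _toy_interval("4", 200, 230), 0.02, 0.02),
    ]


def study_common_loci() -> list[CommonLocus]:
    return [
        CommonLocus("common_dup1", _toy_interval("1", 300, 340), 3, 0.25),
        CommonLocus("common_del1", _toy_interval("1", 900, 925), 1, 0.30),
    ]


def study_artifact_regions() -> list[AnnotatedRegion]:
    return [AnnotatedRegion(_toy_interval("1", 60, 120), "segdup_artifact")]


def study_common_catalog() -> list[AnnotatedRegion]:
    return [
        AnnotatedRegion(_toy_interval("1", 300, 340), "catalog_common_dup1", frequency=0.25),
        AnnotatedRegion(_toy_interval("1", 900, 925), "catalog_common_del1", frequency=0.30),
    ]


def study_gene_models() -> list[AnnotatedRegion]:
    """Toy gene models: genes inside each risk locus plus null genes elsewhere."""

    def gene(name, chrom, lo, hi, exon_spans):
        iv = _toy_interval(chrom, lo, hi)
        exons = [_toy_interval(chrom, a, b) for a, b in exon_spans]
        return AnnotatedRegion(iv, name, exons=exons)

    genes = [
        gene("GENE_D2", "2", 390, 460, [(392, 394), (420, 423), (450, 454)]),
        gene("GENE_D4", "4", 702, 726, [(703, 705), (715, 718)]),
        gene("GENE_D10_UNIQ", "10", 510, 560, [(512, 515), (545, 548)]),
        gene("GENE_D10_SHARED", "10", 580, 620, [(582, 585), (610, 613)]),
    ]
    rng = np.random.default_rng(20200811)
    for k in range(12):
        chrom = _TOY_CHROMS[k % 4]
        lo = int(rng.integers(20, _TOY_MARKERS_PER_CHROM - 80))
        hi = lo + int(rng.integers(10, 50))
        genes.append(gene(f"NULLGENE_{k:02d}", chrom, lo, hi, [(lo + 2, lo + 4), (hi - 4, hi - 2)]))
    return genes


def study_config(seed: int = 0, n_cases: int = 1614, n_controls: int = 3922) -> CohortConfig:
    """The scaled emulation of the study cohort: 1614 cases / 3922 controls on a
    6,000-marker toy genome with the three planted risk duplications."""
    return CohortConfig(
        n_cases=n_cases,
        n_controls=n_controls,
        seed=seed,
        risk_loci=study_risk_loci(),
        common_loci=study_common_loci(),
        qc_fail_fraction=0.02,
        family_fraction=0.145,
        markers=toy_marker_map(),
        artifact_regions=study_artifact_regions(),
        common_catalog=study_common_catalog(),
        genes=study_gene_models(),
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

_SUBTYPES = ("accommodative", "infantile", "nonaccommodative")


def _sample_rng(config: CohortConfig, sample_id: str) -> np.random.Generator:
    """Deterministic per-sample stream derived from the cohort seed."""
    return np.random.default_rng([config.seed, zlib.crc32(sample_id.encode()) & 0x7FFFFFFF])


def generate_cohort(config: CohortConfig) -> tuple[list[SampleMeta], list[TruthCnv]]:
    """Draw sample metadata and ground-truth CNVs for one synthetic cohort.

    Carrier draws per risk locus are independent Bernoulli per sample at the
    group-specific frequency (relatives copy their proband's status).  A
    configured fraction of extra samples receives QC metrics beyond the
    exclusion thresholds.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    mmap = config.marker_map()

    # -- sample sheet -------------------------------------------------------
    samples: list[SampleMeta] = []
    n_fail_case = int(round(config.qc_fail_fraction * config.n_cases))
    n_fail_ctrl = int(round(config.qc_fail_fraction * config.n_controls))

    case_ids = [f"CASE{i:05d}" for i in range(config.n_cases)]
    ctrl_ids = [f"CTRL{i:05d}" for i in range(config.n_controls)]
    fail_ids = [f"CASEQF{i:04d}" for i in range(n_fail_case)] + [
        f"CTRLQF{i:04d}" for i in range(n_fail_ctrl)
    ]
    fail_groups = ["case"] * n_fail_case + ["control"] * n_fail_ctrl

    subtype_idx = rng.choice(3, size=config.n_cases + n_fail_case, p=list(config.subtype_probs))

    # family structure: the last n_rel cases are relatives of earlier probands
    n_rel = int(round(config.family_fraction * config.n_cases))
    n_prob = config.n_cases - n_rel
    if n_rel > 0 and n_prob < 1:
        raise ValueError("family_fraction leaves no probands")
    relative_of = np.full(config.n_cases, -1, dtype=int)
    family_of = {i: f"FAM{i:05d}" for i in range(config.n_cases)}
    rel_idx = config.n_cases - n_rel
    while rel_idx < config.n_cases:
        proband = int(rng.integers(0, n_prob))
        for _ in range(int(rng.integers(1, 3))):  # 1-2 relatives per chosen proband
            if rel_idx >= config.n_cases:
                break
            relative_of[rel_idx] = proband
            family_of[rel_idx] = family_of[proband]
            rel_idx += 1

    def passing_metrics():
        return dict(
            lrr_sd=float(np.clip(rng.normal(config.lrr_sd, 0.02), 0.08, 0.28)),
            wf=float(np.clip(rng.normal(0.0, 0.10), -0.40, 0.40)),
            baf_drift=float(min(abs(rng.normal(0.0, 0.003)), 0.009)),
            call_rate=float(min(1.0, 0.998 - abs(rng.normal(0.0, 0.004)))),
        )

    for i, sid in enumerate(case_ids):
        samples.append(
            SampleMeta(sid, "case", _SUBTYPES[subtype_idx[i]], family_id=family_of[i], **passing_metrics())
        )
    for sid in ctrl_ids:
        samples.append(SampleMeta(sid, "control", "none", family_id=None, **passing_metrics()))
    for k, (sid, grp) in enumerate(zip(fail_ids, fail_groups)):
        m = passing_metrics()
        which = k % 4
        if which == 0:
            m["lrr_sd"] = float(rng.uniform(0.31, 0.42))
        elif which == 1:
            m["wf"] = float(rng.choice([-1, 1]) * rng.uniform(0.44, 0.60))
        elif which == 2:
            m["baf_drift"] = float(rng.uniform(0.011, 0.03))
        else:
            m["call_rate"] = float(rng.uniform(0.95, 0.979))
        sub = _SUBTYPES[subtype_idx[config.n_cases + k]] if grp == "case" else "none"
        samples.append(SampleMeta(sid, grp, sub, family_id=None, **m))

    is_case = np.array([s.is_case for s in samples])
    n_all = len(samples)

    truth: list[TruthCnv] = []
    occupied: dict[str, list[tuple[str, int, int]]] = {s.sample_id: [] for s in samples}

    def marker_span(interval: GenomicInterval) -> tuple[int, int]:
        i, j = mmap.global_range(interval)
        if j <= i:
            raise ValueError(f"locus {interval} contains no markers")
        return i, j - 1  # inclusive global marker indices

    def add_truth(sample_id, chrom, gi0, gi1, state, origin):
        sl = mmap.chrom_slice(chrom)
        first, last = gi0 - sl.start, gi1 - sl.start
        iv = mmap.interval_from_indices(chrom, first, last)
        truth.append(TruthCnv(sample_id, iv, state, origin))
        occupied[sample_id].append((chrom, gi0, gi1))

    # -- planted risk loci --------------------------------------------------
    for locus in config.risk_loci:
        freqs = np.where(is_case, locus.case_freq, locus.control_freq)
        carrier = rng.random(n_all) < freqs
        partial = np.zeros(n_all, dtype=bool)
        if locus.nested is not None:
            nfreqs = np.where(is_case, locus.nested.case_freq, locus.nested.control_freq)
            partial = (~carrier) & (rng.random(n_all) < nfreqs)
        # relatives share the proband's carrier status
        for ri in range(config.n_cases - n_rel, config.n_cases):
            p = relative_of[ri]
            if p >= 0:
                carrier[ri] = carrier[p]
                partial[ri] = partial[p]
        jit = rng.integers(-2, 3, size=(n_all, 2))
        for si in np.flatnonzero(carrier | partial):
            s = samples[si]
            base = locus.interval if carrier[si] else locus.nested.interval
            state = locus.copy_state if carrier[si] else locus.nested.copy_state
            name = locus.name if carrier[si] else locus.nested.name
            g0, g1 = marker_span(base)
            chrom = base.chrom
            sl = mmap.chrom_slice(chrom)
            g0 = int(np.clip(g0 + jit[si, 0], sl.start, sl.stop - 1))
            g1 = int(np.clip(g1 + jit[si, 1], g0, sl.stop - 1))
            add_truth(s.sample_id, chrom, g0, g1, state, f"risk_locus:{name}")

    # -- common polymorphic loci -------------------------------------------
    for locus in config.common_loci:
        carrier = rng.random(n_all) < locus.pop_freq
        jit = rng.integers(-2, 3, size=(n_all, 2))
        g0b, g1b = marker_span(locus.interval)
        chrom = locus.interval.chrom
        sl = mmap.chrom_slice(chrom)
        for si in np.flatnonzero(carrier):
            g0 = int(np.clip(g0b + jit[si, 0], sl.start, sl.stop - 1))
            g1 = int(np.clip(g1b + jit[si, 1], g0, sl.stop - 1))
            add_truth(samples[si].sample_id, chrom, g0, g1, locus.copy_state, "common")

    # -- background rare events --------------------------------------------
    # Placed outside the configured risk loci: on a genome scaled down by
    # orders of magnitude, uniform placement would collide with a given locus
    # far more often than on a real genome, distorting the planted carrier
    # frequencies the generator is meant to reproduce.
    spacing = float(np.median(np.diff(mmap.positions(mmap.chroms[0])))) if len(mmap) > 1 else 5000.0
    reserved: list[tuple[str, int, int]] = []
    margin = config.risk_zone_margin_markers
    for locus in config.risk_loci:
        g0, g1 = marker_span(locus.interval)
        reserved.append((locus.interval.chrom, g0 - margin, g1 + margin))
    chrom_names = mmap.chroms
    chrom_sizes = np.array([mmap.chrom_slice(c).stop - mmap.chrom_slice(c).start for c in chrom_names])
    chrom_p = chrom_sizes / chrom_sizes.sum()

    def mean_event_kb(s: SampleMeta, cls: str) -> float:
        if cls == "DEL":
            total = config.case_del_total_kb if s.is_case else config.control_del_total_kb
            rate = config.background_del_rate
        else:
            total = config.case_dup_total_kb if s.is_case else config.control_dup_total_kb
            rate = config.background_dup_rate
        return total / max(rate, 1e-12)

    max_span = max(config.min_background_markers, int(chrom_sizes.min()) // 3)
    for s in samples:
        for cls, rate in (("DEL", config.background_del_rate), ("DUP", config.background_dup_rate)):
            n_ev = rng.poisson(rate)
            for _ in range(n_ev):
                mean_kb = mean_event_kb(s, cls)
                mu = np.log(mean_kb * 1000.0) - 0.5 * config.length_log_sd**2
                length_bp = float(rng.lognormal(mu, config.length_log_sd))
                span = int(np.clip(round(length_bp / spacing), config.min_background_markers, max_span))
                state = (1 if rng.random() < 0.85 else 0) if cls == "DEL" else (3 if rng.random() < 0.85 else 4)
                for _attempt in range(40):
                    ci = int(rng.choice(len(chrom_names), p=chrom_p))
                    chrom = chrom_names[ci]
                    sl = mmap.chrom_slice(chrom)
                    if sl.stop - sl.start <= span:
                        continue
                    g0 = sl.start + int(rng.integers(0, sl.stop - sl.start - span))
                    g1 = g0 + span - 1
                    clash = any(
                        c == chrom and not (g1 < a or g0 > b) for c, a, b in reserved
                    ) or any(
                        c == chrom and not (g1 < a or g0 > b) for c, a, b in occupied[s.sample_id]
                    )
                    if not clash:
                        add_truth(s.sample_id, chrom, g0, g1, state, "background_rare")
                        break
    return samples, truth


# ---------------------------------------------------------------------------
# Intensity simulation
# ---------------------------------------------------------------------------


def _draw_baf(rng: np.random.Generator, state: int, n: int, baf_sd: float) -> np.ndarray:
    mix = BAF_STATE_MIXTURE[state]
    if mix is None:  # CN0: no DNA, uniform noise
        return rng.random(n)
    centers, weights = np.asarray(mix[0]), np.asarray(mix[1])
    comp = np.searchsorted(np.cumsum(weights), rng.random(n))
    vals = centers[comp] + rng.normal(0.0, baf_sd, n) if baf_sd > 0 else centers[comp].astype(float)
    return np.clip(vals, 0.0, 1.0)


def _gc_wave(mmap: MarkerMap) -> np.ndarray:
    """Per-chromosome standardized GC track used for the waviness artifact."""
    z = np.zeros(len(mmap))
    for chrom in mmap.chroms:
        sl = mmap.chrom_slice(chrom)
        gc = mmap.gc(chrom)
        sd = gc.std()
        z[sl] = (gc - gc.mean()) / sd if sd > 0 else 0.0
    return z


def simulate_intensities(
    sample: SampleMeta,
    truth: Sequence[TruthCnv],
    mmap: MarkerMap,
    config: CohortConfig,
) -> IntensityProfile:
    """Simulate one sample's LRR/BAF profile with its truth CNVs embedded.

    Deterministic given (config.seed, sample_id).  Raises if a truth interval
    spans no markers.
    """
    rng = _sample_rng(config, sample.sample_id)
    m = len(mmap)
    lrr_sd = sample.lrr_sd if sample.lrr_sd is not None else config.lrr_sd
    wf = sample.wf if sample.wf is not None else 0.0
    drift = sample.baf_drift if sample.baf_drift is not None else 0.0

    lrr = rng.normal(0.0, lrr_sd, m) if lrr_sd > 0 else np.zeros(m)
    lrr += config.wave_gain * wf * _gc_wave(mmap)
    baf = _draw_baf(rng, 2, m, config.baf_sd)

    for t in truth:
        if t.sample_id != sample.sample_id:
            continue
        i, j = mmap.global_range(t.interval)
        if j <= i:
            raise ValueError(f"truth interval {t.interval} spans no markers")
        lrr[i:j] += LRR_STATE_SHIFT[t.copy_state]
        baf[i:j] = _draw_baf(rng, t.copy_state, j - i, config.baf_sd)

    if drift > 0:
        baf = np.clip(baf + rng.normal(0.0, drift, m), 0.0, 1.0)
    return IntensityProfile(sample.sample_id, lrr, baf)


def simulate_intensities_batch(
    samples: Sequence[SampleMeta],
    truth: Sequence[TruthCnv],
    mmap: MarkerMap,
    config: CohortConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """(n_samples, n_markers) float32 LRR and BAF matrices, rows in sample order.

    Row ``i`` is identical to ``simulate_intensities(samples[i], ...)``.
    """
    by_sample: dict[str, list[TruthCnv]] = {s.sample_id: [] for s in samples}
    for t in truth:
        if t.sample_id in by_sample:
            by_sample[t.sample_id].append(t)
    n, m = len(samples), len(mmap)
    lrr = np.empty((n, m), dtype=np.float32)
    baf = np.empty((n, m), dtype=np.float32)
    for i, s in enumerate(samples):
        prof = simulate_intensities(s, by_sample[s.sample_id], mmap, config)
        lrr[i] = prof.lrr
        baf[i] = prof.baf
    return lrr, baf


# ---------------------------------------------------------------------------
# Fixture emission
# ---------------------------------------------------------------------------


def write_truth_bed(truth: Sequence[TruthCnv], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for t in truth:
            iv = t.interval
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{t.sample_id}\t{t.copy_state}\t{t.origin}\n"
            )


def read_truth_bed(path: str | os.PathLike) -> list[TruthCnv]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, s0, e, sid, state, origin = line.rstrip("\n").split("\t")
            out.append(TruthCnv(sid, GenomicInterval(chrom, int(s0) + 1, int(e)), int(state), origin))
    return out


def config_manifest(config: CohortConfig) -> dict:
    """Serializable summary of the study conditions (written beside fixtures)."""
    d = {
        "seed": config.seed,
        "n_cases": config.n_cases,
        "n_controls": config.n_controls,
        "background_del_rate": config.background_del_rate,
        "background_dup_rate": config.background_dup_rate,
        "case_del_total_kb": config.case_del_total_kb,
        "control_del_total_kb": config.control_del_total_kb,
        "case_dup_total_kb": config.case_dup_total_kb,
        "control_dup_total_kb": config.control_dup_total_kb,
        "length_distribution": "log-normal",
        "length_log_sd": config.length_log_sd,
        "lrr_sd": config.lrr_sd,
        "baf_sd": config.baf_sd,
        "wave_gain": config.wave_gain,
        "qc_fail_fraction": config.qc_fail_fraction,
        "family_fraction": config.family_fraction,
        "n_markers": len(config.marker_map()),
        "risk_loci": [
            {
                "name": l.name,
                "interval": str(l.interval),
                "case_freq": l.case_freq,
                "control_freq": l.control_freq,
                "copy_state": l.copy_state,
                "nested": None
                if l.nested is None
                else {
                    "name": l.nested.name,
                    "interval": str(l.nested.interval),
                    "case_freq": l.nested.case_freq,
                    "control_freq": l.nested.control_freq,
                },
            }
            for l in config.risk_loci
        ],
        "common_loci": [
            {"name": l.name, "interval": str(l.interval), "copy_state": l.copy_state, "pop_freq": l.pop_freq}
            for l in config.common_loci
        ],
    }
    return d


def emit_fixture(outdir: str | os.PathLike, config: CohortConfig) -> dict:
    """Write a complete file fixture for one synthetic cohort.

    Emits the marker map, per-sample signal TSVs, sample sheet, truth BED,
    artifact-region BED, common-CNV catalog BED, gene-model BED12 and a YAML
    manifest.  The write is atomic: files land in a temp directory that is
    renamed into place, so a failed run leaves nothing behind.  Re-emitting
    with the same config and seed is byte-identical.
    """
    outdir = os.fspath(outdir)
    if os.path.exists(outdir):
        raise FileExistsError(f"fixture directory {outdir} already exists")
    parent = os.path.dirname(os.path.abspath(outdir)) or "."
    os.makedirs(parent, exist_ok=True)
    tmp = tempfile.mkdtemp(prefix=".fixture-", dir=parent)
    try:
        mmap = config.marker_map()
        samples, truth = generate_cohort(config)
        write_marker_map(mmap, os.path.join(tmp, "markers.tsv"))
        write_sample_sheet(samples, os.path.join(tmp, "samples.tsv"))
        write_truth_bed(truth, os.path.join(tmp, "truth.bed"))
        write_bed_regions(config.artifact_regions, os.path.join(tmp, "artifacts.bed"))
        write_bed_regions(config.common_catalog, os.path.join(tmp, "common_cnvs.bed"), with_frequency=True)
        write_gene_models(config.genes, os.path.join(tmp, "genes.bed12"))
        sigdir = os.path.join(tmp, "signal")
        os.makedirs(sigdir)
        by_sample: dict[str, list[TruthCnv]] = {s.sample_id: [] for s in samples}
        for t in truth:
            by_sample[t.sample_id].append(t)
        for s in samples:
            prof = simulate_intensities(s, by_sample[s.sample_id], mmap, config)
            write_signal(prof, mmap, os.path.join(sigdir, f"{s.sample_id}.tsv"))
        manifest = config_manifest(config)
        manifest["n_samples_emitted"] = len(samples)
        with open(os.path.join(tmp, "manifest.yaml"), "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        os.replace(tmp, outdir)
    except Exception:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    logger.info("fixture written to %s (%d samples, %d truth CNVs)", outdir, len(samples), len(truth))
    return manifest
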