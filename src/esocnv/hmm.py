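"""Hidden-Markov CNV segmentation over LRR/BAF with GC-wave correction.

A simplified five-state HMM (copy numbers 0-4, diploid = 2) with Gaussian LRR
emissions and BAF cluster-mixture emissions.  Transitions are
distance-independent: a single per-marker probability of leaving the diploid
state and of returning to it.  Two bundled parameter profiles, ``callerA`` and
``callerB``, differ in their LRR noise prior and transition penalties, so they
produce overlapping but non-identical call sets -- the precondition for the
downstream dual-caller consensus stage.

Homozygous BAF clusters at {0, 1} carry identical weight in every state, so
long runs of homozygosity are uninformative about copy number and cannot mimic
deletions on their own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numba
import numpy as np

from .core import CnvCall, GenomicInterval, IntensityProfile, MarkerMap, logger

N_STATES = 5
DIPLOID = 2

# Caller emission model: BAF cluster centers and weights per state.  CN0 has no
# DNA and emits uniform BAF.  Homozygous weight (at 0 and 1) is equal across
# states by design.
CALLER_BAF_MIXTURE: dict[int, Optional[tuple[tuple[float, ...], tuple[float, ...]]]] = {
    0: None,
    1: ((0.0, 1.0), (0.5, 0.5)),
    2: ((0.0, 0.5, 1.0), (0.33, 0.34, 0.33)),
    3: ((0.0, 1 / 3, 2 / 3, 1.0), (0.33, 0.17, 0.17, 0.33)),
    4: ((0.0, 0.25, 0.5, 0.75, 1.0), (0.33, 0.11, 0.12, 0.11, 0.33)),
}


@dataclass
class HmmParams:
    """Emission and transition parameters for one calling pass.

    ``p_enter`` is the per-marker probability of jumping from the diploid
    state into one specific CNV state; ``p_return`` the probability of
    returning to diploid from a CNV state.  ``uniform_floor`` mixes a small
    uniform component into every BAF emission for robustness to outliers.
    """

    parameter_profile: str = "callerA"
    lrr_means: tuple[float, ...] = (-3.5, -0.55, 0.0, 0.35, 0.65)
    lrr_sd: float = 0.13
    baf_sd: float = 0.04
    p_enter: float = 1e-3
    p_return: float = 0.04
    p_cross: float = 1e-6
    uniform_floor: float = 0.01

    def __post_init__(self):
        if not all(b > a for a, b in zip(self.lrr_means, self.lrr_means[1:])):
            raise ValueError("lrr_means must be strictly increasing in copy number")
        if self.lrr_sd <= 0 or self.baf_sd <= 0:
            raise ValueError("emission standard deviations must be positive")
        row_out = 4 * self.p_enter
        if not (0 < row_out < 1 and 0 < self.p_return + 3 * self.p_cross < 1):
            raise ValueError("transition probabilities out of range")

    def transition_matrix(self) -> np.ndarray:
        A = np.zeros((N_STATES, N_STATES))
        for s in range(N_STATES):
            if s == DIPLOID:
                A[s, :] = self.p_enter
                A[s, s] = 1.0 - 4 * self.p_enter
            else:
                A[s, :] = self.p_cross
                A[s, DIPLOID] = self.p_return
                A[s, s] = 1.0 - self.p_return - 3 * self.p_cross
        assert np.allclose(A.sum(axis=1), 1.0)
        return A

    def initial_distribution(self) -> np.ndarray:
        pi = np.full(N_STATES, self.p_enter)
        pi[DIPLOID] = 1.0 - 4 * self.p_enter
        return pi


def caller_params(profile: str) -> HmmParams:
    """The two bundled calling profiles."""
    if profile == "callerA":
        return HmmParams("callerA", lrr_sd=0.13, p_enter=1e-3, p_return=0.04)
    if profile == "callerB":
        return HmmParams("callerB", lrr_sd=0.14, p_enter=2.5e-3, p_return=0.05)
    raise ValueError(f"unknown caller profile {profile!r}")


# ---------------------------------------------------------------------------
# GC-wave correction
# ---------------------------------------------------------------------------


def gc_adjust_lrr_batch(
    lrr: np.ndarray, mmap: MarkerMap, outlier_abs_resid: float = 0.5
) -> np.ndarray:
    """Per-chromosome least-squares removal of the GC wave from LRR rows.

    Each row of ``lrr`` (one sample, aligned to ``mmap``) is replaced by the
    residuals of a linear fit of LRR on GC fraction within each chromosome.
    The fit is two-pass: after an initial OLS fit, markers whose residual
    exceeds ``outlier_abs_resid`` in absolute value (large CNV segments,
    spikes) are masked and the line is refit, so a real deletion cannot drag
    the baseline of the rest of the chromosome.  On CNV-free signal the
    adjusted LRR has zero mean per chromosome.  Constant GC degenerates to
    mean-centering (logged).
    """
    out = np.array(lrr, dtype=lrr.dtype, copy=True)
    two_d = out.ndim == 2
    if not two_d:
        out = out[None, :]
    for chrom in mmap.chroms:
        sl = mmap.chrom_slice(chrom)
        gc = mmap.gc(chrom).astype(np.float64)
        gcc = gc - gc.mean()
        denom = float(gcc @ gcc)
        block = np.asarray(out[:, sl], dtype=np.float64)
        if denom == 0.0:
            logger.info("constant GC on chromosome %s; mean-centering only", chrom)
            out[:, sl] = block - block.mean(axis=1, keepdims=True)
            continue
        means = block.mean(axis=1, keepdims=True)
        slopes = (block @ gcc)[:, None] / denom
        resid = block - means - slopes * gcc[None, :]
        w = (np.abs(resid) <= outlier_abs_resid).astype(np.float64)
        wsum = w.sum(axis=1, keepdims=True)
        # refit on inlier markers only (weighted closed form, per sample)
        ok = wsum[:, 0] >= 2
        gw_mean = (w * gcc[None, :]).sum(axis=1, keepdims=True) / np.where(wsum > 0, wsum, 1)
        yw_mean = (w * block).sum(axis=1, keepdims=True) / np.where(wsum > 0, wsum, 1)
        gc_dev = gcc[None, :] - gw_mean
        denom_w = (w * gc_dev**2).sum(axis=1, keepdims=True)
        good = ok & (denom_w[:, 0] > 0)
        slope_w = np.where(
            denom_w > 0, (w * gc_dev * (block - yw_mean)).sum(axis=1, keepdims=True) / np.where(denom_w > 0, denom_w, 1), 0.0
        )
        means = np.where(good[:, None], yw_mean - slope_w * gw_mean, means)
        slopes = np.where(good[:, None], slope_w, slopes)
        out[:, sl] = block - means - slopes * gcc[None, :]
    return out if two_d else out[0]


def gc_adjust_lrr(profile: IntensityProfile, mmap: MarkerMap) -> IntensityProfile:
    """GC-wave-adjusted copy of one sample's profile (BAF unchanged)."""
    if profile.n_markers != len(mmap):
        raise ValueError("profile is not aligned to the marker map")
    adj = gc_adjust_lrr_batch(profile.lrr.astype(np.float64), mmap)
    return IntensityProfile(profile.sample_id, adj, profile.baf.copy())


# ---------------------------------------------------------------------------
# Emissions
# ---------------------------------------------------------------------------

_LOG_2PI = math.log(2 * math.pi)


def baf_state_log_density(baf: np.ndarray, params: HmmParams) -> np.ndarray:
    """Log BAF mixture density per state, shape ``(5,) + baf.shape``.

    Depends only on the BAF emission parameters, which the bundled caller
    profiles share, so it can be computed once and reused across callers.
    """
    baf = np.asarray(baf)
    dtype = np.float32 if baf.dtype == np.float32 else np.float64
    out = np.zeros((N_STATES,) + baf.shape, dtype=dtype)
    centers = sorted({c for mix in CALLER_BAF_MIXTURE.values() if mix for c in mix[0]})
    bafn = 1.0 / (params.baf_sd * math.sqrt(2 * math.pi))
    inv2vb = 1.0 / (2.0 * params.baf_sd**2)
    comp = {c: (bafn * np.exp(-((baf - c) ** 2) * inv2vb)).astype(dtype) for c in centers}
    floor = params.uniform_floor
    for s in range(N_STATES):
        mix = CALLER_BAF_MIXTURE[s]
        if mix is None:
            continue  # uniform on [0, 1]: log density 0
        dens = np.full(baf.shape, floor, dtype=dtype)
        for c, w in zip(*mix):
            dens += dtype((1.0 - floor) * w) * comp[c]
        out[s] = np.log(dens)
    return out


def state_log_emission(
    lrr: np.ndarray, baf: np.ndarray, params: HmmParams, baf_logdens: Optional[np.ndarray] = None
) -> np.ndarray:
    """Joint per-marker log emission density for each state.

    Returns an array of shape ``(5,) + lrr.shape``: Gaussian LRR log-density
    plus the log BAF mixture density (precomputable via
    :func:`baf_state_log_density`).
    """
    lrr = np.asarray(lrr)
    dtype = np.float32 if lrr.dtype == np.float32 else np.float64
    if baf_logdens is None:
        baf_logdens = baf_state_log_density(baf, params)
    out = np.empty((N_STATES,) + lrr.shape, dtype=dtype)
    inv2v = dtype(1.0 / (2.0 * params.lrr_sd**2))
    lrr_const = dtype(-math.log(params.lrr_sd) - 0.5 * _LOG_2PI)
    for s in range(N_STATES):
        d = lrr - dtype(params.lrr_means[s])
        out[s] = -(d * d) * inv2v + lrr_const
        out[s] += baf_logdens[s]
    return out


# ---------------------------------------------------------------------------
# Viterbi segmentation
# ---------------------------------------------------------------------------


@numba.njit(cache=False)
def _viterbi_kernel(loglik_t: np.ndarray, logA: np.ndarray, logpi: np.ndarray) -> np.ndarray:
    """Per-sample Viterbi over ``loglik_t`` of shape (n_samples, n_markers, S).

    Accumulates in float64; ties break toward the lower state index.
    """
    n, m, S = loglik_t.shape
    path = np.empty((n, m), dtype=np.int8)
    bp = np.empty((m, S), dtype=np.int8)
    delta = np.empty(S, dtype=np.float64)
    tmp = np.empty(S, dtype=np.float64)
    for i in range(n):
        for s in range(S):
            delta[s] = logpi[s] + loglik_t[i, 0, s]
        for t in range(1, m):
            for s in range(S):
                best = delta[0] + logA[0, s]
                arg = 0
                for r in range(1, S):
                    v = delta[r] + logA[r, s]
                    if v > best:
                        best = v
                        arg = r
                bp[t, s] = arg
                tmp[s] = best + loglik_t[i, t, s]
            for s in range(S):
                delta[s] = tmp[s]
        best = delta[0]
        arg = 0
        for s in range(1, S):
            if delta[s] > best:
                best = delta[s]
                arg = s
        path[i, m - 1] = arg
        for t in range(m - 1, 0, -1):
            path[i, t - 1] = bp[t, path[i, t]]
    return path


def _viterbi_paths(loglik: np.ndarray, params: HmmParams) -> np.ndarray:
    """Most likely state path per sample.

    ``loglik``: (5, n_samples, n_markers) log emission densities.
    Returns an int8 array (n_samples, n_markers) of state indices.
    """
    logA = np.log(params.transition_matrix())
    logpi = np.log(params.initial_distribution())
    loglik_t = np.moveaxis(loglik, 0, 2).astype(np.float64)  # (n, m, S) contiguous
    return _viterbi_kernel(loglik_t, logA, logpi)


def _calls_from_paths(
    path: np.ndarray,
    loglik: np.ndarray,
    sample_ids: Sequence[str],
    chrom: str,
    positions: np.ndarray,
    params: HmmParams,
) -> list[CnvCall]:
    n, m = path.shape
    ri, ci = np.nonzero(path[:, 1:] != path[:, :-1])
    counts = np.bincount(ri, minlength=n)  # state changes per row
    total = int(counts.sum()) + n  # runs per row = changes + 1
    offsets = np.cumsum(counts + 1)
    row_first = np.concatenate(([0], offsets[:-1]))
    starts = np.empty(total, dtype=np.int64)
    starts[row_first] = 0
    rest = np.ones(total, dtype=bool)
    rest[row_first] = False
    starts[rest] = ci + 1
    ends = np.empty(total, dtype=np.int64)
    ends[:-1] = starts[1:]
    ends[offsets - 1] = m
    run_row = np.repeat(np.arange(n), counts + 1)
    run_state = path[run_row, starts]
    keep = run_state != DIPLOID

    # confidence per run: cumulative sums of the state-vs-diploid log ratio
    conf = np.zeros(total)
    for s in range(N_STATES):
        if s == DIPLOID:
            continue
        sel = keep & (run_state == s)
        if not sel.any():
            continue
        cs = np.zeros((n, m + 1))
        np.cumsum(loglik[s] - loglik[DIPLOID], axis=1, dtype=np.float64, out=cs[:, 1:])
        conf[sel] = cs[run_row[sel], ends[sel]] - cs[run_row[sel], starts[sel]]

    calls: list[CnvCall] = []
    for k in np.flatnonzero(keep):
        a, b, i = int(starts[k]), int(ends[k]), int(run_row[k])
        calls.append(
            CnvCall(
                sample_id=sample_ids[i],
                interval=GenomicInterval(chrom, int(positions[a]), int(positions[b - 1])),
                copy_state=int(run_state[k]),
                n_markers=b - a,
                confidence=float(conf[k]),
                caller=params.parameter_profile,
            )
        )
    return calls


def segment_with_profiles(
    lrr: np.ndarray,
    baf: np.ndarray,
    sample_ids: Sequence[str],
    mmap: MarkerMap,
    params_list: Sequence[HmmParams],
) -> dict[str, list[CnvCall]]:
    """Segment many samples with several calling profiles in one pass.

    The BAF mixture log-densities are shared across profiles when their BAF
    emission parameters agree (true for the bundled callers), which halves
    the emission work of a dual-caller run.
    """
    calls: dict[str, list[CnvCall]] = {p.parameter_profile: [] for p in params_list}
    share_baf = len({(p.baf_sd, p.uniform_floor) for p in params_list}) == 1
    for chrom in mmap.chroms:
        sl = mmap.chrom_slice(chrom)
        if sl.stop - sl.start < 2:
            logger.warning("chromosome %s has fewer than 2 markers; skipped", chrom)
            continue
        baf_block = baf[:, sl]
        shared = baf_state_log_density(baf_block, params_list[0]) if share_baf else None
        for params in params_list:
            E = state_log_emission(lrr[:, sl], baf_block, params, baf_logdens=shared)
            path = _viterbi_paths(E, params)
            calls[params.parameter_profile].extend(
                _calls_from_paths(path, E, sample_ids, chrom, mmap.positions(chrom), params)
            )
    return calls


def hmm_segment_batch(
    lrr: np.ndarray,
    baf: np.ndarray,
    sample_ids: Sequence[str],
    mmap: MarkerMap,
    params: HmmParams,
) -> list[CnvCall]:
    """Segment many samples at once; rows of ``lrr``/``baf`` follow ``sample_ids``.

    Each maximal non-diploid run of the per-chromosome Viterbi path becomes a
    call spanning its first to last marker, with a log-likelihood-ratio
    confidence (called state vs diploid) summed over the run.
    """
    return segment_with_profiles(lrr, baf, sample_ids, mmap, [params])[params.parameter_profile]


def hmm_segment(profile: IntensityProfile, mmap: MarkerMap, params: HmmParams) -> list[CnvCall]:
    """Viterbi segmentation of one sample's profile into CNV calls."""
    if profile.n_markers != len(mmap):
        raise ValueError("profile is not aligned to the marker map")
    return hmm_segment_batch(
        profile.lrr[None, :].astype(np.float64),
        profile.baf[None, :].astype(np.float64),
        [profile.sample_id],
        mmap,
        params,
    )


def segment_confidence(
    profile: IntensityProfile, mmap: MarkerMap, call: CnvCall, params: HmmParams
) -> float:
    """Log-likelihood of the call's markers under the called state minus the
    diploid log-likelihood; positive for well-supported calls and monotone
    non-decreasing in segment length for fixed per-marker evidence."""
    i, j = mmap.global_range(call.interval)
    if j <= i:
        raise ValueError(f"call interval {call.interval} spans no markers")
    E = state_log_emission(
        profile.lrr[i:j].astype(np.float64), profile.baf[i:j].astype(np.float64), params
    )
    return float((E[call.copy_state] - E[DIPLOID]).sum())
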