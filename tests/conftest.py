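"""Shared helpers for the test suite: tiny marker maps, samples and calls."""

from __future__ import annotations

import numpy as np
import pytest

from esocnv import CnvCall, GenomicInterval, MarkerMap, SampleMeta


def simple_map(n=100, chrom="1", spacing=1000, start=1000, gc=None) -> MarkerMap:
    """Regular single-chromosome marker grid."""
    if gc is None:
        gc = 0.45 + 0.1 * np.sin(np.arange(n) / 7.0)
    return MarkerMap.from_records(
        [(f"m{chrom}_{i}", chrom, start + spacing * i, float(gc[i])) for i in range(n)]
    )


def make_samples(n_case, n_ctrl, lrr_sd=0.15, wf=0.0, baf_drift=0.001, call_rate=0.995):
    samples = [
        SampleMeta(f"CASE{i:04d}", "case", "nonaccommodative", None, call_rate, lrr_sd, wf, baf_drift)
        for i in range(n_case)
    ]
    samples += [
        SampleMeta(f"CTRL{i:04d}", "control", "none", None, call_rate, lrr_sd, wf, baf_drift)
        for i in range(n_ctrl)
    ]
    return samples


def make_call(sid, chrom, start, end, state=3, n_markers=10, conf=100.0, caller="consensus"):
    return CnvCall(sid, GenomicInterval(chrom, start, end), state, n_markers, conf, caller)


@pytest.fixture
def map100():
    return simple_map(100)
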