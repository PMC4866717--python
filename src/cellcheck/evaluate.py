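"""Scoring called segments against simulated truth.

A truth region counts as detected when any call of matching direction
(loss truth vs CN0/CN1 call, gain truth vs CN3 call) overlaps it by at
least one basepair; a non-diploid call is a false positive when it
overlaps no truth region of matching direction.  Diploid (CN2) calls
are ignored.  Boundary accuracy is summarized as missed length (truth
bp not covered by its matched calls) and added length (matched-call bp
outside the truth) for detected regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import CNVSegment
from .simulate import TruthRegion

__all__ = ["Matching", "EvalReport", "match_overlaps", "boundary_errors",
           "summarize"]

_LOSS_STATES = (0, 1)
_GAIN_STATES = (3,)


def _direction(state: int) -> int | None:
    if state in _LOSS_STATES:
        return 1       # matches CN1 truth
    if state in _GAIN_STATES:
        return 3
    return None        # CN2: ignored


@dataclass
class Matching:
    """Overlap matching between calls and truth regions."""

    truth: list[TruthRegion]
    calls: list[CNVSegment]
    aberrant_call_idx: np.ndarray       # indices of non-CN2 calls
    truth_detected: np.ndarray          # bool per truth region
    call_is_fp: np.ndarray              # bool per aberrant call
    pairs: list[tuple[int, int]]        # (truth index, call index) overlaps

    @property
    def n_detected(self) -> int:
        return int(self.truth_detected.sum())


def _check_sorted(items, what: str) -> None:
    last: dict[str, int] = {}
    for it in items:
        if it.chrom in last and it.start < last[it.chrom]:
            raise ValueError(f"{what} not sorted by (chromosome, start)")
        last[it.chrom] = it.start


def match_overlaps(calls: Sequence[CNVSegment],
                   truth: Sequence[TruthRegion]) -> Matching:
    """Direction-aware arbitrary-length overlap matching."""
    calls = list(calls)
    truth = list(truth)
    _check_sorted(calls, "calls")
    _check_sorted(truth, "truth regions")
    ab_idx = np.array([i for i, c in enumerate(calls)
                       if _direction(c.state) is not None], dtype=int)
    detected = np.zeros(len(truth), dtype=bool)
    is_fp = np.ones(len(ab_idx), dtype=bool)
    pairs: list[tuple[int, int]] = []
    for k, ci in enumerate(ab_idx):
        c = calls[ci]
        cdir = _direction(c.state)
        for ti, t in enumerate(truth):
            if t.chrom != c.chrom or t.state != cdir:
                continue
            if c.start <= t.end and t.start <= c.end:
                detected[ti] = True
                is_fp[k] = False
                pairs.append((ti, ci))
    return Matching(truth, calls, ab_idx, detected, is_fp, pairs)


def boundary_errors(matching: Matching) -> tuple[np.ndarray, np.ndarray]:
    """(missed_length, added_length) in bp per detected truth region.

    Missed length is truth bp not covered by the union of its matched
    calls; added length is matched-call bp outside the truth region.
    """
    missed, added = [], []
    by_truth: dict[int, list[int]] = {}
    for ti, ci in matching.pairs:
        by_truth.setdefault(ti, []).append(ci)
    for ti, cis in sorted(by_truth.items()):
        t = matching.truth[ti]
        ivals = sorted((matching.calls[ci].start, matching.calls[ci].end)
                       for ci in cis)
        merged: list[list[int]] = []
        for s, e in ivals:
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        cov = sum(min(e, t.end) - max(s, t.start) + 1
                  for s, e in merged if s <= t.end and e >= t.start)
        tot = sum(e - s + 1 for s, e in merged)
        missed.append(t.length - cov)
        added.append(tot - cov)
    return np.asarray(missed, dtype=np.int64), np.asarray(added, dtype=np.int64)


_DEFAULT_BINS = (0, 50_000, 100_000, 200_000, 500_000, 1_000_000,
                 2_000_000, 4_000_000, np.inf)


@dataclass
class EvalReport:
    """Error-rate summary of a benchmark run."""

    n_truth: int
    n_called: int                  # non-CN2 calls
    n_detected: int
    n_fp: int
    miss_rate: float
    fdr: float
    fdr_defined: bool              # False when there were no aberrant calls
    dup_fraction_of_fn: float
    dup_fraction_of_fp: float
    missed_length: dict            # bp stats over detected regions
    added_length: dict
    length_bins: list              # per-truth-length-bin miss rates
    missed_marker_counts: list     # n_markers of missed CN1 regions
    missed_het_counts: list        # n_het_markers of missed CN3 regions
    del_rate_ge10_markers: float = float("nan")   # detection, CN1 with >=10 markers
    dup_rate_ge4_hets: float = float("nan")       # detection, CN3 with >=4 het markers

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)


def _stats(x: np.ndarray) -> dict:
    if len(x) == 0:
        return {"n": 0, "mean": 0.0, "median": 0.0, "max": 0}
    return {"n": int(len(x)), "mean": float(x.mean()),
            "median": float(np.median(x)), "max": int(x.max())}


def summarize(matching: Matching,
              length_bins: Sequence[float] = _DEFAULT_BINS) -> EvalReport:
    """Overall and length-stratified error rates."""
    truth = matching.truth
    n_truth = len(truth)
    n_ab = len(matching.aberrant_call_idx)
    n_det = matching.n_detected
    n_fp = int(matching.call_is_fp.sum())
    miss_rate = 1.0 - n_det / n_truth if n_truth else 0.0
    fdr_defined = n_ab > 0
    fdr = n_fp / n_ab if fdr_defined else 0.0

    missed_mask = ~matching.truth_detected
    fn_states = np.array([t.state for t in truth])[missed_mask] if n_truth else np.array([])
    dup_fn = float(np.mean(fn_states == 3)) if len(fn_states) else 0.0
    fp_states = np.array([matching.calls[ci].state
                          for ci in matching.aberrant_call_idx])[matching.call_is_fp] \
        if n_ab else np.array([])
    dup_fp = float(np.mean(fp_states == 3)) if len(fp_states) else 0.0

    missed_len, added_len = boundary_errors(matching)

    lengths = np.array([t.length for t in truth], dtype=float)
    bins = np.asarray(length_bins, dtype=float)
    rows = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        sel = (lengths >= lo) & (lengths < hi)
        rows.append({"lo": float(lo), "hi": float(hi), "n": int(sel.sum()),
                     "miss_rate": float(missed_mask[sel].mean()) if sel.any() else 0.0})

    missed_markers = [t.n_markers for t, m in zip(truth, missed_mask)
                      if m and t.state == 1]
    missed_hets = [t.n_het_markers for t, m in zip(truth, missed_mask)
                   if m and t.state == 3]

    det = matching.truth_detected
    del_big = np.array([t.state == 1 and t.n_markers >= 10 for t in truth])
    dup_big = np.array([t.state == 3 and t.n_het_markers >= 4 for t in truth])
    del_rate = float(det[del_big].mean()) if del_big.any() else float("nan")
    dup_rate = float(det[dup_big].mean()) if dup_big.any() else float("nan")
    return EvalReport(
        n_truth=n_truth, n_called=n_ab, n_detected=n_det, n_fp=n_fp,
        miss_rate=miss_rate, fdr=fdr, fdr_defined=fdr_defined,
        dup_fraction_of_fn=dup_fn, dup_fraction_of_fp=dup_fp,
        missed_length=_stats(missed_len), added_length=_stats(added_len),
        length_bins=rows, missed_marker_counts=missed_markers,
        missed_het_counts=missed_hets,
        del_rate_ge10_markers=del_rate, dup_rate_ge4_hets=dup_rate,
    )
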