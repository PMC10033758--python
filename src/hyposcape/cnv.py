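"""Windowed copy-number analysis of a hypoxia track against its matched control.

A simplified re-implementation of the windowed read-depth approach used for
case/control CNV calling: per-window depths (default 50 kb windows) are
median-normalized within each track and divided case/control, windows
failing mappability (default >= 0.85) or control-depth filters are dropped,
log2 ratios are segmented by recursive binary change-point splitting with a
breakpoint threshold (default 0.8, in multiples of the pooled within-segment
standard deviation), a baseline ploidy is selected among {2, 3, 4} as the
value under which segment ratios best resolve to integer copy numbers, and
per-window gain/loss/neutral counts are reported against that ploidy.
Matched-control normalization makes GC and mappability biases cancel in the
ratio; segmentation and every downstream step are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError

DEFAULT_MIN_MAPPABILITY = 0.85
DEFAULT_MIN_CONTROL_DEPTH = 10.0
DEFAULT_BREAKPOINT_THRESHOLD = 0.8
DEFAULT_PLOIDY_CANDIDATES = (2, 3, 4)
DEFAULT_PLOIDY_EPSILON = 0.1
MIN_SEGMENT_WINDOWS = 3
#: minimum length of an interior (segment-vs-rest) candidate; shorter interior
#: events cannot be distinguished from noise extremes under a fixed threshold
MIN_INTERIOR_WINDOWS = 20
_RATIO_FLOOR = 1e-3  # guards log2 of zero-depth case windows


@dataclass
class CnvSegment:
    chromosome: str
    start_index: int  # index into the retained-window array, half-open
    end_index: int
    mean_ratio: float  # geometric mean of window ratios
    copy_number: int | None = None
    status: str | None = None  # gain | loss | neutral

    @property
    def n_windows(self) -> int:
        return self.end_index - self.start_index


@dataclass
class CnvSummary:
    selected_ploidy: int
    cnv_windows: int
    cng_windows: int
    cnl_windows: int
    retained_windows: int
    breakpoint_threshold: float


def window_ratios(
    case: pd.DataFrame,
    control: pd.DataFrame,
    min_mappability: float = DEFAULT_MIN_MAPPABILITY,
    min_control_depth: float = DEFAULT_MIN_CONTROL_DEPTH,
) -> pd.DataFrame:
    """Median-normalized case/control depth ratio per retained window.

    Both tracks must share an identical window grid (chrom, start, end).
    Windows with mappability below ``min_mappability`` in either track or
    control depth below ``min_control_depth`` are dropped from all further
    analysis. Ratios are invariant to uniform depth scaling of either track.
    """
    grid_cols = ["chrom", "start", "end"]
    for df, name in ((case, "case"), (control, "control")):
        missing = [c for c in grid_cols + ["depth", "mappability"] if c not in df.columns]
        if missing:
            raise FormatError(f"{name} track is missing columns: {missing}")
    if len(case) != len(control) or not (
        case[grid_cols].reset_index(drop=True).equals(control[grid_cols].reset_index(drop=True))
    ):
        raise FormatError("case and control tracks do not share the same window grid")

    case_depth = case["depth"].to_numpy(dtype=float)
    control_depth = control["depth"].to_numpy(dtype=float)
    keep = (
        (case["mappability"].to_numpy(dtype=float) >= min_mappability)
        & (control["mappability"].to_numpy(dtype=float) >= min_mappability)
        & (control_depth >= min_control_depth)
    )
    if not keep.any():
        raise DomainError("all windows were filtered out")

    case_med = float(np.median(case_depth[keep]))
    control_med = float(np.median(control_depth[keep]))
    if case_med <= 0 or control_med <= 0:
        raise DomainError("median depth of a track is zero after filtering")
    ratio = (case_depth[keep] / case_med) / (control_depth[keep] / control_med)
    out = case.loc[keep, grid_cols].reset_index(drop=True)
    out["ratio"] = np.maximum(ratio, _RATIO_FLOOR)
    return out


def _best_single_cut(
    cum: np.ndarray, cum2: np.ndarray, lo: int, hi: int
) -> tuple[float, tuple[int, ...], float, float] | None:
    """Best single breakpoint of [lo, hi): (sse, cuts, |mean diff|, pooled sd)."""
    n = hi - lo
    if n < 2 * MIN_SEGMENT_WINDOWS:
        return None
    ks = np.arange(lo + MIN_SEGMENT_WINDOWS, hi - MIN_SEGMENT_WINDOWS + 1)
    nl = ks - lo
    nr = hi - ks
    sum_l = cum[ks] - cum[lo]
    sum_r = cum[hi] - cum[ks]
    sse = (cum2[ks] - cum2[lo] - sum_l**2 / nl) + (cum2[hi] - cum2[ks] - sum_r**2 / nr)
    i = int(np.argmin(sse))
    diff = abs(float(sum_l[i] / nl[i] - sum_r[i] / nr[i]))
    pooled_sd = float(np.sqrt(max(float(sse[i]), 0.0) / max(n - 2, 1)))
    return float(sse[i]), (int(ks[i]),), diff, pooled_sd


def _best_interior_segment(
    cum: np.ndarray, cum2: np.ndarray, lo: int, hi: int
) -> tuple[float, tuple[int, ...], float, float] | None:
    """Best interior segment [i, j) of [lo, hi) tested against the rest.

    Both flanks must be at least ``MIN_SEGMENT_WINDOWS`` long and the
    interior at least ``MIN_INTERIOR_WINDOWS``; the two flanks are pooled as
    a single "rest" segment.
    """
    n = hi - lo
    total_s = cum[hi] - cum[lo]
    total_s2 = cum2[hi] - cum2[lo]
    starts = np.arange(lo + MIN_SEGMENT_WINDOWS, hi - MIN_SEGMENT_WINDOWS - MIN_INTERIOR_WINDOWS + 1)
    best: tuple[float, tuple[int, ...], float, float] | None = None
    for i in starts:
        js = np.arange(i + MIN_INTERIOR_WINDOWS, hi - MIN_SEGMENT_WINDOWS + 1)
        if js.size == 0:
            continue
        ni = js - i
        nr = n - ni
        s_i = cum[js] - cum[i]
        s2_i = cum2[js] - cum2[i]
        s_r = total_s - s_i
        s2_r = total_s2 - s2_i
        sse = (s2_i - s_i**2 / ni) + (s2_r - s_r**2 / nr)
        k = int(np.argmin(sse))
        if best is None or float(sse[k]) < best[0]:
            diff = abs(float(s_i[k] / ni[k] - s_r[k] / nr[k]))
            pooled_sd = float(np.sqrt(max(float(sse[k]), 0.0) / max(n - 2, 1)))
            best = (float(sse[k]), (int(i), int(js[k])), diff, pooled_sd)
    return best


def segment_ratios(
    ratios: pd.DataFrame,
    breakpoint_threshold: float = DEFAULT_BREAKPOINT_THRESHOLD,
) -> list[CnvSegment]:
    """Recursive change-point segmentation of log2 ratios per contig.

    At each step the candidate change is either a single breakpoint or an
    interior segment tested against the rest (the circular-binary-style
    statistic needed to resolve events away from segment edges); among
    candidates the one minimizing the within-segment squared error of the
    log2 ratios is taken, and it is accepted when the absolute difference of
    the two part means exceeds ``breakpoint_threshold`` times the pooled
    within-segment standard deviation. Accepted cuts recurse into their
    parts. Segments are at least ``MIN_SEGMENT_WINDOWS`` windows long
    (interior candidates at least ``MIN_INTERIOR_WINDOWS``); each segment
    reports the geometric mean of its window ratios. Fully deterministic.
    """
    if breakpoint_threshold <= 0:
        raise DomainError("breakpoint_threshold must be > 0")
    if ratios.empty:
        raise DomainError("no retained windows to segment")

    segments: list[CnvSegment] = []
    offset = 0
    for chrom, sub in ratios.groupby("chrom", sort=False):
        x = np.log2(sub["ratio"].to_numpy(dtype=float))
        cum = np.concatenate([[0.0], np.cumsum(x)])
        cum2 = np.concatenate([[0.0], np.cumsum(x * x)])
        bounds: set[int] = set()
        stack = [(0, len(x))]
        while stack:
            lo, hi = stack.pop()
            candidates = [
                c
                for c in (
                    _best_single_cut(cum, cum2, lo, hi),
                    _best_interior_segment(cum, cum2, lo, hi),
                )
                if c is not None
            ]
            if not candidates:
                continue
            _sse, cuts, diff, pooled_sd = min(candidates, key=lambda c: c[0])
            if diff > breakpoint_threshold * pooled_sd:
                edges = [lo, *cuts, hi]
                for a, b in zip(edges[:-1], edges[1:]):
                    if b > a:
                        bounds.add(a)
                        stack.append((a, b))
        edges = sorted(bounds | {0, len(x)})
        for a, b in zip(edges[:-1], edges[1:]):
            mean_ratio = float(2.0 ** np.mean(x[a:b]))
            segments.append(CnvSegment(str(chrom), offset + a, offset + b, mean_ratio))
        offset += len(x)
    return segments


def select_ploidy(
    ratios: Sequence[float] | np.ndarray,
    candidates: Sequence[int] = DEFAULT_PLOIDY_CANDIDATES,
    epsilon: float = DEFAULT_PLOIDY_EPSILON,
) -> int:
    """Baseline ploidy explaining the most windows.

    A window is explained by candidate P when ``ratio * P`` is within
    ``epsilon`` of an integer copy number. Returns the candidate with the
    highest explained fraction; ties go to the smallest P.
    """
    if not len(candidates):
        raise DomainError("candidate set is empty")
    r = np.asarray(ratios, dtype=float)
    if r.size == 0:
        raise DomainError("empty ratio set")
    best_p, best_frac = None, -1.0
    for p in sorted(candidates):
        scaled = r * p
        explained = float(np.mean(np.abs(scaled - np.round(scaled)) <= epsilon))
        if explained > best_frac:
            best_p, best_frac = int(p), explained
    return best_p


def call_copy_number(segments: Sequence[CnvSegment], ploidy: int) -> list[CnvSegment]:
    """Assign integer copy numbers (round half away from zero) and status."""
    if ploidy < 1:
        raise DomainError("ploidy must be >= 1")
    called = []
    for seg in segments:
        cn = int(np.floor(seg.mean_ratio * ploidy + 0.5))
        status = "gain" if cn > ploidy else "loss" if cn < ploidy else "neutral"
        called.append(
            CnvSegment(seg.chromosome, seg.start_index, seg.end_index, seg.mean_ratio, cn, status)
        )
    return called


def count_cnv(
    segments: Sequence[CnvSegment],
    breakpoint_threshold: float = DEFAULT_BREAKPOINT_THRESHOLD,
) -> CnvSummary:
    """Window counts of gain/loss/total-variant status over called segments."""
    cng = sum(s.n_windows for s in segments if s.status == "gain")
    cnl = sum(s.n_windows for s in segments if s.status == "loss")
    retained = sum(s.n_windows for s in segments)
    ploidies = {s.copy_number for s in segments if s.status == "neutral"}
    selected = ploidies.pop() if len(ploidies) == 1 else 0
    return CnvSummary(
        selected_ploidy=selected,
        cnv_windows=cng + cnl,
        cng_windows=cng,
        cnl_windows=cnl,
        retained_windows=retained,
        breakpoint_threshold=breakpoint_threshold,
    )


def run_cnv(
    case: pd.DataFrame,
    control: pd.DataFrame,
    min_mappability: float = DEFAULT_MIN_MAPPABILITY,
    min_control_depth: float = DEFAULT_MIN_CONTROL_DEPTH,
    breakpoint_threshold: float = DEFAULT_BREAKPOINT_THRESHOLD,
    ploidy: int | None = None,
    ploidy_candidates: Sequence[int] = DEFAULT_PLOIDY_CANDIDATES,
    ploidy_epsilon: float = DEFAULT_PLOIDY_EPSILON,
) -> tuple[pd.DataFrame, list[CnvSegment], CnvSummary]:
    """Full CNV pipeline: ratios -> segmentation -> ploidy -> calls -> counts.

    Ploidy selection operates on segmented ratios (each retained window
    carries its segment's geometric-mean ratio), which is what lets planted
    copy-number states resolve to integers under the true baseline. Pass
    ``ploidy`` to skip selection.
    """
    ratios = window_ratios(case, control, min_mappability, min_control_depth)
    segments = segment_ratios(ratios, breakpoint_threshold)
    window_level = np.concatenate(
        [np.full(s.n_windows, s.mean_ratio) for s in segments]
    )
    if ploidy is None:
        ploidy = select_ploidy(window_level, ploidy_candidates, ploidy_epsilon)
    called = call_copy_number(segments, ploidy)
    summary = count_cnv(called, breakpoint_threshold)
    summary.selected_ploidy = int(ploidy)
    return ratios, called, summary


def window_status(segments: Sequence[CnvSegment]) -> np.ndarray:
    """Per-retained-window status array expanded from called segments."""
    return np.concatenate(
        [np.full(s.n_windows, s.status, dtype=object) for s in segments]
    )


def segments_to_frame(segments: Sequence[CnvSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chromosome": [s.chromosome for s in segments],
            "start_index": [s.start_index for s in segments],
            "end_index": [s.end_index for s in segments],
            "n_windows": [s.n_windows for s in segments],
            "mean_ratio": [s.mean_ratio for s in segments],
            "copy_number": [s.copy_number for s in segments],
            "status": [s.status for s in segments],
        }
    )
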