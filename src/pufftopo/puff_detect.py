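"""Puff identification and characterization in recorded flow traces.

Detection runs on a lightly median-filtered copy of the trace with a
dual-threshold (hysteresis) rule: a candidate puff starts when flow crosses
above the on-threshold and persists until it falls below the lower
off-threshold, which keeps noise wiggles around a single threshold from
fragmenting one puff into several. Thresholds alone truncate the slow
trapezoid ramps, biasing duration and volume low, so each candidate boundary
is then extended outward to the nearest near-zero sample. Candidates closer
together than a minimum gap are merged (a mid-puff dip is not two puffs) and
implausibly short ones dropped. All reported metrics — duration, volume,
peak and mean flow — are computed on the raw, unfiltered trace so filtering
never biases the numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import nan

import numpy as np
from scipy.ndimage import median_filter

from .flow_io import ML_PER_S_PER_SLPM, FlowTrace
from .synth_gen import TopographyParams


@dataclass(frozen=True)
class DetectConfig:
    """Detection parameters.

    Attributes
    ----------
    on_threshold_slpm
        Flow that must be reached for a candidate puff to be declared.
    off_threshold_slpm
        Flow below which a candidate ends (hysteresis: <= on threshold).
    boundary_floor_slpm
        Near-zero level to which candidate boundaries are extended outward,
        recovering the full ramp.
    min_duration_s
        Candidates shorter than this are dropped.
    min_gap_s
        Candidates separated by less than this are merged.
    median_window_ms
        Width of the denoising median filter applied before thresholding.
    """

    on_threshold_slpm: float = 0.1
    off_threshold_slpm: float = 0.05
    boundary_floor_slpm: float = 0.01
    min_duration_s: float = 0.3
    min_gap_s: float = 1.0
    median_window_ms: float = 5.0

    def __post_init__(self) -> None:
        vals = (
            self.on_threshold_slpm,
            self.off_threshold_slpm,
            self.boundary_floor_slpm,
            self.min_duration_s,
            self.min_gap_s,
            self.median_window_ms,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all detection parameters must be positive")
        if self.off_threshold_slpm > self.on_threshold_slpm:
            raise ValueError("off_threshold must not exceed on_threshold")
        if self.boundary_floor_slpm > self.off_threshold_slpm:
            raise ValueError("boundary_floor must not exceed off_threshold")


@dataclass(frozen=True)
class Puff:
    """One detected puff and its raw-trace metrics."""

    start_s: float
    end_s: float
    volume_ml: float
    max_flow_slpm: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def avg_flow_slpm(self) -> float:
        """Volume-based mean flow: (V/D) converted to slpm."""
        return self.volume_ml / self.duration_s / ML_PER_S_PER_SLPM


@dataclass(frozen=True)
class TopographySummary:
    """Per-metric means over a detected puff sequence.

    ``interpuff_s`` is the mean start-to-start interval (NaN for a single
    puff); ``intervals_s`` lists the successive intervals themselves.
    """

    duration_s: float
    volume_ml: float
    max_flow_slpm: float
    avg_flow_slpm: float
    interpuff_s: float
    n_puffs: int
    intervals_s: tuple = field(default_factory=tuple)

    def as_params(self) -> TopographyParams:
        """Convert to a programmable topography (requires >= 2 puffs)."""
        if self.n_puffs < 2 or not np.isfinite(self.interpuff_s):
            raise ValueError("need >= 2 puffs to define an inter-puff interval")
        return TopographyParams(
            duration_s=self.duration_s,
            volume_ml=self.volume_ml,
            max_flow_slpm=self.max_flow_slpm,
            interpuff_s=self.interpuff_s,
            n_puffs=self.n_puffs,
        )


def integrate_volume(trace: FlowTrace, t0: float, t1: float) -> float:
    """Trapezoidal volume (ml) of the trace between two times.

    Endpoint flows are linearly interpolated so the integral of a
    piecewise-linear signal between samples is exact.
    """
    if t1 <= t0:
        raise ValueError(f"need t0 < t1, got [{t0}, {t1}]")
    if t0 < trace.time_s[0] - 1e-12 or t1 > trace.time_s[-1] + 1e-12:
        raise ValueError(
            f"interval [{t0}, {t1}] outside trace span "
            f"[{trace.time_s[0]}, {trace.time_s[-1]}]"
        )
    t = trace.time_s
    q = trace.flow_slpm
    i0, i1 = np.searchsorted(t, [t0, t1])
    inner_t = t[i0:i1]
    inner_q = q[i0:i1]
    ts = np.concatenate(([t0], inner_t, [t1]))
    qs = np.concatenate(([np.interp(t0, t, q)], inner_q, [np.interp(t1, t, q)]))
    # searchsorted may duplicate an exact-match endpoint; dedupe keeps trapz sane
    keep = np.concatenate(([True], np.diff(ts) > 0))
    return float(np.trapezoid(qs[keep], ts[keep])) * ML_PER_S_PER_SLPM


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean mask as (first, last) index pairs."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def detect_puffs(trace: FlowTrace, cfg: DetectConfig | None = None) -> list[Puff]:
    """Identify puffs in a flow trace; returns a time-ordered disjoint list.

    Pipeline: median filter -> hysteresis candidates -> boundary extension to
    the near-zero floor -> merge close candidates -> drop short ones ->
    raw-trace metrics by trapezoidal integration. An empty list is a valid
    result for a signal-free trace.
    """
    if cfg is None:
        cfg = DetectConfig()
    f = trace.flow_slpm
    n = len(f)
    win = int(round(cfg.median_window_ms * trace.sample_rate_hz / 1000.0))
    win = max(1, win)
    if win % 2 == 0:
        win += 1
    filt = median_filter(f, size=win, mode="nearest") if win > 1 else f

    # Hysteresis: a run above the off-threshold that reaches the on-threshold.
    cands: list[tuple[int, int]] = []
    for i0, i1 in _runs(filt > cfg.off_threshold_slpm):
        if filt[i0 : i1 + 1].max() >= cfg.on_threshold_slpm:
            cands.append((i0, i1))

    # Extend boundaries outward to the nearest sample at/below the floor.
    floor_idx = np.flatnonzero(filt <= cfg.boundary_floor_slpm)
    extended: list[tuple[int, int]] = []
    for i0, i1 in cands:
        p = np.searchsorted(floor_idx, i0)
        j0 = int(floor_idx[p - 1]) if p > 0 else 0
        p = np.searchsorted(floor_idx, i1, side="right")
        j1 = int(floor_idx[p]) if p < len(floor_idx) else n - 1
        extended.append((j0, j1))

    # Merge candidates whose gap is below min_gap_s.
    t = trace.time_s
    merged: list[list[int]] = []
    for i0, i1 in extended:
        if merged and t[i0] - t[merged[-1][1]] < cfg.min_gap_s:
            merged[-1][1] = max(merged[-1][1], i1)
        else:
            merged.append([i0, i1])

    puffs: list[Puff] = []
    for i0, i1 in merged:
        start, end = float(t[i0]), float(t[i1])
        if end - start < cfg.min_duration_s:
            continue
        vol = integrate_volume(trace, start, end)
        puffs.append(
            Puff(
                start_s=start,
                end_s=end,
                volume_ml=vol,
                max_flow_slpm=float(f[i0 : i1 + 1].max()),
            )
        )
    return puffs


def summarize_topography(puffs: list[Puff]) -> TopographySummary:
    """Mean topography metrics and start-to-start intervals of a puff list."""
    if not puffs:
        raise ValueError("cannot summarize an empty puff list")
    starts = np.array([p.start_s for p in puffs])
    intervals = tuple(np.diff(starts).tolist())
    return TopographySummary(
        duration_s=float(np.mean([p.duration_s for p in puffs])),
        volume_ml=float(np.mean([p.volume_ml for p in puffs])),
        max_flow_slpm=float(np.mean([p.max_flow_slpm for p in puffs])),
        avg_flow_slpm=float(np.mean([p.avg_flow_slpm for p in puffs])),
        interpuff_s=float(np.mean(intervals)) if intervals else nan,
        n_puffs=len(puffs),
        intervals_s=intervals,
    )
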