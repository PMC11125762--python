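"""Delimited-text I/O for flow-meter logs and smoking-machine control profiles.

The sampling system records airflow through the cigarette at ~1 kHz with a
solid-state flow meter; recorded traces are reduced to 100-ms setpoint
profiles that drive the mass flow controller. Both artifacts are plain
delimited text (CSV/TSV) so they survive transfer between the field tablet
and the analysis machine. Canonical internal units are seconds, standard
liters per minute (slpm), and milliliters for volumes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

#: ml drawn per second at a flow of 1 slpm (1 L/min = 1000 ml / 60 s).
ML_PER_S_PER_SLPM = 1000.0 / 60.0

#: Relative tolerance on sample spacing for a trace to count as uniform.
UNIFORMITY_TOL = 0.1


class FlowIOError(ValueError):
    """Malformed flow log or control profile."""


@dataclass
class FlowTrace:
    """Uniformly sampled flow time series (sensor record or simulator output).

    Parameters
    ----------
    time_s
        Sample times in seconds from record start; strictly increasing,
        non-negative, uniform to within 10% of the nominal sample period.
    flow_slpm
        Flow rate in standard L/min. May dip slightly below zero from
        sensor noise.
    sample_rate_hz
        Nominal sampling frequency.
    meta
        Free-form provenance (device id, acquisition date, generator
        parameters, ...).
    """

    time_s: np.ndarray
    flow_slpm: np.ndarray
    sample_rate_hz: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.flow_slpm = np.asarray(self.flow_slpm, dtype=float)
        if self.time_s.ndim != 1 or self.flow_slpm.ndim != 1:
            raise FlowIOError("time and flow must be 1-D arrays")
        if len(self.time_s) != len(self.flow_slpm):
            raise FlowIOError(
                f"time ({len(self.time_s)}) and flow ({len(self.flow_slpm)}) "
                "lengths differ"
            )
        if len(self.time_s) < 1:
            raise FlowIOError("trace must contain at least one sample")
        if self.time_s[0] < 0:
            raise FlowIOError("time must be non-negative")
        if self.sample_rate_hz <= 0:
            raise FlowIOError("sample_rate_hz must be positive")
        if len(self.time_s) > 1:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0))
                raise FlowIOError(
                    f"time not strictly increasing at sample {i + 1} "
                    f"(t={self.time_s[i + 1]:g} after t={self.time_s[i]:g})"
                )
            period = 1.0 / self.sample_rate_hz
            if np.max(np.abs(dt - period)) >= UNIFORMITY_TOL * period:
                raise FlowIOError(
                    "sampling is not uniform at the declared rate "
                    f"({self.sample_rate_hz:g} Hz)"
                )

    def __len__(self) -> int:
        return len(self.time_s)

    @classmethod
    def from_samples(
        cls, flow_slpm: np.ndarray, sample_rate_hz: float, meta: dict | None = None
    ) -> "FlowTrace":
        """Build a trace from flow samples on an implicit uniform grid."""
        flow = np.asarray(flow_slpm, dtype=float)
        t = np.arange(len(flow)) / sample_rate_hz
        return cls(t, flow, sample_rate_hz, meta or {})

    def baseline_ok(self, window_s: float = 1.0, floor_slpm: float = -0.05) -> bool:
        """Check that no 1-s moving-average window dips below the noise floor.

        A physical draw cannot be persistently negative; sustained negative
        means indicate a sensor or parsing problem rather than jitter.
        """
        n = max(1, int(round(window_s * self.sample_rate_hz)))
        if len(self.flow_slpm) < n:
            return bool(np.mean(self.flow_slpm) >= floor_slpm)
        c = np.cumsum(np.concatenate(([0.0], self.flow_slpm)))
        means = (c[n:] - c[:-n]) / n
        return bool(means.min() >= floor_slpm)


@dataclass
class ControlProfile:
    """100-ms bin-averaged flow setpoints driving the smoking machine."""

    bin_start_s: np.ndarray
    bin_flow_slpm: np.ndarray
    bin_width_s: float = 0.1

    def __post_init__(self) -> None:
        self.bin_start_s = np.asarray(self.bin_start_s, dtype=float)
        self.bin_flow_slpm = np.asarray(self.bin_flow_slpm, dtype=float)
        if len(self.bin_start_s) != len(self.bin_flow_slpm):
            raise FlowIOError("bin_start_s and bin_flow_slpm lengths differ")
        if len(self.bin_start_s) < 1:
            raise FlowIOError("profile must contain at least one bin")
        if self.bin_width_s <= 0:
            raise FlowIOError("bin_width_s must be positive")
        if np.any(self.bin_flow_slpm < 0):
            raise FlowIOError("setpoints must be non-negative")
        if len(self.bin_start_s) > 1:
            gaps = np.diff(self.bin_start_s)
            if np.max(np.abs(gaps - self.bin_width_s)) > 1e-6 * self.bin_width_s:
                raise FlowIOError("bins must be contiguous and non-overlapping")

    def __len__(self) -> int:
        return len(self.bin_start_s)

    @property
    def end_s(self) -> float:
        """Right edge of the last bin."""
        return float(self.bin_start_s[-1] + self.bin_width_s)


# ---------------------------------------------------------------------------
# Flow logs
# ---------------------------------------------------------------------------

def _read_two_columns(path: Union[str, Path], delimiter: str | None) -> pd.DataFrame:
    """Read a two-column numeric table, auto-detecting header and delimiter."""
    path = Path(path)
    if not path.exists():
        raise FlowIOError(f"no such file: {path}")
    text = path.read_text()
    if not text.strip():
        raise FlowIOError(f"empty file: {path}")
    if delimiter is None:
        # sniff from the first non-comment line: comma, tab, or whitespace
        first_line = next(
            (ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")),
            "",
        )
        delimiter = "," if "," in first_line else ("\t" if "\t" in first_line else r"\s+")
    try:
        df = pd.read_csv(
            io.StringIO(text),
            sep=delimiter,
            header=None,
            comment="#",
            skip_blank_lines=True,
            float_precision="round_trip",
        )
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise FlowIOError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise FlowIOError(f"{path}: need at least two columns, got {df.shape[1]}")
    df = df.iloc[:, :2]
    # Header auto-detection: a non-numeric first row is a header.
    first = df.iloc[0]
    if pd.to_numeric(first, errors="coerce").isna().any():
        df = df.iloc[1:].reset_index(drop=True)
        if df.empty:
            raise FlowIOError(f"{path}: header only, no data rows")
    probe = df.apply(pd.to_numeric, errors="coerce")
    bad = probe.isna().any(axis=1)
    if bad.any():
        row = int(np.argmax(bad.to_numpy()))
        raise FlowIOError(f"{path}: non-numeric cell in data row {row + 1}")
    # astype goes through Python float() on object columns, which round-trips
    # exactly; to_numeric's parser can be off by one ulp
    return df.astype(float)


def read_flow_log(
    path: Union[str, Path],
    time_unit: str = "ms",
    delimiter: str | None = None,
) -> FlowTrace:
    """Read a raw flow-meter log into a :class:`FlowTrace`.

    The default dialect is the meter software's export: comma- or
    tab-delimited, first column time in milliseconds, second column flow in
    slpm, with an optional header row detected by a non-numeric first line.
    Time is shifted so the record starts at zero; the original offset is kept
    in ``meta['time_offset_s']``.

    Parameters
    ----------
    path
        File to read.
    time_unit
        ``"ms"`` or ``"s"`` — unit of the time column.
    delimiter
        Explicit delimiter; ``None`` sniffs comma/tab/whitespace.
    """
    if time_unit not in ("ms", "s"):
        raise FlowIOError(f"time_unit must be 'ms' or 's', got {time_unit!r}")
    num = _read_two_columns(path, delimiter)
    t = num.iloc[:, 0].to_numpy(dtype=float)
    flow = num.iloc[:, 1].to_numpy(dtype=float)
    if time_unit == "ms":
        t = t / 1000.0
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise FlowIOError(
                f"{path}: time not strictly increasing at data row {i + 2}"
            )
        sample_rate = 1.0 / float(np.median(dt))
    else:
        sample_rate = 1.0
    offset = float(t[0])
    return FlowTrace(
        t - offset,
        flow,
        sample_rate_hz=sample_rate,
        meta={"source": str(path), "time_offset_s": offset},
    )


def write_flow_log(trace: FlowTrace, path: Union[str, Path]) -> None:
    """Write a trace as ``time_ms,flow_slpm`` delimited text with header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("time_ms,flow_slpm\n")
        for t, q in zip(trace.time_s, trace.flow_slpm):
            fh.write(f"{t * 1000.0:.6f},{q:.10g}\n")


# ---------------------------------------------------------------------------
# Control profiles
# ---------------------------------------------------------------------------

def _fmt_flow(v: float) -> str:
    # Six decimals for readability; fall back to repr when that would lose
    # precision so write -> read is exact.
    v = float(v)
    s = f"{v:.6f}"
    return s if float(s) == v else repr(v)


def write_control_profile(profile: ControlProfile, path: Union[str, Path]) -> None:
    """Write a control profile as ``time_ms,flow_slpm`` delimited text.

    Bin starts are written as integer milliseconds (the machine's command
    grid); flows with at least six decimals, exactly invertible by
    :func:`read_control_profile`.
    """
    if not isinstance(profile, ControlProfile):
        raise FlowIOError("profile must be a ControlProfile")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("time_ms,flow_slpm\n")
        for t, q in zip(profile.bin_start_s, profile.bin_flow_slpm):
            fh.write(f"{int(round(t * 1000.0))},{_fmt_flow(q)}\n")


def read_control_profile(
    path: Union[str, Path],
    bin_width_s: float | None = None,
    delimiter: str | None = None,
) -> ControlProfile:
    """Read a control profile written by :func:`write_control_profile`.

    ``bin_width_s`` is inferred from the bin spacing when the file has two or
    more bins; a single-bin file needs it passed explicitly (default 0.1 s).
    """
    num = _read_two_columns(path, delimiter)
    start_s = num.iloc[:, 0].to_numpy(dtype=float) / 1000.0
    flow = num.iloc[:, 1].to_numpy(dtype=float)
    if bin_width_s is None:
        if len(start_s) > 1:
            bin_width_s = float(np.median(np.diff(start_s)))
        else:
            bin_width_s = 0.1
    return ControlProfile(start_s, flow, bin_width_s)
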