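"""Simulated playback of a control profile through the smoking machine.

The mass flow controller is modeled as a first-order lag driven by a
zero-order-hold command stream: the setpoint is the profile value, refreshed
every command interval and delayed by the serial-transport latency, and the
achieved flow relaxes toward it as dQ/dt = (setpoint - Q)/tau. Each
simulation step applies the exact exponential update for a held setpoint, so
the integration is exact between command switches at any sample rate. The
actuator ceiling is applied to the setpoint, which keeps the response inside
[0, max_flow] without distorting the dynamics.

Fidelity scoring compares the achieved trace, re-binned onto the profile's
grid, against the programmed setpoints: per-bin relative deviations (bins
with near-zero programmed flow are excluded from the statistics to avoid
division blow-ups) and the total-volume relative error, the headline figure
of merit for a playback system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .flow_io import ControlProfile, FlowTrace
from .profile_control import bin_average, profile_volume
from .puff_detect import integrate_volume


@dataclass(frozen=True)
class MfcModel:
    """First-order mass-flow-controller dynamics.

    Attributes
    ----------
    time_constant_s
        First-order response constant tau; 0 means instantaneous tracking.
    command_interval_s
        Setpoint refresh period of the command stream (>= 10 ms).
    latency_s
        Transport delay between issuing a command and the setpoint change.
    max_flow_slpm
        Actuator ceiling.
    """

    time_constant_s: float = 0.05
    command_interval_s: float = 0.1
    latency_s: float = 0.02
    max_flow_slpm: float = 5.0

    def __post_init__(self) -> None:
        if min(self.time_constant_s, self.latency_s, self.max_flow_slpm) < 0:
            raise ValueError("model parameters must be non-negative")
        if self.command_interval_s < 0.01:
            raise ValueError("command_interval_s must be >= 0.01 s")


@dataclass(frozen=True)
class FidelityReport:
    """How well an achieved trace reproduced its programmed profile."""

    programmed_volume_ml: float
    achieved_volume_ml: float
    volume_error_frac: float
    mean_bin_deviation_frac: float
    max_bin_deviation_frac: float
    n_bins_scored: int

    def as_dict(self) -> dict:
        return {
            "programmed_volume_ml": self.programmed_volume_ml,
            "achieved_volume_ml": self.achieved_volume_ml,
            "volume_error_frac": self.volume_error_frac,
            "mean_bin_deviation_frac": self.mean_bin_deviation_frac,
            "max_bin_deviation_frac": self.max_bin_deviation_frac,
            "n_bins_scored": self.n_bins_scored,
        }


def _setpoints(
    profile: ControlProfile, model: MfcModel, t: np.ndarray
) -> np.ndarray:
    """Commanded setpoint at each sample time (ZOH + latency + ceiling)."""
    ci = model.command_interval_s
    k = np.floor((t - model.latency_s) / ci + 1e-9)
    cmd_t = np.maximum(k, 0) * ci
    bins = np.floor(cmd_t / profile.bin_width_s + 1e-9).astype(int)
    # the right edge of the profile belongs to the last bin (ZOH holds the
    # final setpoint through its full bin, including the closing instant)
    valid = (k >= 0) & (cmd_t <= profile.end_s * (1 + 1e-12))
    bins = np.clip(bins, 0, len(profile) - 1)
    sp = np.where(valid, profile.bin_flow_slpm[bins], 0.0)
    return np.clip(sp, 0.0, model.max_flow_slpm)


def simulate_mfc(
    profile: ControlProfile,
    model: MfcModel | None = None,
    sample_rate_hz: float = 1000.0,
) -> FlowTrace:
    """Play a control profile through the first-order MFC model.

    Returns the achieved flow trace sampled at ``sample_rate_hz`` over the
    profile's span, starting from zero flow.
    """
    if model is None:
        model = MfcModel()
    dt = 1.0 / sample_rate_hz
    n = int(round(profile.end_s * sample_rate_hz))
    t = np.arange(n + 1) * dt
    sp = _setpoints(profile, model, t)
    tau = model.time_constant_s
    if tau == 0:
        q = sp.copy()
    else:
        # Exact discrete update for a held setpoint:
        #   Q[i+1] = a*Q[i] + (1-a)*sp[i],  a = exp(-dt/tau)
        a = np.exp(-dt / tau)
        q = np.empty_like(sp)
        q[0] = 0.0
        q[1:] = lfilter([1.0 - a], [1.0, -a], sp[:-1])
    meta = {
        "simulator": "first-order MFC",
        "time_constant_s": model.time_constant_s,
        "command_interval_s": model.command_interval_s,
        "latency_s": model.latency_s,
        "max_flow_slpm": model.max_flow_slpm,
    }
    return FlowTrace(t, q, sample_rate_hz, meta)


def fidelity(
    profile: ControlProfile,
    achieved: FlowTrace,
    score_threshold_slpm: float = 0.1,
) -> FidelityReport:
    """Score how faithfully an achieved trace reproduces its profile.

    The achieved trace is bin-averaged onto the profile's bins; per-bin
    deviation |achieved - programmed| / programmed is reported for bins whose
    programmed flow is at least ``score_threshold_slpm`` (all bins still
    count toward the volumes). The volume error compares total integrated
    achieved volume with the programmed profile volume.
    """
    prog_vol = profile_volume(profile)
    if prog_vol <= 0:
        raise ValueError("programmed profile volume is zero; nothing to score")
    if achieved.time_s[-1] < profile.end_s - profile.bin_width_s:
        raise ValueError("achieved trace does not span the profile")
    t_end = min(float(achieved.time_s[-1]), profile.end_s)
    ach_vol = integrate_volume(achieved, float(achieved.time_s[0]), t_end)

    ach_bins = bin_average(achieved, profile.bin_width_s).bin_flow_slpm
    n = len(profile)
    if len(ach_bins) < n:
        ach_bins = np.pad(ach_bins, (0, n - len(ach_bins)))
    ach_bins = ach_bins[:n]
    prog = profile.bin_flow_slpm
    scored = prog >= score_threshold_slpm
    if not scored.any():
        raise ValueError(
            "no profile bin reaches the scoring threshold "
            f"({score_threshold_slpm} slpm)"
        )
    dev = np.abs(ach_bins[scored] - prog[scored]) / prog[scored]
    return FidelityReport(
        programmed_volume_ml=prog_vol,
        achieved_volume_ml=ach_vol,
        volume_error_frac=abs(ach_vol - prog_vol) / prog_vol,
        mean_bin_deviation_frac=float(dev.mean()),
        max_bin_deviation_frac=float(dev.max()),
        n_bins_scored=int(scored.sum()),
    )
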