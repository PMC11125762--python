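"""Synthetic flow traces with known ground-truth puff topography.

A puff is rendered as a symmetric trapezoid: linear ramp up, plateau at the
maximum flow, linear ramp down. The trapezoid is the minimal waveform that
simultaneously honours the three per-puff quantities a topography table
prints — duration D, volume V, and peak flow Qmax — because the ramp length
r = D - V/Qmax (with Qmax in ml/s) is then fully determined. Traces carry
i.i.d. Gaussian sensor noise and a zero-flow second of padding at each end,
so the detector downstream is exercised under realistic conditions without
any hardware.

The built-in named profiles are the four smoking-regimen topographies used
when sampling hemp cigarettes: three flow conditions spanning real-world
cannabis users' behaviour plus the Massachusetts DPH medium-intensive
regimen. All use 30-s start-to-start inter-puff spacing and three puffs per
sample, matching the collection protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flow_io import ML_PER_S_PER_SLPM, FlowTrace

#: Relative slack on the trapezoid feasibility bounds (float round-off only).
_FEAS_RTOL = 1e-9


@dataclass(frozen=True)
class TopographyParams:
    """A programmable puff topography (one column of a regimen table).

    Attributes
    ----------
    duration_s
        Single-puff duration D.
    volume_ml
        Single-puff volume V.
    max_flow_slpm
        Peak flow Qmax, in standard L/min.
    interpuff_s
        Start-to-start interval between consecutive puffs.
    n_puffs
        Number of puffs in the sequence.
    """

    duration_s: float
    volume_ml: float
    max_flow_slpm: float
    interpuff_s: float = 30.0
    n_puffs: int = 3

    def __post_init__(self) -> None:
        for name in ("duration_s", "volume_ml", "max_flow_slpm", "interpuff_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_puffs < 1:
            raise ValueError("n_puffs must be >= 1")
        if self.n_puffs > 1 and self.interpuff_s <= self.duration_s:
            raise ValueError(
                "interpuff_s (start-to-start) must exceed duration_s, got "
                f"{self.interpuff_s} <= {self.duration_s}"
            )
        qmax = self.max_flow_ml_s
        vmax = qmax * self.duration_s
        if self.volume_ml > vmax * (1 + _FEAS_RTOL):
            raise ValueError(
                f"volume {self.volume_ml} ml exceeds max_flow*duration = "
                f"{vmax:.4g} ml: physically impossible"
            )
        if self.volume_ml < vmax / 2 * (1 - _FEAS_RTOL):
            raise ValueError(
                f"volume {self.volume_ml} ml below the triangle limit "
                f"{vmax / 2:.4g} ml; lower max_flow_slpm to make the "
                "trapezoid feasible"
            )

    @property
    def max_flow_ml_s(self) -> float:
        """Peak flow in ml/s."""
        return self.max_flow_slpm * ML_PER_S_PER_SLPM

    @property
    def ramp_s(self) -> float:
        """Ramp length r = D - V/Qmax of the symmetric trapezoid."""
        return self.duration_s - self.volume_ml / self.max_flow_ml_s

    @property
    def avg_flow_slpm(self) -> float:
        """Volume-based mean flow V/D, converted to slpm."""
        return self.volume_ml / self.duration_s / ML_PER_S_PER_SLPM


#: Named topographies: hemp-cigarette sampling conditions (High/Med/Low flow)
#: and the Mass. DPH medium-intensive regimen. 30-s spacing, 3 puffs each.
PROFILES: dict[str, TopographyParams] = {
    "high_flow": TopographyParams(1.7, 65.0, 3.4),
    "med_flow": TopographyParams(1.6, 59.7, 2.9),
    "low_flow": TopographyParams(2.1, 66.5, 2.4),
    "mdph": TopographyParams(2.0, 45.7, 1.9),
}


def puff_flow(t_rel: np.ndarray, params: TopographyParams) -> np.ndarray:
    """Trapezoid flow (slpm) at times relative to puff start; 0 outside."""
    r = params.ramp_s
    d = params.duration_s
    q = params.max_flow_slpm
    t_rel = np.asarray(t_rel, dtype=float)
    if r <= 0:  # rectangle limit
        return np.where((t_rel >= 0) & (t_rel <= d), q, 0.0)
    out = np.interp(t_rel, [0.0, r, d - r, d], [0.0, q, q, 0.0], left=0.0, right=0.0)
    # interp is flat outside; zero anything outside the puff explicitly
    out = np.where((t_rel < 0) | (t_rel > d), 0.0, out)
    return out


def trapezoid_from_topography(
    params: TopographyParams, sample_rate_hz: float = 1000.0
) -> tuple[np.ndarray, np.ndarray]:
    """Render one puff as a sampled symmetric trapezoid.

    Returns ``(time_s, flow_slpm)`` covering exactly one puff duration,
    endpoints included. The numeric integral of the waveform equals the
    programmed volume to within 0.1% at 1 kHz.
    """
    n = int(round(params.duration_s * sample_rate_hz))
    t = np.arange(n + 1) / sample_rate_hz
    return t, puff_flow(t, params)


def generate_trace(
    params: TopographyParams,
    sample_rate_hz: float = 1000.0,
    noise_sd_slpm: float = 0.0,
    seed: int | None = None,
    pad_s: float = 1.0,
) -> FlowTrace:
    """Generate a puff-train trace: trapezoids, baseline, noise, padding.

    ``n_puffs`` trapezoids are placed at start-to-start spacing
    ``interpuff_s`` on a zero baseline, with ``pad_s`` of zero flow at both
    ends, and i.i.d. Gaussian noise of sd ``noise_sd_slpm`` added to every
    sample (unclipped — negative excursions mimic sensor jitter). The trace
    is reproducible for a fixed ``seed``.
    """
    if noise_sd_slpm < 0:
        raise ValueError("noise_sd_slpm must be non-negative")
    if sample_rate_hz < 100:
        raise ValueError("sample_rate_hz must be >= 100")
    total = 2 * pad_s + (params.n_puffs - 1) * params.interpuff_s + params.duration_s
    n = int(round(total * sample_rate_hz))
    t = np.arange(n + 1) / sample_rate_hz
    flow = np.zeros_like(t)
    for i in range(params.n_puffs):
        start = pad_s + i * params.interpuff_s
        flow += puff_flow(t - start, params)
    if noise_sd_slpm > 0:
        rng = np.random.default_rng(seed)
        flow = flow + rng.normal(0.0, noise_sd_slpm, size=len(flow))
    meta = {
        "generator": "trapezoid",
        "duration_s": params.duration_s,
        "volume_ml": params.volume_ml,
        "max_flow_slpm": params.max_flow_slpm,
        "interpuff_s": params.interpuff_s,
        "n_puffs": params.n_puffs,
        "noise_sd_slpm": noise_sd_slpm,
        "seed": seed,
        "pad_s": pad_s,
    }
    return FlowTrace(t, flow, sample_rate_hz, meta)
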