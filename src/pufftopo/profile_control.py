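"""Reduce a recorded trace to the 100-ms control profile the machine replays.

Bins are left-aligned at trace time zero and contiguous, so zero-flow bins
between puffs are retained: the machine must reproduce the inter-puff pauses
as faithfully as the puffs themselves. Bin values are sample means; a
trailing partial bin is averaged over the samples it actually contains, and
negative means (sensor noise) are clipped to zero because a mass flow
controller cannot command negative flow.
"""

from __future__ import annotations

import numpy as np

from .flow_io import ML_PER_S_PER_SLPM, ControlProfile, FlowTrace


def bin_average(trace: FlowTrace, bin_width_s: float = 0.1) -> ControlProfile:
    """Bin-average a flow trace into a contiguous setpoint profile.

    Bin k covers [k*width, (k+1)*width); its setpoint is the mean of the
    samples falling in that window, clipped at zero. Requires the bin to
    span at least two sample periods.
    """
    if bin_width_s < 2.0 / trace.sample_rate_hz:
        raise ValueError(
            f"bin width {bin_width_s} s is narrower than two sample periods "
            f"at {trace.sample_rate_hz:g} Hz"
        )
    t = trace.time_s
    idx = np.floor(t / bin_width_s + 1e-9).astype(int)
    n_bins = int(idx.max()) + 1
    sums = np.bincount(idx, weights=trace.flow_slpm, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    means = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    means = np.clip(means, 0.0, None)
    starts = np.arange(n_bins) * bin_width_s
    return ControlProfile(starts, means, bin_width_s)


def profile_volume(profile: ControlProfile) -> float:
    """Total programmed volume (ml): sum of setpoint * bin width."""
    return float(np.sum(profile.bin_flow_slpm) * profile.bin_width_s) * ML_PER_S_PER_SLPM
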