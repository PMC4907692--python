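"""Threshold-crossing idealization of leak-subtracted current traces.

The 50% threshold-crossing technique converts a noisy sweep into an
integer occupancy sequence: a sample whose amplitude exceeds half the
unitary current is called open.  With N channels in the patch, N evenly
spaced thresholds assign levels 0..N (simultaneous openings).  When
subconductance levels should be counted as openings, the threshold
fraction is dropped slightly below 50% of the full amplitude.

For inward currents (negative voltages) all comparisons run on
magnitudes with the sign carried through, so a -2.5 pA channel with a
-1.25 pA threshold behaves exactly like its outward mirror image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d

__all__ = [
    "IdealizedSweep",
    "BINOMIAL_KERNEL",
    "binomial_smooth",
    "choose_thresholds",
    "idealize_threshold",
    "idealize_sweep",
]

# normalized 4th-order binomial kernel; one pass of the standard
# "binomial smoothing" operation
BINOMIAL_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass
class IdealizedSweep:
    """Integer occupancy levels aligned sample-for-sample to a trace."""

    levels: np.ndarray           # int, values in 0..n_channels
    thresholds: tuple[float, ...]  # pA, ascending magnitude, signed
    n_channels: int
    voltage_mV: float

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=int)
        if self.levels.min(initial=0) < 0 or self.levels.max(initial=0) > self.n_channels:
            raise ValueError("levels must lie in 0..n_channels")


def binomial_smooth(trace: np.ndarray, passes: int = 5) -> np.ndarray:
    """Apply ``passes`` rounds of (1,4,6,4,1)/16 smoothing, reflecting at
    the edges.  ``passes=0`` returns the trace unchanged."""
    if passes < 0:
        raise ValueError("passes must be >= 0")
    trace = np.asarray(trace, dtype=float)
    if trace.size < BINOMIAL_KERNEL.size:
        raise ValueError("trace shorter than the smoothing kernel")
    for _ in range(passes):
        trace = convolve1d(trace, BINOMIAL_KERNEL, mode="reflect")
    return trace


def choose_thresholds(
    unitary_amplitude: float, n_channels: int = 1, subconductance_mode: bool = False
) -> list[float]:
    """Evenly spaced occupancy thresholds from the unitary amplitude.

    The level-k threshold is ``(k - 1 + f) * |amplitude|`` with the sign
    of the amplitude, k = 1..N.  ``f`` is 0.50 (the midpoint rule) or
    0.45 in subconductance mode, where the threshold is pulled slightly
    below 50% so that substate sojourns are still counted as openings.
    """
    if unitary_amplitude == 0:
        raise ValueError("unitary amplitude must be nonzero")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    f = 0.45 if subconductance_mode else 0.50
    sign = 1.0 if unitary_amplitude > 0 else -1.0
    mag = abs(unitary_amplitude)
    return [sign * (k - 1 + f) * mag for k in range(1, n_channels + 1)]


def idealize_threshold(
    trace: np.ndarray, thresholds, *, voltage_mV: float = 0.0
) -> IdealizedSweep:
    """Assign each sample the count of thresholds it strictly exceeds.

    Comparison is on magnitudes; a sample exactly at a threshold takes
    the lower level (conservative opening count).  Thresholds must share
    one sign and ascend in magnitude.
    """
    thr = np.asarray(thresholds, dtype=float)
    if thr.size == 0:
        raise ValueError("at least one threshold is required")
    if np.any(thr > 0) and np.any(thr < 0):
        raise ValueError("thresholds must share a sign")
    mags = np.abs(thr)
    if np.any(np.diff(mags) <= 0):
        raise ValueError("threshold magnitudes must be strictly ascending")
    sample_mag = np.abs(np.asarray(trace, dtype=float))
    levels = (sample_mag[:, None] > mags[None, :]).sum(axis=1)
    return IdealizedSweep(levels=levels, thresholds=tuple(thr.tolist()),
                          n_channels=thr.size, voltage_mV=voltage_mV)


def idealize_sweep(
    trace: np.ndarray,
    unitary_amplitude: float,
    n_channels: int = 1,
    *,
    voltage_mV: float = 0.0,
    subconductance_mode: bool = False,
    smooth_passes: int = 0,
) -> IdealizedSweep:
    """Smooth (optionally) and threshold one analysis slice.

    Convenience wrapper combining :func:`binomial_smooth`,
    :func:`choose_thresholds` and :func:`idealize_threshold`.  Smoothing
    is conventionally applied only where the signal-to-noise ratio is
    poor (small-amplitude inward currents); the caller decides by
    passing ``smooth_passes``.
    """
    if smooth_passes:
        trace = binomial_smooth(trace, smooth_passes)
    thresholds = choose_thresholds(unitary_amplitude, n_channels, subconductance_mode)
    out = idealize_threshold(trace, thresholds, voltage_mV=voltage_mV)
    out.n_channels = n_channels
    return out
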