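"""Open-probability, amplitude and conductance estimation.

Two independent estimates of the open probability are supported, and
agreement between them is a useful internal control:

* **idealized** — P_o per sweep is the mean of the 0/1 (or 0..N)
  idealized occupancy levels; the patch mean averages sweeps acquired
  after the initial agonist wash-in silent period.
* **histogram** — an all-points amplitude histogram is compiled from
  every analyzed data point, normalized to unit area, and fit with a
  Gaussian mixture; the closed component (centered at 0 pA) has area
  ``A_C`` and ``P_o = 1 - A_C``.  Any density not under the closed peak
  — including subconductance occupancy — counts as open.

The unitary current amplitude is the mean of the open-level Gaussian,
and the chord conductance follows as ``g = i / V`` (reversal at 0 mV in
symmetrical solutions).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import ndtr

from .idealize import IdealizedSweep, idealize_sweep
from .filters import gaussian_lowpass
from .sweepio import Recording, segment_by_voltage

__all__ = [
    "PoEstimate",
    "AllPointsHistogram",
    "HistogramFit",
    "po_per_sweep",
    "po_timecourse",
    "lowpass_recording",
    "allpoints_histogram",
    "fit_histogram",
    "estimate_po_idealized",
    "estimate_po_histogram",
    "compare_po_methods",
    "chord_conductance",
]

#: per-sweep P_o below which an initial sweep counts as pre-activation
#: silence (roughly one single-sample opening per 500 ms sweep)
DEFAULT_ACTIVITY_FLOOR = 0.005


@dataclass
class PoEstimate:
    """Per-sweep open-probability series and its patch mean.

    ``mean_po`` excludes the silent prefix (the maximal initial run of
    sweeps below the activity floor); for multi-channel patches the
    values are NP_o in [0, N] rather than P_o in [0, 1].
    """

    per_sweep: list[tuple[int, float]]
    mean_po: float
    method: str                      # "idealized" or "histogram"
    excluded_prefix_sweeps: int = 0
    n_channels: int = 1

    @property
    def is_npo(self) -> bool:
        return self.n_channels > 1


@dataclass
class AllPointsHistogram:
    """Area-normalized amplitude density over one voltage's data points."""

    bin_edges: np.ndarray   # pA, len = len(density) + 1
    density: np.ndarray     # 1/pA; integrates to 1
    voltage_mV: float
    n_points: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def binwidth(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class HistogramFit:
    """Gaussian-mixture decomposition of an all-points histogram."""

    closed_mean: float
    closed_sd: float
    closed_area: float                       # A_C
    open_components: list[tuple[float, float, float]]  # (mean, sd, area)
    converged: bool
    residual_norm: float
    binwidth: float

    @property
    def po_hist(self) -> float:
        return 1.0 - self.closed_area

    @property
    def unitary_amplitude(self) -> float:
        """Mean of the largest-area open component, pA."""
        if not self.open_components:
            return float("nan")
        return max(self.open_components, key=lambda c: c[2])[0]


def po_per_sweep(ideal: IdealizedSweep) -> float:
    """Mean idealized level: P_o for one channel, NP_o for N channels."""
    if ideal.levels.size == 0:
        raise ValueError("idealized sweep has no samples")
    return float(ideal.levels.mean())


def po_timecourse(
    ideals: list[IdealizedSweep],
    sweep_indices: list[int] | None = None,
    activity_floor: float = DEFAULT_ACTIVITY_FLOOR,
    method: str = "idealized",
) -> PoEstimate:
    """Per-sweep P_o series with the agonist wash-in prefix excluded.

    The silent prefix is the maximal initial run of sweeps whose P_o is
    below ``activity_floor``; those sweeps are reported but excluded
    from the mean, which should reflect agonist-bound channels.  If
    every sweep is silent the mean is NaN.
    """
    if not ideals:
        raise ValueError("no idealized sweeps given")
    if sweep_indices is None:
        sweep_indices = list(range(len(ideals)))
    values = [po_per_sweep(i) for i in ideals]
    n_excluded = 0
    for v in values:
        if v < activity_floor:
            n_excluded += 1
        else:
            break
    included = values[n_excluded:]
    mean = float(np.mean(included)) if included else float("nan")
    return PoEstimate(
        per_sweep=list(zip(sweep_indices, values)),
        mean_po=mean,
        method=method,
        excluded_prefix_sweeps=n_excluded,
        n_channels=max(i.n_channels for i in ideals),
    )


def lowpass_recording(rec: Recording, cutoff_hz: float) -> Recording:
    """Offline low-pass filter applied to every sweep of a recording."""
    sweeps = [
        dataclasses.replace(s, samples=gaussian_lowpass(s.samples, cutoff_hz,
                                                        rec.sample_rate_hz))
        for s in rec.sweeps
    ]
    metadata = dict(rec.metadata)
    metadata["offline_filter_applied_hz"] = float(cutoff_hz)
    return Recording(protocol=rec.protocol, sweeps=sweeps,
                     sample_rate_hz=rec.sample_rate_hz, metadata=metadata)


def allpoints_histogram(
    rec: Recording,
    voltage_mV: float,
    binwidth: float = 0.1,
    skip_sweeps: int = 0,
) -> AllPointsHistogram:
    """Amplitude histogram over one voltage's analysis slices.

    Compiled from every data point of the voltage's analysis window
    across all active sweeps (optionally skipping an initial run, e.g.
    the pre-activation silent period) and normalized so the total area
    under the density is 1.  Bins are aligned so that 0 pA falls on a
    bin center.
    """
    if binwidth <= 0:
        raise ValueError("binwidth must be positive")
    sweeps = rec.active_sweeps[skip_sweeps:]
    if not sweeps:
        raise ValueError("no sweeps to histogram")
    sl = segment_by_voltage(len(sweeps[0].samples), rec.protocol,
                            rec.sample_rate_hz)[voltage_mV]
    data = np.concatenate([s.samples[sl] for s in sweeps])
    if data.size == 0:
        raise ValueError("analysis slice is empty")
    lo = np.floor(data.min() / binwidth) - 1
    hi = np.ceil(data.max() / binwidth) + 1
    edges = (np.arange(lo, hi + 1) - 0.5) * binwidth
    counts, edges = np.histogram(data, bins=edges)
    density = counts / (data.size * binwidth)
    return AllPointsHistogram(bin_edges=edges, density=density,
                              voltage_mV=voltage_mV, n_points=data.size)


def _mixture_density(edges: np.ndarray, params: np.ndarray) -> np.ndarray:
    """Bin-averaged density of a Gaussian mixture.

    Integrating each component over the bins (CDF differences) rather
    than evaluating the PDF at bin centers keeps the fit unbiased even
    when a peak is narrower than a bin — the noiseless limit, where each
    level collapses to a spike, is then represented exactly.
    """
    bw = edges[1] - edges[0]
    out = np.zeros(edges.size - 1)
    for mean, sd, area in params.reshape(-1, 3):
        cdf = ndtr((edges - mean) / sd)
        out += area * np.diff(cdf) / bw
    return out


def _find_peak(centers: np.ndarray, density: np.ndarray,
               guess: float, halfwidth: float) -> float:
    """Center of the densest bin within +-halfwidth of the guess."""
    mask = np.abs(centers - guess) <= halfwidth
    if not np.any(mask):
        return guess
    return float(centers[mask][np.argmax(density[mask])])


def fit_histogram(
    hist: AllPointsHistogram,
    n_open_components: int = 1,
    init_amplitude: float = 10.0,
) -> HistogramFit:
    """Least-squares Gaussian mixture fit of an all-points histogram.

    One component is constrained to the closed level (mean within one
    bin of 0 pA); ``n_open_components`` further Gaussians start at
    multiples of ``init_amplitude`` refined by a local peak search
    (deterministic, seed-free).  ``P_o = 1 - A_C`` where ``A_C`` is the
    fitted closed-component area.
    """
    if init_amplitude == 0:
        raise ValueError("init_amplitude must be nonzero")
    if n_open_components < 1:
        raise ValueError("need at least one open component")
    x = hist.bin_centers
    y = hist.density
    bw = hist.binwidth
    amp = float(init_amplitude)
    sign = 1.0 if amp > 0 else -1.0
    mag = abs(amp)

    sd0 = max(3 * bw, 0.05 * mag)
    # initial areas from the density mass near each candidate level
    def mass(center: float) -> float:
        mask = np.abs(x - center) <= mag / 2
        return float(np.sum(y[mask]) * bw)

    # Component widths are bounded well below the level spacing: each
    # Gaussian describes one current level broadened by baseline noise,
    # and an unconstrained width lets a sparse component degenerate into
    # a pedestal soaking up the inter-level density left by filtered
    # sub-sample transitions.
    sd_hi_closed = mag / 4
    sd_hi_open = mag / 2
    sd_lo = bw / 50
    sd0 = min(sd0, sd_hi_closed / 2)
    p0 = [0.0, sd0, np.clip(mass(0.0), 1e-6, 1.0)]
    lo = [-bw, sd_lo, 0.0]
    hi = [bw, sd_hi_closed, 1.0]
    for k in range(1, n_open_components + 1):
        mean_k = _find_peak(x, y, sign * k * mag, mag / 4)
        p0 += [mean_k, sd0, np.clip(mass(mean_k), 1e-6, 1.0)]
        lo += [sign * k * mag - mag / 2, sd_lo, 0.0]
        hi += [sign * k * mag + mag / 2, sd_hi_open, 1.0]
    lo_arr, hi_arr = np.array(lo, float), np.array(hi, float)
    p0_arr = np.clip(np.array(p0, float), lo_arr + 1e-12, hi_arr - 1e-12)

    edges = hist.bin_edges
    result = least_squares(lambda p: _mixture_density(edges, p) - y, p0_arr,
                           bounds=(lo_arr, hi_arr), method="trf")
    params = result.x.reshape(-1, 3)
    closed_mean, closed_sd, closed_area = params[0]
    if closed_area > 1 + 1e-9:
        raise ValueError("closed-component area exceeds 1")
    open_components = [(float(m), float(s), float(a)) for m, s, a in params[1:]]
    return HistogramFit(
        closed_mean=float(closed_mean), closed_sd=float(closed_sd),
        closed_area=float(min(closed_area, 1.0)),
        open_components=open_components,
        converged=bool(result.success),
        residual_norm=float(np.linalg.norm(result.fun)),
        binwidth=bw,
    )


# --------------------------------------------------------------------------
# Recording-level estimators
# --------------------------------------------------------------------------

def idealize_recording(
    rec: Recording,
    unitary_amplitude: float,
    voltage_mV: float,
    n_channels: int = 1,
    *,
    subconductance_mode: bool = False,
    smooth_passes: int = 0,
) -> list[IdealizedSweep]:
    """Idealize the analysis slice of every active sweep at one voltage."""
    sweeps = rec.active_sweeps
    if not sweeps:
        raise ValueError("recording has no active sweeps")
    sl = segment_by_voltage(len(sweeps[0].samples), rec.protocol,
                            rec.sample_rate_hz)[voltage_mV]
    return [
        idealize_sweep(s.samples[sl], unitary_amplitude, n_channels,
                       voltage_mV=voltage_mV,
                       subconductance_mode=subconductance_mode,
                       smooth_passes=smooth_passes)
        for s in sweeps
    ]


def estimate_po_idealized(
    rec: Recording,
    unitary_amplitude: float,
    voltage_mV: float,
    n_channels: int = 1,
    *,
    subconductance_mode: bool = False,
    smooth_passes: int = 0,
    activity_floor: float = DEFAULT_ACTIVITY_FLOOR,
) -> PoEstimate:
    """Mean P_o (or NP_o) from threshold-crossing idealization."""
    ideals = idealize_recording(rec, unitary_amplitude, voltage_mV, n_channels,
                                subconductance_mode=subconductance_mode,
                                smooth_passes=smooth_passes)
    indices = [s.index for s in rec.active_sweeps]
    return po_timecourse(ideals, indices, activity_floor=activity_floor)


def estimate_po_histogram(
    rec: Recording,
    voltage_mV: float,
    init_amplitude: float,
    *,
    binwidth: float = 0.1,
    n_open_components: int = 1,
    skip_sweeps: int = 0,
) -> HistogramFit:
    """Histogram-method P_o: Gaussian mixture fit, ``P_o = 1 - A_C``."""
    hist = allpoints_histogram(rec, voltage_mV, binwidth=binwidth,
                               skip_sweeps=skip_sweeps)
    return fit_histogram(hist, n_open_components=n_open_components,
                         init_amplitude=init_amplitude)


def compare_po_methods(
    rec: Recording,
    unitary_amplitude: float,
    voltage_mV: float,
    *,
    binwidth: float = 0.1,
    n_open_components: int = 1,
    subconductance_mode: bool = False,
    smooth_passes: int = 0,
    activity_floor: float = DEFAULT_ACTIVITY_FLOOR,
) -> float:
    """Absolute difference between idealized and histogram mean P_o.

    Single-channel recordings only (``1 - A_C`` is the probability of at
    least one channel being open, which is P_o only for N = 1).  Both
    estimates run over the same sweeps: the silent prefix found by the
    idealization is also skipped when compiling the histogram.
    """
    ideal = estimate_po_idealized(
        rec, unitary_amplitude, voltage_mV, 1,
        subconductance_mode=subconductance_mode, smooth_passes=smooth_passes,
        activity_floor=activity_floor,
    )
    fit = estimate_po_histogram(
        rec, voltage_mV, unitary_amplitude, binwidth=binwidth,
        n_open_components=n_open_components,
        skip_sweeps=ideal.excluded_prefix_sweeps,
    )
    return abs(ideal.mean_po - fit.po_hist)


def chord_conductance(i_pA: float, V_mV: float) -> float:
    """Chord conductance in pS from a unitary current and voltage.

    ``g = 1000 * i / V`` converts pA/mV to pS, taking the reversal
    potential as 0 mV (symmetrical recording solutions).
    """
    if V_mV == 0:
        raise ValueError("voltage must be nonzero")
    return 1000.0 * i_pA / V_mV
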