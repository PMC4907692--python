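"""Synthetic single-channel recordings and saturation-binding datasets.

The gating ground truth is a continuous-time Markov chain over a small
state set; each state carries a relative conductance fraction (0 closed,
1 fully open, intermediate values for subconductance states).  Paths are
realized event-by-event (Gillespie), then sampled onto the acquisition
grid: a sample straddled by several dwells takes their time-weighted mean
conductance, mimicking how analog filtering blurs events briefer than a
sample.  The stationary distribution of the rate matrix provides an
analytic open-probability oracle against which the downstream estimators
are validated.

Binding datasets follow a Hill isotherm plus a linear nonspecific
component, with multiplicative Gaussian replicate noise, mirroring the
structure of a saturation radioligand assay with paired nonspecific
measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import null_space

from .binding import BindingDataset
from .filters import gaussian_lowpass, noise_attenuation
from .sweepio import Protocol, Recording, SweepRecord, segment_slices

__all__ = [
    "GatingModel",
    "NoiseModel",
    "BindingTruth",
    "simulate_gating",
    "analytic_po",
    "sample_path",
    "render_recording",
    "simulate_binding",
]


@dataclass(frozen=True)
class GatingModel:
    """Markov gating scheme: labelled states, conductances, rate matrix.

    Parameters
    ----------
    states
        ``(label, conductance_fraction)`` pairs; the fraction is the
        state's current relative to the fully open level, in [0, 1].
        At least one closed state (fraction 0) is required; models with
        no fully open state are permitted so that silent controls can be
        expressed.
    Q
        Rate matrix in 1/s: ``Q[i, j]`` (i != j) is the transition rate
        from state i to state j; rows sum to zero.
    initial_distribution
        Start-state probabilities; defaults to "all probability on the
        first closed state".
    """

    states: tuple[tuple[str, float], ...]
    Q: np.ndarray
    initial_distribution: np.ndarray | None = None

    def __post_init__(self) -> None:
        states = tuple((str(lbl), float(f)) for lbl, f in self.states)
        object.__setattr__(self, "states", states)
        Q = np.array(self.Q, dtype=float)
        n = len(states)
        if Q.shape != (n, n):
            raise ValueError("Q must be square with one row per state")
        off = Q[~np.eye(n, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be nonnegative")
        if np.any(np.abs(Q.sum(axis=1)) > 1e-12 * max(1.0, np.abs(Q).max())):
            raise ValueError("rows of Q must sum to zero")
        object.__setattr__(self, "Q", Q)
        fracs = [f for _, f in states]
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("conductance fractions must lie in [0, 1]")
        if not any(f == 0 for f in fracs):
            raise ValueError("at least one closed state (fraction 0) is required")
        if self.initial_distribution is None:
            p0 = np.zeros(n)
            p0[fracs.index(0.0)] = 1.0
        else:
            p0 = np.array(self.initial_distribution, dtype=float)
            if p0.shape != (n,) or np.any(p0 < 0) or abs(p0.sum() - 1) > 1e-9:
                raise ValueError("initial distribution must be a probability vector")
        object.__setattr__(self, "initial_distribution", p0)

    @property
    def conductance_fractions(self) -> np.ndarray:
        return np.array([f for _, f in self.states])

    @classmethod
    def two_state(cls, opening_rate: float, closing_rate: float) -> "GatingModel":
        """Closed <-> Open with the given rates (1/s)."""
        Q = np.array([[-opening_rate, opening_rate],
                      [closing_rate, -closing_rate]])
        return cls(states=(("C", 0.0), ("O", 1.0)), Q=Q)

    @classmethod
    def two_state_po(cls, po: float, closing_rate: float = 100.0) -> "GatingModel":
        """Two-state model with stationary open probability ``po``.

        The closing rate is held fixed (default 100 1/s, i.e. 10 ms mean
        open time) and the opening rate set to ``closing_rate * po/(1-po)``.
        """
        if not 0 < po < 1:
            raise ValueError("po must lie strictly between 0 and 1")
        return cls.two_state(closing_rate * po / (1.0 - po), closing_rate)


@dataclass(frozen=True)
class NoiseModel:
    """Recording noise and filtering parameters.

    ``baseline_sd`` is the standard deviation of the recorded baseline
    noise (pA) after acquisition filtering; ``open_extra_sd`` adds
    open-channel excess noise scaled by the conductance fraction.  The
    acquisition filter shapes the simulated noise spectrum; the offline
    filter is applied later, during analysis, not by the simulator.
    """

    baseline_sd: float = 1.0
    open_extra_sd: float = 0.0
    sample_rate_hz: float = 20_000.0
    acquisition_filter_hz: float = 5_000.0
    offline_filter_hz: float = 2_000.0
    leak_template: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.baseline_sd < 0 or self.open_extra_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        nyquist = self.sample_rate_hz / 2
        if not (0 < self.acquisition_filter_hz < nyquist):
            raise ValueError("acquisition filter cutoff must lie below Nyquist")
        if not (0 < self.offline_filter_hz < nyquist):
            raise ValueError("offline filter cutoff must lie below Nyquist")
        if self.leak_template is not None:
            object.__setattr__(self, "leak_template",
                               np.asarray(self.leak_template, dtype=float))


@dataclass(frozen=True)
class BindingTruth:
    """Ground truth for a simulated saturation-binding experiment."""

    Kd: float            # nM
    nH: float = 1.0      # Hill slope
    Bmax: float = 100.0  # counts at saturation
    ns_slope: float = 0.0  # nonspecific counts per nM
    cv: float = 0.05     # relative SD per replicate

    def __post_init__(self) -> None:
        if self.Kd <= 0 or self.nH <= 0 or self.Bmax <= 0:
            raise ValueError("Kd, nH and Bmax must be positive")
        if self.ns_slope < 0 or self.cv < 0:
            raise ValueError("ns_slope and cv must be nonnegative")

    def specific(self, L):
        L = np.asarray(L, dtype=float)
        return self.Bmax * L**self.nH / (self.Kd**self.nH + L**self.nH)


# --------------------------------------------------------------------------
# Continuous-time Markov chain machinery
# --------------------------------------------------------------------------

def simulate_gating(
    model: GatingModel, duration: float, seed: int | np.random.Generator
) -> list[tuple[int, float]]:
    """Exact event-driven realization of the gating chain.

    Returns a list of ``(state_index, dwell_s)`` whose dwells sum to
    ``duration``.  A state with no exit rate is absorbing: the path ends
    there with the remaining time as its final dwell.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Q = model.Q
    n = Q.shape[0]
    state = int(rng.choice(n, p=model.initial_distribution))
    t = 0.0
    path: list[tuple[int, float]] = []
    while t < duration:
        exit_rate = -Q[state, state]
        if exit_rate <= 0:
            path.append((state, duration - t))
            break
        dwell = rng.exponential(1.0 / exit_rate)
        if t + dwell >= duration:
            path.append((state, duration - t))
            break
        path.append((state, dwell))
        t += dwell
        p = Q[state].copy()
        p[state] = 0.0
        state = int(rng.choice(n, p=p / exit_rate))
    return path


def analytic_po(model: GatingModel, weighted: bool = False) -> tuple[np.ndarray, float]:
    """Stationary occupancy and expected open probability.

    Solves ``pi Q = 0`` with ``sum(pi) = 1``.  ``P_o`` is the stationary
    probability of all conducting states (fraction > 0); with
    ``weighted=True`` each state contributes its conductance fraction,
    giving the expected normalized current instead.

    Raises
    ------
    ValueError
        If the stationary distribution is not unique (reducible chain
        with several closed classes).
    """
    ns = null_space(model.Q.T)
    if ns.shape[1] != 1:
        raise ValueError("stationary distribution is not unique for this Q")
    pi = ns[:, 0]
    pi = pi / pi.sum()
    if np.any(pi < -1e-10):
        raise ValueError("invalid stationary solution")
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    frac = model.conductance_fractions
    po = float(np.sum(pi * frac)) if weighted else float(np.sum(pi[frac > 0]))
    return pi, po


def sample_path(
    path: list[tuple[int, float]],
    fractions: np.ndarray,
    n_samples: int,
    sample_rate_hz: float,
) -> np.ndarray:
    """Time-weighted mean conductance fraction in each sample interval.

    A dwell shorter than one sample contributes proportionally to the
    sample(s) it straddles, which is how brief events survive (at reduced
    apparent amplitude) in filtered analog recordings.
    """
    states = np.array([s for s, _ in path], dtype=int)
    dwells = np.array([d for _, d in path], dtype=float)
    values = fractions[states]
    t_events = np.concatenate([[0.0], np.cumsum(dwells)])
    cum = np.concatenate([[0.0], np.cumsum(values * dwells)])

    edges = np.arange(n_samples + 1) / sample_rate_hz
    edges = np.minimum(edges, t_events[-1])
    k = np.searchsorted(t_events, edges, side="right") - 1
    k = np.clip(k, 0, len(values) - 1)
    F = cum[k] + values[k] * (edges - t_events[k])
    out = np.diff(F) * sample_rate_hz
    # samples wholly inside one dwell take its value exactly, bypassing
    # the cumulative-sum rounding of the integral representation
    same = k[:-1] == k[1:]
    out[same] = values[k[:-1][same]]
    return out


# --------------------------------------------------------------------------
# Recording renderer
# --------------------------------------------------------------------------

def _shaped_noise(rng: np.random.Generator, n: int, noise: NoiseModel,
                  atten: float) -> np.ndarray:
    """Unit-SD Gaussian noise band-limited by the acquisition filter."""
    white = rng.standard_normal(n)
    return gaussian_lowpass(white, noise.acquisition_filter_hz,
                            noise.sample_rate_hz) / atten


def _states_at(path: list[tuple[int, float]], times: np.ndarray) -> np.ndarray:
    """State index occupied at each query time (instantaneous sampling)."""
    t_events = np.cumsum([d for _, d in path])
    states = np.array([s for s, _ in path], dtype=int)
    k = np.clip(np.searchsorted(t_events, times, side="right"), 0, len(states) - 1)
    return states[k]


def render_recording(
    model: GatingModel,
    protocol: Protocol,
    noise: NoiseModel,
    n_channels: int = 1,
    n_null_sweeps: int = 5,
    silent_delay: float = 0.0,
    seed: int = 0,
    return_truth: bool = False,
) -> Recording | tuple[Recording, list[np.ndarray]]:
    """Render a full episodic recording from the gating ground truth.

    Null sweeps (leak + noise only, flagged) come first, emulating the
    control period before agonist application.  The agonist wash-in delay
    is modeled by forcing the channels closed for the first
    ``ceil(silent_delay / cycle_period)`` agonist sweeps, so the
    per-sweep open-probability time course shows the silent period rather
    than omitting it.  Channels are simulated independently and their
    currents summed; every randomness stream is derived from the single
    master seed, so identical arguments give an identical recording.

    With ``return_truth=True`` the ground-truth occupancy is returned as
    well: one integer array per active sweep giving the number of open
    channels at each sample center (instantaneous sampling of the Markov
    paths), which downstream idealization can be checked against.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    for v in protocol.voltages():
        if v not in protocol.unitary_amplitude_pA:
            raise ValueError(f"no unitary amplitude given for {v} mV")

    fs = noise.sample_rate_hz
    n_samples = protocol.n_samples(fs)
    sweep_dur = protocol.sweep_duration_s
    cycle_s = protocol.cycle_period_ms / 1000.0

    amp = np.empty(n_samples)
    for v, sl in segment_slices(protocol, fs):
        amp[sl] = protocol.unitary_amplitude_pA[v]

    leak = noise.leak_template
    if leak is None:
        leak = np.zeros(n_samples)
    elif len(leak) != n_samples:
        raise ValueError("leak template length must match the sweep length")

    n_silent = math.ceil(silent_delay / cycle_s) if silent_delay > 0 else 0
    n_active = protocol.n_sweeps
    has_noise = noise.baseline_sd > 0 or noise.open_extra_sd > 0
    atten = noise_attenuation(noise.acquisition_filter_hz, fs) if has_noise else 1.0

    ss = np.random.SeedSequence(seed)
    noise_rng = np.random.default_rng(ss.spawn(1)[0])
    channel_rngs = [np.random.default_rng(s) for s in ss.spawn(n_channels)]

    sweeps: list[SweepRecord] = []
    idx = 0
    for _ in range(n_null_sweeps):
        trace = leak.copy()
        if has_noise:
            trace = trace + noise.baseline_sd * _shaped_noise(noise_rng, n_samples, noise, atten)
        sweeps.append(SweepRecord(index=idx, t0=idx * cycle_s, samples=trace, is_null=True))
        idx += 1

    # Episodes of a real recording are slices of one continuous gating
    # process, so each rendered sweep starts from the stationary law
    # rather than the model's (typically closed) initial state.
    try:
        pi, _ = analytic_po(model)
        sweep_model = GatingModel(states=model.states, Q=model.Q,
                                  initial_distribution=pi)
    except ValueError:
        sweep_model = model

    fracs = model.conductance_fractions
    centers = (np.arange(n_samples) + 0.5) / fs
    truths: list[np.ndarray] = []
    for k in range(n_active):
        frac_sum = np.zeros(n_samples)
        true_open = np.zeros(n_samples, dtype=int)
        for ch_rng in channel_rngs:
            path = simulate_gating(sweep_model, cycle_s, ch_rng)
            if k >= n_silent:
                frac_sum += sample_path(path, fracs, n_samples, fs)
                true_open += (fracs[_states_at(path, centers)] > 0).astype(int)
        truths.append(true_open)
        trace = leak + frac_sum * amp
        if has_noise:
            sd = np.sqrt(noise.baseline_sd**2 + (noise.open_extra_sd * frac_sum)**2)
            trace = trace + sd * _shaped_noise(noise_rng, n_samples, noise, atten)
        sweeps.append(SweepRecord(index=idx, t0=idx * cycle_s, samples=trace, is_null=False))
        idx += 1

    metadata = {
        "seed": int(seed),
        "n_channels": int(n_channels),
        "n_null_sweeps": int(n_null_sweeps),
        "silent_delay_s": float(silent_delay),
        "baseline_sd_pA": float(noise.baseline_sd),
        "acquisition_filter_hz": float(noise.acquisition_filter_hz),
        "offline_filter_hz": float(noise.offline_filter_hz),
    }
    rec = Recording(protocol=protocol, sweeps=sweeps, sample_rate_hz=fs,
                    metadata=metadata)
    return (rec, truths) if return_truth else rec


# --------------------------------------------------------------------------
# Binding-data generator
# --------------------------------------------------------------------------

def simulate_binding(
    truth: BindingTruth,
    concentrations,
    n_replicates: int = 3,
    seed: int = 0,
    label: str = "simulated",
) -> BindingDataset:
    """Simulate total and paired nonspecific binding at each concentration.

    Total counts follow ``Bmax L^nH / (Kd^nH + L^nH) + ns_slope * L``;
    each replicate is multiplied by ``1 + cv * N(0, 1)``.  Nonspecific
    measurements (``ns_slope * L``) carry the same multiplicative noise
    law, as in a paired assay on a non-binding control.
    """
    L = np.asarray(concentrations, dtype=float)
    if np.any(L <= 0):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for conc in L:
        total = truth.specific(conc) + truth.ns_slope * conc
        nonspec = truth.ns_slope * conc
        for rep in range(n_replicates):
            tot = total * (1.0 + truth.cv * rng.standard_normal())
            ns = nonspec * (1.0 + truth.cv * rng.standard_normal())
            rows.append((conc, tot, rep, False))
            rows.append((conc, ns, rep, True))
    df = pd.DataFrame(rows, columns=["concentration_nM", "counts", "replicate",
                                     "is_nonspecific"])
    return BindingDataset(
        points=df[~df.is_nonspecific].drop(columns="is_nonspecific").reset_index(drop=True),
        nonspecific=df[df.is_nonspecific].drop(columns="is_nonspecific").reset_index(drop=True),
        label=label,
    )
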