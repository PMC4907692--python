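"""Sweep-based recording data model, text I/O, leak subtraction and
voltage segmentation.

An episodic single-channel recording is a sequence of sweeps, each
acquired by replaying the same voltage protocol (e.g. 100 ms at -90 mV,
a 500 ms step to +90 mV, then 100 ms at -90 mV, repeated every 700 ms).
Sweeps recorded before agonist application, containing only leak and
capacitive current, are flagged as null traces and used for leak
subtraction.

Units are fixed package-wide: current in pA, voltage in mV, time in s
(durations in protocol definitions are in ms, as labelled).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Protocol",
    "SweepRecord",
    "Recording",
    "ResponseRatio",
    "read_recording",
    "write_recording",
    "leak_subtract",
    "segment_slices",
    "segment_by_voltage",
    "normalize_response",
]


@dataclass(frozen=True)
class Protocol:
    """Voltage-pulse protocol shared by every sweep of a recording.

    Parameters
    ----------
    segments
        Ordered ``(voltage_mV, duration_ms)`` pairs. Samples are acquired
        only during the segments; their total duration may be shorter than
        the cycle period (dead time between episodes).
    cycle_period_ms
        Interval between the starts of consecutive sweeps.
    n_sweeps
        Number of sweeps the protocol is replayed for.
    unitary_amplitude_pA
        Map from segment voltage (mV) to the full single-channel current
        amplitude (pA) at that voltage, signed (inward current negative).
    """

    segments: tuple[tuple[float, float], ...]
    cycle_period_ms: float
    n_sweeps: int
    unitary_amplitude_pA: Mapping[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple((float(v), float(d)) for v, d in self.segments))
        object.__setattr__(self, "unitary_amplitude_pA",
                           {float(v): float(a) for v, a in dict(self.unitary_amplitude_pA).items()})
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        if any(d <= 0 for _, d in self.segments):
            raise ValueError("segment durations must be positive")
        if sum(d for _, d in self.segments) > self.cycle_period_ms + 1e-9:
            raise ValueError("segment durations exceed the cycle period")
        for amp in self.unitary_amplitude_pA.values():
            if not np.isfinite(amp):
                raise ValueError("unitary amplitudes must be finite")

    @property
    def sweep_duration_s(self) -> float:
        return sum(d for _, d in self.segments) / 1000.0

    def n_samples(self, sample_rate_hz: float) -> int:
        return int(round(self.sweep_duration_s * sample_rate_hz))

    def voltages(self) -> tuple[float, ...]:
        out: list[float] = []
        for v, _ in self.segments:
            if v not in out:
                out.append(v)
        return tuple(out)


@dataclass
class SweepRecord:
    """One episode: a uniformly sampled current trace plus bookkeeping."""

    index: int
    t0: float            # cycle start, s from the start of the recording
    samples: np.ndarray  # current, pA
    is_null: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("sweep samples must be one-dimensional")


@dataclass
class Recording:
    """An ordered collection of sweeps sharing one protocol and sample rate."""

    protocol: Protocol
    sweeps: list[SweepRecord]
    sample_rate_hz: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = self.protocol.n_samples(self.sample_rate_hz)
        for sw in self.sweeps:
            if abs(len(sw.samples) - expected) > 1:
                raise ValueError(
                    f"sweep {sw.index} has {len(sw.samples)} samples, expected {expected}"
                )

    @property
    def null_sweeps(self) -> list[SweepRecord]:
        return [s for s in self.sweeps if s.is_null]

    @property
    def active_sweeps(self) -> list[SweepRecord]:
        return [s for s in self.sweeps if not s.is_null]


@dataclass(frozen=True)
class ResponseRatio:
    """Macroscopic current response normalized to a reference agonist."""

    test_label: str
    reference_label: str
    voltage_mV: float
    ratio: float


# --------------------------------------------------------------------------
# Text I/O.  Data file: two whitespace-separated columns (time_s,
# current_pA) with a blank line between sweeps; sidecar YAML (same path
# plus ".meta.yaml") carries the protocol, sample rate, null flags and
# free-form metadata.  The pairing keeps the trace file trivially
# plottable while the round trip stays lossless.
# --------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".meta.yaml")


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write ``rec`` as delimited text plus a YAML metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dt = 1.0 / rec.sample_rate_hz
    with open(path, "w") as fh:
        fh.write("# time_s\tcurrent_pA\n")
        for k, sw in enumerate(rec.sweeps):
            if k:
                fh.write("\n")
            t = sw.t0 + dt * np.arange(len(sw.samples))
            np.savetxt(fh, np.column_stack([t, sw.samples]), fmt="%.17g", delimiter="\t")
    meta = {
        "sample_rate_hz": float(rec.sample_rate_hz),
        "protocol": {
            "segments_mV_ms": [[v, d] for v, d in rec.protocol.segments],
            "cycle_period_ms": float(rec.protocol.cycle_period_ms),
            "n_sweeps": int(rec.protocol.n_sweeps),
            "unitary_amplitude_pA": {float(v): float(a)
                                     for v, a in rec.protocol.unitary_amplitude_pA.items()},
        },
        "sweeps": [
            {"index": int(s.index), "t0_s": float(s.t0), "is_null": bool(s.is_null)}
            for s in rec.sweeps
        ],
        "metadata": rec.metadata,
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`.

    Raises
    ------
    FileNotFoundError
        If the data file or its metadata sidecar is missing.
    ValueError
        If a sweep's sample count disagrees with the protocol (the error
        names the offending sweep).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    proto_meta = meta["protocol"]
    protocol = Protocol(
        segments=tuple((v, d) for v, d in proto_meta["segments_mV_ms"]),
        cycle_period_ms=proto_meta["cycle_period_ms"],
        n_sweeps=proto_meta["n_sweeps"],
        unitary_amplitude_pA=proto_meta.get("unitary_amplitude_pA", {}),
    )
    sample_rate = float(meta["sample_rate_hz"])

    table = pd.read_csv(
        path, sep=r"\s+", comment="#", header=None, names=["time_s", "current_pA"],
        skip_blank_lines=False, engine="c", float_precision="round_trip",
    )
    is_break = table["time_s"].isna().to_numpy()
    block_id = np.cumsum(is_break)
    blocks = [
        grp["current_pA"].to_numpy()
        for _, grp in table.loc[~is_break].groupby(block_id[~is_break], sort=True)
    ]
    sweep_meta = meta["sweeps"]
    if len(blocks) != len(sweep_meta):
        raise ValueError(f"found {len(blocks)} sweeps, sidecar lists {len(sweep_meta)}")
    expected = protocol.n_samples(sample_rate)
    # sweeps must agree with the protocol (within one sample of rounding)
    # and with each other exactly: a ragged block means lost samples
    ref_len = max(len(b) for b in blocks)
    sweeps = []
    for sm, samples in zip(sweep_meta, blocks):
        if len(samples) != ref_len or abs(len(samples) - expected) > 1:
            raise ValueError(
                f"sweep {sm['index']} has {len(samples)} samples, expected {expected}"
            )
        if not np.all(np.isfinite(samples)):
            raise ValueError(f"sweep {sm['index']} contains non-finite samples")
        sweeps.append(SweepRecord(index=sm["index"], t0=sm["t0_s"],
                                  samples=samples, is_null=sm["is_null"]))
    return Recording(protocol=protocol, sweeps=sweeps, sample_rate_hz=sample_rate,
                     metadata=meta.get("metadata") or {})


# --------------------------------------------------------------------------
# Leak subtraction and segmentation
# --------------------------------------------------------------------------

def leak_subtract(rec: Recording) -> Recording:
    """Subtract the averaged null-trace template from every active sweep.

    The template is the pointwise arithmetic mean of all null sweeps
    (passive leak + capacitive transients, no channel activity).  Null
    sweeps are dropped from the output; the metadata notes how many were
    averaged.
    """
    nulls = rec.null_sweeps
    if not nulls:
        raise ValueError("leak subtraction requires at least one null sweep")
    n = min(len(s.samples) for s in rec.sweeps)
    template = np.mean([s.samples[:n] for s in nulls], axis=0)
    out_sweeps = [
        dataclasses.replace(s, samples=s.samples[:n] - template)
        for s in rec.active_sweeps
    ]
    metadata = dict(rec.metadata)
    metadata["leak_nulls_averaged"] = len(nulls)
    return Recording(protocol=rec.protocol, sweeps=out_sweeps,
                     sample_rate_hz=rec.sample_rate_hz, metadata=metadata)


def segment_slices(protocol: Protocol, sample_rate_hz: float) -> list[tuple[float, slice]]:
    """Partition a sweep into per-segment half-open sample slices.

    Cumulative rounding keeps the slices gap- and overlap-free even when
    individual segment durations are not integer numbers of samples.
    """
    edges_ms = np.concatenate([[0.0], np.cumsum([d for _, d in protocol.segments])])
    idx = np.round(edges_ms / 1000.0 * sample_rate_hz).astype(int)
    return [(v, slice(int(a), int(b)))
            for (v, _), a, b in zip(protocol.segments, idx[:-1], idx[1:])]


def segment_by_voltage(
    n_samples: int, protocol: Protocol, sample_rate_hz: float
) -> dict[float, slice]:
    """Map each protocol voltage to its analysis slice of the sweep.

    For a voltage visited more than once per sweep (the holding potential
    of a step protocol), the analysis slice is the occurrence immediately
    preceding the most depolarized segment: channel behaviour at the
    holding potential is read from the window just before the step, not
    the tail segment after repolarization.
    """
    slices = segment_slices(protocol, sample_rate_hz)
    total = slices[-1][1].stop
    if abs(n_samples - total) > 1:
        raise ValueError(
            f"sweep has {n_samples} samples but the protocol spans {total}"
        )
    peak = max(range(len(slices)), key=lambda k: slices[k][0])
    out: dict[float, slice] = {}
    for k, (v, sl) in enumerate(slices):
        if v not in out or k == peak - 1:
            out[v] = sl
    return out


def normalize_response(
    i_test: float, i_ref: float, *,
    test_label: str = "test", reference_label: str = "reference",
    voltage_mV: float = 0.0,
) -> ResponseRatio:
    """Ratio of a test-agonist current to a reference-agonist current.

    Sign-preserving; used to summarize macroscopic responses across cells
    (e.g. vanilloid-evoked current normalized to a saturating reference
    agonist at the same voltage).
    """
    if i_ref == 0:
        raise ValueError("reference current must be nonzero")
    return ResponseRatio(test_label=test_label, reference_label=reference_label,
                         voltage_mV=voltage_mV, ratio=float(i_test) / float(i_ref))
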