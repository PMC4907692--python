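"""Pipeline configuration: structured text (YAML) with units in key names.

Analysis defaults follow the single-channel study conditions this
package targets: 20 kHz sampling with a 5 kHz acquisition and 2 kHz
offline filter, a 100 ms / 500 ms / 100 ms step protocol repeated every
700 ms, thresholds at ~50% of the unitary amplitude (45% at positive
voltages so subconductance sojourns count as openings), and 5-pass
binomial smoothing of the small-amplitude negative-voltage data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .channelsim import BindingTruth, GatingModel, NoiseModel
from .popen import DEFAULT_ACTIVITY_FLOOR
from .sweepio import Protocol

__all__ = [
    "AnalysisSettings",
    "SingleChannelConfig",
    "BindingCondition",
    "BindingConfig",
    "PipelineConfig",
    "load_config",
    "default_protocol",
    "default_noise",
]


def default_protocol(n_sweeps: int = 100,
                     amplitudes: dict[float, float] | None = None) -> Protocol:
    """The step protocol used throughout: -90 mV hold, +90 mV pulse."""
    if amplitudes is None:
        # unitary currents matching 101 pS at +90 mV and 28 pS at -90 mV
        amplitudes = {90.0: 9.09, -90.0: -2.52}
    return Protocol(
        segments=((-90.0, 100.0), (90.0, 500.0), (-90.0, 100.0)),
        cycle_period_ms=700.0,
        n_sweeps=n_sweeps,
        unitary_amplitude_pA=amplitudes,
    )


def default_noise(baseline_sd: float = 1.0) -> NoiseModel:
    return NoiseModel(baseline_sd=baseline_sd, sample_rate_hz=20_000.0,
                      acquisition_filter_hz=5_000.0, offline_filter_hz=2_000.0)


@dataclass
class AnalysisSettings:
    binwidth_pA: float = 0.1
    smooth_passes_negative: int = 5
    subconductance_mode: bool = True
    n_open_components: int = 1
    activity_floor: float = DEFAULT_ACTIVITY_FLOOR


@dataclass
class SingleChannelConfig:
    gating: GatingModel
    protocol: Protocol
    noise: NoiseModel
    n_channels: int = 1
    n_null_sweeps: int = 5
    silent_delay_s: float = 0.0


@dataclass
class BindingCondition:
    label: str
    truth: BindingTruth


@dataclass
class BindingConfig:
    conditions: list[BindingCondition]
    concentrations_nM: list[float]
    n_replicates: int = 3
    correction_mode: str = "paired"


@dataclass
class PipelineConfig:
    single_channel: SingleChannelConfig | None = None
    binding: BindingConfig | None = None
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)
    seed: int = 0


def _gating_from_dict(d: dict) -> GatingModel:
    if "open_probability" in d:
        return GatingModel.two_state_po(
            float(d["open_probability"]),
            closing_rate=float(d.get("closing_rate_per_s", 100.0)),
        )
    return GatingModel(
        states=tuple((s[0], float(s[1])) for s in d["states"]),
        Q=np.array(d["rates_per_s"], dtype=float),
        initial_distribution=d.get("initial_distribution"),
    )


def _protocol_from_dict(d: dict) -> Protocol:
    return Protocol(
        segments=tuple((float(v), float(ms)) for v, ms in d["segments_mV_ms"]),
        cycle_period_ms=float(d["cycle_period_ms"]),
        n_sweeps=int(d["n_sweeps"]),
        unitary_amplitude_pA={float(v): float(a)
                              for v, a in d["unitary_amplitude_pA"].items()},
    )


def _noise_from_dict(d: dict) -> NoiseModel:
    return NoiseModel(
        baseline_sd=float(d.get("baseline_sd_pA", 1.0)),
        open_extra_sd=float(d.get("open_extra_sd_pA", 0.0)),
        sample_rate_hz=float(d.get("sample_rate_hz", 20_000.0)),
        acquisition_filter_hz=float(d.get("acquisition_filter_hz", 5_000.0)),
        offline_filter_hz=float(d.get("offline_filter_hz", 2_000.0)),
    )


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML pipeline configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    sc = None
    if "single_channel" in raw:
        d = raw["single_channel"]
        sc = SingleChannelConfig(
            gating=_gating_from_dict(d["gating"]),
            protocol=_protocol_from_dict(d["protocol"]),
            noise=_noise_from_dict(d.get("noise", {})),
            n_channels=int(d.get("n_channels", 1)),
            n_null_sweeps=int(d.get("n_null_sweeps", 5)),
            silent_delay_s=float(d.get("silent_delay_s", 0.0)),
        )

    binding = None
    if "binding" in raw:
        d = raw["binding"]
        conditions = [
            BindingCondition(
                label=str(c["label"]),
                truth=BindingTruth(
                    Kd=float(c["Kd_nM"]),
                    nH=float(c.get("nH", 1.0)),
                    Bmax=float(c.get("Bmax_counts", 100.0)),
                    ns_slope=float(c.get("ns_slope_counts_per_nM", 0.0)),
                    cv=float(c.get("cv", 0.05)),
                ),
            )
            for c in d["conditions"]
        ]
        binding = BindingConfig(
            conditions=conditions,
            concentrations_nM=[float(x) for x in d["concentrations_nM"]],
            n_replicates=int(d.get("n_replicates", 3)),
            correction_mode=str(d.get("correction_mode", "paired")),
        )

    analysis = AnalysisSettings(**(raw.get("analysis") or {}))
    return PipelineConfig(single_channel=sc, binding=binding, analysis=analysis,
                          seed=int(raw.get("seed", 0)))
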