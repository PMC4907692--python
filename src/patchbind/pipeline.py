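"""End-to-end pipelines: simulate -> leak-subtract -> filter -> idealize
-> P_o/amplitude report, and simulate-binding -> correct -> fit ->
fold-change report.

Every stage is deterministic given the configuration and seed, and the
summary files contain only quantities recomputable from them, so two
runs with identical inputs produce byte-identical reports.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import binding as bindmod
from .channelsim import analytic_po, render_recording, simulate_binding
from .config import AnalysisSettings, PipelineConfig
from .popen import (
    allpoints_histogram,
    chord_conductance,
    estimate_po_idealized,
    fit_histogram,
    lowpass_recording,
)
from .sweepio import Recording, leak_subtract, write_recording

logger = logging.getLogger("patchbind")

__all__ = ["run_sc_pipeline", "run_binding_pipeline", "analyze_recording"]


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                logger.info("stage %s: done in %.2f s", stage, dt)
            else:
                logger.error("stage %s: failed after %.2f s: %s", stage, dt, exc)
            return False

    return _Timer()


def _round6(x: float) -> float:
    return float(round(float(x), 6))


def analyze_recording(
    rec: Recording,
    analysis: AnalysisSettings,
    n_channels: int = 1,
) -> dict:
    """Full single-channel analysis of a leak-subtracted recording.

    Applies the offline filter, then for every protocol voltage
    estimates P_o by idealization (and, for single-channel patches, by
    the all-points-histogram method), the unitary amplitude from the
    open-level Gaussian, and the chord conductance.
    """
    cutoff = rec.metadata.get("offline_filter_hz", 2000.0)
    filtered = lowpass_recording(rec, cutoff)
    out: dict = {"n_channels": n_channels, "voltages": {}}
    for voltage in filtered.protocol.voltages():
        amp = filtered.protocol.unitary_amplitude_pA[voltage]
        smooth = analysis.smooth_passes_negative if voltage < 0 else 0
        sub = analysis.subconductance_mode and voltage > 0
        ideal = estimate_po_idealized(
            filtered, amp, voltage, n_channels,
            subconductance_mode=sub, smooth_passes=smooth,
            activity_floor=analysis.activity_floor,
        )
        entry = {
            "excluded_prefix_sweeps": int(ideal.excluded_prefix_sweeps),
            "n_sweeps_analyzed": len(ideal.per_sweep) - ideal.excluded_prefix_sweeps,
            "per_sweep": [(int(i), _round6(v)) for i, v in ideal.per_sweep],
        }
        if n_channels == 1:
            entry["po_idealized"] = _round6(ideal.mean_po)
            fit = fit_histogram(
                allpoints_histogram(filtered, voltage, binwidth=analysis.binwidth_pA,
                                    skip_sweeps=ideal.excluded_prefix_sweeps),
                n_open_components=analysis.n_open_components,
                init_amplitude=amp,
            )
            entry["po_histogram"] = _round6(fit.po_hist)
            entry["unitary_amplitude_pA"] = _round6(fit.unitary_amplitude)
            entry["chord_conductance_pS"] = _round6(
                chord_conductance(fit.unitary_amplitude, voltage))
            entry["histogram_converged"] = bool(fit.converged)
        else:
            # 1 - A_C is "any channel open", not NP_o, so only the
            # idealized estimator is meaningful for multi-channel patches
            entry["npo_idealized"] = _round6(ideal.mean_po)
        out["voltages"][f"{voltage:g}"] = entry
    return out


def run_sc_pipeline(config: PipelineConfig, outdir: str | Path,
                    seed: int | None = None) -> Path:
    """Simulate, analyze and report a single-channel experiment."""
    if config.single_channel is None:
        raise ValueError("configuration has no single_channel section")
    sc = config.single_channel
    seed = config.seed if seed is None else seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with _timed("simulate"):
        rec = render_recording(
            sc.gating, sc.protocol, sc.noise,
            n_channels=sc.n_channels, n_null_sweeps=sc.n_null_sweeps,
            silent_delay=sc.silent_delay_s, seed=seed,
        )
        write_recording(rec, outdir / "recording.txt")
    with _timed("leak-subtract"):
        subtracted = leak_subtract(rec)
    with _timed("analyze"):
        summary = analyze_recording(subtracted, config.analysis, sc.n_channels)

    _, po_true = analytic_po(sc.gating)
    summary["seed"] = int(seed)
    summary["analytic_po_per_channel"] = _round6(po_true)

    per_sweep_rows = []
    for voltage, entry in summary["voltages"].items():
        for idx, po in entry.pop("per_sweep"):
            per_sweep_rows.append((voltage, idx, po))
    pd.DataFrame(per_sweep_rows, columns=["voltage_mV", "sweep", "po"]).to_csv(
        outdir / "po_per_sweep.tsv", sep="\t", index=False)
    with open(outdir / "summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=True)
    return outdir


def run_binding_pipeline(config: PipelineConfig, outdir: str | Path,
                         seed: int | None = None) -> Path:
    """Simulate, fit and compare binding conditions."""
    if config.binding is None:
        raise ValueError("configuration has no binding section")
    bc = config.binding
    seed = config.seed if seed is None else seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(seed)
    fits: list[bindmod.HillFit] = []
    summary: dict = {"seed": int(seed), "conditions": {}, "fold_changes": {}}
    for cond, child in zip(bc.conditions, ss.spawn(len(bc.conditions))):
        with _timed(f"binding:{cond.label}"):
            ds = simulate_binding(cond.truth, bc.concentrations_nM,
                                  n_replicates=bc.n_replicates,
                                  seed=child, label=cond.label)
            bindmod.write_binding_table(ds, outdir / f"binding_{cond.label}.tsv")
            specific = bindmod.correct_nonspecific(ds, mode=bc.correction_mode)
            fit = bindmod.fit_hill(specific, label=cond.label)
            fits.append(fit)
            summary["conditions"][cond.label] = {
                "Kd_nM": _round6(fit.Kd), "se_Kd_nM": _round6(fit.se_Kd),
                "nH": _round6(fit.nH), "se_nH": _round6(fit.se_nH),
                "Bmax_counts": _round6(fit.Bmax),
                "converged": bool(fit.converged),
            }
    for i, fa in enumerate(fits):
        for fb in fits[i + 1:]:
            fc = bindmod.fold_change(fa, fb)
            summary["fold_changes"][f"{fa.label}_vs_{fb.label}"] = {
                "kd_ratio": _round6(fc.ratio),
                "se": _round6(fc.se),
                "approx": bindmod.format_fold(fc.ratio),
            }
    pd.DataFrame([summary["conditions"][f.label] | {"condition": f.label}
                  for f in fits]).to_csv(outdir / "hill_fits.tsv", sep="\t", index=False)
    with open(outdir / "summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=True)
    return outdir
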