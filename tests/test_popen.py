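"""Open-probability estimators: per-sweep means, silent-prefix handling,
all-points histograms and their Gaussian decomposition, conductance."""

import numpy as np
import pytest

from patchbind.channelsim import GatingModel, NoiseModel, render_recording
from patchbind.idealize import IdealizedSweep
from patchbind.popen import (
    AllPointsHistogram,
    allpoints_histogram,
    chord_conductance,
    compare_po_methods,
    fit_histogram,
    po_per_sweep,
    po_timecourse,
)
from patchbind.sweepio import Protocol, Recording, SweepRecord, leak_subtract


def ideal(levels, n_channels=1):
    thr = tuple(4.5 + 10.0 * k for k in range(n_channels))
    return IdealizedSweep(levels=np.asarray(levels, int), thresholds=thr,
                          n_channels=n_channels, voltage_mV=90.0)


class TestPoPerSweep:
    def test_all_closed_is_zero(self):
        assert po_per_sweep(ideal([0, 0, 0, 0])) == 0.0

    def test_mean_of_levels(self):
        assert po_per_sweep(ideal([0, 1, 1, 1])) == pytest.approx(0.75)

    def test_two_channels_fully_open_gives_npo_two(self):
        assert po_per_sweep(ideal([2, 2, 2], n_channels=2)) == pytest.approx(2.0)


class TestPoTimecourse:
    def test_silent_prefix_excluded_from_mean(self):
        sweeps = [ideal([0] * 200)] * 10 + [ideal([1] * 196 + [0] * 4)] * 90
        est = po_timecourse(sweeps)
        assert est.excluded_prefix_sweeps == 10
        assert est.mean_po == pytest.approx(0.98)
        assert len(est.per_sweep) == 100

    def test_no_prefix_means_all_sweeps(self):
        sweeps = [ideal([1, 1, 0, 0]), ideal([1, 1, 1, 1])]
        est = po_timecourse(sweeps)
        assert est.excluded_prefix_sweeps == 0
        assert est.mean_po == pytest.approx(0.75)

    def test_interior_silent_sweeps_still_count(self):
        # only the *initial* run is a wash-in artifact
        sweeps = [ideal([1, 1, 1, 1]), ideal([0, 0, 0, 0])]
        est = po_timecourse(sweeps)
        assert est.excluded_prefix_sweeps == 0
        assert est.mean_po == pytest.approx(0.5)

    def test_all_silent_flagged_as_nan(self):
        est = po_timecourse([ideal([0, 0, 0])] * 5)
        assert est.excluded_prefix_sweeps == 5
        assert np.isnan(est.mean_po)


def single_segment_recording(traces, voltage=90.0, fs=1000.0, amp=10.0):
    n = len(traces[0])
    proto = Protocol(segments=((voltage, 1000.0 * n / fs),),
                     cycle_period_ms=1000.0 * n / fs, n_sweeps=len(traces),
                     unitary_amplitude_pA={voltage: amp})
    sweeps = [SweepRecord(index=i, t0=0.0, samples=np.asarray(t, float))
              for i, t in enumerate(traces)]
    return Recording(protocol=proto, sweeps=sweeps, sample_rate_hz=fs)


class TestAllPointsHistogram:
    def test_constant_data_single_bin(self):
        rec = single_segment_recording([np.zeros(100)])
        hist = allpoints_histogram(rec, 90.0, binwidth=0.1)
        assert hist.density.max() == pytest.approx(1 / 0.1)
        assert np.count_nonzero(hist.density) == 1

    def test_fifty_fifty_mixture_splits_area(self):
        trace = np.repeat([0.0, 10.0], 50)
        hist = allpoints_histogram(single_segment_recording([trace]), 90.0, 0.1)
        occupied = hist.density[hist.density > 0] * hist.binwidth
        assert np.allclose(sorted(occupied), [0.5, 0.5])

    def test_area_normalized_for_simulated_recording(self, two_state_09,
                                                     step_protocol, paper_noise):
        rec = render_recording(two_state_09, step_protocol, paper_noise, seed=8)
        sub = leak_subtract(rec)
        for v in (90.0, -90.0):
            hist = allpoints_histogram(sub, v, binwidth=0.1)
            assert np.sum(hist.density) * hist.binwidth == pytest.approx(1.0, abs=1e-9)

    def test_nonpositive_binwidth_rejected(self):
        rec = single_segment_recording([np.zeros(10)])
        with pytest.raises(ValueError):
            allpoints_histogram(rec, 90.0, binwidth=0.0)


def histogram_from_samples(samples, binwidth=0.1):
    lo = np.floor(samples.min() / binwidth) - 1
    hi = np.ceil(samples.max() / binwidth) + 1
    edges = (np.arange(lo, hi + 1) - 0.5) * binwidth
    counts, edges = np.histogram(samples, bins=edges)
    return AllPointsHistogram(bin_edges=edges,
                              density=counts / (samples.size * binwidth),
                              voltage_mV=90.0, n_points=samples.size)


class TestFitHistogram:
    def test_pure_closed_gaussian_gives_po_zero(self, rng):
        hist = histogram_from_samples(rng.normal(0.0, 0.8, 100_000))
        fit = fit_histogram(hist, 1, init_amplitude=10.0)
        assert fit.closed_area == pytest.approx(1.0, abs=0.01)
        assert fit.po_hist == pytest.approx(0.0, abs=0.01)

    def test_known_mixture_recovered(self, rng):
        # 25% closed (sd 0.8) + 75% open at 10 pA (sd 1.2)
        n = 400_000
        closed = rng.normal(0.0, 0.8, int(0.25 * n))
        opened = rng.normal(10.0, 1.2, n - closed.size)
        fit = fit_histogram(histogram_from_samples(np.concatenate([closed, opened])),
                            1, init_amplitude=10.0)
        assert fit.po_hist == pytest.approx(0.75, abs=0.01)
        assert fit.unitary_amplitude == pytest.approx(10.0, abs=0.1)
        assert fit.converged

    def test_amplitude_unbiased_within_two_percent(self, rng):
        for true_amp in (8.0, 10.0, 12.0):
            samples = np.concatenate([
                rng.normal(0.0, 1.0, 100_000),
                rng.normal(true_amp, 1.0, 100_000),
            ])
            fit = fit_histogram(histogram_from_samples(samples), 1,
                                init_amplitude=true_amp)
            assert abs(fit.unitary_amplitude - true_amp) / true_amp < 0.02

    def test_subconductance_component_counts_as_open(self, rng):
        # closed 20%, substate 30% at 5 pA, full 50% at 10 pA
        samples = np.concatenate([
            rng.normal(0.0, 0.6, 20_000),
            rng.normal(5.0, 0.6, 30_000),
            rng.normal(10.0, 0.6, 50_000),
        ])
        fit = fit_histogram(histogram_from_samples(samples), 2, init_amplitude=5.0)
        assert fit.po_hist == pytest.approx(0.8, abs=0.02)

    def test_negative_amplitude_channel(self, rng):
        samples = np.concatenate([
            rng.normal(0.0, 0.4, 50_000),
            rng.normal(-2.5, 0.4, 50_000),
        ])
        fit = fit_histogram(histogram_from_samples(samples), 1, init_amplitude=-2.5)
        assert fit.po_hist == pytest.approx(0.5, abs=0.01)
        assert fit.unitary_amplitude == pytest.approx(-2.5, abs=0.05)


class TestComparePoMethods:
    def test_noiseless_square_wave_methods_agree_exactly(self):
        # transitions aligned to sample boundaries: no bridge samples
        trace = np.tile(np.repeat([0.0, 10.0], 25), 4)
        rec = single_segment_recording([trace] * 5)
        diff = compare_po_methods(rec, 10.0, 90.0)
        assert diff == pytest.approx(0.0, abs=1e-6)


class TestChordConductance:
    def test_printed_conductance_pairs(self):
        assert chord_conductance(9.09, 90.0) == pytest.approx(101.0, abs=0.1)
        assert chord_conductance(-2.52, -90.0) == pytest.approx(28.0, abs=0.1)

    def test_zero_current_zero_conductance(self):
        assert chord_conductance(0.0, 90.0) == 0.0

    def test_zero_voltage_rejected(self):
        with pytest.raises(ValueError):
            chord_conductance(1.0, 0.0)
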