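"""Gating simulator: exactness of the Markov realization, agreement with
the stationary-solution oracle, and determinism of rendered recordings."""

import numpy as np
import pytest

from patchbind.channelsim import (
    BindingTruth,
    GatingModel,
    NoiseModel,
    analytic_po,
    render_recording,
    sample_path,
    simulate_binding,
    simulate_gating,
)
from patchbind.sweepio import Protocol, segment_by_voltage


def occupancy_fraction(path, state):
    total = sum(d for _, d in path)
    return sum(d for s, d in path if s == state) / total


class TestSimulateGating:
    def test_single_absorbing_state_spans_duration(self):
        model = GatingModel(states=(("C", 0.0),), Q=np.zeros((1, 1)))
        path = simulate_gating(model, 5.0, seed=0)
        assert path == [(0, 5.0)]

    def test_dwells_sum_to_duration(self, two_state_09):
        path = simulate_gating(two_state_09, 3.0, seed=42)
        assert sum(d for _, d in path) == pytest.approx(3.0, abs=1e-12)

    def test_two_state_occupancy_matches_stationary(self, two_state_09):
        # batch the 100 s path to estimate the Monte-Carlo SE of the mean
        rng = np.random.default_rng(7)
        fracs = [occupancy_fraction(simulate_gating(two_state_09, 5.0, rng), 1)
                 for _ in range(20)]
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.9) < 3 * se + 1e-4

    def test_same_seed_identical_path(self, two_state_09):
        p1 = simulate_gating(two_state_09, 2.0, seed=9)
        p2 = simulate_gating(two_state_09, 2.0, seed=9)
        assert p1 == p2

    def test_absorbing_state_ends_path(self):
        # O has no exit: the path must terminate there
        Q = np.array([[-50.0, 50.0], [0.0, 0.0]])
        model = GatingModel(states=(("C", 0.0), ("O", 1.0)), Q=Q)
        path = simulate_gating(model, 50.0, seed=3)
        assert path[-1][0] == 1

    def test_invalid_duration_rejected(self, two_state_09):
        with pytest.raises(ValueError):
            simulate_gating(two_state_09, 0.0, seed=0)


class TestGatingModelValidation:
    def test_negative_offdiagonal_rejected(self):
        Q = np.array([[1.0, -1.0], [2.0, -2.0]])
        with pytest.raises(ValueError, match="nonnegative"):
            GatingModel(states=(("C", 0.0), ("O", 1.0)), Q=Q)

    def test_rows_must_sum_to_zero(self):
        Q = np.array([[-1.0, 2.0], [3.0, -3.0]])
        with pytest.raises(ValueError, match="sum to zero"):
            GatingModel(states=(("C", 0.0), ("O", 1.0)), Q=Q)

    def test_closed_state_required(self):
        with pytest.raises(ValueError, match="closed"):
            GatingModel(states=(("O", 1.0),), Q=np.zeros((1, 1)))


class TestAnalyticPo:
    def test_two_state_closed_form(self):
        # beta/(alpha+beta) with beta=900, alpha=100
        _, po = analytic_po(GatingModel.two_state(900.0, 100.0))
        assert po == pytest.approx(0.9, abs=1e-12)

    def test_three_state_linear_chain_vs_simulation(self):
        # C1 <-> C2 <-> O; stationary solve cross-checked by a long run
        k12, k21, k23, k32 = 50.0, 50.0, 500.0, 100.0
        Q = np.array([
            [-k12, k12, 0.0],
            [k21, -(k21 + k23), k23],
            [0.0, k32, -k32],
        ])
        model = GatingModel(states=(("C1", 0.0), ("C2", 0.0), ("O", 1.0)), Q=Q)
        pi, po = analytic_po(model)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(pi @ Q, 0.0, atol=1e-10)
        sim_po = occupancy_fraction(simulate_gating(model, 200.0, seed=17), 2)
        assert sim_po == pytest.approx(po, abs=0.03)

    def test_all_closed_model_has_po_zero(self):
        Q = np.array([[-10.0, 10.0], [10.0, -10.0]])
        model = GatingModel(states=(("C1", 0.0), ("C2", 0.0)), Q=Q)
        _, po = analytic_po(model)
        assert po == 0.0

    def test_reducible_chain_flagged(self):
        # two disconnected closed classes: no unique stationary law
        Q = np.zeros((2, 2))
        model = GatingModel(states=(("C", 0.0), ("O", 1.0)), Q=Q)
        with pytest.raises(ValueError, match="not unique"):
            analytic_po(model)

    def test_weighted_po_counts_subconductance_fractionally(self):
        Q = np.array([[-100.0, 50.0, 50.0],
                      [100.0, -100.0, 0.0],
                      [100.0, 0.0, -100.0]])
        model = GatingModel(states=(("C", 0.0), ("S", 0.5), ("O", 1.0)), Q=Q)
        _, po_any = analytic_po(model)
        _, po_w = analytic_po(model, weighted=True)
        assert po_w < po_any


class TestSamplePath:
    def test_aligned_dwells_reproduce_square_wave(self):
        fs = 1000.0
        path = [(0, 0.01), (1, 0.01), (0, 0.01)]
        frac = sample_path(path, np.array([0.0, 1.0]), 30, fs)
        assert np.allclose(frac, np.repeat([0.0, 1.0, 0.0], 10), atol=1e-9)

    def test_subsample_dwell_time_weighted(self):
        # half-sample opening contributes 0.5 to the straddled sample
        fs = 1000.0
        path = [(0, 0.0005), (1, 0.0005), (0, 0.001)]
        frac = sample_path(path, np.array([0.0, 1.0]), 2, fs)
        assert frac == pytest.approx([0.5, 0.0], abs=1e-12)


class TestRenderRecording:
    def always_open(self):
        return GatingModel(states=(("C", 0.0), ("O", 1.0)), Q=np.zeros((2, 2)),
                           initial_distribution=[0.0, 1.0])

    def test_zero_noise_always_open_is_amplitude_rectangle(
            self, step_protocol, quiet_noise):
        rec = render_recording(self.always_open(), step_protocol, quiet_noise,
                               n_null_sweeps=1, seed=0)
        sweep = rec.active_sweeps[0].samples
        slices = segment_by_voltage(len(sweep), step_protocol, 20_000.0)
        assert np.all(sweep[slices[90.0]] == 10.0)
        assert np.all(sweep[slices[-90.0]] == -2.5)

    def test_two_channels_superpose(self, step_protocol, quiet_noise):
        rec = render_recording(self.always_open(), step_protocol, quiet_noise,
                               n_channels=2, n_null_sweeps=0, seed=0)
        sweep = rec.active_sweeps[0].samples
        sl = segment_by_voltage(len(sweep), step_protocol, 20_000.0)[90.0]
        assert np.all(sweep[sl] == 20.0)

    def test_null_sweeps_contain_only_leak(self, step_protocol, quiet_noise):
        import dataclasses
        leak = np.full(step_protocol.n_samples(20_000.0), 5.0)
        noise = dataclasses.replace(quiet_noise, leak_template=leak)
        rec = render_recording(self.always_open(), step_protocol, noise,
                               n_null_sweeps=2, seed=0)
        assert [s.is_null for s in rec.sweeps[:2]] == [True, True]
        assert np.all(rec.sweeps[0].samples == 5.0)

    def test_silent_delay_forces_closed_prefix(self, two_state_09,
                                               step_protocol, quiet_noise):
        rec, truth = render_recording(two_state_09, step_protocol, quiet_noise,
                                      n_null_sweeps=0, silent_delay=2.0, seed=1,
                                      return_truth=True)
        n_silent = int(np.ceil(2.0 / 0.7))
        for k in range(n_silent):
            assert np.all(rec.sweeps[k].samples == 0.0)
            assert np.all(truth[k] == 0)
        assert any(np.any(t > 0) for t in truth[n_silent:])

    def test_same_seed_byte_identical(self, two_state_09, step_protocol,
                                      paper_noise):
        r1 = render_recording(two_state_09, step_protocol, paper_noise, seed=5)
        r2 = render_recording(two_state_09, step_protocol, paper_noise, seed=5)
        for a, b in zip(r1.sweeps, r2.sweeps):
            assert np.array_equal(a.samples, b.samples)

    def test_missing_amplitude_rejected(self, two_state_09, quiet_noise):
        proto = Protocol(segments=((60.0, 100.0),), cycle_period_ms=100.0,
                         n_sweeps=1, unitary_amplitude_pA={})
        with pytest.raises(ValueError, match="amplitude"):
            render_recording(two_state_09, proto, quiet_noise, seed=0)

    def test_mean_po_of_rendered_sweeps_matches_oracle(self, two_state_09,
                                                       quiet_noise):
        # time-weighted occupancy of the rendered traces against pi Q = 0
        proto = Protocol(segments=((90.0, 500.0),), cycle_period_ms=500.0,
                         n_sweeps=200, unitary_amplitude_pA={90.0: 10.0})
        rec = render_recording(two_state_09, proto, quiet_noise,
                               n_null_sweeps=0, seed=23)
        mean_current = np.mean([s.samples.mean() for s in rec.sweeps])
        assert mean_current / 10.0 == pytest.approx(0.9, abs=0.02)


class TestSimulateBinding:
    def test_noiseless_points_on_hill_plus_line(self):
        truth = BindingTruth(Kd=5.0, nH=1.0, Bmax=200.0, ns_slope=2.0, cv=0.0)
        L = np.array([1.0, 5.0, 50.0])
        ds = simulate_binding(truth, L, n_replicates=2, seed=0)
        expected = 200.0 * L / (5.0 + L) + 2.0 * L
        for conc, exp in zip(L, expected):
            got = ds.points.loc[ds.points.concentration_nM == conc, "counts"]
            assert np.allclose(got, exp, rtol=1e-12)

    def test_midpoint_specific_is_half_bmax(self):
        truth = BindingTruth(Kd=7.0, nH=1.3, Bmax=80.0, ns_slope=0.0, cv=0.0)
        assert truth.specific(7.0) == pytest.approx(40.0, rel=1e-12)

    def test_saturation_approaches_bmax(self):
        truth = BindingTruth(Kd=2.0, nH=1.0, Bmax=100.0, cv=0.0)
        assert truth.specific(200.0) == pytest.approx(100.0 * 100 / 101, rel=1e-12)

    def test_nonpositive_concentration_rejected(self):
        truth = BindingTruth(Kd=1.0)
        with pytest.raises(ValueError):
            simulate_binding(truth, [0.0, 1.0], seed=0)
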