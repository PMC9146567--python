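"""Twist distributions, expulsion events and the stability verdict."""

import numpy as np
import pytest

import g4integrity as g4
from g4integrity.stability import (circular_difference,
                                   detect_guanine_expulsion,
                                   stability_verdict, twist_distribution,
                                   analyze_trajectory)
from g4integrity.geometry import twist_series


class TestTwistDistribution:
    def test_constant_series(self):
        dist = twist_distribution(np.full(200, 30.0))
        ref = twist_distribution(np.full(200, 30.0), reference=None)
        shifted = twist_distribution(np.full(200, 30.0), reference=ref)
        assert dist.mode == pytest.approx(30.0, abs=2.0)
        assert dist.width == pytest.approx(0.0, abs=1e-9)
        assert shifted.shift == pytest.approx(0.0, abs=1e-9)

    def test_translated_series_shifts_by_constant(self):
        rng = np.random.default_rng(0)
        base = rng.normal(30.0, 3.0, size=2000)
        ref = twist_distribution(base)
        shifted = twist_distribution(base + 7.0, reference=ref)
        assert shifted.shift == pytest.approx(7.0, abs=2.0)  # bin width

    def test_wraparound_width_matches_unwrapped(self):
        rng = np.random.default_rng(1)
        centred = rng.normal(0.0, 8.0, size=3000)
        straddling = ((centred + 180.0 + 180.0) % 360.0) - 180.0  # at ±180
        a = twist_distribution(centred)
        b = twist_distribution(straddling)
        assert b.width == pytest.approx(a.width, abs=1e-6)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            twist_distribution(np.empty(0))

    def test_circular_difference_wraps(self):
        assert circular_difference(170.0, -170.0) == pytest.approx(-20.0)
        assert circular_difference(-170.0, 170.0) == pytest.approx(20.0)

    def test_twist_shift_recovered_from_rebuilt_stack(self, ideal_model):
        # an ensemble built with +7 degrees of twist shifts the mode by 7
        native = g4.generate_ensemble(ideal_model, g4.EnsembleParams(
            n_frames=120, seed=21, sigma_core=0.2))
        twisted_model = g4.build_ideal_g4(g4.BuilderParams(twist=37.0))
        twisted = g4.generate_ensemble(twisted_model, g4.EnsembleParams(
            n_frames=120, seed=22, sigma_core=0.2))
        top_n = g4.detect_topology(ideal_model)
        top_t = g4.detect_topology(twisted_model)
        ref = twist_distribution(twist_series(native, top_n))
        dist = twist_distribution(twist_series(twisted, top_t), reference=ref)
        assert dist.shift == pytest.approx(7.0, abs=2.0)


class TestExpulsionDetection:
    def test_intact_trajectory_has_no_events(self, ideal_model,
                                             ideal_topology):
        traj = g4.generate_ensemble(ideal_model, g4.EnsembleParams(
            n_frames=80, seed=31))
        assert detect_guanine_expulsion(traj, ideal_topology) == []

    def test_injected_expulsion_recovered(self, ideal_model, ideal_topology):
        events = (g4.InjectedEvent("guanine_expulsion", frame=40,
                                   magnitude=12.0, resid=8),)
        traj = g4.generate_ensemble(ideal_model, g4.EnsembleParams(
            n_frames=120, seed=32, events=events))
        found = detect_guanine_expulsion(traj, ideal_topology)
        assert len(found) == 1
        event = found[0]
        assert event.kind == "guanine_expulsion"
        assert event.resid == 8
        assert event.onset_frame == 40
        assert event.persists_to_end

    def test_subthreshold_displacement_is_disruption_not_expulsion(
            self, ideal_model, ideal_topology):
        events = (g4.InjectedEvent("guanine_expulsion", frame=40,
                                   magnitude=5.0, resid=8),)
        traj = g4.generate_ensemble(ideal_model, g4.EnsembleParams(
            n_frames=120, seed=33, events=events))
        found = detect_guanine_expulsion(traj, ideal_topology)
        assert all(e.kind != "guanine_expulsion" for e in found)

    def test_no_false_events_across_seeds(self, ideal_model, ideal_topology):
        for seed in range(20):
            traj = g4.generate_ensemble(ideal_model, g4.EnsembleParams(
                n_frames=60, seed=100 + seed))
            assert detect_guanine_expulsion(traj, ideal_topology) == []


class TestVerdict:
    def test_native_run_is_stable(self, ideal_model):
        traj = g4.generate_ensemble(ideal_model, g4.EnsembleParams(
            n_frames=100, seed=41))
        report = analyze_trajectory(traj, label="Native")
        assert report.verdict == "stable"
        assert report.events == []

    def test_leak_plus_persistent_expulsion_is_destabilized(self, ideal_model):
        events = (g4.InjectedEvent("cation_leak", frame=50, magnitude=15.0,
                                   ion=0),
                  g4.InjectedEvent("guanine_expulsion", frame=50,
                                   magnitude=12.0, resid=8))
        traj = g4.generate_ensemble(ideal_model, g4.EnsembleParams(
            n_frames=140, seed=42, events=events))
        report = analyze_trajectory(traj, label="CA 14-15 r2")
        assert report.verdict == "destabilized"
        kinds = {e["type"] for e in report.events}
        assert "guanine_expulsion" in kinds and "cation_leakage" in kinds

    def test_leakage_alone_does_not_flip_verdict(self, ideal_model):
        events = (g4.InjectedEvent("cation_leak", frame=50, magnitude=15.0,
                                   ion=0),)
        traj = g4.generate_ensemble(ideal_model, g4.EnsembleParams(
            n_frames=140, seed=43, events=events))
        report = analyze_trajectory(traj, label="leak only")
        assert report.verdict == "stable"
        assert any(e["type"] == "cation_leakage" for e in report.events)

    def test_verdict_rule_is_deterministic_on_event_lists(self):
        from g4integrity.stability import DisruptionEvent
        persistent = DisruptionEvent("tetrad_disruption", 8, 0, 10, None, 4.0)
        transient = DisruptionEvent("tetrad_disruption", 8, 0, 10, 60, 4.0)
        assert stability_verdict([persistent], [], 100).verdict == "destabilized"
        assert stability_verdict([transient], [], 100).verdict == "stable"
        assert stability_verdict([], [], 100).verdict == "stable"

    def test_report_json_round_trip(self, ideal_model):
        traj = g4.generate_ensemble(ideal_model, g4.EnsembleParams(
            n_frames=60, seed=44))
        report = analyze_trajectory(traj, label="Native")
        text = report.to_json()
        assert g4.StabilityReport.from_json(text).to_json() == text

    def test_summaries_match_native_reference_geometry(self, ideal_model):
        traj = g4.generate_ensemble(ideal_model, g4.EnsembleParams(
            n_frames=100, seed=45))
        report = analyze_trajectory(traj)
        s = report.summaries
        assert s["n_tetrads"] == 3
        assert s["twist_01_mode"] == pytest.approx(30.0, abs=3.0)
        assert s["com_distance_01_mean"] == pytest.approx(3.3, abs=0.3)
        assert s["adjacent_angle_t0_mean"] == pytest.approx(90.0, abs=2.0)
        assert s["opposite_angle_t0_mean"] == pytest.approx(180.0, abs=3.0)
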