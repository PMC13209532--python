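import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tugait.errors import PairingError, UndefinedStatisticError
from tugait.features import (
    GaitStateVector,
    StepEvents,
    build_state_vector,
    detect_steps,
    foot_depth_difference,
    stride_stats,
    temporal_params,
    walking_speed,
)
from tugait.segmentation import PhaseSegmentation


def _phases(n, walk1, walk2=None, fps=30.0):
    """A minimal valid segmentation whose walking span is configurable."""
    walk2 = walk2 or (n - 3, n - 2)
    intervals = {
        "Sit1": (0, 1),
        "SitToStand": (1, 2),
        "Walk1": (2, walk1[1]) if walk1[0] <= 2 else walk1,
        "Turn1": (walk1[1], walk2[0]),
        "Walk2": walk2,
        "Turn2": (walk2[1], n - 1),
        "StandToSit": (n - 1, n),
        "Sit2": (n, n),
    }
    intervals["Walk1"] = (2, walk1[1])
    return PhaseSegmentation(fps=fps, intervals=intervals)


class TestFootDepthDifference:
    def test_identical_tracks_give_zero(self):
        z = np.linspace(1, 4, 50)
        np.testing.assert_allclose(foot_depth_difference(z, z), 0.0)

    def test_swapping_feet_negates(self):
        rng = np.random.default_rng(0)
        zl, zr = rng.normal(size=50), rng.normal(size=50)
        np.testing.assert_allclose(
            foot_depth_difference(zl, zr), -foot_depth_difference(zr, zl)
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(PairingError):
            foot_depth_difference(np.zeros(5), np.zeros(6))


class TestDetectSteps:
    def test_sinusoid_yields_analytic_extrema_count(self):
        """0.5 m amplitude at 1 Hz over 4 s has exactly 4 peaks + 4 valleys,
        each with |D| = 0.5 m."""
        fps = 30.0
        t = np.arange(120) / fps
        d = 0.5 * np.sin(2 * np.pi * 1.0 * t)
        phases = _phases(120, walk1=(2, 60), walk2=(61, 117), fps=fps)
        steps = detect_steps(d, phases, fps)
        assert steps.n_total == 8
        # extrema fall between samples at 30 fps: |D| within cos(pi/30) of 0.5
        np.testing.assert_allclose(steps.stride_proxies(walking_only=False), 0.5, atol=5e-3)

    def test_phase_restriction_halves_the_walk_count(self):
        fps = 30.0
        t = np.arange(120) / fps
        d = 0.5 * np.sin(2 * np.pi * 1.0 * t)
        phases = _phases(120, walk1=(2, 60), walk2=(118, 119), fps=fps)
        steps = detect_steps(d, phases, fps)
        assert steps.n_total == 8
        assert steps.n_walk == 4  # only the first two seconds are walking

    def test_constant_signal_has_no_events(self):
        phases = _phases(60, walk1=(2, 30))
        steps = detect_steps(np.full(60, 1.0), phases, 30.0)
        assert steps.n_total == 0


class TestStrideStats:
    def test_hand_computed_mean_and_cv(self):
        """Strides {0.4, 0.6}: mean 0.5 m, population sigma 0.1, CV 20%."""
        d = np.array([0.4, 0.0, -0.6, 0.0])
        steps = StepEvents(d_signal=d, all_events=[0, 2], walk_events=[0, 2])
        sl, cv = stride_stats(steps)
        assert sl == pytest.approx(0.5)
        assert cv == pytest.approx(20.0)

    def test_equal_strides_have_zero_cv(self):
        d = np.array([0.5, -0.5, 0.5])
        steps = StepEvents(d_signal=d, all_events=[0, 1, 2], walk_events=[0, 1, 2])
        assert stride_stats(steps)[1] == pytest.approx(0.0)

    @given(st.floats(0.1, 10.0))
    def test_cv_scale_invariant_mean_equivariant(self, c):
        d = np.array([0.4, -0.6, 0.5])
        a = StepEvents(d_signal=d, all_events=[0, 1, 2], walk_events=[0, 1, 2])
        b = StepEvents(d_signal=c * d, all_events=[0, 1, 2], walk_events=[0, 1, 2])
        sl_a, cv_a = stride_stats(a)
        sl_b, cv_b = stride_stats(b)
        assert sl_b == pytest.approx(c * sl_a)
        assert cv_b == pytest.approx(cv_a)

    def test_no_walking_steps_is_undefined(self):
        steps = StepEvents(d_signal=np.zeros(5), all_events=[1], walk_events=[])
        with pytest.raises(UndefinedStatisticError):
            stride_stats(steps)

    def test_sample_sd_switch(self):
        d = np.array([0.4, 0.0, -0.6, 0.0])
        steps = StepEvents(d_signal=d, all_events=[0, 2], walk_events=[0, 2])
        _, cv = stride_stats(steps, ddof=1)
        assert cv == pytest.approx(100 * np.std([0.4, 0.6], ddof=1) / 0.5)


class TestTemporalParams:
    def test_printed_session_arithmetic(self):
        """Boundaries 30 -> 396 at 30 fps give the printed 12.2 s total, and
        a 36-frame turn gives 1.2 s."""
        intervals = {
            "Sit1": (0, 30),
            "SitToStand": (30, 78),
            "Walk1": (78, 150),
            "Turn1": (150, 186),
            "Walk2": (186, 330),
            "Turn2": (330, 360),
            "StandToSit": (360, 396),
            "Sit2": (396, 420),
        }
        phases = PhaseSegmentation(fps=30.0, intervals=intervals)
        t_total, t_turn, t_sts = temporal_params(phases, 30.0)
        assert t_total == pytest.approx(12.2)
        assert t_turn == pytest.approx(1.2)
        assert t_sts == pytest.approx(1.6)

    def test_doubling_fps_halves_durations(self):
        intervals = {
            "Sit1": (0, 30), "SitToStand": (30, 78), "Walk1": (78, 150),
            "Turn1": (150, 186), "Walk2": (186, 330), "Turn2": (330, 360),
            "StandToSit": (360, 396), "Sit2": (396, 420),
        }
        p30 = PhaseSegmentation(fps=30.0, intervals=intervals)
        p60 = PhaseSegmentation(fps=60.0, intervals=intervals)
        assert temporal_params(p60, 60.0)[0] == pytest.approx(
            temporal_params(p30, 30.0)[0] / 2
        )


class TestWalkingSpeed:
    def test_printed_session_values(self):
        assert walking_speed(0.53, 12, 12.2) == pytest.approx(0.5213, abs=1e-4)

    def test_zero_steps_zero_speed(self):
        assert walking_speed(0.5, 0, 10.0) == 0.0

    def test_linear_in_stride_length(self):
        assert walking_speed(1.0, 12, 12.2) == pytest.approx(2 * walking_speed(0.5, 12, 12.2))

    def test_identity_with_total_duration(self):
        v = walking_speed(0.53, 12, 12.2)
        assert v * 12.2 == pytest.approx(0.53 * 12, abs=1e-12)


class TestStateVector:
    PRINTED = dict(
        T_total=12.2, V_walk=0.53 * 12 / 12.2, T_turn=1.2, T_sts=1.6,
        N_total=14, N_walk=12, SL_mean=0.53, CV=21.65,
    )

    def test_report_table_has_exact_labels_and_units(self):
        table = GaitStateVector(**self.PRINTED).to_table()
        assert list(table["Parameter"]) == [
            "Total Time", "Step Count (Total)", "Step Count (Walk)",
            "Avg Stride", "Stride CV", "Turn Duration", "Sit-Stand Duration",
        ]
        assert list(table["Unit"]) == ["s", "1", "1", "m", "%", "s", "s"]
        row = table.set_index("Parameter")["Value"]
        assert row["Total Time"] == 12.2
        assert row["Stride CV"] == 21.65
        assert row["Avg Stride"] == 0.53

    def test_serialization_roundtrip_lossless(self):
        x = GaitStateVector(**self.PRINTED)
        assert GaitStateVector.from_json(x.to_json()) == x

    def test_counts_ordering_enforced(self):
        bad = dict(self.PRINTED)
        bad.update(N_walk=15)
        with pytest.raises(Exception):
            GaitStateVector(**bad)


def test_build_state_vector_respects_eq19_identity():
    fps = 30.0
    t = np.arange(360) / fps
    d = 0.5 * np.sin(2 * np.pi * 1.0 * t)
    phases = _phases(360, walk1=(2, 180), walk2=(181, 357), fps=fps)
    steps = detect_steps(d, phases, fps)
    x = build_state_vector(steps, phases, fps)
    assert x.V_walk * x.T_total == pytest.approx(x.SL_mean * x.N_walk, abs=1e-12)
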