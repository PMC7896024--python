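"""Rigid base-pair geometry: step transforms, chain building, cores and
fiber assembly."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fibertopo.geometry import (BasePairFrame, CoreTemplate, FiberSpec,
                                StepParams, assemble_fiber, build_chain,
                                build_core, extract_steps, regular_fiber,
                                step_to_transform, steps_to_array)


class TestStepTransform:
    def test_twist_only_step_is_pure_z_screw(self):
        R, d = step_to_transform(StepParams(0, 0, 36.0, 0, 0, 0.34))
        expected = Rotation.from_euler("z", 36.0, degrees=True).as_matrix()
        np.testing.assert_allclose(R, expected, atol=1e-12)
        np.testing.assert_allclose(d, [0, 0, 0.34], atol=1e-12)

    def test_zero_step_is_identity(self):
        R, d = step_to_transform(StepParams(0, 0, 0, 0, 0, 1e-9))
        np.testing.assert_allclose(R, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(d, [0, 0, 1e-9], atol=1e-15)

    def test_rotation_angle_matches_quaternion_composition(self):
        """Net rotation angle agrees with an independent quaternion
        composition of the half-twist / bend / half-twist factors."""
        step = StepParams(5.0, 5.0, 34.0, 0.1, 0.1, 0.34)
        R, _ = step_to_transform(step)
        q_half = Rotation.from_euler("z", 17.0, degrees=True)
        q_bend = Rotation.from_rotvec(np.deg2rad([5.0, 5.0, 0.0]))
        q = q_half * q_bend * q_half
        angle = np.linalg.norm(q.as_rotvec())
        got = np.linalg.norm(Rotation.from_matrix(R).as_rotvec())
        assert abs(angle - got) < 1e-10
        np.testing.assert_allclose(R, q.as_matrix(), atol=1e-12)

    def test_forward_then_inverse_is_identity(self):
        R, _ = step_to_transform(StepParams(3, -2, 35, 0.05, 0, 0.33))
        np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-12)


class TestBuildChain:
    def test_ten_twist_steps_give_straight_helical_axis(self):
        steps = [StepParams(0, 0, 36.0, 0, 0, 0.34)] * 10
        frames = build_chain(BasePairFrame.identity(), steps)
        assert len(frames) == 11
        np.testing.assert_allclose(frames[-1].origin, [0, 0, 3.4], atol=1e-12)
        # full turn: end frame equals start frame
        np.testing.assert_allclose(frames[-1].axes, np.eye(3), atol=1e-12)

    def test_empty_steps_return_start_only(self):
        frames = build_chain(BasePairFrame.identity(), [])
        assert len(frames) == 1
        np.testing.assert_allclose(frames[0].origin, np.zeros(3))

    def test_constant_roll_arc_matches_analytic_chord(self):
        """A chain with constant roll (no twist) is a planar circular arc
        whose end-to-end distance is the analytic chord."""
        n, roll, rise = 146, 4.0, 0.34
        steps = [StepParams(0, roll, 0, 0, 0, rise)] * n
        frames = build_chain(BasePairFrame.identity(), steps)
        theta = np.deg2rad(roll)
        radius = (rise / 2) / np.sin(theta / 2)
        chord = 2 * radius * abs(np.sin(n * theta / 2))
        got = np.linalg.norm(frames[-1].origin - frames[0].origin)
        assert abs(got - chord) < 1e-6 * max(chord, 1)

    def test_non_orthonormal_start_rejected(self):
        bad = BasePairFrame(np.zeros(3), np.eye(3) * 1.5)
        with pytest.raises(ValueError, match="orthonormal"):
            build_chain(bad, [StepParams.relaxed()])

    def test_all_frames_orthonormal(self, rng):
        steps = [StepParams(*row) for row in
                 rng.normal([0, 0, 34.3, 0, 0, 0.34],
                            [4, 4, 3, 0.1, 0.1, 0.02], size=(80, 6))]
        for f in build_chain(BasePairFrame.identity(), steps):
            f.require_orthonormal(tol=1e-9)


class TestRoundTrip:
    def test_extract_and_rebuild_reproduces_origins(self, rng):
        steps = [StepParams(*row) for row in
                 rng.normal([1, -2, 34.3, 0.02, -0.05, 0.34],
                            [3, 3, 3, 0.1, 0.1, 0.02], size=(60, 6))]
        frames = build_chain(BasePairFrame.identity(), steps)
        back = extract_steps(frames)
        rebuilt = build_chain(frames[0], back)
        o1 = np.array([f.origin for f in frames])
        o2 = np.array([f.origin for f in rebuilt])
        assert np.abs(o1 - o2).max() < 1e-6
        s1 = steps_to_array(steps)
        s2 = steps_to_array(back)
        assert np.abs(s1 - s2).max() < 1e-9


class TestBuildCore:
    def test_default_core_shape(self):
        core = build_core()
        assert core.L_NCP == 147
        assert abs(np.linalg.norm(core.superhelical_axis) - 1) < 1e-12
        np.testing.assert_allclose(core.entry_frame.origin,
                                   core.bp_path[0].origin)
        np.testing.assert_allclose(core.exit_frame.origin,
                                   core.bp_path[-1].origin)

    def test_left_handed_wrap_about_axis(self):
        """Going along the wrap, the azimuth about the superhelical axis
        decreases (left-handed) while the axial coordinate advances."""
        core = build_core()
        pts = core.origins() - core.center
        ax = core.superhelical_axis
        e1 = pts[0] - (pts[0] @ ax) * ax
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(ax, e1)
        phi = np.unwrap(np.arctan2(pts @ e2, pts @ e1))
        assert phi[-1] - phi[0] < -2 * np.pi  # > 1 turn, negative sense
        z = pts @ ax
        assert abs(z[-1] - z[0]) > 2.0

    def test_zero_wrap_rejected(self):
        with pytest.raises(ValueError, match="wrap_turns"):
            build_core(wrap_turns=0.0)

    def test_right_handed_parameterization_rejected(self):
        with pytest.raises(ValueError, match="left-handed"):
            CoreTemplate(left_handed=False)

    def test_wrap_angular_extent(self):
        tpl = CoreTemplate(wrap_turns=1.65)
        pts = tpl.bp_local - tpl.center_local
        ax = tpl.axis_local
        e1 = pts[0] - (pts[0] @ ax) * ax
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(ax, e1)
        phi = np.unwrap(np.arctan2(pts @ e2, pts @ e1))
        assert abs(abs(phi[-1] - phi[0]) - 1.65 * 2 * np.pi) < 1e-6


class TestAssembleFiber:
    def test_single_nucleosome_is_placed_core(self, template):
        spec = FiberSpec(L=20, n_nucleosomes=1)
        fiber = assemble_fiber(spec, [], template=template)
        assert fiber.bp_origins().shape == (147, 3)
        np.testing.assert_allclose(fiber.cores[0].entry_frame.axes, np.eye(3),
                                   atol=1e-12)

    def test_bp_count_bookkeeping(self, template):
        spec = FiberSpec(L=20, n_nucleosomes=3)
        fiber = regular_fiber(spec, StepParams.relaxed(), template=template)
        assert len(fiber.bp_origins()) == 3 * 147 + 2 * 20

    def test_wrong_linker_count_rejected(self, template):
        spec = FiberSpec(L=20, n_nucleosomes=3)
        with pytest.raises(ValueError, match="linkers"):
            assemble_fiber(spec, [np.zeros((21, 6))], template=template)

    def test_wrong_steps_per_linker_rejected(self, template):
        spec = FiberSpec(L=20, n_nucleosomes=2)
        with pytest.raises(ValueError, match="L\\+1"):
            assemble_fiber(spec, [steps_to_array(
                [StepParams.relaxed()] * 5)], template=template)

    def test_chain_is_gap_free(self, template):
        spec = FiberSpec(L=25, n_nucleosomes=4)
        fiber = regular_fiber(spec, StepParams.relaxed(), template=template)
        gaps = np.linalg.norm(np.diff(fiber.bp_origins(), axis=0), axis=1)
        assert gaps.max() < 0.75  # no jump larger than ~2 bp rises
        assert gaps.min() > 0.05


class TestRotationalSetting:
    def test_five_extra_bp_flip_the_setting_by_half_turn(self, template):
        """Adding 5 bp of relaxed linker rotates each successive
        nucleosome by ~180 deg about the linker: the angle between
        successive superhelical-axis pairs changes by 180 +- 15 deg."""
        def axis_angle(L):
            spec = FiberSpec(L=L, n_nucleosomes=3)
            fiber = regular_fiber(spec, StepParams.relaxed(),
                                  template=template)
            _, axes = fiber.core_centers_axes()
            return np.degrees(np.arccos(np.clip(axes[0] @ axes[1], -1, 1)))

        delta = axis_angle(25) - axis_angle(20)
        assert abs(abs(delta) - 180) % 360 < 15 or \
            abs((axis_angle(25) + axis_angle(20)) - 180) < 15

    def test_linker_class_labels(self):
        assert FiberSpec(L=20, n_nucleosomes=2).linker_class == "10n-like"
        assert FiberSpec(L=25, n_nucleosomes=2).linker_class == "10n+5-like"
        assert FiberSpec(L=34, n_nucleosomes=2).linker_class == "10n-like"
        assert FiberSpec(L=37, n_nucleosomes=2).linker_class == "10n+5-like"


class TestFiberSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(L=9, n_nucleosomes=2),
        dict(L=20, L_NCP=150, n_nucleosomes=2),
        dict(L=20, n_nucleosomes=0),
        dict(L=20, n_nucleosomes=2, family_hint="T3"),
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FiberSpec(**kwargs)

    def test_nrl_is_derived(self):
        assert FiberSpec(L=20, L_NCP=147, n_nucleosomes=2).NRL == 167
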