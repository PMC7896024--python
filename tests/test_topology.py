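"""Twist, writhe and linking-number computations."""

import numpy as np
import pytest

from fibertopo import _kernels
from fibertopo.fixtures import make_fixtures, planar_circle, trefoil
from fibertopo.geometry import (FiberConformation, FiberSpec, StepParams,
                                regular_fiber, relaxed_step_array)
from fibertopo.topology import (ClosedCurve, close_curve, close_fiber,
                                delta_lk, linking_number, ribbon_twist,
                                twist_of, writhe)


def _single_core_fiber(template):
    spec = FiberSpec(L=20, n_nucleosomes=1)
    return FiberConformation(spec=spec, template=template,
                             core_R=np.eye(3)[None].copy(),
                             core_t=np.zeros((1, 3)),
                             linker_steps=np.zeros((0, 21, 6)))


class TestTwist:
    def test_ten_36deg_steps_make_one_turn(self):
        steps = [StepParams(0, 0, 36.0, 0, 0, 0.34)] * 10
        tw, _ = twist_of(steps)
        assert abs(tw - 1.0) < 1e-12

    def test_relaxed_chain_has_zero_twist_change(self):
        _, dtw = twist_of(relaxed_step_array(105))
        assert abs(dtw) < 1e-12

    def test_mixed_twist_equals_running_sum(self, rng):
        twists = rng.uniform(25, 45, size=40)
        arr = relaxed_step_array(40)
        arr[:, 2] = twists
        tw, dtw = twist_of(arr)
        assert abs(tw - twists.sum() / 360.0) < 1e-12
        assert abs(dtw - (twists.sum() - 40 * 34.3) / 360.0) < 1e-12

    def test_empty_steps_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            twist_of(np.zeros((0, 6)))


class TestWrithe:
    def test_planar_circle_has_zero_writhe(self):
        fx = planar_circle(200)
        for method in ("levitt_le_bret", "gauss_pairs"):
            assert abs(writhe(ClosedCurve(fx.vertices), method)) < 1e-6

    def test_trefoil_matches_fine_discretization(self):
        fx = trefoil(400, 4000)
        got = writhe(ClosedCurve(fx.vertices))
        assert abs(got - fx.expected_writhe) < fx.tolerance

    @pytest.mark.parametrize("alpha", [15.0, 30.0, 45.0])
    def test_solenoid_matches_fuller_closed_form(self, alpha):
        from fibertopo.fixtures import toroidal_solenoid
        fx = toroidal_solenoid(alpha)
        got = writhe(ClosedCurve(fx.vertices))
        assert abs(got - fx.expected_writhe) <= fx.tolerance

    def test_methods_agree_on_all_fixtures(self):
        for fx in make_fixtures():
            c = ClosedCurve(fx.vertices)
            assert abs(writhe(c, "levitt_le_bret")
                       - writhe(c, "gauss_pairs")) < 0.02

    def test_invariance_under_rigid_motion_and_scaling(self, rng):
        fx = trefoil(300)
        c = ClosedCurve(fx.vertices)
        w0 = writhe(c)
        from scipy.spatial.transform import Rotation
        R = Rotation.random(random_state=7).as_matrix()
        c2 = c.transformed(R=R, t=rng.normal(0, 50, 3), scale=2.7)
        assert abs(writhe(c2) - w0) < 1e-9

    def test_antisymmetric_under_mirror_reflection(self):
        fx = trefoil(300)
        c = ClosedCurve(fx.vertices)
        assert abs(writhe(c.mirrored()) + writhe(c)) < 1e-9

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            writhe(ClosedCurve(planar_circle().vertices), method="midpoint")


def _random_framed_loop(rng, n=400, twist_turns=7.3):
    """Smooth random closed curve with parallel-transported normals plus
    a uniform added twist: a discrete closed ribbon."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.zeros((n, 3))
    pts[:, 0] = 10 * np.cos(t)
    pts[:, 1] = 10 * np.sin(t)
    for k in range(2, 6):
        for d in range(3):
            a, b = rng.normal(0, 3.0 / k, 2)
            pts[:, d] += a * np.cos(k * t) + b * np.sin(k * t)
    tang = np.roll(pts, -1, axis=0) - pts
    tang /= np.linalg.norm(tang, axis=1)[:, None]
    u = np.cross(tang[0], [0, 0, 1.0])
    u /= np.linalg.norm(u)
    normals = np.zeros((n, 3))
    rate = 2 * np.pi * twist_turns / n
    for i in range(n):
        if i > 0:
            c = np.cross(tang[i - 1], tang[i])
            cn = np.linalg.norm(c)
            dt = np.clip(tang[i - 1] @ tang[i], -1, 1)
            if cn > 1e-14:
                ang = np.arctan2(cn, dt)
                u = _kernels._rodrigues(*(ang * c / cn)) @ u
            ct, st = np.cos(rate), np.sin(rate)
            u = ct * u + st * np.cross(tang[i], u) \
                + (1 - ct) * (tang[i] @ u) * tang[i]
        u = u - (u @ tang[i]) * tang[i]
        u /= np.linalg.norm(u)
        normals[i] = u
    return pts, normals


class TestWhiteTheorem:
    def test_linking_number_decomposes_into_twist_plus_writhe(self, rng):
        pts, normals = _random_framed_loop(rng)
        lk = linking_number(pts, pts + 0.3 * normals)
        tw = ribbon_twist(pts, normals)
        wr = writhe(ClosedCurve(pts))
        assert abs(lk - round(lk)) < 5e-3   # Lk of a closed ribbon is integer
        assert abs(tw + wr - lk) < 5e-3

    def test_sum_invariant_under_noncrossing_deformation(self, rng):
        pts, normals = _random_framed_loop(rng)
        lk0 = ribbon_twist(pts, normals) + writhe(ClosedCurve(pts))
        n = len(pts)
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        for trial in range(3):
            # smooth, small random deformation: cannot cross itself
            d = np.zeros((n, 3))
            for k in range(1, 5):
                for dim in range(3):
                    a, b = rng.normal(0, 0.25 / k, 2)
                    d[:, dim] += a * np.cos(k * t) + b * np.sin(k * t)
            p2 = pts + d
            tang = np.roll(p2, -1, axis=0) - p2
            tang /= np.linalg.norm(tang, axis=1)[:, None]
            n2 = normals - np.sum(normals * tang, axis=1)[:, None] * tang
            n2 /= np.linalg.norm(n2, axis=1)[:, None]
            tw = ribbon_twist(p2, n2)
            wr = writhe(ClosedCurve(p2))
            # Tw and Wr trade against each other; their sum is pinned
            assert abs((tw + wr) - lk0) < 0.02
            assert abs(wr - writhe(ClosedCurve(pts))) > 1e-4


class TestCloseFiber:
    def test_straight_relaxed_dna_closes_with_zero_writhe(self):
        from fibertopo.geometry import BasePairFrame, build_chain
        frames = build_chain(BasePairFrame.identity(),
                             [StepParams.relaxed()] * 199)
        pts = np.array([f.origin for f in frames])
        closed = close_curve(pts)
        assert abs(writhe(closed)) < 0.01

    def test_single_core_closure_writhe(self, template):
        """The wrapped core closed by the distant return path: about one
        negative turn of writhe (left-handed wrap), value frozen from the
        two independent Gauss-integral evaluations."""
        closed = close_fiber(_single_core_fiber(template))
        w_exact = writhe(closed, "levitt_le_bret")
        w_quad = writhe(closed, "gauss_pairs")
        assert abs(w_exact - w_quad) < 0.02
        assert -1.3 < w_exact < -0.7

    def test_circular_input_rejected(self, template):
        spec = FiberSpec(L=20, n_nucleosomes=2, circular=True)
        fiber = regular_fiber(spec, StepParams.relaxed(), template=template)
        with pytest.raises(ValueError, match="circular"):
            close_fiber(fiber)


class TestDeltaLk:
    def test_relaxed_naked_circular_dna_is_topologically_relaxed(self):
        """A closed planar circle of relaxed-twist DNA has dLk = 0."""
        n = 360
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        r = n * 0.34 / (2 * np.pi)
        pts = np.stack([r * np.cos(t), r * np.sin(t), np.zeros(n)], 1)
        arr = relaxed_step_array(n)
        tw, dtw = twist_of(arr)
        wr = writhe(ClosedCurve(pts))
        assert abs(dtw + wr) < 0.01

    def test_t2_fiber_per_nucleosome_value(self, t2_fiber):
        res = delta_lk(t2_fiber, rebuild=lambda n: regular_fiber(
            FiberSpec(L=20, n_nucleosomes=n),
            t2_fiber.linker_steps[0][0], template=t2_fiber.template))
        assert res.dLk_per_nucleosome == pytest.approx(-1.5, abs=0.15)
        assert abs(res.dLk - (res.dTw + res.Wr)) < 1e-9

    def test_t1_fiber_per_nucleosome_value(self, t1_fiber):
        res = delta_lk(t1_fiber, rebuild=lambda n: regular_fiber(
            FiberSpec(L=25, n_nucleosomes=n),
            t1_fiber.linker_steps[0][0], template=t1_fiber.template))
        assert res.dLk_per_nucleosome == pytest.approx(-1.0, abs=0.15)

    def test_per_nucleosome_value_independent_of_size(self, template):
        """Regularity: dividing the closed-chain dLk by n converges to
        the same per-repeat value for n = 8 and 12 (to 0.05 after end
        effects, handled by the slope over n)."""
        from fibertopo.fixtures import CANONICAL_T2_LINKER

        def slope(ns):
            vals = []
            for n in ns:
                f = regular_fiber(FiberSpec(L=20, n_nucleosomes=n),
                                  CANONICAL_T2_LINKER, template=template)
                res = delta_lk(f, per_nucleosome="divide")
                vals.append(res.dLk)
            return np.polyfit(ns, vals, 1)[0]

        assert abs(slope([4, 6, 8]) - slope([8, 10, 12])) < 0.05


class TestClosedCurveValidation:
    def test_too_few_vertices_rejected(self):
        with pytest.raises(ValueError):
            ClosedCurve(np.zeros((2, 3)))

    def test_repeated_vertices_rejected(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [1, 0, 0], [0, 1, 0.0]])
        with pytest.raises(ValueError, match="distinct"):
            ClosedCurve(v)
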