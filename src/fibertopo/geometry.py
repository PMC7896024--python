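"""Base-pair-resolution DNA geometry for nucleosome fibers.

The model represents duplex DNA as a chain of rigid base-pair frames
connected by six step parameters (tilt, roll, twist in degrees; shift,
slide, rise in nm).  A nucleosome core is ~147 bp wound on a left-handed
superhelix; fibers are cores joined by free linkers of L bp, so the
nucleosome repeat length is NRL = L_NCP + L.

Angles are degrees at this interface; all coordinates are nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels

#: relaxed B-DNA step: 10.5 bp/turn, 0.34 nm rise.  This defines the
#: twist reference state (dTw = 0).
RELAXED_TWIST_DEG = 34.3
RELAXED_RISE_NM = 0.34

#: default nucleosome superhelix: crystal-like radius and pitch.  The
#: effective wrap is 1.525 left-handed turns: the terminal ~10 bp on each
#: side of a real core leave the superhelical ramp nearly straight, so the
#: entry/exit tangent geometry corresponds to fewer turns than the full
#: 1.65-turn wrap.  This value anchors the template to the tetranucleosome
#: crystal: with it, 10n-class linkers (L = 20 bp) fold into the
#: face-stacked two-start fiber with essentially straight relaxed linkers.
CORE_RADIUS_NM = 4.18
CORE_PITCH_NM = 2.39
CORE_WRAP_TURNS = 1.525

#: intrinsic twist of nucleosome-bound DNA (degrees per step); kept at the
#: relaxed B-DNA value so the wrapped core contributes no twist change.
CORE_TWIST_DEG = RELAXED_TWIST_DEG


@dataclass(frozen=True)
class StepParams:
    """Six rigid base-pair step parameters (degrees / nm)."""

    tilt: float = 0.0
    roll: float = 0.0
    twist: float = RELAXED_TWIST_DEG
    shift: float = 0.0
    slide: float = 0.0
    rise: float = RELAXED_RISE_NM

    def __post_init__(self):
        a = self.as_array()
        if not np.all(np.isfinite(a)):
            raise ValueError("step parameters must be finite")
        if self.rise <= 0:
            raise ValueError("rise must be > 0 for a physical step")

    def as_array(self) -> np.ndarray:
        return np.array([self.tilt, self.roll, self.twist,
                         self.shift, self.slide, self.rise], dtype=float)

    @classmethod
    def from_array(cls, a) -> "StepParams":
        return cls(*[float(x) for x in a])

    @classmethod
    def relaxed(cls) -> "StepParams":
        return cls()


def relaxed_step_array(n: int) -> np.ndarray:
    """(n, 6) array of relaxed B-DNA steps."""
    out = np.zeros((n, 6))
    out[:, 2] = RELAXED_TWIST_DEG
    out[:, 5] = RELAXED_RISE_NM
    return out


@dataclass
class BasePairFrame:
    """A rigid base-pair frame: origin (nm) and right-handed orthonormal
    axes (columns: short axis, long axis, normal)."""

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)

    def require_orthonormal(self, tol: float = 1e-9) -> None:
        err = np.abs(self.axes.T @ self.axes - np.eye(3)).max()
        if err > tol:
            raise ValueError(f"frame axes not orthonormal (error {err:.2e})")
        if np.linalg.det(self.axes) < 0:
            raise ValueError("frame axes must be right-handed")

    @classmethod
    def identity(cls) -> "BasePairFrame":
        return cls(np.zeros(3), np.eye(3))


def step_to_transform(step: StepParams) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform of one step: rotation R and world-frame-relative
    displacement d, such that ``F_{i+1} = F_i R`` and
    ``o_{i+1} = o_i + F_i d``."""
    R, d = _kernels.step_transform(step.as_array())
    return R, d


def build_chain(start: BasePairFrame, steps) -> list[BasePairFrame]:
    """Compound a list of StepParams from a start frame.

    Returns len(steps)+1 frames; every frame is re-orthonormalized during
    compounding so numerical drift cannot accumulate.
    """
    start.require_orthonormal(tol=1e-6)
    arr = steps_to_array(steps)
    origins, frames = _kernels.build_chain(start.origin, start.axes, arr)
    return [BasePairFrame(origins[i], frames[i]) for i in range(len(origins))]


def steps_to_array(steps) -> np.ndarray:
    """StepParams list (or (N,6) array) -> (N,6) float array."""
    if isinstance(steps, np.ndarray):
        return np.asarray(steps, dtype=float).reshape(-1, 6)
    return np.array([s.as_array() for s in steps], dtype=float).reshape(-1, 6)


def extract_steps(frames: list[BasePairFrame]) -> list[StepParams]:
    """Inverse of build_chain: recover the step parameters between
    consecutive frames."""
    origins = np.array([f.origin for f in frames])
    axes = np.array([f.axes for f in frames])
    arr = _kernels.extract_steps(origins, axes)
    return [StepParams.from_array(a) for a in arr]


@dataclass
class NucleosomeCore:
    """A nucleosome core: L_NCP base-pair frames on a left-handed
    superhelix, plus derived entry/exit markers."""

    index: int
    bp_path: list[BasePairFrame]
    center: np.ndarray
    superhelical_axis: np.ndarray

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        a = np.asarray(self.superhelical_axis, dtype=float).reshape(3)
        self.superhelical_axis = a / np.linalg.norm(a)

    @property
    def entry_frame(self) -> BasePairFrame:
        return self.bp_path[0]

    @property
    def exit_frame(self) -> BasePairFrame:
        return self.bp_path[-1]

    @property
    def entry_point(self) -> np.ndarray:
        return self.bp_path[0].origin

    @property
    def exit_point(self) -> np.ndarray:
        return self.bp_path[-1].origin

    @property
    def L_NCP(self) -> int:
        return len(self.bp_path)

    def origins(self) -> np.ndarray:
        return np.array([f.origin for f in self.bp_path])


@dataclass(frozen=True)
class FiberSpec:
    """Regular-fiber specification: NRL = L_NCP + L."""

    L: int
    L_NCP: int = 147
    n_nucleosomes: int = 1
    circular: bool = False
    family_hint: str = "auto"

    def __post_init__(self):
        if self.L < 10:
            raise ValueError("linker length L must be >= 10 bp")
        if self.L_NCP not in (146, 147):
            raise ValueError("L_NCP must be 146 or 147 bp")
        if self.n_nucleosomes < 1:
            raise ValueError("need at least one nucleosome")
        if self.family_hint not in ("T1", "T2", "auto"):
            raise ValueError("family_hint must be T1, T2 or auto")

    @property
    def NRL(self) -> int:
        return self.L_NCP + self.L

    @property
    def linker_class(self) -> str:
        """'10n-like' for L mod 10 in 0..4, else '10n+5-like'."""
        return "10n-like" if self.L % 10 <= 4 else "10n+5-like"

    @property
    def n_linkers(self) -> int:
        return self.n_nucleosomes if self.circular else self.n_nucleosomes - 1


class CoreTemplate:
    """Immutable local-coordinate template of a nucleosome core.

    The template is expressed in the coordinates of its own entry frame
    (entry frame = identity at the origin), so placing a core is a single
    rigid transform.
    """

    def __init__(self, L_NCP: int = 147, wrap_turns: float = CORE_WRAP_TURNS,
                 radius: float = CORE_RADIUS_NM, pitch: float = CORE_PITCH_NM,
                 entry_phase_deg: float = 0.0,
                 left_handed: bool = True,
                 twist_deg: float = CORE_TWIST_DEG):
        if L_NCP not in (146, 147):
            raise ValueError("L_NCP must be 146 or 147 bp")
        if not (1.5 <= wrap_turns <= 1.8):
            raise ValueError("wrap_turns must lie in [1.5, 1.8]")
        if not left_handed:
            raise ValueError("nucleosomal wrapping is left-handed; "
                             "right-handed cores violate chirality")
        self.L_NCP = L_NCP
        self.wrap_turns = float(wrap_turns)
        self.radius = float(radius)
        self.pitch = float(pitch)
        self.entry_phase_deg = float(entry_phase_deg)
        self.twist_deg = float(twist_deg)
        self._build()

    def _build(self):
        n = self.L_NCP
        s = np.linspace(0.0, self.wrap_turns * 2 * np.pi, n)
        r, p = self.radius, self.pitch
        # left-handed superhelix about +z: angle decreases as z increases
        pos = np.stack([r * np.cos(s), -r * np.sin(s), p * s / (2 * np.pi)], axis=1)
        tan = np.stack([-r * np.sin(s), -r * np.cos(s),
                        np.full_like(s, p / (2 * np.pi))], axis=1)
        tan /= np.linalg.norm(tan, axis=1)[:, None]
        # frames: normal = tangent; short axis starts radially inward at
        # entry (phase-shifted by entry_phase_deg) and is parallel-
        # transported with an added relaxed-twist rotation per step.
        frames = np.empty((n, 3, 3))
        radial_in = -np.array([np.cos(s[0]), -np.sin(s[0]), 0.0])
        x = radial_in - np.dot(radial_in, tan[0]) * tan[0]
        x /= np.linalg.norm(x)
        phase = np.deg2rad(self.entry_phase_deg)
        x = (np.cos(phase) * x
             + np.sin(phase) * np.cross(tan[0], x))
        for i in range(n):
            if i > 0:
                # parallel transport x from tan[i-1] to tan[i]
                c = np.cross(tan[i - 1], tan[i])
                cn = np.linalg.norm(c)
                dt = float(np.clip(np.dot(tan[i - 1], tan[i]), -1, 1))
                if cn > 1e-14:
                    ang = np.arctan2(cn, dt)
                    x = _kernels._rodrigues(*(ang * c / cn)) @ x
                # intrinsic twist about the new tangent
                tw = np.deg2rad(self.twist_deg)
                x = (np.cos(tw) * x + np.sin(tw) * np.cross(tan[i], x)
                     + (1 - np.cos(tw)) * np.dot(tan[i], x) * tan[i])
                x -= np.dot(x, tan[i]) * tan[i]
                x /= np.linalg.norm(x)
            y = np.cross(tan[i], x)
            frames[i, :, 0] = x
            frames[i, :, 1] = y
            frames[i, :, 2] = tan[i]
        # re-express in entry-frame coordinates: entry frame -> identity
        F0 = frames[0].copy()
        o0 = pos[0].copy()
        pos = (pos - o0) @ F0
        for i in range(n):
            frames[i] = F0.T @ frames[i]
        self.bp_local = pos
        self.frames_local = frames
        # coarse proxy of the wrapped-DNA path for steric checks
        self.wrap_proxy_local = pos[np.linspace(0, n - 1, 16).astype(int)].copy()
        self.entry_to_exit_R = frames[-1].copy()
        self.entry_to_exit_t = pos[-1].copy()
        axis_world = np.array([0.0, 0.0, 1.0])
        center_world = (np.array([0.0, 0.0, p * self.wrap_turns / 2.0]) - o0)
        self.axis_local = F0.T @ axis_world
        self.center_local = center_world @ F0
        self.steps = _kernels.extract_steps(pos, frames)

    def place(self, index: int, R: np.ndarray, t: np.ndarray) -> NucleosomeCore:
        """World-coordinate core from an entry-frame placement (R, t)."""
        pos = self.bp_local @ R.T + t
        path = [BasePairFrame(pos[i], R @ self.frames_local[i])
                for i in range(self.L_NCP)]
        return NucleosomeCore(index=index, bp_path=path,
                              center=R @ self.center_local + t,
                              superhelical_axis=R @ self.axis_local)


def build_core(L_NCP: int = 147, wrap_turns: float = CORE_WRAP_TURNS,
               radius: float = CORE_RADIUS_NM, pitch: float = CORE_PITCH_NM,
               **kw) -> NucleosomeCore:
    """A nucleosome core placed at the identity entry frame."""
    tpl = CoreTemplate(L_NCP=L_NCP, wrap_turns=wrap_turns, radius=radius,
                       pitch=pitch, **kw)
    return tpl.place(0, np.eye(3), np.zeros(3))


@dataclass
class FiberConformation:
    """A full fiber: placed cores plus per-linker step parameters.

    ``linker_steps[i]`` holds the L+1 steps joining core i's exit base
    pair to core i+1's entry base pair, enclosing L free linker bp.
    """

    spec: FiberSpec
    template: CoreTemplate
    core_R: np.ndarray      # (n, 3, 3) entry-frame rotations
    core_t: np.ndarray      # (n, 3) entry-frame origins
    linker_steps: np.ndarray  # (n_linkers, L+1, 6)

    _linker_pts: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.spec.n_nucleosomes

    @property
    def cores(self) -> list[NucleosomeCore]:
        return [self.template.place(i, self.core_R[i], self.core_t[i])
                for i in range(self.n)]

    def core_centers_axes(self) -> tuple[np.ndarray, np.ndarray]:
        return _kernels.core_world_centers_axes(
            self.core_R, self.core_t,
            self.template.center_local, self.template.axis_local)

    def linker_points(self) -> np.ndarray:
        """(n_linkers, L, 3) free linker bp origins."""
        if self._linker_pts is None:
            _, _, pts = _kernels.place_cores_and_linkers(
                self.core_t[0], self.core_R[0],
                self.template.entry_to_exit_R, self.template.entry_to_exit_t,
                self.linker_steps, self.n)
            self._linker_pts = pts
        return self._linker_pts

    def bp_origins(self) -> np.ndarray:
        """Concatenated duplex-axis path: core bp and free linker bp, in
        chain order.  Length n*L_NCP + (n-1)*L open, n*NRL circular."""
        tpl = self.template
        pts = self.linker_points()
        parts = []
        for i in range(self.n):
            parts.append(self.bp_local_world(i))
            if i < pts.shape[0]:
                parts.append(pts[i])
        return np.concatenate(parts, axis=0)

    def bp_local_world(self, i: int) -> np.ndarray:
        return self.template.bp_local @ self.core_R[i].T + self.core_t[i]

    def all_step_twists(self) -> np.ndarray:
        """Twist (degrees) of every DNA step along the chain, cores and
        linkers, in chain order."""
        core_tw = self.template.steps[:, 2]
        out = []
        nl = self.linker_steps.shape[0]
        for i in range(self.n):
            out.append(core_tw)
            if i < nl:
                out.append(self.linker_steps[i][:, 2])
        return np.concatenate(out)

    def n_dna_steps(self) -> int:
        return len(self.all_step_twists())

    def core_index_of_bp(self) -> np.ndarray:
        """Per-bp label: core index, or -1 for free linker bp."""
        lab = []
        nl = self.linker_steps.shape[0]
        for i in range(self.n):
            lab.append(np.full(self.spec.L_NCP, i))
            if i < nl:
                lab.append(np.full(self.spec.L, -1))
        return np.concatenate(lab)

    def mirrored(self) -> "MirroredPath":
        """Coordinate mirror image (for chirality checks): only the bp
        path is meaningful, not the step parameters."""
        pts = self.bp_origins().copy()
        pts[:, 2] *= -1.0
        return MirroredPath(pts)


@dataclass
class MirroredPath:
    points: np.ndarray


def assemble_fiber(spec: FiberSpec, linker_steps, template: CoreTemplate | None = None,
                   start_R: np.ndarray | None = None,
                   start_t: np.ndarray | None = None) -> FiberConformation:
    """Place cores along per-linker step-parameter chains.

    ``linker_steps`` — one (L+1, 6) array (or StepParams list) per linker;
    n-1 linkers for open fibers, n for circular ones.
    """
    if template is None:
        template = CoreTemplate(L_NCP=spec.L_NCP)
    if template.L_NCP != spec.L_NCP:
        raise ValueError("core template L_NCP inconsistent with spec")
    n_link = spec.n_linkers
    if len(linker_steps) != n_link:
        raise ValueError(f"expected {n_link} linkers, got {len(linker_steps)}")
    arrs = [steps_to_array(ls) for ls in linker_steps]
    for a in arrs:
        if a.shape[0] != spec.L + 1:
            raise ValueError(
                f"each linker needs L+1 = {spec.L + 1} steps "
                f"(L = {spec.L} free bp), got {a.shape[0]}")
    steps = np.stack(arrs, axis=0) if n_link else np.zeros((0, spec.L + 1, 6))
    R0 = np.eye(3) if start_R is None else np.asarray(start_R, float)
    t0 = np.zeros(3) if start_t is None else np.asarray(start_t, float)
    if n_link:
        core_R, core_t, pts = _kernels.place_cores_and_linkers(
            t0, R0, template.entry_to_exit_R, template.entry_to_exit_t,
            steps, spec.n_nucleosomes)
    else:
        core_R = R0[None]
        core_t = t0[None]
        pts = np.zeros((0, spec.L, 3))
    return FiberConformation(spec=spec, template=template, core_R=core_R,
                             core_t=core_t, linker_steps=steps,
                             _linker_pts=pts)


def regular_fiber(spec: FiberSpec, linker_step: StepParams | np.ndarray,
                  template: CoreTemplate | None = None) -> FiberConformation:
    """Regular fiber: every linker step identical (the optimization DOF)."""
    one = linker_step.as_array() if isinstance(linker_step, StepParams) \
        else np.asarray(linker_step, float).reshape(6)
    steps = [np.tile(one, (spec.L + 1, 1)) for _ in range(spec.n_linkers)]
    return assemble_fiber(spec, steps, template=template)
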