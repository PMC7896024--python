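"""Search for optimal regular fibers and sample Monte Carlo ensembles.

Regular two-start fibers are parameterized by one shared linker step
(six degrees of freedom): nucleosome i+1 is then generated from i by a
fixed screw transform.  Local minima of the total energy are found by
derivative-free coordinate descent from many random starts, deduplicated
and labeled T1/T2 by their per-nucleosome linking-number change.

Monte Carlo relaxes the regularity: every step of every linker is an
independent degree of freedom, sampled by Metropolis with single-
parameter moves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .energy import EnergyBreakdown, EnergyParams
from .geometry import (CoreTemplate, FiberConformation, FiberSpec, StepParams,
                       regular_fiber)
from .topology import TopologyResult, delta_lk

#: dLk-per-nucleosome threshold separating the T2 (<= -1.25) from the T1
#: family: the midpoint of the two nominal values -1.5 and -1.0.
FAMILY_THRESHOLD = -1.25

#: validity window of the rigid-base-pair description (degrees / nm):
#: linker steps outside it are not physical DNA and are excluded from the
#: regular-fiber search.
STEP_BOUNDS_LO = np.array([-45.0, -45.0, -10.0, -0.8, -0.8, 0.05])
STEP_BOUNDS_HI = np.array([45.0, 45.0, 80.0, 0.8, 0.8, 0.60])


def classify_family(dlk_per_nucleosome: float) -> str:
    return "T2" if dlk_per_nucleosome <= FAMILY_THRESHOLD else "T1"


@dataclass
class OptimalFiber:
    """A deduplicated local energy minimum of the regular-fiber search."""

    spec: FiberSpec
    linker_step: StepParams
    conformation: FiberConformation
    energy: EnergyBreakdown
    topology: TopologyResult
    family: str

    def rebuild(self, n: int) -> FiberConformation:
        spec = FiberSpec(L=self.spec.L, L_NCP=self.spec.L_NCP,
                         n_nucleosomes=n, circular=self.spec.circular,
                         family_hint=self.spec.family_hint)
        return regular_fiber(spec, self.linker_step,
                             template=self.conformation.template)


def _energy_closure(spec: FiberSpec, params: EnergyParams,
                    template: CoreTemplate):
    eq = params.step_equilibrium.as_array()
    K = params.step_stiffness

    def efun(step6: np.ndarray) -> float:
        e, viol = _kernels.uniform_fiber_energy(
            step6, spec.L, spec.n_nucleosomes, template.entry_to_exit_R,
            template.entry_to_exit_t, template.center_local,
            template.axis_local, template.wrap_proxy_local, eq, K,
            params.stacking_depth, params.stacking_distance,
            params.stacking_width, params.stacking_lateral_width,
            params.core_radius, params.core_half_height, params.dna_radius,
            params.excluded_volume, params.check_linker_linker)
        return float(e)

    return efun


def _coordinate_descent(efun, x0: np.ndarray, h0: np.ndarray,
                        h_min: np.ndarray, max_sweeps: int = 400):
    """Derivative-free local descent: cycle the six coordinates, probe
    +/- h, shrink h where no move helps; stop when every h is below
    h_min.  Small steps keep the search inside the current basin."""
    x = x0.copy()
    e = efun(x)
    h = h0.copy()
    for _ in range(max_sweeps):
        for k in range(6):
            if h[k] < h_min[k]:
                continue
            improved = False
            for sgn in (+1.0, -1.0):
                while True:
                    xt = x.copy()
                    xt[k] += sgn * h[k]
                    et = efun(xt)
                    if et < e - 1e-12:
                        x, e = xt, et
                        improved = True
                    else:
                        break
                if improved:
                    break
            if not improved:
                h[k] *= 0.5
        if np.all(h < h_min):
            break
    return x, e


def _soft_energy_closure(spec: FiberSpec, params: EnergyParams,
                         template: CoreTemplate, w_overlap: float = 500.0):
    """Elastic + stacking + quadratic excluded-volume penalty (smooth)."""
    eq = params.step_equilibrium.as_array()
    K = params.step_stiffness

    def efun(step6: np.ndarray) -> float:
        return float(_kernels.uniform_fiber_soft_energy(
            step6, spec.L, spec.n_nucleosomes, template.entry_to_exit_R,
            template.entry_to_exit_t, template.center_local,
            template.axis_local, template.wrap_proxy_local, eq, K,
            params.stacking_depth, params.stacking_distance,
            params.stacking_width, params.stacking_lateral_width,
            params.core_radius, params.core_half_height, params.dna_radius,
            params.check_linker_linker, w_overlap))

    return efun


def _stacking_residuals(spec: FiberSpec, params: EnergyParams,
                        template: CoreTemplate, mu: float,
                        target_axial: float = 5.8):
    """Least-squares residual vector pulling a regular fiber toward the
    face-stacked two-start geometry: per (i, i+2) pair the axial gap to
    ``target_axial``, the lateral face offset and the axis misalignment;
    per (i, i+1) pair an across-fiber separation floor; plus the elastic
    deviation and the excluded-volume overlap."""
    n = spec.n_nucleosomes
    eq = params.step_equilibrium.as_array()
    kdiag = np.sqrt(np.clip(np.diag(params.step_stiffness), 1e-9, None)
                    * (n - 1) * (spec.L + 1) * 0.5)
    smu = np.sqrt(mu)

    def resid(x):
        core_R, core_t, lp = _kernels.uniform_fiber_geometry(
            x, spec.L, n, template.entry_to_exit_R, template.entry_to_exit_t)
        c, a = _kernels.core_world_centers_axes(
            core_R, core_t, template.center_local, template.axis_local)
        out = list(kdiag * (x - eq))
        for i in range(n - 2):
            dd = c[i + 2] - c[i]
            ax = abs(float(dd @ a[i]))
            lat = np.sqrt(max(float(dd @ dd) - ax * ax, 0.0))
            cos = abs(float(a[i] @ a[i + 2]))
            out += [smu * (ax - target_axial), smu * 0.7 * lat,
                    smu * 5.0 * (1.0 - cos)]
        for i in range(n - 1):
            d01 = float(np.linalg.norm(c[i + 1] - c[i]))
            out.append(smu * 0.8 * max(0.0, 10.0 - d01))
        ov = _kernels.excluded_volume_overlap(
            core_R, core_t, c, a, template.wrap_proxy_local, lp,
            params.core_radius, params.core_half_height, params.dna_radius,
            params.check_linker_linker)
        out.append(np.sqrt(300.0 * ov))
        return np.array(out)

    return resid


def _optimization_starts(spec: FiberSpec, rng: np.random.Generator,
                         starts: int) -> list[np.ndarray]:
    """Deterministic twist/bend grid covering both rotational-setting
    branches, padded with jittered replicas up to ``starts``."""
    base = []
    for tw in (34.3, 34.0, 33.5, 34.6, 35.1):
        base.append((0.0, 0.0, tw))
    for tilt in (-4.0, 4.0):
        for roll in (-4.0, 4.0):
            base.append((tilt, roll, 34.3))
    for tw in (33.0, 35.5):
        base.append((0.0, 0.0, tw))
    out = []
    for i in range(starts):
        tilt, roll, tw = base[i % len(base)]
        jit = np.zeros(3) if i < len(base) else rng.uniform(-1.0, 1.0, 3)
        out.append(np.array([tilt + jit[0], roll + jit[1], tw + jit[2],
                             0.0, 0.0, 0.34]))
    return out


def optimize_regular_fiber(spec: FiberSpec, params: EnergyParams | None = None,
                           starts: int = 50, seed: int = 0,
                           template: CoreTemplate | None = None,
                           dedup_energy: float = 0.5,
                           dedup_dlk: float = 0.05) -> list[OptimalFiber]:
    """Energetically optimal regular two-start fibers for one linker
    length.

    From a grid of twist/bend initializations (jittered for multi-start
    coverage), a staged Levenberg-Marquardt continuation pulls the shared
    linker step toward the face-stacked two-start geometry with
    increasing weight, and a small-step coordinate-descent polish on the
    true energy (with a soft excluded-volume penalty) settles into the
    nearest local minimum.  Feasible minima are deduplicated by energy
    and linking number, labeled T1/T2 and sorted by energy; an empty list
    means no clash-free minimum was found.
    """
    from scipy.optimize import least_squares

    from .energy import total_energy

    if params is None:
        params = EnergyParams()
    if template is None:
        template = CoreTemplate(L_NCP=spec.L_NCP)
    rng = np.random.default_rng(seed)
    soft0 = _soft_energy_closure(spec, params, template)
    hard0 = _energy_closure(spec, params, template)

    def bounded(f):
        def g(x):
            if np.any(x < STEP_BOUNDS_LO) or np.any(x > STEP_BOUNDS_HI):
                return 1e12
            return f(x)
        return g

    soft = bounded(soft0)
    hard = bounded(hard0)
    raw: list[tuple[np.ndarray, float]] = []
    for x0 in _optimization_starts(spec, rng, starts):
        x = x0
        for mu in (2.0, 8.0, 30.0):
            res = least_squares(
                _stacking_residuals(spec, params, template, mu), x,
                x_scale=[1.0, 1.0, 1.0, 0.05, 0.05, 0.02],
                diff_step=1e-4, max_nfev=150)
            x = np.clip(res.x, STEP_BOUNDS_LO, STEP_BOUNDS_HI)
        x, _ = _coordinate_descent(
            soft, x, np.array([0.08, 0.08, 0.08, 0.004, 0.004, 0.0015]),
            np.array([2e-3, 2e-3, 2e-3, 1e-4, 1e-4, 1e-4]), max_sweeps=300)
        e = hard(x)
        if e < 1e10:
            raw.append((x, float(e)))
    raw.sort(key=lambda t: t[1])
    out: list[OptimalFiber] = []
    for x, e in raw:
        if any(np.allclose(x, prev.linker_step.as_array(), atol=0.03)
               for prev in out):
            continue
        step = StepParams.from_array(x)
        fiber = regular_fiber(spec, step, template=template)
        topo = delta_lk(fiber, rebuild=lambda n, s=step: regular_fiber(
            FiberSpec(L=spec.L, L_NCP=spec.L_NCP, n_nucleosomes=n),
            s, template=template))
        dup = False
        for prev in out:
            if (abs(prev.energy.total - e) < dedup_energy
                    and abs(prev.topology.dLk_per_nucleosome
                            - topo.dLk_per_nucleosome) < dedup_dlk):
                dup = True
                break
        if dup:
            continue
        out.append(OptimalFiber(
            spec=spec, linker_step=step, conformation=fiber,
            energy=total_energy(fiber, params), topology=topo,
            family=classify_family(topo.dLk_per_nucleosome)))
    out.sort(key=lambda f: f.energy.total)
    return out


def scan_linkers(L_min: int, L_max: int, spec_template: FiberSpec | None = None,
                 params: EnergyParams | None = None, seed: int = 0,
                 stride: int = 1, starts: int = 50,
                 keep: int = 3) -> pd.DataFrame:
    """Scan linker lengths; one row per retained minimum per L.

    Columns: L, NRL, family, dLk_per_nucleosome, energy, elastic,
    stacking, rank; failures appear as rows with NaN values and a reason.
    """
    if not (10 <= L_min < L_max <= 70):
        raise ValueError("scan range must satisfy 10 <= L_min < L_max <= 70")
    if params is None:
        params = EnergyParams()
    L_NCP = spec_template.L_NCP if spec_template is not None else 147
    n_nuc = spec_template.n_nucleosomes if spec_template is not None else 8
    rows = []
    for L in range(L_min, L_max + 1, stride):
        spec = FiberSpec(L=L, L_NCP=L_NCP, n_nucleosomes=n_nuc)
        minima = optimize_regular_fiber(spec, params, starts=starts,
                                        seed=seed + 1000 * L)
        if not minima:
            rows.append(dict(L=L, NRL=spec.NRL, family=None,
                             dLk_per_nucleosome=np.nan, energy=np.nan,
                             elastic=np.nan, stacking=np.nan, rank=np.nan,
                             reason="no feasible minimum"))
            continue
        for rank, m in enumerate(minima[:keep]):
            rows.append(dict(L=L, NRL=spec.NRL, family=m.family,
                             dLk_per_nucleosome=m.topology.dLk_per_nucleosome,
                             energy=m.energy.total, elastic=m.energy.elastic,
                             stacking=m.energy.stacking, rank=rank,
                             reason=""))
    return pd.DataFrame(rows)


@dataclass
class MCParams:
    temperature: float = 1.0     # kT
    n_steps: int = 200_000
    move_size_angles: float = 3.0  # degrees
    move_size_disp: float = 0.06   # nm
    seed: int = 0
    record_every: int = 500
    burn_in_fraction: float = 0.2

    def __post_init__(self):
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")
        if not (0 <= self.burn_in_fraction < 1):
            raise ValueError("burn-in fraction must be in [0, 1)")


@dataclass
class Ensemble:
    """Recorded MC trajectory of a nucleosome array."""

    spec: FiberSpec
    params: MCParams
    template: CoreTemplate
    snapshot_steps: np.ndarray   # (n_rec, n_linkers, L+1, 6)
    snapshot_core_R: np.ndarray  # (n_rec, n, 3, 3)
    snapshot_core_t: np.ndarray  # (n_rec, n, 3)
    energies: np.ndarray         # (n_rec,)
    acceptance_rate: float
    warnings: list[str] = field(default_factory=list)

    @property
    def n_snapshots(self) -> int:
        return len(self.energies)

    @property
    def burn_in(self) -> int:
        return int(np.ceil(self.params.burn_in_fraction * self.n_snapshots))

    def snapshots(self, include_burn_in: bool = False):
        """FiberConformation objects for the recorded states."""
        lo = 0 if include_burn_in else self.burn_in
        return [self.snapshot(i) for i in range(lo, self.n_snapshots)]

    def snapshot(self, i: int) -> FiberConformation:
        return FiberConformation(
            spec=self.spec, template=self.template,
            core_R=self.snapshot_core_R[i], core_t=self.snapshot_core_t[i],
            linker_steps=self.snapshot_steps[i])

    def centers_axes(self, include_burn_in: bool = False):
        """(n_used, n, 3) core centers and axes, post burn-in."""
        lo = 0 if include_burn_in else self.burn_in
        cs, as_ = [], []
        for i in range(lo, self.n_snapshots):
            c, a = _kernels.core_world_centers_axes(
                self.snapshot_core_R[i], self.snapshot_core_t[i],
                self.template.center_local, self.template.axis_local)
            cs.append(c)
            as_.append(a)
        return np.array(cs), np.array(as_)


def mc_sample(start: FiberConformation, energy: EnergyParams | None = None,
              mc: MCParams | None = None) -> Ensemble:
    """Metropolis MC over the linker step parameters of ``start``.

    Proposals are symmetric single-parameter perturbations, so detailed
    balance holds; the same seed reproduces the trajectory bit for bit.
    """
    if energy is None:
        energy = EnergyParams()
    if mc is None:
        mc = MCParams()
    from .energy import total_energy
    if total_energy(start, energy).excluded_volume_violated:
        raise ValueError("start conformation violates excluded volume")
    tpl = start.template
    rec = _kernels.mc_run(
        start.linker_steps, start.spec.L, start.spec.n_nucleosomes,
        tpl.entry_to_exit_R, tpl.entry_to_exit_t, tpl.center_local,
        tpl.axis_local, tpl.wrap_proxy_local,
        energy.step_equilibrium.as_array(), energy.step_stiffness,
        energy.stacking_depth, energy.stacking_distance,
        energy.stacking_width, energy.stacking_lateral_width,
        energy.core_radius, energy.core_half_height, energy.dna_radius,
        energy.excluded_volume, energy.check_linker_linker, mc.temperature,
        mc.n_steps, mc.move_size_angles, mc.move_size_disp, mc.seed,
        mc.record_every)
    steps, core_R, core_t, energies, acc = rec
    warnings = []
    if not (0.05 < acc < 0.95):
        warnings.append(f"acceptance rate {acc:.3f} outside (0.05, 0.95)")
    return Ensemble(spec=start.spec, params=mc, template=tpl,
                    snapshot_steps=steps, snapshot_core_R=core_R,
                    snapshot_core_t=core_t, energies=energies,
                    acceptance_rate=float(acc), warnings=warnings)
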