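"""Conformational energy of nucleosome fibers (units of kT).

Three terms score a conformation:

* harmonic rigid-base-pair elastic energy of the linker DNA, with a
  stiffness matrix defaulting to persistence-length-matched diagonal
  values (bending 50 nm, torsional 75 nm);
* an attractive face-to-face nucleosome stacking well (Gaussian radial
  profile, modulated by superhelical-axis alignment);
* hard-core excluded volume: nucleosomes as oriented cylinders, linker
  DNA as a tube, violations carry an infinite-energy sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .geometry import (FiberConformation, NucleosomeCore, StepParams,
                       steps_to_array)

#: default diagonal stiffness, kT per deg^2 / nm^2 per step: bending
#: persistence length 50 nm and torsional 75 nm at 0.34 nm rise give
#: k_bend ~ 0.043 kT/deg^2 and k_twist ~ 0.06 kT/deg^2; the translational
#: step parameters are made stiff.
DEFAULT_STIFFNESS_DIAG = (0.043, 0.043, 0.06, 50.0, 50.0, 50.0)


@dataclass
class EnergyParams:
    """Energy-function parameters; all config-overridable."""

    step_equilibrium: StepParams = field(default_factory=StepParams.relaxed)
    step_stiffness: np.ndarray = None  # 6x6, kT/(deg^2 or nm^2)
    stacking_depth: float = 7.5        # kT, stored positive
    stacking_distance: float = 5.7     # nm, axial center-to-center at face stacking
    stacking_width: float = 0.5        # nm, radial width of the axial well
    stacking_lateral_width: float = 2.75  # nm, lateral face-overlap width
    core_radius: float = 5.5           # nm, excluded-volume cylinder
    core_half_height: float = 2.75     # nm
    dna_radius: float = 1.0            # nm
    excluded_volume: bool = True
    check_linker_linker: bool = True

    def __post_init__(self):
        if self.step_stiffness is None:
            self.step_stiffness = np.diag(DEFAULT_STIFFNESS_DIAG).astype(float)
        else:
            self.step_stiffness = np.asarray(self.step_stiffness, float).reshape(6, 6)
        K = self.step_stiffness
        if not np.allclose(K, K.T, atol=1e-12):
            raise ValueError("stiffness matrix must be symmetric")
        if np.linalg.eigvalsh(K).min() <= 0:
            raise ValueError("stiffness matrix must be positive-definite")
        if self.stacking_depth <= 0:
            raise ValueError("stacking depth is stored as a positive magnitude")

    @property
    def stacking_cutoff(self) -> float:
        return self.stacking_distance + 3.0 * self.stacking_width


@dataclass(frozen=True)
class EnergyBreakdown:
    elastic: float
    stacking: float
    excluded_volume_violated: bool

    @property
    def total(self) -> float:
        if self.excluded_volume_violated:
            return float("inf")
        return self.elastic + self.stacking


def step_energy(step: StepParams, params: EnergyParams) -> float:
    """Harmonic energy of a single step: 0.5 * d^T K d (kT)."""
    d = step.as_array() - params.step_equilibrium.as_array()
    return float(0.5 * d @ params.step_stiffness @ d)


def stacking_energy(core_i: NucleosomeCore, core_j: NucleosomeCore,
                    params: EnergyParams) -> float:
    """Pairwise face-to-face stacking well.

    -depth * f(axial face distance) * h(lateral offset) * |cos(axis angle)|:
    the separation vector is decomposed along the mean superhelical axis,
    so only genuinely face-on-face arrangements are rewarded.
    """
    if core_i.index == core_j.index:
        raise ValueError("stacking is defined between distinct cores")
    return float(_kernels.stacking_pair(
        core_i.center, core_i.superhelical_axis, core_j.center,
        core_j.superhelical_axis, params.stacking_depth,
        params.stacking_distance, params.stacking_width,
        params.stacking_lateral_width))


def excluded_volume(fiber: FiberConformation, params: EnergyParams) -> bool:
    """True iff the hard-core constraints are violated."""
    centers, axes = fiber.core_centers_axes()
    return bool(_kernels.excluded_volume_violated(
        fiber.core_R, fiber.core_t, centers, axes,
        fiber.template.wrap_proxy_local, fiber.linker_points(),
        params.core_radius, params.core_half_height, params.dna_radius,
        params.check_linker_linker))


def total_energy(fiber: FiberConformation, params: EnergyParams) -> EnergyBreakdown:
    """Linker elastic + all pairwise stacking + excluded-volume flag."""
    centers, axes = fiber.core_centers_axes()
    eq = params.step_equilibrium.as_array()
    el, st, viol = _kernels.fiber_energy(
        fiber.core_R, fiber.core_t, centers, axes,
        fiber.template.wrap_proxy_local, fiber.linker_steps,
        fiber.linker_points(), eq, params.step_stiffness,
        params.stacking_depth, params.stacking_distance,
        params.stacking_width, params.stacking_lateral_width,
        params.core_radius, params.core_half_height, params.dna_radius,
        params.excluded_volume, params.check_linker_linker)
    return EnergyBreakdown(elastic=float(el), stacking=float(st),
                           excluded_volume_violated=bool(viol))
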