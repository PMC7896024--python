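"""TOML run configuration.

A run config has tables [fiber], [energy], [mc], [observables] and
[output]; every key is optional (defaults fill in), unknown keys are
rejected, and the fully materialized configuration is what the
provenance sidecar records.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .energy import EnergyParams
from .geometry import FiberSpec, StepParams
from .search import MCParams

_FIBER_KEYS = {"L", "L_NCP", "NRL", "n_nucleosomes", "circular", "family_hint"}
_ENERGY_KEYS = {"step_equilibrium", "step_stiffness", "stacking_depth",
                "stacking_distance", "stacking_width",
                "stacking_lateral_width", "core_radius", "core_half_height",
                "dna_radius", "excluded_volume", "check_linker_linker"}
_MC_KEYS = {"temperature", "n_steps", "move_size_angles", "move_size_disp",
            "seed", "record_every", "burn_in_fraction"}
_OBS_KEYS = {"lambda_nm", "fld_range", "contact_cutoff", "s_mono", "R_eff"}
_OUTPUT_KEYS = {"directory", "formats"}


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class ObservableSettings:
    lambda_nm: float = 4.0
    fld_range: tuple[int, int] = (250, 400)
    contact_cutoff: float = 11.0
    s_mono: float = 11.1
    R_eff: float = 5.5


@dataclass
class OutputSettings:
    directory: str = "out"
    formats: tuple[str, ...] = ("tsv",)


@dataclass
class RunConfig:
    fiber: FiberSpec
    energy: EnergyParams
    mc: MCParams
    observables: ObservableSettings = field(default_factory=ObservableSettings)
    output: OutputSettings = field(default_factory=OutputSettings)

    def as_dict(self) -> dict:
        """Fully materialized configuration for the provenance sidecar."""
        return {
            "fiber": {"L": self.fiber.L, "L_NCP": self.fiber.L_NCP,
                      "NRL": self.fiber.NRL,
                      "n_nucleosomes": self.fiber.n_nucleosomes,
                      "circular": self.fiber.circular,
                      "family_hint": self.fiber.family_hint},
            "energy": {
                "step_equilibrium": self.energy.step_equilibrium.as_array().tolist(),
                "step_stiffness": self.energy.step_stiffness.tolist(),
                "stacking_depth": self.energy.stacking_depth,
                "stacking_distance": self.energy.stacking_distance,
                "stacking_width": self.energy.stacking_width,
                "stacking_lateral_width": self.energy.stacking_lateral_width,
                "core_radius": self.energy.core_radius,
                "core_half_height": self.energy.core_half_height,
                "dna_radius": self.energy.dna_radius,
                "excluded_volume": self.energy.excluded_volume,
                "check_linker_linker": self.energy.check_linker_linker},
            "mc": {"temperature": self.mc.temperature,
                   "n_steps": self.mc.n_steps,
                   "move_size_angles": self.mc.move_size_angles,
                   "move_size_disp": self.mc.move_size_disp,
                   "seed": self.mc.seed, "record_every": self.mc.record_every,
                   "burn_in_fraction": self.mc.burn_in_fraction},
            "observables": vars(self.observables),
            "output": {"directory": self.output.directory,
                       "formats": list(self.output.formats)},
        }


def _check_keys(table: dict, allowed: set, name: str) -> None:
    unknown = set(table) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in [{name}]: {sorted(unknown)}")


def load_config(path) -> RunConfig:
    """Parse and validate a TOML run configuration, filling defaults."""
    raw = tomllib.loads(Path(path).read_text())
    _check_keys(raw, {"fiber", "energy", "mc", "observables", "output"},
                "top level")

    fib = dict(raw.get("fiber", {}))
    _check_keys(fib, _FIBER_KEYS, "fiber")
    nrl = fib.pop("NRL", None)
    fib.setdefault("L", 20)
    fib.setdefault("L_NCP", 147)
    fib.setdefault("n_nucleosomes", 8)
    if nrl is not None and nrl != fib["L"] + fib["L_NCP"]:
        raise ConfigError(
            f"NRL = {nrl} inconsistent with L + L_NCP = "
            f"{fib['L'] + fib['L_NCP']}")
    try:
        fiber = FiberSpec(**fib)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    en = dict(raw.get("energy", {}))
    _check_keys(en, _ENERGY_KEYS, "energy")
    if "step_equilibrium" in en:
        en["step_equilibrium"] = StepParams.from_array(en["step_equilibrium"])
    if "step_stiffness" in en:
        en["step_stiffness"] = np.asarray(en["step_stiffness"], float)
    try:
        energy = EnergyParams(**en)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    mc = dict(raw.get("mc", {}))
    _check_keys(mc, _MC_KEYS, "mc")
    try:
        mcp = MCParams(**mc)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    ob = dict(raw.get("observables", {}))
    _check_keys(ob, _OBS_KEYS, "observables")
    if "fld_range" in ob:
        ob["fld_range"] = tuple(int(v) for v in ob["fld_range"])
    obs = ObservableSettings(**ob)

    out = dict(raw.get("output", {}))
    _check_keys(out, _OUTPUT_KEYS, "output")
    if "formats" in out:
        out["formats"] = tuple(out["formats"])
    output = OutputSettings(**out)

    return RunConfig(fiber=fiber, energy=energy, mc=mcp, observables=obs,
                     output=output)
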