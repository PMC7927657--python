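"""YAML/JSON run configuration: fluids, materials, constants, geometry, tank.

Quantities are SI internally; config values may be given either as bare
numbers (already SI) or as strings with an explicit unit, e.g. ``"850 um"``,
``"0.41 mm^2"``, ``"0.9 m"``, converted at this boundary.

Default constants describe the reference study conditions: 'Carnation' mineral
oil as the working fluid, clear printing resin for the models, near-surface
seawater as the natural fluid, and an effective foraminifera-test density that
places sub-millimetre particles in the Re ~ 18-55 settling regime.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import G_STANDARD, FluidSpec, InvalidInputError, MaterialSpec, ParticleGeometry
from .walls import WallGeometry

__all__ = [
    "RunConfig",
    "load_config",
    "parse_quantity",
    "default_seawater",
    "default_mineral_oil",
    "default_resin",
    "default_test_material",
]

_LENGTH_UNITS = {"m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6, "µm": 1e-6}


def default_seawater() -> FluidSpec:
    """Near-surface seawater (~20 degC, salinity 35)."""
    return FluidSpec(density=1025.0, viscosity=1.08e-3, name="seawater")


def default_mineral_oil() -> FluidSpec:
    """'Carnation' white mineral oil."""
    return FluidSpec(density=830.0, viscosity=0.022, name="mineral oil")


def default_resin() -> MaterialSpec:
    """Clear stereolithography printing resin."""
    return MaterialSpec(density=1121.43, name="clear resin")


def default_test_material() -> MaterialSpec:
    """Effective (bulk) density of an empty foraminifera test."""
    return MaterialSpec(density=1400.0, name="foraminifera test")


def parse_quantity(value, dimension: int = 1) -> float:
    """Convert a config quantity to SI.

    ``dimension`` is the length power: 1 for lengths, 2 for areas, 3 for
    volumes.  Bare numbers are taken as SI already; strings must look like
    ``"<number> <unit>"`` with unit one of m/cm/mm/um, optionally with a
    ``^dimension`` suffix (``"0.41 mm^2"``).
    """
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip()
    m = re.fullmatch(r"([-+0-9.eE]+)\s*([a-zµ]+)(?:\^([123]))?", text)
    if not m:
        raise InvalidInputError(f"cannot parse quantity {value!r}")
    number, unit, power = m.group(1), m.group(2), m.group(3)
    if unit not in _LENGTH_UNITS:
        raise InvalidInputError(f"unknown unit {unit!r} in {value!r}")
    p = int(power) if power else dimension
    if p != dimension:
        raise InvalidInputError(
            f"unit power {p} does not match expected dimension {dimension} in {value!r}"
        )
    return float(number) * _LENGTH_UNITS[unit] ** dimension


@dataclass
class RunConfig:
    """Everything needed to run an estimation or a simulation."""

    particle: ParticleGeometry
    natural_fluid: FluidSpec
    working_fluid: FluidSpec
    particle_material: MaterialSpec
    model_material: MaterialSpec
    tank_diameter: float
    g: float = G_STANDARD
    re_bracket: tuple[float, float] = (18.0, 55.0)
    depth_window: tuple[float, float] = (0.19, 0.99)
    extra: dict = field(default_factory=dict)

    def wall_geometry(self, model_length: float) -> WallGeometry:
        return WallGeometry(particle_diameter=model_length, tank_diameter=self.tank_diameter)


def _fluid_from(d: dict, name: str) -> FluidSpec:
    return FluidSpec(density=float(d["density"]), viscosity=float(d["viscosity"]),
                     name=d.get("name", name))


def _material_from(d: dict, name: str) -> MaterialSpec:
    return MaterialSpec(density=float(d["density"]), name=d.get("name", name))


def load_config(path) -> RunConfig:
    """Load a YAML (or JSON) run configuration file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)

    fluids = {k: _fluid_from(v, k) for k, v in data.get("fluids", {}).items()}
    materials = {k: _material_from(v, k) for k, v in data.get("materials", {}).items()}
    fluids.setdefault("seawater", default_seawater())
    fluids.setdefault("oil", default_mineral_oil())
    materials.setdefault("resin", default_resin())
    materials.setdefault("test", default_test_material())

    p = data["particle"]
    particle = ParticleGeometry(
        L=parse_quantity(p["L"], 1),
        A=parse_quantity(p["A"], 2),
        V=parse_quantity(p["V"], 3),
        shape_label=p.get("shape_label", ""),
    )
    constants = data.get("constants", {})
    tank = data.get("tank", {})
    return RunConfig(
        particle=particle,
        natural_fluid=fluids[data.get("natural_fluid", "seawater")],
        working_fluid=fluids[data.get("working_fluid", "oil")],
        particle_material=materials[data.get("particle_material", "test")],
        model_material=materials[data.get("model_material", "resin")],
        tank_diameter=parse_quantity(tank.get("diameter", 0.9), 1),
        g=float(constants.get("g", G_STANDARD)),
        re_bracket=tuple(data.get("re_bracket", (18.0, 55.0))),
        depth_window=tuple(data.get("depth_window", (0.19, 0.99))),
        extra={k: v for k, v in data.items()
               if k not in {"fluids", "materials", "particle", "constants", "tank"}},
    )
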