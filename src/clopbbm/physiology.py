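"""Nine-compartment fasted-state human GI physiology (ACAT-style).

The gastrointestinal tract is discretized into nine serial compartments
(stomach, duodenum, two jejunum, three ileum, cecum, ascending colon), each
carrying the physiological properties the absorption model needs: pH,
mean transit time, cylindrical dimensions, and the fraction of the
geometric volume occupied by free fluid.  Fasted-state defaults follow the
widely published ACAT parameterization, with the fluid-volume fractions
set to 23% in the small intestine and 0.5% in the colon.  All values are
assumptions that can be overridden per compartment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

__all__ = [
    "COMPARTMENT_NAMES",
    "GICompartment",
    "GIPhysiology",
    "default_fasted_physiology",
    "with_overrides",
]

#: Fixed anatomical order; every physiology has exactly these nine.
COMPARTMENT_NAMES = (
    "stomach",
    "duodenum",
    "jejunum1",
    "jejunum2",
    "ileum1",
    "ileum2",
    "ileum3",
    "cecum",
    "asc_colon",
)

SMALL_INTESTINE = COMPARTMENT_NAMES[1:7]
COLON = COMPARTMENT_NAMES[7:9]

#: Documented small-intestinal / colonic fluid fractions (fasted overrides).
SMALL_INTESTINE_FLUID_FRACTION = 0.23
COLON_FLUID_FRACTION = 0.005

#: Total fasted small-intestinal transit time implied by the per-compartment
#: defaults below (h); kept as an explicit consistency constant.
SMALL_INTESTINE_TRANSIT_H = 3.30


class PhysiologyError(ValueError):
    """Invalid physiology configuration (bad override, broken invariant)."""


@dataclass(frozen=True)
class GICompartment:
    """One GI segment with the properties the transit/absorption model uses.

    ``absorption_scale`` multiplies the baseline absorption rate constant
    2*Peff/R; 0 disables absorption (stomach), values < 1 encode reduced
    absorptive surface (colon).
    """

    name: str
    pH: float
    transit_time: float  # h
    length: float  # cm
    radius: float  # cm
    fluid_fraction: float  # 0-1, fraction of geometric volume that is fluid
    absorption_scale: float = 1.0
    #: compartment resting volume (mL); defaults to the cylinder pi*r^2*L.
    #: The published ACAT fasted volumes are smaller than the anatomical
    #: cylinder (the gut lumen is collapsed, not a fluid-filled tube), so
    #: the defaults set this explicitly.
    geometric_volume: Optional[float] = None

    def __post_init__(self) -> None:
        if self.name not in COMPARTMENT_NAMES:
            raise PhysiologyError(f"unknown compartment name {self.name!r}")
        if not (1.0 <= self.pH <= 8.0):
            raise PhysiologyError(f"{self.name}: pH {self.pH} outside [1, 8]")
        if self.transit_time <= 0:
            raise PhysiologyError(f"{self.name}: transit_time must be > 0")
        if self.length <= 0 or self.radius <= 0:
            raise PhysiologyError(f"{self.name}: non-positive dimensions")
        if not (0.0 < self.fluid_fraction <= 1.0):
            raise PhysiologyError(
                f"{self.name}: fluid_fraction {self.fluid_fraction} outside (0, 1]"
            )
        if self.absorption_scale < 0:
            raise PhysiologyError(f"{self.name}: negative absorption_scale")
        if self.geometric_volume is None:
            object.__setattr__(
                self, "geometric_volume",
                math.pi * self.radius**2 * self.length,
            )
        elif self.geometric_volume <= 0:
            raise PhysiologyError(f"{self.name}: non-positive geometric_volume")

    @property
    def fluid_volume(self) -> float:
        """Free luminal fluid volume in mL."""
        return self.geometric_volume * self.fluid_fraction

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "pH": self.pH,
            "transit_time": self.transit_time,
            "length": self.length,
            "radius": self.radius,
            "fluid_fraction": self.fluid_fraction,
            "absorption_scale": self.absorption_scale,
            "geometric_volume": self.geometric_volume,
        }


@dataclass(frozen=True)
class GIPhysiology:
    """Ordered nine-compartment GI physiology."""

    compartments: tuple[GICompartment, ...]
    small_intestine_fluid_fraction: float = SMALL_INTESTINE_FLUID_FRACTION
    colon_fluid_fraction: float = COLON_FLUID_FRACTION

    def __post_init__(self) -> None:
        names = tuple(c.name for c in self.compartments)
        if names != COMPARTMENT_NAMES:
            raise PhysiologyError(
                f"expected the 9 compartments {COMPARTMENT_NAMES} in order, got {names}"
            )

    def __getitem__(self, name: str) -> GICompartment:
        for c in self.compartments:
            if c.name == name:
                return c
        raise KeyError(name)

    def to_records(self) -> list[dict]:
        """Serializable list of compartment records (lossless)."""
        return [c.to_dict() for c in self.compartments]

    @classmethod
    def from_records(cls, records: list[Mapping]) -> "GIPhysiology":
        comps = tuple(GICompartment(**dict(r)) for r in records)
        return cls(compartments=comps)


# Fasted-human ACAT-style defaults.  Transit times, pH and compartment
# volumes follow the widely published fasted values; lengths/radii are
# anatomical (small intestine ~280 cm) and set the absorptive
# surface-to-volume ratio 2/R.  Compartment resting volumes are the
# published ACAT values, smaller than the anatomical cylinders; the fluid
# fractions (23% small intestine, 0.5% colon) apply to them.  The stomach
# volume x fraction gives the ~46 mL resting gastric fluid; coadministered
# water is added at dose time.
_DEFAULTS = (
    # name        pH   Tt(h)  L(cm)  R(cm)  fluid_frac                      abs_scale V(mL)
    ("stomach",   1.3, 0.25,  29.0,  4.00,  1.0,                            0.0,  46.56),
    ("duodenum",  6.0, 0.26,  22.0,  1.60,  SMALL_INTESTINE_FLUID_FRACTION, 1.0,  41.56),
    ("jejunum1",  6.2, 0.95,  81.0,  1.45,  SMALL_INTESTINE_FLUID_FRACTION, 1.0,  154.20),
    ("jejunum2",  6.4, 0.76,  64.0,  1.30,  SMALL_INTESTINE_FLUID_FRACTION, 1.0,  122.20),
    ("ileum1",    6.6, 0.59,  50.0,  1.15,  SMALL_INTESTINE_FLUID_FRACTION, 1.0,  94.30),
    ("ileum2",    6.9, 0.43,  36.0,  1.05,  SMALL_INTESTINE_FLUID_FRACTION, 1.0,  70.50),
    ("ileum3",    7.4, 0.31,  26.0,  1.00,  SMALL_INTESTINE_FLUID_FRACTION, 1.0,  49.80),
    ("cecum",     6.4, 4.55,  13.8,  3.50,  COLON_FLUID_FRACTION,           0.4,  48.00),
    ("asc_colon", 6.8, 13.5,  13.0,  2.50,  COLON_FLUID_FRACTION,           0.4,  50.30),
)


def default_fasted_physiology() -> GIPhysiology:
    """Fasted healthy-adult physiology with the fluid-fraction overrides.

    Pure function: repeated calls return structurally identical objects.
    """
    comps = tuple(
        GICompartment(
            name=n, pH=p, transit_time=t, length=ln, radius=r,
            fluid_fraction=f, absorption_scale=a, geometric_volume=v,
        )
        for n, p, t, ln, r, f, a, v in _DEFAULTS
    )
    return GIPhysiology(compartments=comps)


_OVERRIDABLE = {
    "pH", "transit_time", "length", "radius", "fluid_fraction",
    "absorption_scale", "geometric_volume",
}


def with_overrides(
    base: GIPhysiology, overrides: Mapping[str, Mapping[str, float]]
) -> GIPhysiology:
    """Return a new physiology with the named per-compartment fields changed.

    ``overrides`` maps compartment name -> field -> value.  Unknown
    compartments or fields raise :class:`PhysiologyError`; value validation
    (positivity, ranges) is enforced by :class:`GICompartment`.
    """
    for comp_name, fields in overrides.items():
        if comp_name not in COMPARTMENT_NAMES:
            raise PhysiologyError(f"unknown compartment {comp_name!r}")
        unknown = set(fields) - _OVERRIDABLE
        if unknown:
            raise PhysiologyError(
                f"unknown field(s) {sorted(unknown)} for compartment {comp_name!r}"
            )
    new_comps = []
    for c in base.compartments:
        if c.name in overrides:
            c = replace(c, **dict(overrides[c.name]))
        new_comps.append(c)
    return replace(base, compartments=tuple(new_comps))
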