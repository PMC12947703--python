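"""Trait registry: names, units, and expected response direction under limited water.

Every trait handled by the pipeline carries an expected direction of change
under the limited-water (LW) treatment relative to the ponded-water (PW)
control.  The direction is what makes the composite index *directional*: a
genotype that moves a trait along its expected stress-response direction is
scored as adjusting, one that moves against it is not.

The default registry covers the standard leaf water-use-efficiency trait set:
stomatal conductance (gs) and stomatal density (SD), cuticular/epicuticular
wax (CEW) and flavonol band indices from ATR-FTIR, chlorophyll-fluorescence
parameters (PhiPSII, FvFm, PhiNPQ, NPQt, PhiNO), relative chlorophyll (RCh),
leaf temperature (LT), surface contact angle, and the leaf isotope/elemental
traits delta13C, %N, %C and C:N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping

import yaml

from .errors import ConfigError


class Direction(str, Enum):
    """Expected direction of change under LW relative to PW."""

    INCREASE = "increase"
    DECREASE = "decrease"
    NEUTRAL = "neutral"


class Role(str, Enum):
    PHOTOCHEMICAL = "photochemical"
    STOMATAL = "stomatal"
    SURFACE = "surface"
    ISOTOPE = "isotope"
    OTHER = "other"


@dataclass(frozen=True)
class TraitEntry:
    """Metadata for one trait."""

    units: str
    lw_direction: Direction
    role: Role = Role.OTHER


@dataclass
class TraitRegistry:
    """Mapping of trait name -> :class:`TraitEntry`.

    Lookup is exact (trait tokens are case-sensitive identifiers); unknown
    traits raise ``KeyError`` so that typos fail loudly.
    """

    entries: dict[str, TraitEntry] = field(default_factory=dict)

    def lookup(self, trait: str) -> TraitEntry:
        try:
            return self.entries[trait]
        except KeyError:
            raise KeyError(f"trait {trait!r} is not registered") from None

    def __contains__(self, trait: str) -> bool:
        return trait in self.entries

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    @property
    def traits(self) -> list[str]:
        return list(self.entries)

    def register(
        self,
        trait: str,
        units: str = "a.u.",
        lw_direction: Direction | str = Direction.NEUTRAL,
        role: Role | str = Role.OTHER,
    ) -> None:
        """Register an ad-hoc trait, replacing any existing entry."""
        self.entries[trait] = TraitEntry(
            units=units,
            lw_direction=Direction(lw_direction),
            role=Role(role),
        )

    def direction_sign(self, trait: str) -> int:
        """+1 if the trait is expected to increase under LW, -1 if it is
        expected to decrease, 0 if neutral."""
        d = self.lookup(trait).lw_direction
        if d is Direction.INCREASE:
            return 1
        if d is Direction.DECREASE:
            return -1
        return 0


#: (units, direction, role) for the default trait set.
_DEFAULT_ENTRIES: dict[str, tuple[str, Direction, Role]] = {
    "gs": ("mmol m-2 s-1", Direction.DECREASE, Role.STOMATAL),
    "SD": ("mm-2", Direction.DECREASE, Role.STOMATAL),
    "CEW": ("a.u. cm-1", Direction.INCREASE, Role.SURFACE),
    "flavonol": ("a.u. cm-1", Direction.INCREASE, Role.SURFACE),
    "RCh": ("a.u.", Direction.DECREASE, Role.PHOTOCHEMICAL),
    "LT": ("degC", Direction.INCREASE, Role.OTHER),
    "PhiPSII": ("dimensionless", Direction.DECREASE, Role.PHOTOCHEMICAL),
    "FvFm": ("dimensionless", Direction.DECREASE, Role.PHOTOCHEMICAL),
    "PhiNPQ": ("dimensionless", Direction.INCREASE, Role.PHOTOCHEMICAL),
    "NPQt": ("dimensionless", Direction.INCREASE, Role.PHOTOCHEMICAL),
    "PhiNO": ("dimensionless", Direction.NEUTRAL, Role.PHOTOCHEMICAL),
    "delta13C": ("permil VPDB", Direction.INCREASE, Role.ISOTOPE),
    "pctN": ("percent", Direction.INCREASE, Role.ISOTOPE),
    "pctC": ("percent", Direction.NEUTRAL, Role.ISOTOPE),
    "CN_ratio": ("dimensionless", Direction.DECREASE, Role.ISOTOPE),
    "contact_angle": ("deg", Direction.INCREASE, Role.SURFACE),
}


def default_registry() -> TraitRegistry:
    """Registry with the 16 default traits and their LW response directions.

    Directions encode the treatment contrasts of moderate water limitation:
    quenching traits (PhiNPQ, NPQt), leaf temperature, wax and flavonol
    deposition, contact angle, delta13C (less negative, i.e. higher intrinsic
    WUE) and %N increase under LW; stomatal conductance, stomatal density,
    chlorophyll, PhiPSII, Fv/Fm and the C:N ratio decrease.  %C and PhiNO have
    no established direction and are registered neutral, which excludes them
    from directional index construction unless re-registered.
    """
    return TraitRegistry(
        entries={
            name: TraitEntry(units=u, lw_direction=d, role=r)
            for name, (u, d, r) in _DEFAULT_ENTRIES.items()
        }
    )


def load_registry_overrides(path: str, base: TraitRegistry | None = None) -> TraitRegistry:
    """Apply a YAML override file ``{trait: {units, lw_direction, role}}``
    on top of ``base`` (default registry if omitted)."""
    reg = base if base is not None else default_registry()
    with open(path) as fh:
        raw: Mapping[str, Mapping[str, str]] = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"registry override file {path!r} must map traits to entries")
    for trait, spec in raw.items():
        spec = spec or {}
        current = reg.entries.get(trait)
        try:
            reg.register(
                trait,
                units=spec.get("units", current.units if current else "a.u."),
                lw_direction=spec.get(
                    "lw_direction",
                    current.lw_direction if current else Direction.NEUTRAL,
                ),
                role=spec.get("role", current.role if current else Role.OTHER),
            )
        except ValueError as exc:
            raise ConfigError(f"invalid registry override for {trait!r}: {exc}") from exc
    return reg
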