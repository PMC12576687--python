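"""Composition algebra for crystallization solutions.

A :class:`Solution` is a bag of named :class:`Component`\\ s, each carrying a
concentration in one of a small set of laboratory units.  Mixing two solutions
under the ideal well-mixed assumption is linear interpolation of every
component concentration (the lever rule), and the position of a composition
between two end-member solutions is summarized by a single *exchange
fraction* ``x`` in ``[0, 1]``: the fraction of the pot contents that is target
solution.  A gradient "from 0 to 95% of the target solution" sweeps ``x``
from 0 to 0.95.

No cross-unit conversion is attempted: a component keeps the unit it was
declared in, and two solutions may only share a component name if they agree
on its unit.  Converting e.g. %w/v to molarity would require molecular data
the user has not supplied.

Density contributions are bookkeeping only.  When provided (g/ml per unit of
concentration) they let reports estimate which of two solutions is denser, so
the inflow tube and crystal can be placed to avoid dense inflow sinking
directly onto the crystal; they never enter the mixing math.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "UNITS",
    "Component",
    "Solution",
    "UnitConflictError",
    "DegenerateGradientError",
    "canonical_unit",
    "mix",
    "exchange_fraction_of",
]

#: Canonical concentration units.  ``molar``/``millimolar`` are accepted as
#: aliases for ``M``/``mM`` on input.
UNITS = frozenset({"%w/v", "%v/v", "M", "mM", "mg/ml"})

_UNIT_ALIASES = {
    "molar": "M",
    "millimolar": "mM",
    "m": "M",
    "mm": "mM",
    "mg/mL": "mg/ml",
}


class UnitConflictError(ValueError):
    """Two solutions disagree on the unit of a shared component name."""


class DegenerateGradientError(ValueError):
    """Start and target solutions are identical; the exchange fraction is undefined."""


def canonical_unit(unit: str) -> str:
    """Normalize a unit string, raising ``ValueError`` if it is unknown."""
    if unit in UNITS:
        return unit
    u = _UNIT_ALIASES.get(unit) or _UNIT_ALIASES.get(unit.lower())
    if u is None:
        raise ValueError(
            f"unknown concentration unit {unit!r}; expected one of {sorted(UNITS)}"
        )
    return u


@dataclass(frozen=True)
class Component:
    """One named solute with a concentration in a fixed unit.

    Parameters
    ----------
    name
        Label, e.g. ``"NaCl"`` or ``"glycerol"``.
    concentration
        Nonnegative concentration value.
    unit
        One of :data:`UNITS` (aliases ``molar``/``millimolar`` accepted).
    density_contribution
        Optional g/ml of solution density added per unit of concentration.
        Reported for tube-placement advice; never used in mixing.
    """

    name: str
    concentration: float
    unit: str
    density_contribution: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("component name must be nonempty")
        if not math.isfinite(self.concentration) or self.concentration < 0:
            raise ValueError(
                f"component {self.name!r}: concentration must be finite and >= 0, "
                f"got {self.concentration}"
            )
        object.__setattr__(self, "unit", canonical_unit(self.unit))
        if self.density_contribution is not None and self.density_contribution < 0:
            raise ValueError(f"component {self.name!r}: density_contribution must be >= 0")


@dataclass(frozen=True)
class Solution:
    """An immutable set of components keyed by name.

    A component missing from the set is equivalent to one present at
    concentration zero (in whatever unit the other solution declares).
    Pure water is the empty solution.
    """

    components: tuple[Component, ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        names = [c.name for c in self.components]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate component names: {dup}")
        # normalize ordering so equal compositions compare equal
        object.__setattr__(
            self, "components", tuple(sorted(self.components, key=lambda c: c.name))
        )

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[str, tuple[float, str]], label: str = ""
    ) -> "Solution":
        """Build from ``{name: (concentration, unit)}``."""
        return cls(
            tuple(Component(n, conc, unit) for n, (conc, unit) in mapping.items()),
            label=label,
        )

    @classmethod
    def water(cls, label: str = "water") -> "Solution":
        return cls((), label=label)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components)

    def component(self, name: str) -> Component | None:
        for c in self.components:
            if c.name == name:
                return c
        return None

    def __getitem__(self, name: str) -> float:
        """Concentration of ``name``; 0.0 if absent."""
        c = self.component(name)
        return 0.0 if c is None else c.concentration

    def unit_of(self, name: str) -> str | None:
        c = self.component(name)
        return None if c is None else c.unit

    def density_excess(self) -> float | None:
        """Sum of concentration × density_contribution over components.

        Returns ``None`` when no component declares a density contribution.
        The value approximates how much denser than water the solution is
        (g/ml); only the comparison between two solutions is meaningful.
        """
        terms = [
            c.concentration * c.density_contribution
            for c in self.components
            if c.density_contribution is not None
        ]
        return sum(terms) if terms else None

    def to_json_obj(self) -> list[dict]:
        """Serialize as a list of ``{name, concentration, unit}`` objects."""
        out = []
        for c in self.components:
            d = {"name": c.name, "concentration": c.concentration, "unit": c.unit}
            if c.density_contribution is not None:
                d["density_contribution"] = c.density_contribution
            out.append(d)
        return out

    def same_composition(self, other: "Solution", tol: float = 0.0) -> bool:
        for name in set(self.names) | set(other.names):
            if abs(self[name] - other[name]) > tol:
                return False
        return True


def _merged_units(solutions: Iterable[Solution]) -> dict[str, str]:
    """Unit per component name across solutions; raise on conflicts."""
    units: dict[str, str] = {}
    for sol in solutions:
        for c in sol.components:
            prev = units.setdefault(c.name, c.unit)
            if prev != c.unit:
                raise UnitConflictError(
                    f"component {c.name!r} declared as {prev!r} in one solution "
                    f"and {c.unit!r} in another; no cross-unit conversion is performed"
                )
    return units


def mix(start: Solution, target: Solution, x: float) -> Solution:
    """Lever-rule mixture: ``(1 - x) * start + x * target`` per component.

    ``x`` is the exchange fraction — the fraction of the pot contents that is
    target solution under ideal well-mixed exchange.  Components present in
    only one input count as concentration 0 in the other.

    Raises
    ------
    UnitConflictError
        If a shared component name carries different units.
    ValueError
        If ``x`` is outside ``[0, 1]``.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"exchange fraction must lie in [0, 1], got {x}")
    units = _merged_units((start, target))
    comps = []
    for name, unit in units.items():
        conc = (1.0 - x) * start[name] + x * target[name]
        dc_s = start.component(name)
        dc_t = target.component(name)
        dens = None
        for c in (dc_t, dc_s):  # prefer target's declaration
            if c is not None and c.density_contribution is not None:
                dens = c.density_contribution
        comps.append(Component(name, conc, unit, dens))
    label = f"{start.label or 'start'} + {x:g}*({target.label or 'target'})"
    return Solution(tuple(comps), label=label)


def exchange_fraction_of(current: Solution, start: Solution, target: Solution) -> float:
    """Infer the exchange fraction ``x`` such that ``current ≈ mix(start, target, x)``.

    Least-squares over the union of component names, clamped to ``[0, 1]``;
    exact when ``current`` lies on the mixing line.  This is the reporting
    inverse of :func:`mix`: given a measured or simulated pot composition it
    says how far along the gradient the pot is.

    Raises
    ------
    DegenerateGradientError
        If start and target are identical in every component.
    UnitConflictError
        On unit disagreement for a shared name.
    """
    units = _merged_units((current, start, target))
    num = 0.0
    den = 0.0
    for name in units:
        d = target[name] - start[name]
        num += d * (current[name] - start[name])
        den += d * d
    if den == 0.0:
        raise DegenerateGradientError(
            "start and target solutions are identical; exchange fraction is undefined"
        )
    return min(1.0, max(0.0, num / den))
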