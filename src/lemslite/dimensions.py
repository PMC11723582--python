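"""Physical dimensions, units, and quantity strings.

Dimensional bookkeeping is done over the seven SI base quantities
(mass, length, time, current, temperature, amount, luminous intensity).
A *dimension* is an integer exponent vector over that basis; a *unit* is
a named power-of-ten scaling (plus an additive offset for Celsius) of
the SI coherent unit of its dimension. Validation compares dimensions;
conversion rescales between units of equal dimension.

Quantity attribute values in model documents are strings like ``"5 nA"``
or ``"-1.1e-5"`` (dimensionless); :func:`parse_quantity` implements that
grammar and resolves the SI value exactly (powers of ten are applied
as exact exponent arithmetic, never as accumulated float products).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "Dimension",
    "Unit",
    "Quantity",
    "DimensionError",
    "DIMENSIONS",
    "UNITS",
    "parse_quantity",
    "convert",
    "dim_combine",
    "serialize_quantity",
]


class DimensionError(ValueError):
    """Raised for unknown symbols, grammar violations and dimension mismatches."""


_BASIS = ("mass", "length", "time", "current", "temperature", "amount", "luminosity")


@dataclass(frozen=True)
class Dimension:
    """An exponent vector over the 7 SI base quantities.

    Two dimensions are equal iff all seven exponents are equal; the name
    is a registry label and does not participate in equality.
    """

    name: str
    exponents: tuple[int, int, int, int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.exponents) != 7 or not all(
            isinstance(e, int) for e in self.exponents
        ):
            raise DimensionError(
                f"dimension {self.name!r}: exponents must be 7 integers"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dimension):
            return NotImplemented
        return self.exponents == other.exponents

    def __hash__(self) -> int:
        return hash(self.exponents)

    def __mul__(self, other: "Dimension") -> "Dimension":
        return dim_combine(self, other, "mul")

    def __truediv__(self, other: "Dimension") -> "Dimension":
        return dim_combine(self, other, "div")

    def __pow__(self, n: int) -> "Dimension":
        if not isinstance(n, int):
            raise DimensionError("dimension exponents must be integers")
        return Dimension(
            f"({self.name})^{n}", tuple(e * n for e in self.exponents)
        )

    @property
    def is_dimensionless(self) -> bool:
        return all(e == 0 for e in self.exponents)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Dimension({self.name!r}, {self.exponents})"


def _dim(name: str, m: int = 0, l: int = 0, t: int = 0, i: int = 0,
         k: int = 0, n: int = 0, j: int = 0) -> Dimension:
    return Dimension(name, (m, l, t, i, k, n, j))


# Core dimension registry.  Names follow the NeuroML core-dimension
# vocabulary; vectors are the standard SI assignments.
DIMENSIONS: dict[str, Dimension] = {
    d.name: d
    for d in [
        _dim("none"),
        _dim("area", l=2),
        _dim("capacitance", m=-1, l=-2, t=4, i=2),
        _dim("charge", t=1, i=1),
        _dim("charge_per_mole", t=1, i=1, n=-1),
        _dim("concentration", l=-3, n=1),
        _dim("conductance", m=-1, l=-2, t=3, i=2),
        _dim("conductance_per_voltage", m=-2, l=-4, t=6, i=3),
        _dim("conductanceDensity", m=-1, l=-4, t=3, i=2),
        _dim("current", i=1),
        _dim("currentDensity", l=-2, i=1),
        _dim("idealGasConstantDims", m=1, l=2, t=-2, k=-1, n=-1),
        _dim("length", l=1),
        _dim("per_time", t=-1),
        _dim("per_voltage", m=-1, l=-2, t=3, i=1),
        _dim("permeability", l=1, t=-1),
        _dim("resistance", m=1, l=2, t=-3, i=-2),
        _dim("resistivity", m=1, l=3, t=-3, i=-2),
        _dim("rho_factor", l=-3, t=-1, i=-1, n=1),
        _dim("specificCapacitance", m=-1, l=-4, t=4, i=2),
        _dim("substance", n=1),
        _dim("temperature", k=1),
        _dim("time", t=1),
        _dim("voltage", m=1, l=2, t=-3, i=-1),
        _dim("volume", l=3),
    ]
}

DIMENSIONLESS = DIMENSIONS["none"]


@dataclass(frozen=True)
class Unit:
    """A named power-of-ten scale of a dimension's SI coherent unit.

    ``si = magnitude * 10**power + offset``; offset is nonzero only for
    Celsius.  Compound symbols use the underscore dialect (``S_per_m2``).
    """

    symbol: str
    dimension: str
    power: int
    offset: float = 0.0

    def dim(self) -> Dimension:
        return DIMENSIONS[self.dimension]


UNITS: dict[str, Unit] = {
    u.symbol: u
    for u in [
        # voltage
        Unit("V", "voltage", 0),
        Unit("mV", "voltage", -3),
        # time
        Unit("s", "time", 0),
        Unit("ms", "time", -3),
        Unit("us", "time", -6),
        # current
        Unit("A", "current", 0),
        Unit("mA", "current", -3),
        Unit("uA", "current", -6),
        Unit("nA", "current", -9),
        Unit("pA", "current", -12),
        # capacitance
        Unit("F", "capacitance", 0),
        Unit("uF", "capacitance", -6),
        Unit("nF", "capacitance", -9),
        Unit("pF", "capacitance", -12),
        # conductance
        Unit("S", "conductance", 0),
        Unit("mS", "conductance", -3),
        Unit("uS", "conductance", -6),
        Unit("nS", "conductance", -9),
        Unit("pS", "conductance", -12),
        # conductance density
        Unit("S_per_m2", "conductanceDensity", 0),
        Unit("mS_per_cm2", "conductanceDensity", 1),
        # resistance
        Unit("ohm", "resistance", 0),
        Unit("kohm", "resistance", 3),
        Unit("Mohm", "resistance", 6),
        # length
        Unit("m", "length", 0),
        Unit("cm", "length", -2),
        Unit("mm", "length", -3),
        Unit("um", "length", -6),
        # temperature
        Unit("K", "temperature", 0),
        Unit("degC", "temperature", 0, offset=273.15),
        # amount / concentration
        Unit("mol", "substance", 0),
        Unit("M", "concentration", 3),   # mol/L = 1000 mol/m3
        Unit("mM", "concentration", 0),
        # rates
        Unit("per_s", "per_time", 0),
        Unit("per_ms", "per_time", 3),
        # areas/volumes
        Unit("m2", "area", 0),
        Unit("cm2", "area", -4),
        Unit("um2", "area", -12),
        Unit("m3", "volume", 0),
        Unit("cm3", "volume", -6),
        # charge
        Unit("C", "charge", 0),
    ]
}


@dataclass(frozen=True)
class Quantity:
    """A magnitude in a unit, with its exact SI value and dimension."""

    magnitude: float
    unit: Optional[Unit]
    si_value: float = field(init=False)
    dimension: Dimension = field(init=False)

    def __post_init__(self) -> None:
        if self.unit is None:
            object.__setattr__(self, "si_value", float(self.magnitude))
            object.__setattr__(self, "dimension", DIMENSIONLESS)
        else:
            si = self.magnitude * 10.0 ** self.unit.power + self.unit.offset
            object.__setattr__(self, "si_value", si)
            object.__setattr__(self, "dimension", self.unit.dim())

    def __repr__(self) -> str:
        return f"Quantity({serialize_quantity(self)!r})"


# Optional sign, decimal or scientific numeral, optional whitespace, then
# an optional unit symbol (identifier token).
_QUANTITY_RE = re.compile(
    r"""^\s*
        (?P<num>[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)
        \s*
        (?P<unit>[A-Za-z_][A-Za-z0-9_]*)?
        \s*$""",
    re.VERBOSE,
)


def parse_quantity(text: str, expected_dimension: str | Dimension | None = None) -> Quantity:
    """Parse a quantity string like ``"5 nA"`` or ``"-1.1e-5"``.

    Parameters
    ----------
    text:
        The attribute string: an optional sign, a decimal or scientific
        numeral, optional whitespace and an optional unit symbol.  A bare
        numeral is dimensionless.
    expected_dimension:
        If given (registry name or :class:`Dimension`), the parsed
        quantity's dimension must match it.

    Raises
    ------
    DimensionError
        On a malformed numeral, an unknown unit symbol, or a dimension
        mismatch against ``expected_dimension``.
    """
    if not isinstance(text, str) or not text.strip():
        raise DimensionError("empty quantity string")
    expected: Optional[Dimension] = None
    if expected_dimension is not None:
        if isinstance(expected_dimension, Dimension):
            expected = expected_dimension
        else:
            try:
                expected = DIMENSIONS[expected_dimension]
            except KeyError:
                raise DimensionError(
                    f"unknown dimension {expected_dimension!r}"
                ) from None
    m = _QUANTITY_RE.match(text)
    if m is None:
        raise DimensionError(f"malformed quantity string {text!r}")
    magnitude = float(m.group("num"))
    symbol = m.group("unit")
    if symbol is None:
        q = Quantity(magnitude, None)
    else:
        unit = UNITS.get(symbol)
        if unit is None:
            raise DimensionError(f"unknown unit symbol {symbol!r} in {text!r}")
        q = Quantity(magnitude, unit)
    if expected is not None and q.dimension != expected:
        raise DimensionError(
            f"quantity {text!r} has dimension {q.dimension.name!r}, "
            f"expected {expected.name!r}"
        )
    return q


def convert(q: Quantity, target_unit: str) -> Quantity:
    """Re-express ``q`` in ``target_unit`` (same dimension; si_value unchanged)."""
    unit = UNITS.get(target_unit)
    if unit is None:
        raise DimensionError(f"unknown unit symbol {target_unit!r}")
    if unit.dim() != q.dimension:
        raise DimensionError(
            f"cannot convert {q.dimension.name!r} quantity to unit "
            f"{target_unit!r} ({unit.dimension!r})"
        )
    magnitude = (q.si_value - unit.offset) / 10.0 ** unit.power
    return Quantity(magnitude, unit)


def dim_combine(a: Dimension, b: Dimension, op: str) -> Dimension:
    """Component-wise exponent arithmetic: ``mul`` sums, ``div`` subtracts."""
    if op == "mul":
        exps = tuple(x + y for x, y in zip(a.exponents, b.exponents))
        name = f"{a.name}*{b.name}"
    elif op == "div":
        exps = tuple(x - y for x, y in zip(a.exponents, b.exponents))
        name = f"{a.name}/{b.name}"
    else:
        raise ValueError(f"op must be 'mul' or 'div', got {op!r}")
    for registered in DIMENSIONS.values():
        if registered.exponents == exps:
            return registered
    return Dimension(name, exps)


def serialize_quantity(q: Quantity) -> str:
    """Canonical string form: ``magnitude<space>symbol``; bare numeral if dimensionless."""
    mag = repr(float(q.magnitude))
    if mag.endswith(".0"):
        mag = mag[:-2]
    if q.unit is None:
        return mag
    return f"{mag} {q.unit.symbol}"
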