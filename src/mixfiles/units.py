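"""Standard concentration units, quantity scaling to MInChI shorthand,
molecular-formula parsing, and mass↔molar conversion.

The unit-translation table is shipped as a machine-readable JSON resource
(``mixfiles/data/units.json``) so downstream tools can audit it; this
module loads it once at import. Each of the 15 standard unit common names
maps to a Units Ontology URI, a two-character MInChI shorthand code and a
multiplicative scale factor: e.g. mol/L, mmol/L and μmol/L all translate
to MInChI's ``mr`` (molarity) after scaling by 1, 1e-3 and 1e-6.

Ratio concentrations are a special case: a Mixfile stores
``[numerator, denominator]`` but MInChI records only the numerator under
the ``vp`` code, with the denominator implied by the sibling set.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Union

from .errors import FormulaError, UnknownUnitError
from .model import Quantity

Number = Union[int, float]


@dataclass(frozen=True)
class UnitEntry:
    """One row of the unit-translation table."""

    common: str
    uri: str
    minchiCode: str
    scale: float


def _load_table() -> tuple[list[UnitEntry], str]:
    raw = json.loads(resources.files("mixfiles.data").joinpath("units.json").read_text("utf-8"))
    prefix = raw["uriPrefix"]
    entries = [
        UnitEntry(row["common"], prefix + row["uri"], row["minchiCode"], float(row["scale"]))
        for row in raw["units"]
    ]
    return entries, prefix


UNIT_TABLE, URI_PREFIX = _load_table()
UNIT_NAMES = frozenset(e.common for e in UNIT_TABLE)
_BY_COMMON = {e.common: e for e in UNIT_TABLE}


def lookup_unit(common: str) -> UnitEntry:
    """Exact lookup by unit common name. ASCII ``u`` is accepted for
    ``μ`` on input (``umol/L`` → ``μmol/L``); the Greek letter is
    canonical."""
    entry = _BY_COMMON.get(common)
    if entry is None and "u" in common:
        entry = _BY_COMMON.get(common.replace("u", "μ", 1))
    if entry is None:
        raise UnknownUnitError(f"unknown unit {common!r}")
    return entry


def to_minchi_concentration(q: Quantity) -> tuple[Union[Number, list], str]:
    """Translate a quantity to (scaled value, MInChI code).

    Point values and both ends of a range are multiplied by the unit's
    scale factor. A ratio returns ``(numerator, "vp")`` — the denominator
    is dropped, implied by the sibling set.
    """
    if q.ratio is not None:
        num, den = q.ratio
        if den <= 0:
            raise ValueError(f"ratio denominator must be > 0, got {den}")
        return num, "vp"
    if q.value is None:
        raise ValueError("quantity has neither value nor ratio")
    entry = lookup_unit(q.units) if q.units is not None else None
    if entry is None:
        raise UnknownUnitError("quantity value without units")
    if isinstance(q.value, list):
        low, high = q.value
        return [low * entry.scale, high * entry.scale], entry.minchiCode
    return q.value * entry.scale, entry.minchiCode


# ---------------------------------------------------------------------------
# molecular formulas

# IUPAC 2021 standard atomic weights (conventional values; radioactive
# elements use the mass number of the most stable isotope).
ATOMIC_MASSES = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.95, "K": 39.098, "Ca": 40.078,
    "Sc": 44.956, "Ti": 47.867, "V": 50.942, "Cr": 51.996, "Mn": 54.938,
    "Fe": 55.845, "Co": 58.933, "Ni": 58.693, "Cu": 63.546, "Zn": 65.38,
    "Ga": 69.723, "Ge": 72.630, "As": 74.922, "Se": 78.971, "Br": 79.904,
    "Kr": 83.798, "Rb": 85.468, "Sr": 87.62, "Y": 88.906, "Zr": 91.224,
    "Nb": 92.906, "Mo": 95.95, "Tc": 97.0, "Ru": 101.07, "Rh": 102.91,
    "Pd": 106.42, "Ag": 107.87, "Cd": 112.41, "In": 114.82, "Sn": 118.71,
    "Sb": 121.76, "Te": 127.60, "I": 126.90, "Xe": 131.29, "Cs": 132.91,
    "Ba": 137.33, "La": 138.91, "Ce": 140.12, "Pr": 140.91, "Nd": 144.24,
    "Pm": 145.0, "Sm": 150.36, "Eu": 151.96, "Gd": 157.25, "Tb": 158.93,
    "Dy": 162.50, "Ho": 164.93, "Er": 167.26, "Tm": 168.93, "Yb": 173.05,
    "Lu": 174.97, "Hf": 178.49, "Ta": 180.95, "W": 183.84, "Re": 186.21,
    "Os": 190.23, "Ir": 192.22, "Pt": 195.08, "Au": 196.97, "Hg": 200.59,
    "Tl": 204.38, "Pb": 207.2, "Bi": 208.98, "Po": 209.0, "At": 210.0,
    "Rn": 222.0, "Fr": 223.0, "Ra": 226.0, "Ac": 227.0, "Th": 232.04,
    "Pa": 231.04, "U": 238.03, "Np": 237.0, "Pu": 244.0, "Am": 243.0,
    "Cm": 247.0, "Bk": 247.0, "Cf": 251.0, "Es": 252.0, "Fm": 257.0,
    "Md": 258.0, "No": 259.0, "Lr": 262.0,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse a molecular formula into an element→count map.

    Accepts the multi-part formulas that appear in the first layer of an
    InChI for disconnected structures: dot-separated segments with an
    optional leading multiplier (e.g. ``3C2H5.Al``). Charge and isotope
    labels are not supported. An omitted count means 1.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula")
    counts: dict[str, int] = {}
    for segment in text.strip().split("."):
        mult = 1
        lead = re.match(r"(\d+)", segment)
        if lead:
            mult = int(lead.group(1))
            segment = segment[lead.end():]
        if not segment:
            raise FormulaError(f"formula segment with no elements in {text!r}")
        pos = 0
        while pos < len(segment):
            m = _FORMULA_TOKEN.match(segment, pos)
            if not m:
                raise FormulaError(f"unparseable formula token at {segment[pos:]!r} in {text!r}")
            sym, num = m.group(1), m.group(2)
            if sym not in ATOMIC_MASSES:
                raise FormulaError(f"unknown element {sym!r} in {text!r}")
            counts[sym] = counts.get(sym, 0) + mult * (int(num) if num else 1)
            pos = m.end()
    return counts


_INCHI_PREFIXES = ("InChI=1S/", "InChI=1/")


def strip_inchi_prefix(inchi: str) -> str:
    """Remove the ``InChI=1S/`` prefix, turning an identifier into the
    bare fragment used in MInChI component layers. Fragments pass
    through unchanged."""
    for prefix in _INCHI_PREFIXES:
        if inchi.startswith(prefix):
            return inchi[len(prefix):]
    return inchi


def formula_from_inchi(inchi: str) -> str:
    """Extract the molecular-formula layer: the text before the first
    ``/`` of the prefix-stripped identifier."""
    fragment = strip_inchi_prefix(inchi)
    formula = fragment.split("/", 1)[0]
    if not formula:
        raise FormulaError(f"empty formula layer in {inchi!r}")
    return formula


def molecular_weight(counts: dict[str, int]) -> float:
    """Sum of count × standard atomic mass, in g/mol."""
    if not counts:
        raise FormulaError("empty element counts")
    try:
        return sum(ATOMIC_MASSES[sym] * n for sym, n in counts.items())
    except KeyError as exc:
        raise FormulaError(f"unknown element {exc.args[0]!r}") from exc


_MASS_UNITS = {"g/L": 1.0, "mg/L": 1e-3, "μg/L": 1e-6, "ug/L": 1e-6}


def mass_to_molar(value: Number, units: str, formula: str) -> float:
    """Convert a mass concentration (g/L family) to mol/L using the
    molecular weight computed from ``formula``. This is what lets a
    string-level comparison recognise that 90 g/L of dimethylamine
    (C2H7N, MW 45.08) is approximately 2 mol/L."""
    if units not in _MASS_UNITS:
        raise UnknownUnitError(f"not a mass-per-volume unit: {units!r}")
    mw = molecular_weight(parse_formula(formula))
    return value * _MASS_UNITS[units] / mw


def molar_to_mass(value: Number, formula: str) -> float:
    """Inverse of :func:`mass_to_molar` for the g/L unit."""
    return value * molecular_weight(parse_formula(formula))
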