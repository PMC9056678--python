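"""Element reference data and molecular-formula parsing.

The descriptor pipeline accepts every element from hydrogen (Z = 1) to
rutherfordium (Z = 104).  Formulas are plain composition strings the way
handbooks print them for inorganic compounds: nested parentheses with integer
group multipliers and hydrate units separated by a middle dot (``·``), a
period or an asterisk, each optionally carrying a leading integer multiplier
(``Cu(NO3)2·3H2O``).  Charges, isotope prefixes and square brackets are
rejected — compounds are treated as neutral ground-state species.

Atomic masses are the IUPAC 2021 abridged standard atomic weights; elements
without a stable isotope carry the mass number of their most stable isotope.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping


class FormulaError(ValueError):
    """Malformed molecular formula (syntax, balance, counts)."""


class UnknownElementError(FormulaError):
    """Token does not name a chemical element."""


class UnsupportedElementError(FormulaError):
    """Element is real but beyond the supported range Z = 1..104."""


@dataclass(frozen=True)
class ElementInfo:
    """Reference data for one element."""

    symbol: str
    atomic_number: int
    atomic_mass: float  # g/mol


# symbol, Z, standard atomic weight (g/mol)
_ELEMENT_ROWS = [
    ("H", 1, 1.008), ("He", 2, 4.0026), ("Li", 3, 6.94), ("Be", 4, 9.0122),
    ("B", 5, 10.81), ("C", 6, 12.011), ("N", 7, 14.007), ("O", 8, 15.999),
    ("F", 9, 18.998), ("Ne", 10, 20.180), ("Na", 11, 22.990),
    ("Mg", 12, 24.305), ("Al", 13, 26.982), ("Si", 14, 28.085),
    ("P", 15, 30.974), ("S", 16, 32.06), ("Cl", 17, 35.45), ("Ar", 18, 39.95),
    ("K", 19, 39.098), ("Ca", 20, 40.078), ("Sc", 21, 44.956),
    ("Ti", 22, 47.867), ("V", 23, 50.942), ("Cr", 24, 51.996),
    ("Mn", 25, 54.938), ("Fe", 26, 55.845), ("Co", 27, 58.933),
    ("Ni", 28, 58.693), ("Cu", 29, 63.546), ("Zn", 30, 65.38),
    ("Ga", 31, 69.723), ("Ge", 32, 72.630), ("As", 33, 74.922),
    ("Se", 34, 78.971), ("Br", 35, 79.904), ("Kr", 36, 83.798),
    ("Rb", 37, 85.468), ("Sr", 38, 87.62), ("Y", 39, 88.906),
    ("Zr", 40, 91.224), ("Nb", 41, 92.906), ("Mo", 42, 95.95),
    ("Tc", 43, 97.0), ("Ru", 44, 101.07), ("Rh", 45, 102.906),
    ("Pd", 46, 106.42), ("Ag", 47, 107.868), ("Cd", 48, 112.414),
    ("In", 49, 114.818), ("Sn", 50, 118.710), ("Sb", 51, 121.760),
    ("Te", 52, 127.60), ("I", 53, 126.904), ("Xe", 54, 131.293),
    ("Cs", 55, 132.905), ("Ba", 56, 137.327), ("La", 57, 138.905),
    ("Ce", 58, 140.116), ("Pr", 59, 140.908), ("Nd", 60, 144.242),
    ("Pm", 61, 145.0), ("Sm", 62, 150.36), ("Eu", 63, 151.964),
    ("Gd", 64, 157.25), ("Tb", 65, 158.925), ("Dy", 66, 162.500),
    ("Ho", 67, 164.930), ("Er", 68, 167.259), ("Tm", 69, 168.934),
    ("Yb", 70, 173.045), ("Lu", 71, 174.967), ("Hf", 72, 178.486),
    ("Ta", 73, 180.948), ("W", 74, 183.84), ("Re", 75, 186.207),
    ("Os", 76, 190.23), ("Ir", 77, 192.217), ("Pt", 78, 195.084),
    ("Au", 79, 196.967), ("Hg", 80, 200.592), ("Tl", 81, 204.38),
    ("Pb", 82, 207.2), ("Bi", 83, 208.980), ("Po", 84, 209.0),
    ("At", 85, 210.0), ("Rn", 86, 222.0), ("Fr", 87, 223.0),
    ("Ra", 88, 226.0), ("Ac", 89, 227.0), ("Th", 90, 232.038),
    ("Pa", 91, 231.036), ("U", 92, 238.029), ("Np", 93, 237.0),
    ("Pu", 94, 244.0), ("Am", 95, 243.0), ("Cm", 96, 247.0),
    ("Bk", 97, 247.0), ("Cf", 98, 251.0), ("Es", 99, 252.0),
    ("Fm", 100, 257.0), ("Md", 101, 258.0), ("No", 102, 259.0),
    ("Lr", 103, 262.0), ("Rf", 104, 267.0),
]

MAX_Z = 104

ELEMENTS: Dict[str, ElementInfo] = {
    sym: ElementInfo(sym, z, mass) for sym, z, mass in _ELEMENT_ROWS
}
BY_Z: Dict[int, ElementInfo] = {e.atomic_number: e for e in ELEMENTS.values()}

# Real elements we recognise but do not support (Z > 104): give a specific error.
_BEYOND_RANGE = {
    "Db", "Sg", "Bh", "Hs", "Mt", "Ds", "Rg", "Cn", "Nh", "Fl", "Mc", "Lv",
    "Ts", "Og",
}

_UNIT_SEPARATORS = re.compile(r"[·.*]")


def _element_token(s: str, i: int) -> str:
    """Longest-match-first element token at position ``i`` (s[i] is uppercase).

    A lowercase letter can only ever belong to a two-letter symbol, so
    "Co" != "CO" is resolved unambiguously and "Cx" is an unknown-element
    error rather than carbon followed by garbage.
    """
    if i + 1 < len(s) and s[i + 1].islower():
        token = s[i : i + 2]
    else:
        token = s[i]
    if token in ELEMENTS:
        return token
    if token in _BEYOND_RANGE:
        raise UnsupportedElementError(
            f"element '{token}' has atomic number above {MAX_Z} and is not supported"
        )
    raise UnknownElementError(f"unknown element symbol '{token}' at position {i}")


def _read_int(s: str, i: int) -> tuple[int, int]:
    j = i
    while j < len(s) and s[j].isdigit():
        j += 1
    return int(s[i:j]), j


def _parse_sequence(s: str, i: int, depth: int) -> tuple[Counter, int]:
    counts: Counter = Counter()
    while i < len(s):
        ch = s[i]
        if ch == "(":
            inner, i = _parse_sequence(s, i + 1, depth + 1)
            if i >= len(s) or s[i] != ")":
                raise FormulaError(f"unbalanced parenthesis opened before position {i}")
            i += 1
            mult = 1
            if i < len(s) and s[i].isdigit():
                mult, i = _read_int(s, i)
                if mult < 1:
                    raise FormulaError(f"group multiplier must be >= 1 at position {i}")
            for sym, c in inner.items():
                counts[sym] += c * mult
        elif ch == ")":
            if depth == 0:
                raise FormulaError(f"unbalanced ')' at position {i}")
            return counts, i
        elif ch.isupper():
            token = _element_token(s, i)
            i += len(token)
            n = 1
            if i < len(s) and s[i].isdigit():
                n, i = _read_int(s, i)
                if n < 1:
                    raise FormulaError(f"element count must be >= 1 at position {i}")
            counts[token] += n
        elif ch in "+-^":
            raise FormulaError(
                "charged species are not supported; supply a neutral formula"
            )
        else:
            raise FormulaError(f"unexpected character '{ch}' at position {i}")
    return counts, i


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse a molecular formula into element counts.

    Parameters
    ----------
    formula : str
        E.g. ``"Al2(MoO4)3"`` or ``"Cu(NO3)2·3H2O"``.

    Returns
    -------
    dict mapping element symbol to positive integer stoichiometric count,
    fully expanded (group multipliers distributed, hydrate units merged).
    """
    if not isinstance(formula, str) or not formula.strip():
        raise FormulaError("formula must be a non-empty string")
    s = formula.strip()
    if "[" in s or "]" in s:
        raise FormulaError(
            "square brackets (complex/charge notation) are not supported"
        )
    total: Counter = Counter()
    for unit in _UNIT_SEPARATORS.split(s):
        unit = unit.strip()
        if not unit:
            raise FormulaError(f"empty formula unit in '{formula}'")
        mult = 1
        i = 0
        if unit[0].isdigit():  # leading hydrate multiplier, e.g. "3H2O"
            mult, i = _read_int(unit, 0)
            if mult < 1:
                raise FormulaError(f"unit multiplier must be >= 1 in '{unit}'")
        counts, i = _parse_sequence(unit, i, depth=0)
        if i != len(unit):
            raise FormulaError(f"trailing input at position {i} in '{unit}'")
        if not counts:
            raise FormulaError(f"formula unit '{unit}' contains no elements")
        for sym, c in counts.items():
            total[sym] += c * mult
    return dict(total)


def molecular_weight(counts: Mapping[str, int]) -> float:
    """Molecular weight in g/mol: sum of count × standard atomic weight."""
    mw = 0.0
    for sym, n in counts.items():
        if sym not in ELEMENTS:
            raise UnknownElementError(f"unknown element symbol '{sym}'")
        if n < 1:
            raise FormulaError(f"count for {sym} must be >= 1, got {n}")
        mw += n * ELEMENTS[sym].atomic_mass
    return mw


def render_formula(counts: Mapping[str, int]) -> str:
    """Render counts in Hill-like order (C, H first when carbon is present,
    otherwise plain alphabetical).  ``parse_formula(render_formula(c)) == c``."""

    def hill_key(sym: str) -> tuple:
        if "C" in counts:
            return {"C": (0,), "H": (1,)}.get(sym, (2, sym))
        return (2, sym)

    parts = []
    for sym in sorted(counts, key=hill_key):
        n = counts[sym]
        parts.append(sym if n == 1 else f"{sym}{n}")
    return "".join(parts)


def total_atoms(counts: Mapping[str, int]) -> int:
    return int(sum(counts.values()))


def symbols(counts: Mapping[str, int]) -> Iterable[str]:
    return counts.keys()
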