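"""Electron-configuration bit-vector descriptor for inorganic compounds.

Every neutral atom Z = 1..104 is described by its tabulated ground-state
electron configuration (experimental configurations, i.e. including the
Aufbau exceptions such as Cr 3d⁵ 4s¹).  Each spin-orbital of the subshells
1s; 2s,2p; 3s,3p,3d; 4s,4p,4d,4f; 5s,5p,5d,5f; 6s,6p,6d; 7s,7p is one
descriptor position — 59 orbitals × 2 spins = 118 signed bits.

Within a subshell, electrons fill by Hund's rule: each degenerate component
is singly occupied (spin ``+``, bit +1) before any component takes its
second electron (spin ``-``, bit −1).  Degenerate components fill in a fixed
canonical order (p: x,y,z; d: xy,yz,xz,z2,x2-y2; f: xyz,xz2,yz2,z3,
z(x2-y2),x(x2-3y2),y(3x2-y2)).

A compound vector is the stoichiometry-weighted sum of its element vectors,
so the absolute bits always sum to the compound's total electron count.
Columns constant over a dataset (zero standard deviation) carry no trainable
signal and are pruned before modelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple
import warnings

import numpy as np
import pandas as pd

from .elements import (
    BY_Z,
    ELEMENTS,
    MAX_Z,
    UnsupportedElementError,
    parse_formula,
)

__all__ = [
    "BIT_LABELS",
    "N_BITS",
    "SUBSHELLS",
    "COMPONENTS",
    "GroundStateConfig",
    "ground_state_config",
    "element_bits",
    "compound_vector",
    "featurize_table",
    "prune_constant_bits",
    "FeaturizationError",
]

# (shell n, subshell letter) pairs in canonical vector order:
# ascending shell, then s < p < d < f within a shell.
SUBSHELLS: List[Tuple[int, str]] = [
    (1, "s"),
    (2, "s"), (2, "p"),
    (3, "s"), (3, "p"), (3, "d"),
    (4, "s"), (4, "p"), (4, "d"), (4, "f"),
    (5, "s"), (5, "p"), (5, "d"), (5, "f"),
    (6, "s"), (6, "p"), (6, "d"),
    (7, "s"), (7, "p"),
]

COMPONENTS: Dict[str, List[str]] = {
    "s": [""],
    "p": ["x", "y", "z"],
    "d": ["xy", "yz", "xz", "z2", "x2-y2"],
    "f": ["xyz", "xz2", "yz2", "z3", "z(x2-y2)", "x(x2-3y2)", "y(3x2-y2)"],
}

_CAPACITY = {"s": 2, "p": 6, "d": 10, "f": 14}
_L_NUM = {"s": 0, "p": 1, "d": 2, "f": 3}


def _make_labels() -> List[str]:
    labels = []
    for n, l in SUBSHELLS:
        for comp in COMPONENTS[l]:
            stem = f"{n}{l}" if comp == "" else f"{n}{l}_{comp}"
            labels.append(stem + "+")
            labels.append(stem + "-")
    return labels


#: Canonical descriptor column labels, e.g. "1s+", "2p_x+", "4d_xy-".
BIT_LABELS: List[str] = _make_labels()
N_BITS: int = len(BIT_LABELS)
assert N_BITS == 118

_LABEL_INDEX: Dict[str, int] = {lab: i for i, lab in enumerate(BIT_LABELS)}

# Madelung (n+l, n) order restricted to the supported subshells; used for the
# regular Aufbau fill before exceptions are applied.
_MADELUNG = sorted(SUBSHELLS, key=lambda t: (t[0] + _L_NUM[t[1]], t[0]))

# Experimental ground-state configurations that deviate from the Madelung
# fill (NIST atomic-spectra ground states; predicted configurations for the
# heaviest elements).  Values override the regular occupancy of the listed
# subshells only.
_AUFBAU_EXCEPTIONS: Dict[int, Dict[Tuple[int, str], int]] = {
    24: {(3, "d"): 5, (4, "s"): 1},    # Cr
    29: {(3, "d"): 10, (4, "s"): 1},   # Cu
    41: {(4, "d"): 4, (5, "s"): 1},    # Nb
    42: {(4, "d"): 5, (5, "s"): 1},    # Mo
    44: {(4, "d"): 7, (5, "s"): 1},    # Ru
    45: {(4, "d"): 8, (5, "s"): 1},    # Rh
    46: {(4, "d"): 10, (5, "s"): 0},   # Pd
    47: {(4, "d"): 10, (5, "s"): 1},   # Ag
    57: {(4, "f"): 0, (5, "d"): 1},    # La
    58: {(4, "f"): 1, (5, "d"): 1},    # Ce
    64: {(4, "f"): 7, (5, "d"): 1},    # Gd
    78: {(5, "d"): 9, (6, "s"): 1},    # Pt
    79: {(5, "d"): 10, (6, "s"): 1},   # Au
    89: {(5, "f"): 0, (6, "d"): 1},    # Ac
    90: {(5, "f"): 0, (6, "d"): 2},    # Th
    91: {(5, "f"): 2, (6, "d"): 1},    # Pa
    92: {(5, "f"): 3, (6, "d"): 1},    # U
    93: {(5, "f"): 4, (6, "d"): 1},    # Np
    96: {(5, "f"): 7, (6, "d"): 1},    # Cm
    103: {(6, "d"): 0, (7, "p"): 1},   # Lr (7s2 7p1, not 6d1)
}


class InvalidConfigError(ValueError):
    """Electron configuration violates subshell capacity or electron count."""


class FeaturizationError(ValueError):
    """One or more formulas in a table failed to featurize."""

    def __init__(self, failures: List[Tuple[int, str, str]]):
        self.failures = failures
        lines = "; ".join(f"row {i} '{f}': {msg}" for i, f, msg in failures)
        super().__init__(f"{len(failures)} formula(s) failed to featurize: {lines}")


@dataclass(frozen=True)
class GroundStateConfig:
    """Tabulated ground-state configuration of a neutral atom."""

    atomic_number: int
    subshell_occupations: Tuple[Tuple[int, str, int], ...]  # (n, l, electrons)

    def __post_init__(self):
        total = sum(c for _, _, c in self.subshell_occupations)
        if total != self.atomic_number:
            raise InvalidConfigError(
                f"configuration holds {total} electrons for Z={self.atomic_number}"
            )
        for n, l, c in self.subshell_occupations:
            if not 0 < c <= _CAPACITY[l]:
                raise InvalidConfigError(f"occupation {n}{l}^{c} exceeds capacity")

    def __str__(self) -> str:
        return " ".join(f"{n}{l}{c}" for n, l, c in self.subshell_occupations)


def _resolve_z(element) -> int:
    if isinstance(element, str):
        if element not in ELEMENTS:
            raise UnsupportedElementError(f"unknown element symbol '{element}'")
        return ELEMENTS[element].atomic_number
    z = int(element)
    if not 1 <= z <= MAX_Z:
        raise UnsupportedElementError(f"atomic number {z} outside supported 1..{MAX_Z}")
    return z


def ground_state_config(element) -> GroundStateConfig:
    """Ground-state configuration for an element symbol or atomic number.

    Regular Madelung filling with the experimentally observed exceptions
    applied on top, so e.g. ``ground_state_config("Cr")`` is
    ``[Ar] 3d5 4s1`` and ``ground_state_config("Pd")`` is ``[Kr] 4d10``.
    """
    z = _resolve_z(element)
    occ: Dict[Tuple[int, str], int] = {}
    remaining = z
    for n, l in _MADELUNG:
        if remaining <= 0:
            break
        take = min(remaining, _CAPACITY[l])
        occ[(n, l)] = take
        remaining -= take
    occ.update(_AUFBAU_EXCEPTIONS.get(z, {}))
    ordered = tuple(
        (n, l, occ[(n, l)])
        for n, l in SUBSHELLS
        if occ.get((n, l), 0) > 0
    )
    return GroundStateConfig(z, ordered)


def element_bits(config: GroundStateConfig) -> np.ndarray:
    """Signed 118-bit vector for one atom from its ground-state configuration.

    Hund filling per subshell: with k electrons over g degenerate components,
    the first min(k, g) components (canonical order) take a +1 at their
    spin-+ position; the remaining k − g electrons take a −1 at the spin-−
    position of the same leading components.
    """
    bits = np.zeros(N_BITS, dtype=np.int64)
    for n, l, k in config.subshell_occupations:
        comps = COMPONENTS[l]
        g = len(comps)
        if k > 2 * g:
            raise InvalidConfigError(f"{n}{l}^{k} exceeds capacity {2 * g}")
        for j in range(min(k, g)):
            stem = f"{n}{l}" if comps[j] == "" else f"{n}{l}_{comps[j]}"
            bits[_LABEL_INDEX[stem + "+"]] = 1
        for j in range(max(k - g, 0)):
            stem = f"{n}{l}" if comps[j] == "" else f"{n}{l}_{comps[j]}"
            bits[_LABEL_INDEX[stem + "-"]] = -1
    return bits


def compound_vector(counts: Mapping[str, int]) -> np.ndarray:
    """Descriptor vector of a compound: Σ count_e × element_bits(e).

    The result satisfies Σ|bits| = total electron count of the formula.
    """
    vec = np.zeros(N_BITS, dtype=np.int64)
    for sym, n in counts.items():
        vec += n * element_bits(ground_state_config(sym))
    return vec


def featurize_table(formulas: Sequence[str]) -> pd.DataFrame:
    """Featurize a list of formulas into an (n × 118) integer DataFrame.

    Columns follow :data:`BIT_LABELS`; the row index echoes the input order.
    All failing formulas are collected and reported together in a
    :class:`FeaturizationError` rather than stopping at the first.
    """
    rows = np.zeros((len(formulas), N_BITS), dtype=np.int64)
    failures: List[Tuple[int, str, str]] = []
    for i, formula in enumerate(formulas):
        try:
            rows[i] = compound_vector(parse_formula(formula))
        except ValueError as exc:
            failures.append((i, str(formula), str(exc)))
    if failures:
        raise FeaturizationError(failures)
    return pd.DataFrame(rows, columns=BIT_LABELS)


def prune_constant_bits(
    matrix: pd.DataFrame, keep_columns: Sequence[str] | None = None
) -> Tuple[pd.DataFrame, List[str]]:
    """Drop descriptor columns whose standard deviation over the rows is zero.

    Constant columns cannot train a weight (no atom in the dataset populates
    that spin-orbital, or all rows populate it identically).  Returns the
    reduced matrix and the kept column labels so later inputs can be aligned
    with ``keep_columns``.

    Parameters
    ----------
    matrix : DataFrame with descriptor columns.
    keep_columns : if given, skip the variance computation and simply select
        these columns (alignment of new data to a previously pruned set).
    """
    if len(matrix) == 0:
        raise ValueError("cannot prune an empty descriptor matrix")
    if keep_columns is not None:
        missing = [c for c in keep_columns if c not in matrix.columns]
        if missing:
            raise ValueError(f"columns missing from matrix: {missing}")
        return matrix.loc[:, list(keep_columns)].copy(), list(keep_columns)
    kept = [c for c in matrix.columns if matrix[c].nunique() > 1]
    if not kept:
        warnings.warn("all descriptor columns are constant; result has no columns")
    return matrix.loc[:, kept].copy(), kept
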