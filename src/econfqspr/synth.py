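"""Synthetic formula/property tables with known structure.

Real endpoint compilations (handbook boiling/melting points, curated
solubilities) cannot ship with the package, so tests and examples run on
generated tables whose ground truth is known exactly.  The generator draws
random inorganic-style formulas from an element pool — including
parenthesized groups and hydrate units so the parser is exercised — and
assigns each compound a property that is *linear in its electron-
configuration bits* plus Gaussian noise:

    y_i = β · bits(formula_i) + ε,   ε ~ N(0, noise_sd²)

The coefficient vector couples a dominant size term (the total-atom-count
bit ``1s+`` — physical endpoints such as boiling and melting points depend
strongly on molecular size) with a handful of smaller configuration-
specific bits, and the total atom budget of each formula is drawn uniformly
so the noiseless response covers its range evenly, the way curated endpoint
tables span theirs.  β is sparse and returned alongside the realized values
so recovery can be asserted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .econf import BIT_LABELS, N_BITS, compound_vector
from .elements import parse_formula, render_formula

__all__ = ["SyntheticSpec", "generate_formulas", "generate_endpoint", "generate_table"]

#: A realistic inorganic pool: alkali/alkaline-earth and transition metals
#: with the common anion-forming elements.
DEFAULT_POOL = (
    "H", "O", "N", "S", "Cl", "F",
    "Na", "K", "Ca", "Mg", "Al", "Fe", "Cu", "Zn", "Mo", "Ba",
)

_SIZE_BIT = BIT_LABELS.index("1s+")  # equals the total atom count


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic table.

    Defaults give 300 compounds of 1–3 distinct elements from a 16-element
    inorganic pool, a uniformly drawn total atom budget up to
    ``max_total_atoms``, six secondary active descriptor bits on top of the
    size term, and noise at 5% of the noiseless response range.
    """

    n_compounds: int = 300
    element_pool: Tuple[str, ...] = DEFAULT_POOL
    max_total_atoms: int = 24
    n_active_bits: int = 6
    size_coef: float = 10.0  # coefficient on the total-atom-count bit
    active_coef_sd: float = 2.0  # sd of the secondary bit coefficients
    beta: Optional[np.ndarray] = None  # length-118; overrides the draw if set
    noise_sd: Optional[float] = None  # absolute; overrides noise_frac if set
    noise_frac: float = 0.05  # sd as a fraction of the noiseless y-range
    hydrate_prob: float = 0.12
    group_prob: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not self.element_pool:
            raise ValueError("element_pool must not be empty")
        for sym in self.element_pool:
            parse_formula(sym)  # validates symbol and Z <= 104
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        if self.max_total_atoms < 3:
            raise ValueError("max_total_atoms must be >= 3")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_frac < 0:
            raise ValueError("noise_frac must be >= 0")


def _draw_formula(spec: SyntheticSpec, rng: np.random.Generator) -> str:
    pool = list(spec.element_pool)
    k = int(rng.integers(1, min(3, len(pool)) + 1))
    chosen = rng.choice(len(pool), size=k, replace=False)

    # parser-exercising decorations are decided first so the *final* total
    # atom count stays uniformly distributed (the group multiplier scales
    # the body, hydrate waters add 3 atoms each)
    can_hydrate = "H" in spec.element_pool and "O" in spec.element_pool
    gmult = 2 if rng.random() < spec.group_prob else 1
    hyd = int(rng.integers(1, 4)) if can_hydrate and rng.random() < spec.hydrate_prob else 0

    budget = int(rng.integers(max(k, 2), spec.max_total_atoms + 1)) - 3 * hyd
    budget = max(budget // gmult, k)

    # random composition of the budget into k positive counts
    if k > 1 and budget > k:
        cuts = np.sort(rng.choice(np.arange(1, budget), size=k - 1, replace=False))
        parts = np.diff(np.concatenate([[0], cuts, [budget]]))
    else:
        parts = np.full(k, max(budget // k, 1))
    counts = {pool[i]: int(p) for i, p in zip(chosen, parts)}

    body = render_formula(counts)
    if gmult > 1:
        body = f"({body}){gmult}"
    if hyd:
        body += f"·{hyd}H2O"
    return body


def generate_formulas(spec: SyntheticSpec) -> List[str]:
    """Random formula strings, reproducible by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    return [_draw_formula(spec, rng) for _ in range(spec.n_compounds)]


def _resolve_beta(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.beta is not None:
        beta = np.asarray(spec.beta, dtype=float)
        if beta.shape != (N_BITS,):
            raise ValueError(f"beta must have shape ({N_BITS},)")
        return beta
    # sparse secondary β supported on bits actually populated by the pool
    support = np.zeros(N_BITS, dtype=bool)
    for sym in spec.element_pool:
        support |= compound_vector(parse_formula(sym)) != 0
    support[_SIZE_BIT] = False
    idx = np.flatnonzero(support)
    k = min(spec.n_active_bits, idx.size)
    active = rng.choice(idx, size=k, replace=False)
    beta = np.zeros(N_BITS)
    beta[_SIZE_BIT] = spec.size_coef
    beta[active] = rng.normal(0.0, spec.active_coef_sd, size=k)
    return beta


def generate_endpoint(
    spec: SyntheticSpec, formulas: Sequence[str]
) -> Tuple[np.ndarray, np.ndarray]:
    """Realized property values and the coefficient vector used.

    Returns ``(y, beta)`` with ``y_i = beta · bits(formula_i) + noise``.
    The noise standard deviation is ``spec.noise_sd`` if given, otherwise
    ``spec.noise_frac`` × (range of the noiseless response).
    """
    rng = np.random.default_rng(spec.seed + 1)
    beta = _resolve_beta(spec, rng)
    bits = np.stack([compound_vector(parse_formula(f)) for f in formulas])
    y0 = bits @ beta
    if spec.noise_sd is not None:
        sd = spec.noise_sd
    else:
        spread = float(y0.max() - y0.min())
        sd = spec.noise_frac * (spread if spread > 0 else 1.0)
    y = y0 + rng.normal(0.0, sd, size=y0.shape) if sd > 0 else y0.astype(float)
    return y, beta


def generate_table(spec: SyntheticSpec) -> Tuple[pd.DataFrame, np.ndarray]:
    """``formula,value`` DataFrame plus the generating β."""
    formulas = generate_formulas(spec)
    y, beta = generate_endpoint(spec, formulas)
    return pd.DataFrame({"formula": formulas, "value": y}), beta
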