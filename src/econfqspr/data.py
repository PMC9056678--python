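"""Endpoint tables: reading, inorganic selection, unit conversion, splits.

Endpoint tables are plain CSV/TSV with a ``formula`` column and a ``value``
column (optionally ``temperature`` for solubility records and ``source``).
Supported endpoints: normal boiling point (BP, °C), melting point (MP, °C),
pyrolysis/decomposition point (PP, °C) and aqueous solubility
(logS, log10 mol/L).

The inorganic/organometallic selection keeps a compound if it falls in at
least one of three groups: (1) no carbon, (2) no hydrogen, (3) contains an
element outside {C, H, O, N, F, P, S, Cl, Br, I, Na, Ca, K, Si}.  Si sits in
the exclusion list deliberately: organosilicon compounds behave like
organics and must not qualify through silicon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .elements import parse_formula

ENDPOINTS = ("BP", "MP", "PP", "logS")

#: Elements that never, by themselves, make a compound inorganic.
COMMON_ORGANIC_ELEMENTS = frozenset(
    ["C", "H", "O", "N", "F", "P", "S", "Cl", "Br", "I", "Na", "Ca", "K", "Si"]
)


@dataclass
class SplitDataset:
    """A reproducible train/test partition of an endpoint table."""

    train: pd.DataFrame
    test: pd.DataFrame
    seed: int
    ratio: float

    def __post_init__(self):
        n = len(self.train) + len(self.test)
        if n and abs(len(self.test) - self.ratio * n) > 1:
            raise ValueError("test fraction deviates from ratio by more than one record")


@dataclass
class FilterReport:
    kept: pd.DataFrame
    removed: pd.DataFrame
    unparseable: List[Tuple[int, str, str]] = field(default_factory=list)


def read_endpoint_table(path: str | Path, endpoint: Optional[str] = None) -> pd.DataFrame:
    """Read a ``formula,value[,temperature,source]`` CSV or TSV (by suffix)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    if "formula" not in df.columns or "value" not in df.columns:
        raise ValueError(f"{path} must have 'formula' and 'value' columns")
    if endpoint is not None:
        if endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint '{endpoint}'; expected one of {ENDPOINTS}")
        df = df.copy()
        df["endpoint"] = endpoint
    return df


def is_inorganic(counts) -> bool:
    """Inorganic/organometallic rule on an element-count mapping."""
    no_carbon = "C" not in counts
    no_hydrogen = "H" not in counts
    has_metal = any(sym not in COMMON_ORGANIC_ELEMENTS for sym in counts)
    return no_carbon or no_hydrogen or has_metal


def inorganic_filter(df: pd.DataFrame) -> FilterReport:
    """Apply the three-group inorganic selection to an endpoint table.

    Unparseable formulas are reported in the returned :class:`FilterReport`,
    never silently dropped.
    """
    keep_mask = np.zeros(len(df), dtype=bool)
    unparseable: List[Tuple[int, str, str]] = []
    for pos, (idx, formula) in enumerate(df["formula"].items()):
        try:
            keep_mask[pos] = is_inorganic(parse_formula(formula))
        except ValueError as exc:
            unparseable.append((idx, str(formula), str(exc)))
    return FilterReport(
        kept=df.loc[keep_mask].copy(),
        removed=df.loc[~keep_mask].copy(),
        unparseable=unparseable,
    )


def solubility_to_logS(w: float, mw: float) -> float:
    """Convert a handbook solubility (g per 100 g H2O) to logS.

    Under the dilute approximation 100 g of water occupies ~0.1 L of
    solution, so molarity = w / (mw × 0.1 L) = 10 w / mw and
    logS = log10(10 w / mw).
    """
    if not (w > 0):
        raise ValueError(f"solubility must be positive, got {w}")
    if not (mw > 0):
        raise ValueError(f"molecular weight must be positive, got {mw}")
    return math.log10(10.0 * w / mw)


def select_temperature_window(
    df: pd.DataFrame, low: float = 20.0, high: float = 30.0
) -> pd.DataFrame:
    """Keep solubility records measured within [low, high] °C."""
    if "temperature" not in df.columns:
        raise ValueError("table has no 'temperature' column")
    t = pd.to_numeric(df["temperature"], errors="coerce")
    return df.loc[(t >= low) & (t <= high)].copy()


def dedupe_within_source(df: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse duplicate formulas within one source: first occurrence wins.

    Returns (deduplicated table, dropped duplicate rows) so the drops can be
    logged or audited.
    """
    dup_mask = df.duplicated(subset="formula", keep="first")
    return df.loc[~dup_mask].copy(), df.loc[dup_mask].copy()


def merge_sources(
    primary: pd.DataFrame, secondary: pd.DataFrame
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Union two endpoint tables, preferring the curated primary source.

    On a formula collision the primary value is retained (manual curation
    beats automated compilation).  Duplicates inside each source collapse to
    the first occurrence.  Returns (merged table, conflict report) where the
    conflict report lists formulas whose sources disagreed — including
    conflicting duplicates *within* the primary source.
    """
    prim, prim_dups = dedupe_within_source(primary)
    sec, _ = dedupe_within_source(secondary)

    conflicts = []
    for _, row in prim_dups.iterrows():
        kept_val = prim.loc[prim["formula"] == row["formula"], "value"].iloc[0]
        if not np.isclose(row["value"], kept_val):
            conflicts.append(
                {"formula": row["formula"], "primary_value": kept_val,
                 "other_value": row["value"], "kind": "primary-internal"}
            )

    prim_formulas = set(prim["formula"])
    overlap = sec["formula"].isin(prim_formulas)
    for _, row in sec.loc[overlap].iterrows():
        kept_val = prim.loc[prim["formula"] == row["formula"], "value"].iloc[0]
        if not np.isclose(row["value"], kept_val):
            conflicts.append(
                {"formula": row["formula"], "primary_value": kept_val,
                 "other_value": row["value"], "kind": "cross-source"}
            )

    merged = pd.concat([prim, sec.loc[~overlap]], ignore_index=True)
    conflict_df = pd.DataFrame(
        conflicts, columns=["formula", "primary_value", "other_value", "kind"]
    )
    return merged, conflict_df


def split_dataset(
    df: pd.DataFrame,
    ratio: float,
    seed: int = 0,
    stratify_bins: int = 0,
) -> SplitDataset:
    """Random train/test split, reproducible for a given seed.

    ``ratio`` is the test fraction: 0.1 (9:1) for the small BP/PP tables,
    0.2 (8:2) for the larger MP/logS tables.  ``stratify_bins > 0`` switches
    to stratified sampling over that many quantile bins of ``value``
    (offered because wide, skewed endpoint ranges invite it, though plain
    random sampling behaves the same in practice).
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    n = len(df)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_test = int(round(n * ratio))
    n_test = min(max(n_test, 1), n - 1)
    rng = np.random.default_rng(seed)

    if stratify_bins > 1:
        bins = pd.qcut(df["value"].rank(method="first"), q=stratify_bins, labels=False)
        test_idx: List[int] = []
        for b in range(stratify_bins):
            members = np.flatnonzero(bins.to_numpy() == b)
            k = int(round(len(members) * ratio))
            if k:
                test_idx.extend(rng.choice(members, size=k, replace=False))
        picked = np.asarray(test_idx, dtype=int)
        # per-bin rounding can miss the global test size by a record or two
        if len(picked) > n_test:
            picked = rng.choice(picked, size=n_test, replace=False)
        elif len(picked) < n_test:
            rest = np.setdiff1d(np.arange(n), picked)
            extra = rng.choice(rest, size=n_test - len(picked), replace=False)
            picked = np.concatenate([picked, extra])
        test_pos = np.sort(picked)
    else:
        test_pos = np.sort(rng.permutation(n)[:n_test])

    mask = np.zeros(n, dtype=bool)
    mask[test_pos] = True
    return SplitDataset(
        train=df.loc[~mask].copy(),
        test=df.loc[mask].copy(),
        seed=seed,
        ratio=ratio,
    )


def write_split(split: SplitDataset, out_dir: str | Path) -> Tuple[Path, Path]:
    """Write ``train.csv`` / ``test.csv`` into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    train_path, test_path = out / "train.csv", out / "test.csv"
    split.train.to_csv(train_path, index=False)
    split.test.to_csv(test_path, index=False)
    return train_path, test_path
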