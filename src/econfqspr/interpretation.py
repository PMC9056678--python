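"""Model and dataset interpretation: layer-wise PCA of the first hidden
block, mean-absolute-error binning across the endpoint range, and
periodic-table element-coverage accounting for a train/test split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .data import SplitDataset
from .elements import BY_Z, MAX_Z, parse_formula

__all__ = [
    "LayerTrace",
    "layer_outputs",
    "error_by_range",
    "periodic_coverage",
    "CoverageTable",
]

#: Presentation order of the traced stages (input descriptors, first FC
#: linear combination, activated features, batch-normalized features).
STAGE_ORDER = ("input", "linear", "activation", "batch_norm")


@dataclass
class LayerTrace:
    """Feature matrix of one network stage with its top-2 PCA scores."""

    stage: str
    features: np.ndarray
    pc_scores: np.ndarray
    explained_variance_ratio: np.ndarray


def _pca_scores(features: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Centered (not scaled) 2-component PCA with a deterministic sign:
    the largest-magnitude loading of each component is made positive."""
    n_comp = min(2, features.shape[1], features.shape[0])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(np.asarray(features, dtype=float))
    for j in range(n_comp):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    return scores, pca.explained_variance_ratio_


def layer_outputs(results, X) -> List[LayerTrace]:
    """Per-stage feature maps and PCA scores of the first hidden block.

    ``results`` is a fitted :class:`~econfqspr.models.QSPRResults` (or any
    object exposing ``net.forward_stages``).  Each stage gets its own
    2-component PCA (per-stage fitting).  The ``batch_norm`` stage is
    omitted with a warning when the first block has no bN layer; batch norm
    uses inference-mode (running) statistics.
    """
    net = getattr(results, "net", results)
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    stages = net.forward_stages(np.asarray(X, dtype=float))
    if "batch_norm" not in stages:
        warnings.warn("first hidden block has no batch-norm layer; stage omitted")
    traces = []
    for name in STAGE_ORDER:
        if name not in stages:
            continue
        feats = stages[name]
        scores, evr = _pca_scores(feats)
        traces.append(
            LayerTrace(
                stage=name,
                features=feats,
                pc_scores=scores,
                explained_variance_ratio=evr,
            )
        )
    return traces


def error_by_range(y_exp, y_pred, bin_width: float) -> pd.DataFrame:
    """Mean absolute error within fixed-width intervals of the endpoint.

    Half-open bins step from min(y_exp) in units of ``bin_width``; a value
    landing exactly on the top edge opens one further bin, so every record
    lands in exactly one bin.  Returns a DataFrame with columns ``bin_low``,
    ``bin_high``, ``mean_abs_error``, ``count`` (empty bins are kept with
    count 0 and NaN error).
    """
    y_exp = np.asarray(y_exp, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_exp.size == 0:
        raise ValueError("empty input")
    if y_exp.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if not bin_width > 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    lo, hi = float(y_exp.min()), float(y_exp.max())
    idx = np.floor((y_exp - lo) / bin_width).astype(int)
    n_bins = int(idx.max()) + 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    err = np.abs(y_exp - y_pred)
    rows = []
    for b in range(n_bins):
        in_bin = idx == b
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "mean_abs_error": float(err[in_bin].mean()) if in_bin.any() else np.nan,
                "count": int(in_bin.sum()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CoverageTable:
    """Element presence over a train/test split.

    Codes: 3 = element occurs in both partitions, 2 = training set only,
    1 = test set only, 0 = absent from both.
    """

    codes: pd.DataFrame  # columns: symbol, atomic_number, code
    n_elements: int
    percent_of_supported: float

    def code_of(self, symbol: str) -> int:
        row = self.codes.loc[self.codes["symbol"] == symbol, "code"]
        if row.empty:
            raise KeyError(symbol)
        return int(row.iloc[0])


def _elements_of(frame: pd.DataFrame) -> set:
    present = set()
    for formula in frame["formula"]:
        present.update(parse_formula(formula))
    return present


def periodic_coverage(split: SplitDataset) -> CoverageTable:
    """Element coverage codes for every supported element Z = 1..104."""
    in_train = _elements_of(split.train)
    in_test = _elements_of(split.test)
    rows = []
    for z in range(1, MAX_Z + 1):
        sym = BY_Z[z].symbol
        tr, te = sym in in_train, sym in in_test
        code = 3 if (tr and te) else 2 if tr else 1 if te else 0
        rows.append({"symbol": sym, "atomic_number": z, "code": code})
    codes = pd.DataFrame(rows)
    n_present = int((codes["code"] > 0).sum())
    return CoverageTable(
        codes=codes,
        n_elements=n_present,
        percent_of_supported=100.0 * n_present / MAX_Z,
    )
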