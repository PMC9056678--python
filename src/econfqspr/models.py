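"""QSPR model objects: a Model you build from data, a Results object its
``fit`` returns, cross-validated grid search over hyperparameter bundles,
and the SVM / random-forest baselines.

Typical use::

    from econfqspr import featurize_table, prune_constant_bits
    from econfqspr.models import ModelSpec, NeuralQSPR

    X, kept = prune_constant_bits(featurize_table(df["formula"]))
    spec = ModelSpec(hidden=((105, True),), activation="tanh",
                     optimizer="rmsprop", l2_lambda=0.1, dropout=0.01,
                     epochs=500)
    res = NeuralQSPR(df["value"], X, spec).fit(seed=0)
    print(res.summary())

``NeuralQSPR`` standardizes the target internally (z-score) and maps
predictions back to endpoint units; descriptor inputs are fed raw — the
first batch-norm layer plays the input-normalization role.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .data import SplitDataset
from .econf import featurize_table, prune_constant_bits
from .metrics import MetricReport, compute_report
from .nn import ACTIVATIONS, OPTIMIZERS, NeuralNet

__all__ = [
    "ModelSpec",
    "NeuralQSPR",
    "QSPRResults",
    "CVResult",
    "grid_search_cv",
    "train_baseline",
    "FeaturizedSplit",
    "evaluate_external",
]


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameter bundle for one network.

    ``hidden`` is an ordered tuple of ``(width, batch_norm)`` pairs, e.g.
    ``((97, True), (24, True))`` for two 97- and 24-node hidden layers, each
    followed by batch normalization.
    """

    hidden: Tuple[Tuple[int, bool], ...]
    activation: str = "tanh"
    optimizer: str = "adam"
    l2_lambda: float = 0.0
    dropout: float = 0.0
    epochs: int = 500

    def __post_init__(self):
        object.__setattr__(
            self, "hidden", tuple((int(w), bool(b)) for w, b in self.hidden)
        )
        if not self.hidden or any(w < 1 for w, _ in self.hidden):
            raise ValueError("hidden layer widths must be >= 1")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")
        if self.optimizer.lower() not in OPTIMIZERS:
            raise ValueError(f"optimizer must be one of {OPTIMIZERS}")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be >= 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def to_dict(self) -> dict:
        return {
            "hidden": [[w, b] for w, b in self.hidden],
            "activation": self.activation,
            "optimizer": self.optimizer,
            "l2_lambda": self.l2_lambda,
            "dropout": self.dropout,
            "epochs": self.epochs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            hidden=tuple((int(w), bool(b)) for w, b in d["hidden"]),
            activation=d.get("activation", "tanh"),
            optimizer=d.get("optimizer", "adam"),
            l2_lambda=float(d.get("l2_lambda", 0.0)),
            dropout=float(d.get("dropout", 0.0)),
            epochs=int(d.get("epochs", 500)),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        return cls.from_dict(json.loads(s))

    def label(self) -> str:
        hid = ", ".join(f"{w}{', bN' if b else ''}" for w, b in self.hidden)
        return (
            f"hid: ({hid}), act: {self.activation}, opt: {self.optimizer}, "
            f"lambda: {self.l2_lambda}, dr: {self.dropout}"
        )


class NeuralQSPR:
    """Neural QSPR model over a pruned descriptor matrix.

    Parameters
    ----------
    endog : target vector (endpoint values, endpoint units).
    exog : descriptor matrix, DataFrame (column labels retained for
        alignment) or plain 2-d array.
    spec : the :class:`ModelSpec` to fit.
    standardize_y : z-score the target during optimization (predictions are
        always returned in endpoint units).
    """

    def __init__(self, endog, exog, spec: ModelSpec, standardize_y: bool = True):
        if isinstance(exog, pd.DataFrame):
            self.feature_names: Optional[List[str]] = list(exog.columns)
            X = exog.to_numpy(dtype=float)
        else:
            self.feature_names = None
            X = np.asarray(exog, dtype=float)
        y = np.asarray(endog, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("exog must be 2-d with one row per endog value")
        if not np.isfinite(y).all():
            raise ValueError("endog contains non-finite values")
        self.exog = X
        self.endog = y
        self.spec = spec
        self.standardize_y = standardize_y

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        spec: ModelSpec,
        value_col: str = "value",
        formula_col: str = "formula",
        keep_columns: Optional[Sequence[str]] = None,
        **kwargs,
    ) -> "NeuralQSPR":
        """Build a model straight from a ``formula,value`` table.

        Featurizes the formulas and prunes zero-variance bits (or aligns to
        ``keep_columns`` from a previous fit).
        """
        bits = featurize_table(list(df[formula_col]))
        X, _ = prune_constant_bits(bits, keep_columns=keep_columns)
        return cls(df[value_col].to_numpy(), X, spec, **kwargs)

    def fit(
        self, seed: int = 0, lr: float = 1e-3, batch_size: int = 32
    ) -> "QSPRResults":
        """Train the network for ``spec.epochs`` passes; reproducible by seed."""
        y = self.endog
        if self.standardize_y:
            y_mean, y_std = float(y.mean()), float(y.std())
            y_std = y_std if y_std > 0 else 1.0
        else:
            y_mean, y_std = 0.0, 1.0
        net = NeuralNet(
            n_features=self.exog.shape[1],
            hidden=self.spec.hidden,
            activation=self.spec.activation,
            dropout=self.spec.dropout,
            seed=seed,
        )
        history = net.fit(
            self.exog,
            (y - y_mean) / y_std,
            epochs=self.spec.epochs,
            optimizer=self.spec.optimizer.lower(),
            lr=lr,
            batch_size=batch_size,
            l2_lambda=self.spec.l2_lambda,
            seed=seed,
        )
        return QSPRResults(self, net, y_mean, y_std, history, seed=seed, lr=lr,
                           batch_size=batch_size)


class QSPRResults:
    """Fitted model: predictions, training metrics and a summary table."""

    def __init__(self, model, net, y_mean, y_std, loss_history, seed, lr, batch_size):
        self.model = model
        self.net = net
        self.y_mean = y_mean
        self.y_std = y_std
        self.loss_history = loss_history
        self.seed = seed
        self.lr = lr
        self.batch_size = batch_size

    def _align(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if self.model.feature_names is not None:
                missing = [c for c in self.model.feature_names if c not in X.columns]
                if missing:
                    raise ValueError(f"input lacks fitted columns: {missing}")
                X = X.loc[:, self.model.feature_names]
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.model.exog.shape[1]:
            raise ValueError(
                f"input has {X.shape[1]} columns, model was fitted with "
                f"{self.model.exog.shape[1]}"
            )
        return X

    def predict(self, X=None) -> np.ndarray:
        """Predict endpoint values (deterministic; dropout off, running bN)."""
        X = self.model.exog if X is None else self._align(X)
        return self.net.predict(X) * self.y_std + self.y_mean

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict()

    def train_report(self) -> MetricReport:
        return compute_report(self.model.endog, self.predict())

    def summary(self) -> str:
        rep = self.train_report()
        spec = self.model.spec
        lines = [
            "Neural QSPR regression results",
            "=" * 62,
            f"Observations: {len(self.model.endog):>6}   "
            f"Features: {self.model.exog.shape[1]}",
            f"Spec: {spec.label()}",
            f"Epochs: {spec.epochs}   lr: {self.lr}   batch: {self.batch_size}   "
            f"seed: {self.seed}",
            f"Final training loss (standardized): {self.loss_history[-1]:.5f}",
            "-" * 62,
            f"Train  R2: {rep.r_squared:8.4f}   SpeaR: {rep.spearman:8.4f}",
            f"Train MAE: {rep.mae:8.4f}   MAE/range: {rep.mae_over_range:6.2f}%",
            "=" * 62,
        ]
        return "\n".join(lines)


@dataclass
class CVResult:
    """Cross-validation outcome for one hyperparameter bundle."""

    spec: ModelSpec
    fold_reports: List[MetricReport]
    r2_mean: float = field(init=False)
    r2_sd: float = field(init=False)
    spearman_mean: float = field(init=False)
    spearman_sd: float = field(init=False)
    mae_mean: float = field(init=False)
    mae_sd: float = field(init=False)
    mae_over_range: float = field(init=False)  # percent of full-data range

    def __post_init__(self):
        r2 = np.array([r.r_squared for r in self.fold_reports])
        sp = np.array([r.spearman for r in self.fold_reports])
        ma = np.array([r.mae for r in self.fold_reports])
        self.r2_mean, self.r2_sd = float(r2.mean()), float(r2.std())
        self.spearman_mean, self.spearman_sd = float(sp.mean()), float(sp.std())
        self.mae_mean, self.mae_sd = float(ma.mean()), float(ma.std())
        lo = min(r.endpoint_range[0] for r in self.fold_reports)
        hi = max(r.endpoint_range[1] for r in self.fold_reports)
        self.mae_over_range = 100.0 * self.mae_mean / (hi - lo)

    def __str__(self) -> str:
        return (
            f"{self.spec.label()}  |  R2 {self.r2_mean:.2f}±{self.r2_sd:.2f}  "
            f"SpeaR {self.spearman_mean:.2f}±{self.spearman_sd:.2f}  "
            f"MAE {self.mae_mean:.2f}±{self.mae_sd:.2f}  "
            f"MAE/range {self.mae_over_range:.2f}%"
        )


def grid_search_cv(
    space: Sequence[ModelSpec],
    X,
    y,
    folds: int = 5,
    seed: int = 0,
    cv_epochs: int = 500,
    lr: float = 1e-3,
    batch_size: int = 32,
) -> List[CVResult]:
    """n-fold cross-validated grid search over hyperparameter bundles.

    Every spec is scored on the *same* fold partition (shuffled once with
    ``seed``), each fitted for ``cv_epochs`` passes (epoch count is held
    fixed during the search and tuned separately afterwards).  Results are
    ranked by mean validation MAE, ties broken by mean SpeaR then mean R².
    """
    if not space:
        raise ValueError("hyperparameter space is empty")
    if folds < 2:
        raise ValueError("need at least 2 folds")
    X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    y = np.asarray(y, dtype=float).ravel()
    if folds > len(y):
        raise ValueError(f"{folds} folds exceed {len(y)} records")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    partitions = list(kf.split(X))

    results: List[CVResult] = []
    for spec in space:
        cv_spec = ModelSpec(**{**spec.to_dict(), "hidden": spec.hidden,
                               "epochs": cv_epochs})
        reports = []
        for k, (tr, va) in enumerate(partitions):
            res = NeuralQSPR(y[tr], X[tr], cv_spec).fit(
                seed=seed + k, lr=lr, batch_size=batch_size
            )
            reports.append(compute_report(y[va], res.predict(X[va])))
        results.append(CVResult(spec=spec, fold_reports=reports))

    results.sort(
        key=lambda r: (r.mae_mean, -r.spearman_mean, -r.r2_mean)
    )
    return results


def train_baseline(kind: str, params: dict, X, y, seed: int = 0):
    """Off-the-shelf baseline regressors with the same predict contract.

    ``kind="SVM"`` → epsilon-SVR (params: ``gamma`` in {"auto","scale"},
    ``C``, ``epsilon``); ``kind="RFR"`` → random forest (params: ``tree`` =
    number of trees).
    """
    X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    y = np.asarray(y, dtype=float).ravel()
    kind = kind.upper()
    if kind == "SVM":
        model = SVR(
            gamma=params.get("gamma", "auto"),
            C=float(params.get("C", 1.0)),
            epsilon=float(params.get("epsilon", 0.1)),
        )
    elif kind == "RFR":
        model = RandomForestRegressor(
            n_estimators=int(params.get("tree", 100)), random_state=seed
        )
    else:
        raise ValueError(f"unsupported baseline kind '{kind}' (use 'SVM' or 'RFR')")
    model.fit(X, y)
    return model


@dataclass
class FeaturizedSplit:
    """A train/test partition already featurized and column-aligned."""

    X_train: pd.DataFrame
    y_train: np.ndarray
    X_test: pd.DataFrame
    y_test: np.ndarray
    kept_columns: List[str]
    formulas_train: List[str] = field(default_factory=list)
    formulas_test: List[str] = field(default_factory=list)

    @classmethod
    def from_split(
        cls, split: SplitDataset, prune_on: str = "all"
    ) -> "FeaturizedSplit":
        """Featurize a :class:`SplitDataset`.

        ``prune_on="all"`` prunes zero-variance bits over train+test jointly
        (the historical protocol here); ``"train"`` fits the kept-column set
        on the training rows only and aligns the test rows to it
        (leakage-safe variant).
        """
        f_tr = list(split.train["formula"])
        f_te = list(split.test["formula"])
        bits_tr = featurize_table(f_tr)
        bits_te = featurize_table(f_te)
        if prune_on == "all":
            both = pd.concat([bits_tr, bits_te], ignore_index=True)
            _, kept = prune_constant_bits(both)
        elif prune_on == "train":
            _, kept = prune_constant_bits(bits_tr)
        else:
            raise ValueError("prune_on must be 'all' or 'train'")
        return cls(
            X_train=bits_tr.loc[:, kept].copy(),
            y_train=split.train["value"].to_numpy(dtype=float),
            X_test=bits_te.loc[:, kept].copy(),
            y_test=split.test["value"].to_numpy(dtype=float),
            kept_columns=list(kept),
            formulas_train=f_tr,
            formulas_test=f_te,
        )


def evaluate_external(results, split: FeaturizedSplit) -> Dict[str, object]:
    """Score a fitted model on its training partition and the external test set.

    ``results`` is a :class:`QSPRResults` (or any object with ``predict``
    taking a matrix) trained on ``split.X_train``/``y_train``.  Each
    partition is judged against its own endpoint range, and MAE is also
    reported as a percent of that range.
    """
    if len(split.y_test) == 0:
        raise ValueError("external test set is empty")
    pred_tr = np.asarray(results.predict(split.X_train)).ravel()
    pred_te = np.asarray(results.predict(split.X_test)).ravel()
    train_rep = compute_report(split.y_train, pred_tr)
    test_rep = compute_report(split.y_test, pred_te)
    return {
        "train": train_rep,
        "test": test_rep,
        "train_range": train_rep.endpoint_range,
        "test_range": test_rep.endpoint_range,
        "train_mae_over_range": train_rep.mae_over_range,
        "test_mae_over_range": test_rep.mae_over_range,
    }
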