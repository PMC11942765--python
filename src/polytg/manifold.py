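"""Tg prediction by Isomap embedding plus multiple linear regression.

The descriptor space is strongly inter-correlated and relates to Tg through
non-linear relationships, so ordinary regression on raw descriptors fits
poorly.  Instead, the z-scored training descriptors are embedded on a
non-linear manifold with Isomap (k-nearest-neighbour graph -> geodesic
shortest-path distances -> classical MDS) and Tg is regressed on the
embedding coordinates with plain least squares — the simplest model that
performs well, which keeps it robust.

Test rows are withheld before any fitting: standardisation statistics, the
neighbour graph and the regression all see training rows only.  New rows
are embedded with the standard kernel (Nystrom-type) out-of-sample
extension and flagged as extrapolations when they fall outside the training
neighbourhood.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from sklearn.manifold import Isomap
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold
from sklearn.neighbors import kneighbors_graph

from .correlations import FeatureTable
from .errors import ConfigError, DataError, FitError, SchemaError

N_COMPONENTS_CV_GRID = tuple(range(2, 9))


@dataclass
class Split:
    train_ids: list[str]
    test_ids: list[str]
    test_fraction: float
    seed: int


@dataclass
class ModelMetrics:
    r2_train: float
    rmse_train: float
    r2_test: float | None = None
    rmse_test: float | None = None

    def to_dict(self) -> dict:
        return {
            "r2_train": self.r2_train,
            "rmse_train": self.rmse_train,
            "r2_test": self.r2_test,
            "rmse_test": self.rmse_test,
        }


@dataclass
class PredictionResult:
    id: str
    predicted_tg: float
    embedding: np.ndarray
    extrapolation_flag: bool


@dataclass
class ManifoldTgModel:
    feature_names: list[str]
    mean_: np.ndarray
    scale_: np.ndarray
    n_neighbors: int
    n_components: int
    coef_: np.ndarray
    intercept_: float
    split: Split | None
    train_ids: list[str]
    train_X_std: np.ndarray = field(repr=False)
    train_embedding: np.ndarray = field(repr=False)
    train_tg: np.ndarray = field(repr=False)
    nn_threshold: float
    metrics: ModelMetrics | None = None
    _isomap: Isomap | None = field(default=None, repr=False)

    # -- persistence -----------------------------------------------------
    def to_json(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "n_neighbors": self.n_neighbors,
            "n_components": self.n_components,
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_,
            "split": None
            if self.split is None
            else {
                "train_ids": self.split.train_ids,
                "test_ids": self.split.test_ids,
                "test_fraction": self.split.test_fraction,
                "seed": self.split.seed,
            },
            "train_ids": self.train_ids,
            "train_X_std": self.train_X_std.tolist(),
            "train_embedding": self.train_embedding.tolist(),
            "train_tg": self.train_tg.tolist(),
            "nn_threshold": self.nn_threshold,
            "metrics": None if self.metrics is None else self.metrics.to_dict(),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1))

    @classmethod
    def from_json(cls, doc: dict) -> "ManifoldTgModel":
        split = None
        if doc.get("split") is not None:
            s = doc["split"]
            split = Split(
                s["train_ids"], s["test_ids"], s["test_fraction"], s["seed"]
            )
        metrics = None
        if doc.get("metrics") is not None:
            metrics = ModelMetrics(**doc["metrics"])
        model = cls(
            feature_names=doc["feature_names"],
            mean_=np.asarray(doc["mean"], dtype=float),
            scale_=np.asarray(doc["scale"], dtype=float),
            n_neighbors=doc["n_neighbors"],
            n_components=doc["n_components"],
            coef_=np.asarray(doc["coef"], dtype=float),
            intercept_=float(doc["intercept"]),
            split=split,
            train_ids=doc["train_ids"],
            train_X_std=np.asarray(doc["train_X_std"], dtype=float),
            train_embedding=np.asarray(doc["train_embedding"], dtype=float),
            train_tg=np.asarray(doc["train_tg"], dtype=float),
            nn_threshold=float(doc["nn_threshold"]),
            metrics=metrics,
        )
        return model

    @classmethod
    def load(cls, path: str | Path) -> "ManifoldTgModel":
        return cls.from_json(json.loads(Path(path).read_text()))

    # -- embedding -------------------------------------------------------
    @property
    def isomap(self) -> Isomap:
        """The fitted Isomap; refitted deterministically from the stored
        training matrix after deserialisation."""
        if self._isomap is None:
            iso = _make_isomap(self.n_neighbors, self.n_components)
            iso.fit(self.train_X_std)
            self._isomap = iso
        return self._isomap

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.scale_


def _make_isomap(n_neighbors: int, n_components: int) -> Isomap:
    # dense eigensolver => bit-deterministic fits
    return Isomap(
        n_neighbors=n_neighbors,
        n_components=n_components,
        eigen_solver="dense",
    )


def split_data(
    table: FeatureTable, test_fraction: float = 0.20, seed: int = 0
) -> Split:
    """Seeded uniform train/test split; test rows see no fitting at all."""
    if not 0.0 < test_fraction < 1.0:
        raise ConfigError(
            f"test_fraction must be in (0, 1), got {test_fraction}"
        )
    if table.n < 10:
        raise DataError(f"need at least 10 rows to split, got {table.n}")
    rng = np.random.default_rng(seed)
    n_test = int(round(table.n * test_fraction))
    n_test = max(1, min(table.n - 2, n_test))
    test_idx = set(rng.choice(table.n, size=n_test, replace=False).tolist())
    train_ids = [pid for i, pid in enumerate(table.ids) if i not in test_idx]
    test_ids = [pid for i, pid in enumerate(table.ids) if i in test_idx]
    return Split(train_ids, test_ids, test_fraction, seed)


def _subset(table: FeatureTable, ids: list[str]) -> FeatureTable:
    pos = {pid: i for i, pid in enumerate(table.ids)}
    idx = [pos[pid] for pid in ids]
    return FeatureTable(
        ids=ids,
        X=table.X.iloc[idx].reset_index(drop=True),
        tg=None if table.tg is None else table.tg.iloc[idx].reset_index(drop=True),
    )


def _check_connected(X: np.ndarray, n_neighbors: int, ids: list[str]) -> None:
    graph = kneighbors_graph(X, n_neighbors=n_neighbors, mode="connectivity")
    n_comp, labels = connected_components(graph, directed=False)
    if n_comp > 1:
        counts = np.bincount(labels)
        minority = np.argmin(counts)
        isolated = [ids[i] for i in np.flatnonzero(labels == minority)]
        raise FitError(
            f"neighbour graph has {n_comp} connected components; isolated "
            f"records include {isolated[:10]}"
        )


def _cv_select_components(
    X: np.ndarray,
    y: np.ndarray,
    n_neighbors: int,
    seed: int,
    grid: tuple[int, ...] = N_COMPONENTS_CV_GRID,
) -> int:
    """5-fold CV over the embedding dimension, highest mean R^2 wins
    (ties -> smallest dimension)."""
    n = X.shape[0]
    grid = tuple(d for d in grid if d < n)
    kf = KFold(n_splits=5, shuffle=True, random_state=seed)
    best_d, best_score = grid[0], -np.inf
    for d in grid:
        scores = []
        for tr, va in kf.split(X):
            if n_neighbors >= len(tr) or d >= len(tr):
                continue
            iso = _make_isomap(n_neighbors, d)
            try:
                emb = iso.fit_transform(X[tr])
            except Exception:
                continue
            beta, icept = _ols(emb, y[tr])
            pred = iso.transform(X[va]) @ beta + icept
            scores.append(r2_score(y[va], pred))
        if scores and np.mean(scores) > best_score + 1e-12:
            best_score, best_d = float(np.mean(scores)), d
    return best_d


def _ols(E: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    A = np.column_stack([E, np.ones(len(E))])
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    return sol[:-1], float(sol[-1])


def fit(
    table: FeatureTable,
    split: Split | None = None,
    n_neighbors: int = 5,
    n_components: int | None = None,
    seed: int = 0,
) -> ManifoldTgModel:
    """Fit the Isomap + linear-regression Tg model on the training rows.

    ``n_components=None`` selects the embedding dimension by 5-fold
    cross-validation on the training split.  Standardisation, the neighbour
    graph and the regression use training rows only, so withheld test rows
    influence nothing.
    """
    if table.tg is None:
        raise DataError("fit requires a Tg column")
    train = _subset(table, split.train_ids) if split is not None else table
    n_train = train.n
    if n_neighbors >= n_train:
        raise ConfigError(
            f"n_neighbors={n_neighbors} must be < n train rows ({n_train})"
        )

    X = train.X.to_numpy(dtype=float)
    y = np.asarray(train.tg, dtype=float)
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale

    _check_connected(Xs, n_neighbors, train.ids)

    if n_components is None:
        n_components = _cv_select_components(Xs, y, n_neighbors, seed)
    if n_components >= n_train:
        raise ConfigError(
            f"n_components={n_components} must be < n train rows ({n_train})"
        )

    iso = _make_isomap(n_neighbors, n_components)
    emb = iso.fit_transform(Xs)

    if np.std(y) == 0:
        warnings.warn("Tg is constant on the training set; R^2 reported as 0")
        coef = np.zeros(n_components)
        intercept = float(y[0]) if len(y) else 0.0
        r2_train = 0.0
    else:
        coef, intercept = _ols(emb, y)
        r2_train = float(r2_score(y, emb @ coef + intercept))
    resid = y - (emb @ coef + intercept)
    rmse_train = float(np.sqrt(np.mean(resid**2)))

    # 95th percentile of training nearest-neighbour distances: the
    # interpolation/extrapolation boundary for new predictions.
    from scipy.spatial.distance import cdist

    D = cdist(Xs, Xs)
    np.fill_diagonal(D, np.inf)
    nn_dist = D.min(axis=1)
    nn_threshold = float(np.percentile(nn_dist, 95))

    model = ManifoldTgModel(
        feature_names=list(train.X.columns),
        mean_=mean,
        scale_=scale,
        n_neighbors=n_neighbors,
        n_components=n_components,
        coef_=coef,
        intercept_=intercept,
        split=split,
        train_ids=list(train.ids),
        train_X_std=Xs,
        train_embedding=emb,
        train_tg=y,
        nn_threshold=nn_threshold,
        metrics=ModelMetrics(r2_train=r2_train, rmse_train=rmse_train),
        _isomap=iso,
    )
    if split is not None and split.test_ids:
        test = _subset(table, split.test_ids)
        test_tg = np.asarray(
            table.tg.iloc[[table.ids.index(i) for i in split.test_ids]],
            dtype=float,
        )
        preds = predict(model, test.X, ids=test.ids)
        yhat = np.array([p.predicted_tg for p in preds])
        if np.std(test_tg) == 0:
            model.metrics.r2_test = 0.0
        else:
            model.metrics.r2_test = float(r2_score(test_tg, yhat))
        model.metrics.rmse_test = float(
            np.sqrt(np.mean((test_tg - yhat) ** 2))
        )
    return model


def predict(
    model: ManifoldTgModel,
    X_new: pd.DataFrame,
    ids: list[str] | None = None,
) -> list[PredictionResult]:
    """Embed new descriptor rows with the kernel out-of-sample extension and
    apply the linear model.  Rows whose nearest training neighbour is
    farther than the training 95th-percentile nearest-neighbour distance
    (or whose prediction leaves the training Tg range) are flagged as
    extrapolations."""
    missing = [c for c in model.feature_names if c not in X_new.columns]
    if missing:
        raise SchemaError(f"missing descriptor columns: {missing}")
    X = X_new[model.feature_names].to_numpy(dtype=float)
    if ids is None:
        ids = [f"row{i}" for i in range(len(X))]
    Xs = model.standardize(X)
    emb = model.isomap.transform(Xs)
    yhat = emb @ model.coef_ + model.intercept_

    from scipy.spatial.distance import cdist

    nn = cdist(Xs, model.train_X_std).min(axis=1)
    tg_lo, tg_hi = model.train_tg.min(), model.train_tg.max()
    out = []
    for i in range(len(X)):
        flag = bool(
            nn[i] > model.nn_threshold
            or yhat[i] < tg_lo - 1e-9
            or yhat[i] > tg_hi + 1e-9
        )
        out.append(
            PredictionResult(
                id=ids[i],
                predicted_tg=float(yhat[i]),
                embedding=emb[i],
                extrapolation_flag=flag,
            )
        )
    return out


def evaluate(
    model: ManifoldTgModel, table: FeatureTable
) -> tuple[ModelMetrics, pd.DataFrame]:
    """Metrics plus (measured, predicted) parity pairs for plotting.

    Rows are labelled train/test according to the model's split record; the
    returned metrics are computed on the rows of ``table``.
    """
    if table.tg is None:
        raise DataError("evaluate requires a Tg column")
    preds = predict(model, table.X, ids=table.ids)
    yhat = np.array([p.predicted_tg for p in preds])
    y = np.asarray(table.tg, dtype=float)
    test_ids = set(model.split.test_ids) if model.split is not None else set()
    parity = pd.DataFrame(
        {
            "id": table.ids,
            "measured_tg": y,
            "predicted_tg": yhat,
            "subset": [
                "test" if pid in test_ids else "train" for pid in table.ids
            ],
            "extrapolation": [p.extrapolation_flag for p in preds],
        }
    )
    tr = parity["subset"] == "train"
    te = ~tr

    def _r2(mask) -> float | None:
        if mask.sum() < 2 or np.std(y[mask]) == 0:
            return None
        return float(r2_score(y[mask], yhat[mask]))

    def _rmse(mask) -> float | None:
        if mask.sum() == 0:
            return None
        return float(np.sqrt(np.mean((y[mask] - yhat[mask]) ** 2)))

    metrics = ModelMetrics(
        r2_train=_r2(tr) if tr.any() else None,
        rmse_train=_rmse(tr),
        r2_test=_r2(te) if te.any() else None,
        rmse_test=_rmse(te),
    )
    return metrics, parity
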