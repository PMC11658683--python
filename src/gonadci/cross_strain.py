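"""Cross-dataset projection and label transfer.

One dataset (the reference atlas) is decomposed by independent component
analysis on the gene space shared with the query; the query is then centred
on the reference model's centre, multiplied by the whitening matrix and by
the orthogonal rotation matrix, landing in the reference component space
(``scores = R K (x - mu)``).  Cluster labels are transferred with a
multinomial logistic-regression classifier trained on a class-balanced
subsample (default 500 cells per cell type) of the reference component
scores.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.decomposition import FastICA
from sklearn.linear_model import LogisticRegression


def _dense(X) -> np.ndarray:
    if sp.issparse(X):
        return np.asarray(X.todense(), dtype=float)
    return np.asarray(X, dtype=float)


class ICAProjector(BaseEstimator, TransformerMixin):
    """FastICA decomposition exposing centre, whitening and rotation.

    After ``fit``, ``centre_`` is the per-gene mean, ``whitening_`` maps
    centred data to whitened space and ``rotation_`` is the orthogonal
    unmixing in whitened space; projection of a cell x is
    ``rotation_ @ whitening_ @ (x - centre_)``.  ``transform`` aligns query
    genes to ``gene_ids_`` by name when given, imputing missing genes as 0.
    """

    def __init__(self, n_components: int = 30, random_state: int | None = 0,
                 max_iter: int = 500, tol: float = 1e-4):
        self.n_components = n_components
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None, gene_ids: Sequence[str] | None = None):
        Xd = _dense(X)
        if self.n_components > min(Xd.shape):
            raise ValueError(
                f"n_components={self.n_components} exceeds min(cells, genes)={min(Xd.shape)}"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence reported via n_iter_
            # arbitrary-variance whitening keeps the unmixing orthogonal,
            # so rotation_ = components_ @ pinv(whitening_) satisfies R Rt = I
            ica = FastICA(
                n_components=self.n_components,
                whiten="arbitrary-variance",
                random_state=self.random_state,
                max_iter=self.max_iter,
                tol=self.tol,
            )
            self.training_scores_ = ica.fit_transform(Xd)
        self.centre_ = ica.mean_.copy()
        self.whitening_ = ica.whitening_.copy()
        # components_ = rotation @ whitening; recover the orthogonal rotation
        self.rotation_ = ica.components_ @ np.linalg.pinv(self.whitening_)
        self.components_ = ica.components_.copy()
        self.n_iter_ = ica.n_iter_
        self.gene_ids_ = list(gene_ids) if gene_ids is not None else None
        if self.n_iter_ >= self.max_iter:
            warnings.warn(
                f"FastICA did not converge in {self.max_iter} iterations; "
                "returning the best estimate",
                stacklevel=2,
            )
        return self

    def transform(self, X, gene_ids: Sequence[str] | None = None) -> np.ndarray:
        """Project cells x genes data into the reference component space."""
        Xd = _dense(X)
        if gene_ids is not None:
            if self.gene_ids_ is None:
                raise ValueError("model was fitted without gene identifiers")
            lookup = {g: i for i, g in enumerate(gene_ids)}
            present = [g for g in self.gene_ids_ if g in lookup]
            if len(present) < 0.5 * len(self.gene_ids_):
                raise ValueError(
                    f"only {len(present)}/{len(self.gene_ids_)} model genes present "
                    "in the query; projection would be meaningless"
                )
            if len(present) < len(self.gene_ids_):
                warnings.warn(
                    f"{len(self.gene_ids_) - len(present)} model gene(s) missing "
                    "from the query, imputed as 0",
                    stacklevel=2,
                )
            aligned = np.zeros((Xd.shape[0], len(self.gene_ids_)))
            for j, g in enumerate(self.gene_ids_):
                if g in lookup:
                    aligned[:, j] = Xd[:, lookup[g]]
            Xd = aligned
        return (Xd - self.centre_) @ (self.rotation_ @ self.whitening_).T

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "centre": self.centre_,
            "whitening": self.whitening_,
            "rotation": self.rotation_,
            "gene_ids": self.gene_ids_,
        }


def fit_ica(adata, n_components: int = 30, random_state: int | None = 0,
            **kwargs) -> tuple[ICAProjector, np.ndarray]:
    """Fit an :class:`ICAProjector` on an AnnData's (log-normalized) matrix;
    returns the model and the training component scores."""
    model = ICAProjector(n_components=n_components, random_state=random_state, **kwargs)
    model.fit(adata.X, gene_ids=list(adata.var_names))
    return model, model.training_scores_


def project(model: ICAProjector, adata) -> np.ndarray:
    """Project a query AnnData into the reference component space, aligning
    genes by identifier."""
    return model.transform(adata.X, gene_ids=list(adata.var_names))


class BalancedLabelTransfer(BaseEstimator, ClassifierMixin):
    """Multinomial logistic regression trained on a class-balanced
    subsample (default 500 cells per class, drawn without replacement)."""

    def __init__(self, n_per_class: int = 500, random_state: int | None = 0,
                 max_iter: int = 1000):
        self.n_per_class = n_per_class
        self.random_state = random_state
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("label transfer needs >=2 training classes")
        rng = np.random.default_rng(self.random_state)
        rows = []
        for cls, n in zip(classes, counts):
            idx = np.flatnonzero(y == cls)
            if n >= self.n_per_class:
                idx = rng.choice(idx, size=self.n_per_class, replace=False)
            else:
                warnings.warn(
                    f"class {cls!r} has {n} < {self.n_per_class} cells; using all",
                    stacklevel=2,
                )
            rows.append(idx)
        rows = np.concatenate(rows)
        self.subsample_idx_ = np.sort(rows)
        self.lr_ = LogisticRegression(max_iter=self.max_iter)
        self.lr_.fit(X[self.subsample_idx_], y[self.subsample_idx_])
        self.classes_ = self.lr_.classes_
        return self

    def predict(self, X) -> np.ndarray:
        return self.lr_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X) -> np.ndarray:
        return self.lr_.predict_proba(np.asarray(X, dtype=float))


def transfer_labels(
    train_scores: np.ndarray,
    train_labels: Sequence,
    query_scores: np.ndarray,
    n_per_class: int = 500,
    random_state: int | None = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Train the balanced classifier on reference component scores and
    predict query labels; returns (predicted labels, per-class probability
    table)."""
    clf = BalancedLabelTransfer(n_per_class=n_per_class, random_state=random_state)
    clf.fit(train_scores, np.asarray(train_labels))
    labels = clf.predict(query_scores)
    proba = pd.DataFrame(clf.predict_proba(query_scores), columns=clf.classes_)
    return labels, proba
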