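"""Sertoli/granulosa cell-identity (SCI/GCI) scoring.

The method has three stages:

1. **Gene assessment** — every expressed gene is scored for its ability to
   discriminate the target cell type (Sertoli within XY samples, granulosa
   within XX samples) from all other cell types in scope.  The
   discrimination metric is the ROC AUC, computed exactly from rank sums
   with midranks for ties (the Mann-Whitney probability
   ``P(X_pos > X_neg) + 0.5 P(X_pos = X_neg)``).  Genes are ranked by
   ``|AUC - 0.5|``; direction is positive when AUC > 0.5.  Fitting a
   single-predictor binomial GLM per gene and taking the AUC of its fitted
   scores yields the same ranking, because the AUC is invariant under the
   monotone logistic transform (the fitted-score AUC equals
   ``0.5 + |AUC_raw - 0.5|``); :func:`single_gene_glm_auc` exposes the GLM
   route for verification.

2. **Model building** — ranked genes are offered sequentially to a binomial
   GLM; a candidate is accepted iff it improves the mean stratified
   k-fold cross-validated AUC by more than ``tol`` (a forward stepwise
   selection with CV-AUC as the criterion).  Selection stops at ``max_genes``
   (default 50), when the ranking is exhausted, or after ``patience``
   consecutive rejections.  The final model is refit on all training cells.

3. **Scoring** — every cell receives ``100 x logistic(intercept + X @ coef)``
   under each model: the SCI from the Sertoli model and the GCI from the
   granulosa model, each in [0, 100].
"""

from __future__ import annotations

import warnings
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

DEFAULT_SCOPES = {"sertoli": ("XY_WT",), "granulosa": ("XX_WT",)}
DEFAULT_TARGETS = {"sertoli": "Sertoli", "granulosa": "granulosa"}


# ---------------------------------------------------------------------------
# AUC primitive

def compute_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """Exact ROC AUC of ``values`` against binary ``labels`` via rank sums.

    Equals the Mann-Whitney probability P(X_pos > X_neg) + 0.5 P(X_pos = X_neg),
    with midranks handling ties.
    """
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels).astype(bool).ravel()
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("compute_auc requires both classes to be nonempty")
    ranks = rankdata(values)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _auc_matrix(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Column-wise AUC of a dense cells-x-genes matrix (midrank ties)."""
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(X, axis=0)
    u = ranks[labels].sum(axis=0) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def single_gene_glm_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """AUC of the fitted scores of a one-predictor binomial GLM.

    Provided for verifying the monotone-transform equivalence with
    :func:`compute_auc`; the ranking pipeline uses the rank-sum route.
    """
    values = np.asarray(values, dtype=float).reshape(-1, 1)
    labels = np.asarray(labels).astype(int).ravel()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        glm = LogisticRegression(C=np.inf, max_iter=1000).fit(values, labels)
    return compute_auc(glm.predict_proba(values)[:, 1], labels)


# ---------------------------------------------------------------------------
# Estimator

class IdentityScorer(BaseEstimator, ClassifierMixin):
    """Cell-identity score model: AUC gene ranking + stepwise CV-AUC
    selection + a final binomial GLM, scaled to a [0, 100] score.

    Parameters
    ----------
    max_genes : selected-gene cap (default 50).
    cv : number of stratified folds for the selection criterion.
    tol : minimum mean CV-AUC improvement for accepting a gene.
    patience : consecutive rejections before selection stops early;
        ``None`` disables the early stop and the full ranking is scanned.
    min_cells : a gene must be expressed (value > 0) in at least this many
        in-scope cells to be ranked.
    random_state : seeds the CV splitter.

    Attributes (after ``fit``)
    --------------------------
    ranking_ : DataFrame (gene, auc, direction, rank) over expressed genes.
    selected_genes_ : ordered list of accepted gene names (<= max_genes).
    coef_, intercept_ : final refit GLM parameters.
    cv_trace_ : DataFrame (gene, cv_auc, accepted), one row per candidate.
    """

    def __init__(
        self,
        max_genes: int = 50,
        cv: int = 5,
        tol: float = 1e-4,
        patience: int | None = 20,
        min_cells: int = 3,
        max_iter: int = 200,
        random_state: int | None = 0,
    ):
        self.max_genes = max_genes
        self.cv = cv
        self.tol = tol
        self.patience = patience
        self.min_cells = min_cells
        self.max_iter = max_iter
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _dense(X) -> np.ndarray:
        if sp.issparse(X):
            return np.asarray(X.todense(), dtype=float)
        return np.asarray(X, dtype=float)

    def _new_glm(self) -> LogisticRegression:
        # C=inf: unpenalized binomial GLM
        return LogisticRegression(C=np.inf, solver="lbfgs", max_iter=self.max_iter)

    def _cv_auc(self, X: np.ndarray, y: np.ndarray, folds) -> float:
        aucs = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for train, test in folds:
                glm = self._new_glm().fit(X[train], y[train])
                aucs.append(compute_auc(glm.decision_function(X[test]), y[test]))
        return float(np.mean(aucs))

    # -- API ---------------------------------------------------------------

    def fit(self, X, y, feature_names: Sequence[str] | None = None):
        """Rank genes, select up to ``max_genes`` by stepwise CV-AUC and
        refit the final GLM.  ``X`` is cells x genes (log-normalized
        expression); ``y`` is the binary target-class indicator."""
        y = np.asarray(y).astype(bool).ravel()
        Xd = self._dense(X)
        if Xd.shape[0] != y.size:
            raise ValueError("X and y have inconsistent numbers of cells")
        n_pos, n_neg = int(y.sum()), int((~y).sum())
        if n_pos < 2 or n_neg < 2:
            raise ValueError("need >=2 cells in both the target and the rest class")
        self.n_features_in_ = Xd.shape[1]
        if feature_names is None:
            feature_names = [f"g{i}" for i in range(Xd.shape[1])]
        feature_names = np.asarray(feature_names, dtype=object)

        expressed = (Xd > 0).sum(axis=0) >= self.min_cells
        if not expressed.any():
            raise ValueError("no expressed genes in scope")
        idx = np.flatnonzero(expressed)
        auc = _auc_matrix(Xd[:, idx], y)
        strength = np.abs(auc - 0.5)
        order = np.lexsort((idx, -strength))  # ties broken by gene order
        ranked_idx = idx[order]
        self.ranking_ = pd.DataFrame(
            {
                "gene": feature_names[ranked_idx],
                "auc": auc[order],
                "direction": np.where(auc[order] > 0.5, "positive", "negative"),
                "rank": np.arange(1, ranked_idx.size + 1),
            }
        )

        n_splits = min(self.cv, n_pos, n_neg)
        if n_splits < 2:
            raise ValueError("too few cells per class for cross-validation")
        skf = StratifiedKFold(
            n_splits=n_splits, shuffle=True, random_state=self.random_state
        )
        folds = list(skf.split(Xd, y))

        selected: list[int] = []
        best = 0.5  # empty-model AUC
        streak = 0
        trace = []
        for col in ranked_idx:
            cand = selected + [int(col)]
            cv_auc = self._cv_auc(Xd[:, cand], y, folds)
            accepted = cv_auc > best + self.tol
            trace.append(
                {"gene": feature_names[col], "cv_auc": cv_auc, "accepted": accepted}
            )
            if accepted:
                selected = cand
                best = cv_auc
                streak = 0
                if len(selected) >= self.max_genes:
                    break
            else:
                streak += 1
                if self.patience is not None and streak >= self.patience:
                    break
        self.cv_trace_ = pd.DataFrame(trace, columns=["gene", "cv_auc", "accepted"])
        if not selected:
            raise ValueError("empty model: no gene improved the CV AUC beyond tol")

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            glm = self._new_glm().fit(Xd[:, selected], y.astype(int))
        self.classes_ = glm.classes_
        self.selected_idx_ = np.asarray(selected, dtype=int)
        self.selected_genes_ = list(feature_names[self.selected_idx_])
        self.coef_ = glm.coef_.ravel().copy()
        self.intercept_ = float(glm.intercept_[0])
        self.cv_auc_ = best
        return self

    def decision_function(self, X) -> np.ndarray:
        Xd = self._dense(X)
        return Xd[:, self.selected_idx_] @ self.coef_ + self.intercept_

    def predict_proba(self, X) -> np.ndarray:
        from scipy.special import expit

        p = expit(self.decision_function(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.decision_function(X) > 0).astype(int)]

    def identity_score(self, X) -> np.ndarray:
        """Per-cell score: 100 x logistic(intercept + X @ coef), in [0, 100]."""
        return 100.0 * self.predict_proba(X)[:, 1]

    def score_from_named(self, X, feature_names: Sequence[str]) -> np.ndarray:
        """Score a matrix whose columns are identified by name; model genes
        absent from ``feature_names`` are imputed as 0 expression (warned)."""
        lookup = {g: i for i, g in enumerate(feature_names)}
        Xd = self._dense(X)
        act = np.full(Xd.shape[0], self.intercept_)
        missing = []
        for g, c in zip(self.selected_genes_, self.coef_):
            if g in lookup:
                act += c * Xd[:, lookup[g]]
            else:
                missing.append(g)
        if missing:
            warnings.warn(
                f"{len(missing)} model gene(s) missing from the matrix, "
                "imputed as zero expression",
                stacklevel=2,
            )
        from scipy.special import expit

        return 100.0 * expit(act)

    def to_dict(self) -> dict:
        return {
            "target": getattr(self, "target_", None),
            "training_spec": getattr(self, "training_spec_", None),
            "genes": list(self.selected_genes_),
            "coefficients": [float(c) for c in self.coef_],
            "intercept": self.intercept_,
            "cv_auc": self.cv_auc_,
            "trace": self.cv_trace_.to_dict(orient="records"),
        }


# ---------------------------------------------------------------------------
# AnnData wrappers

def _scope_mask(adata: ad.AnnData, genotypes: Sequence[str] | None) -> np.ndarray:
    if genotypes is None:
        return np.ones(adata.n_obs, dtype=bool)
    return adata.obs["genotype"].isin(list(genotypes)).to_numpy()


def rank_genes(
    adata: ad.AnnData,
    target: str,
    genotypes: Sequence[str] | None = None,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Rank every expressed gene by its AUC for discriminating ``target``
    cells from all other cell types within the genotype scope."""
    mask = _scope_mask(adata, genotypes)
    y = (adata.obs["cell_type"] == target).to_numpy()[mask]
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError(f"scope must contain >=2 {target} and >=2 other cells")
    scorer = IdentityScorer(min_cells=min_cells)
    Xd = scorer._dense(adata.X[mask])
    expressed = (Xd > 0).sum(axis=0) >= min_cells
    idx = np.flatnonzero(expressed)
    auc = _auc_matrix(Xd[:, idx], y)
    strength = np.abs(auc - 0.5)
    order = np.lexsort((idx, -strength))
    return pd.DataFrame(
        {
            "gene": adata.var_names.to_numpy()[idx[order]],
            "auc": auc[order],
            "direction": np.where(auc[order] > 0.5, "positive", "negative"),
            "rank": np.arange(1, idx.size + 1),
        }
    )


def build_model(
    adata: ad.AnnData,
    target: str,
    genotypes: Sequence[str] | None = None,
    **params,
) -> IdentityScorer:
    """Fit an :class:`IdentityScorer` for ``target`` on the genotype scope.

    Keyword arguments are forwarded to the estimator (``max_genes``, ``cv``,
    ``tol``, ``patience``, ``min_cells``, ``random_state``).
    """
    mask = _scope_mask(adata, genotypes)
    y = (adata.obs["cell_type"] == target).to_numpy()[mask]
    scorer = IdentityScorer(**params)
    scorer.fit(adata.X[mask], y, feature_names=list(adata.var_names))
    scorer.target_ = target
    scorer.training_spec_ = {
        "genotypes": list(genotypes) if genotypes is not None else None,
        "positive_class": target,
        "negative_class": "all other cell types in scope",
    }
    return scorer


def train_identity_models(adata: ad.AnnData, **params) -> dict[str, IdentityScorer]:
    """Train the Sertoli model on XY WT cells and the granulosa model on
    XX WT cells (the default training scopes)."""
    return {
        key: build_model(adata, DEFAULT_TARGETS[key], DEFAULT_SCOPES[key], **params)
        for key in ("sertoli", "granulosa")
    }


def score_cells(
    adata: ad.AnnData, models: dict[str, IdentityScorer]
) -> pd.DataFrame:
    """Score every cell with both models; writes ``sci`` and ``gci`` columns
    (each in [0, 100]) to ``.obs`` and returns them."""
    names = list(adata.var_names)
    sci = models["sertoli"].score_from_named(adata.X, names)
    gci = models["granulosa"].score_from_named(adata.X, names)
    adata.obs["sci"] = sci
    adata.obs["gci"] = gci
    return adata.obs[["sci", "gci"]].copy()
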