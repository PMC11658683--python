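"""Proportion and score statistics.

Cell-type proportions per sample (with configurable exclusions, e.g. blood/
immune/mesothelial/endothelial clusters in real data), pairwise chi-square
tests on pooled counts with Benjamini-Hochberg correction and a Fisher exact
fallback for small expected counts, a centred PCA of the sample x cell-type
proportion matrix, and unpaired two-sample Wilcoxon rank-sum comparisons of
identity scores (exact for small tie-free groups, normal approximation with
tie and continuity correction otherwise).
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact, mannwhitneyu
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

EXACT_WILCOXON_MAX_N = 25


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def proportions(
    obs: pd.DataFrame,
    exclude: Sequence[str] = (),
    sample_key: str = "sample_id",
    type_key: str = "cell_type",
) -> pd.DataFrame:
    """Per-sample cell-type proportions over non-excluded types.

    Types absent from a sample appear with count 0; a sample with no
    included cells is dropped with a warning.  Proportions within a sample
    sum to 1.
    """
    kept = obs[~obs[type_key].isin(list(exclude))]
    empty = set(obs[sample_key].unique()) - set(kept[sample_key].unique())
    if empty:
        warnings.warn(
            f"{len(empty)} sample(s) with no included cells dropped: {sorted(empty)}",
            stacklevel=2,
        )
    counts = (
        kept.groupby([sample_key, type_key], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    meta_cols = [c for c in ("genotype", "stage") if c in obs.columns]
    meta = kept.groupby(sample_key, observed=True)[meta_cols].first() if meta_cols else None
    frac = counts.div(counts.sum(axis=1), axis=0)
    long = (
        counts.stack()
        .rename("n_cells")
        .to_frame()
        .join(frac.stack().rename("proportion"))
        .reset_index()
    )
    if meta is not None:
        long = long.merge(meta.reset_index(), on=sample_key, how="left")
    cols = [sample_key] + meta_cols + [type_key, "n_cells", "proportion"]
    return long[cols]


def compare_proportions(
    pt: pd.DataFrame,
    compare_on: str = "genotype",
    within: Sequence[str] = ("stage",),
    type_key: str = "cell_type",
    correction: bool = False,
) -> pd.DataFrame:
    """Pairwise chi-square comparisons of cell-type proportions.

    For each cell type and pair of ``compare_on`` levels (within each level
    of ``within``), counts are pooled across samples into a 2x2 table
    (in-type vs out-of-type) and tested by chi-square (Yates correction off
    by default); expected counts < 5 switch to Fisher's exact test, flagged
    in the ``method`` column.  Benjamini-Hochberg q across all tests.
    """
    within = [w for w in within if w in pt.columns]
    rows = []
    strata = pt.groupby(within, observed=True) if within else [((), pt)]
    for key, frame in strata:
        key = key if isinstance(key, tuple) else (key,)
        pooled = (
            frame.groupby([compare_on, type_key], observed=True)["n_cells"]
            .sum()
            .unstack(fill_value=0)
        )
        for ga, gb in combinations(sorted(pooled.index), 2):
            tot_a, tot_b = pooled.loc[ga].sum(), pooled.loc[gb].sum()
            for ct in pooled.columns:
                a, b = pooled.loc[ga, ct], pooled.loc[gb, ct]
                table = np.array([[a, tot_a - a], [b, tot_b - b]], dtype=float)
                if table.sum() == 0 or (table.sum(axis=1) == 0).any():
                    continue
                expected = (
                    table.sum(axis=1, keepdims=True) @ table.sum(axis=0, keepdims=True)
                ) / table.sum()
                if (expected < 5).any():
                    _, p = fisher_exact(table)
                    stat, method = float("nan"), "fisher"
                else:
                    stat, p, _, _ = chi2_contingency(table, correction=correction)
                    method = "chi2"
                rows.append(
                    dict(zip(within, key))
                    | {type_key: ct, "group_a": ga, "group_b": gb,
                       "statistic": stat, "p": float(p), "method": method}
                )
    out = pd.DataFrame(
        rows,
        columns=list(within) + [type_key, "group_a", "group_b", "statistic", "p", "method"],
    )
    if len(out):
        out["q"] = bh_adjust(out["p"])
    else:
        out["q"] = pd.Series(dtype=float)
    return out


def pca_proportions(pt: pd.DataFrame, sample_key: str = "sample_id",
                    type_key: str = "cell_type") -> tuple[pd.DataFrame, np.ndarray]:
    """Centred PCA of the sample x cell-type proportion matrix.

    Returns (coordinates indexed by sample with genotype/stage carried
    along, explained-variance fractions).  Components are capped at the
    matrix rank; with fewer than 3 samples the analysis is refused.
    """
    wide = pt.pivot_table(index=sample_key, columns=type_key,
                          values="proportion", fill_value=0.0, observed=True)
    if wide.shape[0] < 3:
        raise ValueError("PCA of proportions needs >=3 samples")
    X = wide.to_numpy()
    centred = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(centred) if np.abs(centred).max() > 0 else 0
    if rank == 0:
        coords = pd.DataFrame(
            0.0, index=wide.index, columns=["PC1", "PC2"]
        )
        evr = np.zeros(2)
    else:
        n_comp = min(rank, X.shape[0] - 1, X.shape[1])
        pca = PCA(n_components=n_comp)
        scores = pca.fit_transform(X)
        coords = pd.DataFrame(
            scores, index=wide.index,
            columns=[f"PC{i + 1}" for i in range(n_comp)],
        )
        evr = pca.explained_variance_ratio_
    meta_cols = [c for c in ("genotype", "stage") if c in pt.columns]
    if meta_cols:
        meta = pt.groupby(sample_key, observed=True)[meta_cols].first()
        coords = coords.join(meta)
    return coords, evr


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided unpaired Wilcoxon rank-sum p-value.

    Exact when both groups have <= 25 observations and the data are
    tie-free; otherwise the normal approximation with tie and continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need >=2 observations")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:  # degenerate: no shift detectable
        return 1.0
    tie_free = np.unique(pooled).size == pooled.size
    method = (
        "exact"
        if tie_free and max(x.size, y.size) <= EXACT_WILCOXON_MAX_N
        else "asymptotic"
    )
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def compare_scores(
    obs: pd.DataFrame,
    score_cols: Sequence[str] = ("sci", "gci"),
    compare_on: str = "genotype",
    within: Sequence[str] = ("stage", "cell_type"),
) -> pd.DataFrame:
    """Pairwise Wilcoxon comparisons of identity scores between levels of
    ``compare_on`` within each stratum; BH q across all comparisons.
    Strata where a group has fewer than 2 cells are skipped."""
    within = [w for w in within if w in obs.columns]
    rows = []
    strata = obs.groupby(within, observed=True) if within else [((), obs)]
    for key, frame in strata:
        key = key if isinstance(key, tuple) else (key,)
        levels = sorted(frame[compare_on].unique())
        for ga, gb in combinations(levels, 2):
            xa = frame[frame[compare_on] == ga]
            xb = frame[frame[compare_on] == gb]
            if len(xa) < 2 or len(xb) < 2:
                continue
            for col in score_cols:
                p = wilcoxon_rank_sum(xa[col].to_numpy(), xb[col].to_numpy())
                rows.append(
                    dict(zip(within, key))
                    | {"score": col, "group_a": ga, "group_b": gb,
                       "mean_a": float(xa[col].mean()),
                       "mean_b": float(xb[col].mean()), "p": p}
                )
    out = pd.DataFrame(
        rows,
        columns=list(within) + ["score", "group_a", "group_b", "mean_a", "mean_b", "p"],
    )
    if len(out):
        out["q"] = bh_adjust(out["p"])
    else:
        out["q"] = pd.Series(dtype=float)
    return out
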