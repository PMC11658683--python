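"""Double-positive (DP) cell calling from SCI/GCI scores.

A cell is double-positive when it lies inside a rectangular-hyperbola region
of the (SCI, GCI) plane: ``sci * gci >= a * b``, where ``a`` is a scaling
factor (default 10) and ``b`` is the boundary, the 97.5th percentile of GCI
among a reference population — by default granulosa cells of 14.5 dpc XX
wild-type gonads, the fully differentiated ovarian reference.  The region
contains cells with jointly elevated, similar scores and excludes both axes
(a cell with either score at 0 can never be DP).  Equality on the boundary
counts as inside.  The predicate is isolated in :func:`is_double_positive`
so an alternative region shape is a one-line swap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

DEFAULT_REFERENCE = {"genotype": "XX_WT", "stage": 14.5, "cell_type": "granulosa"}


@dataclass(frozen=True)
class DPParams:
    """Hyperbola parameters: scaling ``a``, boundary ``b`` and the reference
    population ``b`` was computed from."""

    a: float = 10.0
    b: float = float("nan")
    reference_spec: tuple[tuple[str, object], ...] = tuple(DEFAULT_REFERENCE.items())

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("a must be positive")


class DoublePositiveClassifier(BaseEstimator):
    """Flags cells inside the hyperbola region ``sci * gci >= a * b_``.

    ``fit`` takes the reference cells' GCI scores and sets the boundary
    ``b_`` to their ``quantile_pct`` percentile (linear interpolation);
    ``predict`` takes a (n_cells, 2) array of (sci, gci).
    """

    def __init__(self, a: float = 10.0, quantile_pct: float = 97.5,
                 min_reference: int = 20):
        self.a = a
        self.quantile_pct = quantile_pct
        self.min_reference = min_reference

    def fit(self, reference_gci, y=None):
        if self.a <= 0:
            raise ValueError("a must be positive")
        ref = np.asarray(reference_gci, dtype=float).ravel()
        if ref.size < self.min_reference:
            raise ValueError(
                f"boundary needs >={self.min_reference} reference cells, got {ref.size}"
            )
        self.b_ = float(np.percentile(ref, self.quantile_pct))
        if self.b_ <= 0:
            raise ValueError("reference percentile yields a non-positive boundary")
        self.n_reference_ = int(ref.size)
        return self

    def predict(self, scores) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        return is_double_positive(scores[:, 0], scores[:, 1], self.a, self.b_)


def is_double_positive(sci, gci, a: float, b: float) -> np.ndarray | bool:
    """TRUE iff the cell lies inside the hyperbola region: sci * gci >= a * b.

    Vectorized over ``sci``/``gci``; boundary equality counts as inside.
    """
    result = np.asarray(sci, dtype=float) * np.asarray(gci, dtype=float) >= a * b
    return result if result.ndim else bool(result)


def fit_dp_boundary(
    adata: ad.AnnData,
    a: float = 10.0,
    reference_spec: dict | None = None,
    quantile_pct: float = 97.5,
    min_reference: int = 20,
) -> DPParams:
    """Compute the boundary ``b`` from the GCI of reference cells.

    ``reference_spec`` maps obs columns to required values (default: 14.5 dpc
    XX WT granulosa cells).  Errors if no cell matches or fewer than
    ``min_reference`` do.
    """
    spec = dict(DEFAULT_REFERENCE if reference_spec is None else reference_spec)
    mask = np.ones(adata.n_obs, dtype=bool)
    for col, val in spec.items():
        mask &= (adata.obs[col] == val).to_numpy()
    if not mask.any():
        raise ValueError(f"no reference cells matching {spec}")
    clf = DoublePositiveClassifier(a=a, quantile_pct=quantile_pct,
                                   min_reference=min_reference)
    clf.fit(adata.obs.loc[mask, "gci"].to_numpy())
    return DPParams(a=a, b=clf.b_, reference_spec=tuple(spec.items()))


def call_double_positive(adata: ad.AnnData, params: DPParams) -> np.ndarray:
    """Apply the hyperbola predicate to every cell; writes ``is_dp``."""
    flags = is_double_positive(
        adata.obs["sci"].to_numpy(), adata.obs["gci"].to_numpy(), params.a, params.b
    )
    adata.obs["is_dp"] = flags
    return flags


def _test_2x2(table: np.ndarray, correction: bool) -> tuple[float, float, str]:
    expected = (
        table.sum(axis=1, keepdims=True) @ table.sum(axis=0, keepdims=True)
    ) / table.sum()
    if (expected < 5).any():
        _, p = fisher_exact(table)
        return float("nan"), float(p), "fisher"
    stat, p, _, _ = chi2_contingency(table, correction=correction)
    return float(stat), float(p), "chi2"


def dp_proportions(
    obs: pd.DataFrame,
    group_by: Sequence[str] = ("genotype", "stage", "cell_type"),
    compare_on: str = "genotype",
    correction: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group DP proportions and pairwise comparisons.

    Returns ``(proportions, comparisons)``: per-group counts/proportions, and
    pairwise chi-square tests on (DP, non-DP) counts between levels of
    ``compare_on`` within each stratum of the remaining grouping columns,
    with Benjamini-Hochberg q-values across all comparisons and a Fisher
    exact fallback flagged when an expected count is < 5.
    """
    if "is_dp" not in obs:
        raise ValueError("is_dp flags missing; run call_double_positive first")
    group_by = list(group_by)
    # observed=False so empty categorical groups surface and can be warned on
    grouped = obs.groupby(group_by, observed=False)
    prop = grouped["is_dp"].agg(n="size", n_dp="sum").reset_index()
    empty = prop["n"] == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} empty group(s) excluded", stacklevel=2)
        prop = prop[~empty]
    prop["proportion"] = prop["n_dp"] / prop["n"]

    strata = [c for c in group_by if c != compare_on]
    rows = []
    frames = prop.groupby(strata, observed=True) if strata else [((), prop)]
    for key, frame in frames:
        key = key if isinstance(key, tuple) else (key,)
        for ga, gb in combinations(sorted(frame[compare_on].unique()), 2):
            ra = frame[frame[compare_on] == ga].iloc[0]
            rb = frame[frame[compare_on] == gb].iloc[0]
            table = np.array(
                [[ra.n_dp, ra.n - ra.n_dp], [rb.n_dp, rb.n - rb.n_dp]], dtype=float
            )
            if table.sum() == 0 or (table.sum(axis=1) == 0).any():
                continue
            stat, p, method = _test_2x2(table, correction)
            rows.append(
                dict(zip(strata, key))
                | {"group_a": ga, "group_b": gb, "statistic": stat,
                   "p": p, "method": method}
            )
    comparisons = pd.DataFrame(
        rows, columns=strata + ["group_a", "group_b", "statistic", "p", "method"]
    )
    if len(comparisons):
        comparisons["q"] = multipletests(comparisons["p"], method="fdr_bh")[1]
    else:
        comparisons["q"] = pd.Series(dtype=float)
    return prop, comparisons
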