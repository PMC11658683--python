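"""Quality-control filtering, normalization and cell-cycle phase assignment.

Filtering removes low-quality cells by percentile rules applied first per
sample (total counts and genes expressed outside the 2nd-98th percentile,
mitochondrial percentage outside the 2nd-95th) and then globally (bottom 5th
percentile of total counts over the retained cells).  Percentiles use linear
interpolation and removal is strict (< low value, > high value), so a
degenerate all-equal distribution removes nothing.

Normalization scales each cell to a target sum of 10,000 counts computed over
genes *outside* the top 5% by total count — highly expressed genes are still
scaled and log-transformed, they are merely excluded from the size-factor
denominator — followed by log(1 + x).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

TARGET_SUM = 10_000.0


@dataclass(frozen=True)
class QCThresholds:
    """Percentile bounds of the cell filters (low, high), in percent."""

    per_sample_count_pct: tuple[float, float] = (2.0, 98.0)
    per_sample_genes_pct: tuple[float, float] = (2.0, 98.0)
    per_sample_mito_pct: tuple[float, float] = (2.0, 95.0)
    global_count_pct: float = 5.0
    min_sample_cells: int = 10

    def __post_init__(self):
        for lo, hi in (
            self.per_sample_count_pct,
            self.per_sample_genes_pct,
            self.per_sample_mito_pct,
        ):
            if not (0 <= lo < hi <= 100):
                raise ValueError(f"invalid percentile pair ({lo}, {hi})")
        if not (0 <= self.global_count_pct <= 100):
            raise ValueError("invalid global percentile")


def _percentile_band_keep(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Keep mask for values within [P_lo, P_hi]; strict removal outside."""
    lo_v, hi_v = np.percentile(values, [lo, hi])  # linear interpolation
    return (values >= lo_v) & (values <= hi_v)


def filter_cells(
    adata: ad.AnnData, thresholds: QCThresholds | None = None
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Apply the per-sample then global percentile filters.

    Requires ``sample_id`` in ``.obs``; ``total_counts`` and
    ``n_genes_expressed`` are computed from the matrix if absent.  The mito
    filter is skipped with a warning when ``pct_mito`` is missing.  If an
    ``is_doublet`` boolean column is present those cells are removed first.

    Returns the filtered view (copied) and a report with one row per
    (rule, sample) giving the number of cells removed.
    """
    thresholds = thresholds or QCThresholds()
    if "sample_id" not in adata.obs:
        raise ValueError("filter_cells requires a 'sample_id' column")
    obs = adata.obs.copy()
    X = adata.X
    if "total_counts" not in obs:
        obs["total_counts"] = np.asarray(X.sum(axis=1)).ravel()
    if "n_genes_expressed" not in obs:
        obs["n_genes_expressed"] = np.asarray((X > 0).sum(axis=1)).ravel()
    has_mito = "pct_mito" in obs
    if not has_mito:
        logger.warning("pct_mito missing; mitochondrial filter skipped")

    keep = np.ones(adata.n_obs, dtype=bool)
    report_rows = []

    if "is_doublet" in obs:
        doublet = obs["is_doublet"].fillna(False).astype(bool).to_numpy()
        keep &= ~doublet
        report_rows.append({"rule": "doublet", "sample": "all", "n_removed": int(doublet.sum())})

    rules = [("counts", "total_counts", thresholds.per_sample_count_pct),
             ("genes", "n_genes_expressed", thresholds.per_sample_genes_pct)]
    if has_mito:
        rules.append(("mito", "pct_mito", thresholds.per_sample_mito_pct))

    for sample, idx in obs.groupby("sample_id", observed=True).groups.items():
        rows = obs.index.get_indexer(idx)
        rows = rows[keep[rows]]
        if rows.size < thresholds.min_sample_cells:
            logger.warning(
                "sample %s has %d cells (<%d); per-sample filters skipped",
                sample, rows.size, thresholds.min_sample_cells,
            )
            for rule, _, _ in rules:
                report_rows.append({"rule": rule, "sample": sample, "n_removed": 0})
            continue
        for rule, col, (lo, hi) in rules:
            vals = obs[col].to_numpy(dtype=float)[rows]
            ok = _percentile_band_keep(vals, lo, hi)
            removed = rows[~ok]
            keep[removed] = False
            rows = rows[ok]
            report_rows.append(
                {"rule": rule, "sample": sample, "n_removed": int(removed.size)}
            )

    # global filter: bottom percentile of counts across all retained cells
    retained = np.flatnonzero(keep)
    if retained.size:
        counts = obs["total_counts"].to_numpy(dtype=float)[retained]
        cutoff = np.percentile(counts, thresholds.global_count_pct)
        low = retained[counts < cutoff]
        keep[low] = False
        report_rows.append(
            {"rule": "global_counts", "sample": "all", "n_removed": int(low.size)}
        )

    report = pd.DataFrame(report_rows, columns=["rule", "sample", "n_removed"])
    out = adata[keep].copy()
    out.obs["total_counts"] = obs["total_counts"][keep].to_numpy()
    out.obs["n_genes_expressed"] = obs["n_genes_expressed"][keep].to_numpy()
    return out, report


def normalize(
    adata: ad.AnnData,
    target_sum: float = TARGET_SUM,
    exclude_top_frac: float = 0.05,
) -> ad.AnnData:
    """Target-sum normalization excluding highly expressed genes from the
    size-factor denominator, then log1p.

    Raw counts are preserved in ``.layers['counts']``; ``.X`` becomes the
    log-normalized values, ``.obs['size_factor']`` the per-cell factors and
    ``.var['excluded_from_norm']`` flags the top-``exclude_top_frac`` genes by
    total count (scaled and logged like the rest, but outside the sum).
    A cell whose non-excluded sum is 0 falls back to its total sum, with a
    warning.
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("cannot normalize an empty matrix")
    X = adata.X
    X = sp.csr_matrix(X) if not sp.issparse(X) else X.tocsr()
    gene_totals = np.asarray(X.sum(axis=0)).ravel()
    n_excl = int(np.ceil(exclude_top_frac * adata.n_vars)) if exclude_top_frac > 0 else 0
    excluded = np.zeros(adata.n_vars, dtype=bool)
    if n_excl:
        # ties broken by gene order for determinism
        order = np.lexsort((np.arange(adata.n_vars), -gene_totals))
        excluded[order[:n_excl]] = True

    totals = np.asarray(X.sum(axis=1)).ravel()
    non_excl = totals - np.asarray(X[:, excluded].sum(axis=1)).ravel()
    fallback = non_excl <= 0
    if fallback.any():
        warnings.warn(
            f"{int(fallback.sum())} cell(s) with zero non-excluded counts; "
            "size factor taken from total counts",
            stacklevel=2,
        )
    basis = np.where(fallback, totals, non_excl)
    basis = np.where(basis <= 0, 1.0, basis)  # all-zero cells stay all zero
    size_factors = basis / target_sum

    out = adata.copy()
    out.layers["counts"] = X.copy()
    scaled = sp.diags(1.0 / size_factors) @ X
    scaled.data = np.log1p(scaled.data)
    out.X = scaled.tocsr()
    out.obs["size_factor"] = size_factors
    out.var["excluded_from_norm"] = excluded
    return out


def assign_cell_cycle(
    adata: ad.AnnData,
    s_genes: list[str],
    g2m_genes: list[str],
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
    sample_key: str = "sample_id",
) -> pd.DataFrame:
    """Per-sample module scores for the S and G2/M programs and a phase call.

    The module score of a gene set is the mean log-normalized expression of
    its genes minus the mean of control genes drawn (seeded) from matching
    expression bins — the standard construction.  Phase rule: S if the S score
    exceeds both the G2M score and 0; G2M if its score is >= the S score and
    > 0; else G1.  Writes ``s_score``, ``g2m_score`` and ``phase`` to ``.obs``
    and returns them.
    """
    import scanpy as sc

    s_genes = [g for g in s_genes if g in adata.var_names]
    g2m_genes = [g for g in g2m_genes if g in adata.var_names]
    if not s_genes or not g2m_genes:
        raise ValueError("each cycle gene set must contain >=1 gene present in the matrix")
    if set(s_genes) & set(g2m_genes):
        raise ValueError("S and G2M gene sets must be disjoint")

    s_score = np.zeros(adata.n_obs)
    g2m_score = np.zeros(adata.n_obs)
    groups = (
        adata.obs.groupby(sample_key, observed=True).groups.items()
        if sample_key in adata.obs
        else [("all", adata.obs.index)]
    )
    for _, idx in groups:
        rows = adata.obs.index.get_indexer(idx)
        sub = adata[rows].copy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.tl.score_genes(sub, s_genes, ctrl_size=n_ctrl, n_bins=n_bins,
                              score_name="_s", random_state=seed)
            sc.tl.score_genes(sub, g2m_genes, ctrl_size=n_ctrl, n_bins=n_bins,
                              score_name="_g2m", random_state=seed)
        s_score[rows] = sub.obs["_s"].to_numpy()
        g2m_score[rows] = sub.obs["_g2m"].to_numpy()

    phase = np.where(
        (s_score > g2m_score) & (s_score > 0), "S",
        np.where((g2m_score >= s_score) & (g2m_score > 0), "G2M", "G1"),
    )
    adata.obs["s_score"] = s_score
    adata.obs["g2m_score"] = g2m_score
    adata.obs["phase"] = phase
    return adata.obs[["s_score", "g2m_score", "phase"]].copy()
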