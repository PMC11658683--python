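import numpy as np
import pytest

import gonadci as g


@pytest.fixture(scope="session")
def small_adata():
    """A quick dataset: 10 cell types x 60 cells per group, 12 markers each,
    425 genes — enough structure for every stage of the pipeline."""
    cfg = g.default_config(
        n_cells_per_type=60,
        n_markers_per_type=12,
        n_background_genes=300,
        n_mito_genes=5,
        seed=11,
    )
    return g.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_norm(small_adata):
    filtered, _ = g.filter_cells(small_adata)
    return g.normalize(filtered)


@pytest.fixture(scope="session")
def small_models(small_norm):
    return g.train_identity_models(small_norm, random_state=0)


@pytest.fixture(scope="session")
def small_scored(small_norm, small_models):
    adata = small_norm.copy()
    g.score_cells(adata, small_models)
    params = g.fit_dp_boundary(adata)
    g.call_double_positive(adata, params)
    adata.uns["dp_params"] = {"a": params.a, "b": params.b}
    return adata


@pytest.fixture(scope="session")
def easy_norm():
    """Five well-separated types (30 markers each, effect 2.0, no DP class):
    a fixture on which planted structure is recoverable essentially
    perfectly, for recovery-style checks."""
    types = ["Sertoli", "granulosa", "SLC", "PS1", "Germ"]
    cell_types = [
        g.CellTypeSpec(t, tuple(f"{t}_e{i:02d}" for i in range(30)), 2.0)
        for t in types
    ]
    cfg = g.SimulationConfig(
        cell_types=cell_types,
        genotype_stage_mixture={("XY_WT", 12.5): {t: 0.2 for t in types}},
        n_cells_per_type=150,
        n_samples_per_group=2,
        n_background_genes=150,
        n_mito_genes=0,
        nb_mean=0.2,
        dp_fraction=0.0,
        seed=17,
    )
    return g.normalize(g.simulate_dataset(cfg))


# ---------------------------------------------------------------------------
# Study-scale fixtures: the default conditions (200 cells/type, 50 planted
# markers per type with effect 1.5 among 2,000 genes).

@pytest.fixture(scope="session")
def study_adata():
    return g.simulate_dataset(g.default_config(seed=1))


@pytest.fixture(scope="session")
def study_norm(study_adata):
    filtered, _ = g.filter_cells(study_adata)
    return g.normalize(filtered)


@pytest.fixture(scope="session")
def study_models(study_norm):
    return g.train_identity_models(study_norm, random_state=0)


@pytest.fixture(scope="session")
def study_scored(study_norm, study_models):
    adata = study_norm.copy()
    g.score_cells(adata, study_models)
    params = g.fit_dp_boundary(adata)
    g.call_double_positive(adata, params)
    return adata


# ---------------------------------------------------------------------------
# Independent oracles shared across test modules.

def brute_force_auc(values, labels) -> float:
    """O(n^2) pairwise concordance with half credit for ties."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = values[labels]
    neg = values[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (pos.size * neg.size)


def linear_percentile(values, pct) -> float:
    """Linear-interpolation percentile, written out longhand."""
    v = np.sort(np.asarray(values, dtype=float))
    pos = pct / 100.0 * (v.size - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac


def bh_stepup(pvalues) -> np.ndarray:
    """Reference Benjamini-Hochberg step-up."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q
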