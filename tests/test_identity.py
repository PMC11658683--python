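import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.special import expit

import gonadci as g
from conftest import brute_force_auc


class TestComputeAuc:
    def test_perfect_separation(self):
        assert g.compute_auc([5, 4, 1, 0], [1, 1, 0, 0]) == 1.0

    def test_complete_tie(self):
        assert g.compute_auc([2, 2], [1, 0]) == 0.5

    def test_three_of_four_pairs_concordant(self):
        # pairs (3,2),(3,0),(1,0) concordant; (1,2) discordant
        assert g.compute_auc([3, 1, 2, 0], [1, 1, 0, 0]) == 0.75

    def test_one_empty_class_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            g.compute_auc([1, 2, 3], [1, 1, 1])

    def test_agrees_with_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(4, 31)
            values = rng.integers(0, 6, size=n).astype(float)  # many ties
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            assert abs(g.compute_auc(values, labels) - brute_force_auc(values, labels)) < 1e-12

    def test_rank_sum_auc_matches_oracle_property(self):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=100, deadline=None, derandomize=True)
        @given(
            values=st.lists(st.integers(0, 5), min_size=4, max_size=25),
            cut=st.integers(1, 24),
        )
        def check(values, cut):
            n = len(values)
            cut = min(cut, n - 1)
            labels = np.zeros(n, dtype=bool)
            labels[:cut] = True
            got = g.compute_auc(np.asarray(values, dtype=float), labels)
            want = brute_force_auc(values, labels)
            assert abs(got - want) < 1e-12

        check()

    def test_negation_complements_auc_without_ties(self):
        rng = np.random.default_rng(7)
        values = rng.permutation(30).astype(float)  # tie-free
        labels = (rng.random(30) < 0.4).astype(int)
        a = g.compute_auc(values, labels)
        b = g.compute_auc(-values, labels)
        assert abs(a + b - 1.0) < 1e-12

    def test_single_gene_glm_gives_identical_ranking_strength(self):
        """AUC of a one-predictor GLM's fitted scores equals
        0.5 + |AUC_raw - 0.5|: the logistic transform is monotone."""
        rng = np.random.default_rng(3)
        for shift in (1.0, -1.0, 0.5):
            labels = np.repeat([1, 0], 40)
            values = rng.normal(0, 1, 80) + shift * labels
            raw = g.compute_auc(values, labels)
            glm = g.single_gene_glm_auc(values, labels)
            assert abs(glm - (0.5 + abs(raw - 0.5))) < 1e-12


def _toy_adata():
    """4 'genes': perfect positive marker, anti-marker, constant, silent."""
    n = 40
    y = np.repeat([True, False], n // 2)
    marker = np.where(y, 5.0, 0.5) + np.linspace(0, 0.1, n)
    anti = np.where(y, 0.2, 4.0) + np.linspace(0, 0.1, n)
    const = np.full(n, 2.0)
    silent = np.zeros(n)
    X = np.column_stack([marker, anti, const, silent])
    obs = pd.DataFrame(
        {
            "sample_id": ["S1"] * n,
            "genotype": ["XY_WT"] * n,
            "cell_type": np.where(y, "Sertoli", "PS1"),
        },
        index=[f"c{i}" for i in range(n)],
    )
    return ad.AnnData(
        X=X, obs=obs, var=pd.DataFrame(index=["marker", "anti", "const", "silent"])
    )


class TestRankGenes:
    def test_directions_and_order(self):
        ranking = g.rank_genes(_toy_adata(), "Sertoli", ("XY_WT",))
        assert list(ranking["gene"][:2]) == ["marker", "anti"]
        assert ranking.set_index("gene").loc["marker", "direction"] == "positive"
        assert ranking.set_index("gene").loc["anti", "direction"] == "negative"
        # constant gene: AUC exactly 0.5, last tier
        const_row = ranking.set_index("gene").loc["const"]
        assert const_row["auc"] == 0.5
        assert const_row["rank"] == len(ranking)

    def test_silent_genes_excluded(self):
        ranking = g.rank_genes(_toy_adata(), "Sertoli", ("XY_WT",))
        assert "silent" not in set(ranking["gene"])

    def test_planted_markers_occupy_top_ranks(self, small_norm, small_adata):
        truth = small_adata.uns["marker_truth"]
        planted = set(truth.loc[truth.cell_type == "Sertoli", "gene_id"])
        ranking = g.rank_genes(small_norm, "Sertoli", ("XY_WT",))
        top = set(ranking["gene"][: 2 * len(planted)])
        assert len(planted & top) / len(planted) >= 0.9

    def test_scope_without_target_cells_rejected(self, small_norm):
        with pytest.raises(ValueError, match=">=2"):
            g.rank_genes(small_norm, "Sertoli", ("XX_WT",))


class TestBuildModel:
    def test_informative_genes_recovered_and_trace_monotone(self):
        cfg = g.SimulationConfig(
            cell_types=[
                g.CellTypeSpec("Sertoli", ("inf1", "inf2", "inf3"), 2.5),
                g.CellTypeSpec("PS1", (), 0.0),
            ],
            genotype_stage_mixture={("XY_WT", 12.5): {"Sertoli": 0.5, "PS1": 0.5}},
            n_cells_per_type=150,
            n_samples_per_group=1,
            n_background_genes=200,
            n_mito_genes=0,
            nb_mean=0.3,
            dp_fraction=0.0,
            seed=9,
        )
        norm = g.normalize(g.simulate_dataset(cfg))
        model = g.build_model(norm, "Sertoli", ("XY_WT",), random_state=0)
        assert {"inf1", "inf2", "inf3"} <= set(model.selected_genes_)
        accepted = model.cv_trace_[model.cv_trace_["accepted"]]
        assert accepted["cv_auc"].is_monotonic_increasing

    def test_max_genes_cap_is_honored(self):
        cfg = g.stepwise_benchmark_config(
            n_informative=120, n_background=30, n_cells_per_type=150, seed=4
        )
        norm = g.normalize(g.simulate_dataset(cfg))
        model = g.build_model(norm, "Sertoli", ("XY_WT",), max_genes=10, random_state=0)
        assert len(model.selected_genes_) == 10

    def test_infinite_tolerance_yields_empty_model_error(self, small_norm):
        with pytest.raises(ValueError, match="empty model"):
            g.build_model(small_norm, "Sertoli", ("XY_WT",), tol=np.inf)

    def test_cv_trace_bounded(self, small_models):
        for model in small_models.values():
            assert model.cv_trace_["cv_auc"].between(0, 1).all()
            assert len(model.selected_genes_) <= 50


class TestScoring:
    def test_zero_expression_cell_scores_logistic_intercept(self, small_models):
        model = small_models["sertoli"]
        X = np.zeros((1, max(model.selected_idx_) + 1))
        expected = 100.0 * expit(model.intercept_)
        assert model.identity_score(X)[0] == expected

    def test_scores_bounded(self, small_scored):
        assert small_scored.obs["sci"].between(0, 100).all()
        assert small_scored.obs["gci"].between(0, 100).all()

    def test_training_classes_separate(self, small_scored):
        obs = small_scored.obs
        pure = ~obs["dp_truth"]
        gci_g = obs.loc[pure & (obs.cell_type == "granulosa"), "gci"]
        gci_s = obs.loc[pure & (obs.cell_type == "Sertoli"), "gci"]
        assert gci_g.mean() > gci_s.mean()

    def test_dp_cells_score_between_pure_classes(self, small_scored):
        obs = small_scored.obs
        pure = ~obs["dp_truth"]
        sert = pure & (obs.cell_type == "Sertoli")
        gran = pure & (obs.cell_type == "granulosa")
        dp = obs["dp_truth"]
        for col, hi, lo in (("sci", sert, gran), ("gci", gran, sert)):
            assert obs.loc[lo, col].mean() < obs.loc[dp, col].mean() < obs.loc[hi, col].mean()

    def test_missing_model_genes_imputed_with_warning(self, small_models):
        model = small_models["sertoli"]
        X = np.zeros((2, 3))
        with pytest.warns(UserWarning, match="missing"):
            scores = model.score_from_named(X, ["nonexistent_a", "b", "c"])
        assert np.allclose(scores, 100.0 * expit(model.intercept_))

    def test_label_swap_symmetry(self):
        """Refitting with the positive/negative classes swapped yields
        scores s' = 100 - s on an overlapping single-gene fixture."""
        rng = np.random.default_rng(12)
        n = 60
        y = np.repeat([True, False], n // 2)
        x = rng.normal(0, 1, n) + 1.2 * y  # overlapping -> unique MLE
        X = x.reshape(-1, 1)
        kw = dict(max_genes=1, min_cells=0, random_state=0)
        a = g.IdentityScorer(**kw).fit(X, y, feature_names=["x"])
        b = g.IdentityScorer(**kw).fit(X, ~y, feature_names=["x"])
        assert np.abs(a.identity_score(X) + b.identity_score(X) - 100.0).max() < 1e-3

    def test_score_cells_writes_obs_columns(self, small_scored):
        assert {"sci", "gci"} <= set(small_scored.obs.columns)


def test_model_serialization_round_trip(tmp_path, small_models):
    model = small_models["sertoli"]
    g.save_model(model.to_dict(), tmp_path / "m.json")
    back = g.load_model(tmp_path / "m.json")
    assert back["genes"] == model.selected_genes_
    assert np.allclose(back["coefficients"], model.coef_)
    assert back["target"] == "Sertoli"
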