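"""Multiverse enumeration, arm fitting, ranking and benchmark comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import factorverse as fv
import factorverse.multiverse as mv
from factorverse.exceptions import InvalidArgumentError


@pytest.fixture(scope="module")
def planted_world():
    """3 questionnaires, 2 factors; the outcome loads only on the factor
    dominating questionnaires Q1/Q2 — a planted winner for the ranking."""
    spec = fv.build_default_spec(3, [8, 8, 8], 2, seed=5)
    cog = fv.CognitionSpec("model_based_planning", {"F1": -0.05},
                           covariate_effects={"age": -0.1})
    datasets = []
    for i in range(3):
        ds = fv.simulate_responses(spec, 700, seed=50 + i)
        ds.name = "discovery" if i == 0 else f"replication_{i}"
        ds = fv.attach_cognition(ds, cog, seed=60 + i,
                                 factor_corr=spec.factor_corr)
        datasets.append(ds)
    return spec, datasets


@pytest.fixture(scope="module")
def planted_R(planted_world):
    _, datasets = planted_world
    return fv.heterogeneous_matrix(datasets[0].responses)


class TestEnumeration:
    def test_nine_questionnaires_511_subsets(self):
        subsets = fv.enumerate_subsets([f"Q{i}" for i in range(9)])
        assert len(subsets) == 511

    def test_small_counts(self):
        assert len(fv.enumerate_subsets(["a", "b", "c"])) == 7
        assert fv.enumerate_subsets(["only"]) == [("only",)]

    def test_duplicates_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fv.enumerate_subsets(["a", "a"])

    def test_deterministic_order(self):
        subsets = fv.enumerate_subsets(["b", "a", "c"])
        sizes = [len(s) for s in subsets]
        assert sizes == sorted(sizes)
        assert subsets[0] == ("a",)

    def test_combination_candidate_total(self):
        assert mv.count_candidates(9, 5) == 7665

    @settings(deadline=None, max_examples=45, derandomize=True)
    @given(st.integers(1, 9), st.integers(1, 5))
    def test_grid_matches_closed_form(self, q, k_max):
        labels = [f"Q{i}" for i in range(q)]
        grid = mv.combination_grid(labels, k_max)
        assert len(grid) == (2 ** q - 1) * k_max
        assert sum(k for _, k in grid) == mv.count_candidates(q, k_max)


class TestArms:
    def test_factor_number_counts(self, planted_world, planted_R):
        _, datasets = planted_world
        cands = fv.run_factor_number_arm(datasets[0], 2, R=planted_R)
        assert len(cands) == 3  # 1 + 2
        ids = {c.candidate_id for c in cands}
        assert len(ids) == 3

    def test_combination_counts_and_subset_contract(self, planted_world,
                                                    planted_R):
        _, datasets = planted_world
        cands = fv.run_combination_arm(datasets[0], 2, R=planted_R,
                                       questionnaires=["Q1", "Q2"])
        assert len(cands) == 9  # 3 subsets x (1 + 2)
        qmap = datasets[0].questionnaires()
        for c in cands:
            allowed = {i for q in c.questionnaire_subset for i in qmap[q]}
            assert set(c.item_weights.index) == allowed

    def test_rotation_counts_and_orthogonality(self, planted_world, planted_R):
        _, datasets = planted_world
        disc = datasets[0]
        cands = fv.run_rotation_arm(disc, 2, R=planted_R)
        assert len(cands) == 7  # 2 + 2 + (2 + 1)
        bif = [c for c in cands if "bifactor" in c.candidate_id]
        scores = np.column_stack([c.score(disc.responses).scores for c in bif])
        C = (scores.T @ scores) / len(scores)
        np.testing.assert_allclose(C, np.eye(3), atol=1e-6)

    def test_oblimin_varimax_scores_agree(self, planted_world, planted_R):
        _, datasets = planted_world
        disc = datasets[0]
        cands = fv.run_rotation_arm(disc, 2, R=planted_R)
        obl = [c for c in cands if "oblimin" in c.candidate_id]
        var = [c for c in cands if "varimax" in c.candidate_id]
        so = np.column_stack([c.score(disc.responses).scores for c in obl])
        sv = np.column_stack([c.score(disc.responses).scores for c in var])
        C = np.abs(np.corrcoef(so.T, sv.T)[:2, 2:])
        assert (C.max(axis=1) > 0.9).all()


class TestEvaluate:
    def test_planted_winner_recovered(self, planted_world, planted_R):
        """A candidate dominated by the effect-carrying block ranks first."""
        _, datasets = planted_world
        disc = datasets[0]
        cands = fv.run_combination_arm(disc, 2, R=planted_R)
        table = fv.evaluate_candidates(cands, datasets,
                                       "model_based_planning",
                                       "most_negative", conditioning="alone")
        win = table.winner()
        # winner should draw on the planted factor's questionnaires (Q1/Q3
        # dominate F1 under round-robin assignment Q1->F1, Q2->F2, Q3->F1)
        assert win["rank"] == 1.0
        assert win["f2_weighted"] < -0.02
        assert "Q2" != win["questionnaire_subset"]

    def test_rank_is_permutation_and_percentile_formula(self, planted_world,
                                                        planted_R):
        _, datasets = planted_world
        cands = fv.run_factor_number_arm(datasets[0], 2, R=planted_R)
        table = fv.evaluate_candidates(cands, datasets,
                                       "model_based_planning",
                                       "most_negative")
        t = table.table
        ranks = sorted(t["rank"])
        assert ranks == [1.0, 2.0, 3.0]
        m = len(t)
        for _, row in t.iterrows():
            worse = (t["f2_weighted"] > row["f2_weighted"]).sum()
            assert row["percentile_beaten"] == pytest.approx(
                100.0 * worse / (m - 1))

    def test_top_rank_percentile_100(self, planted_world, planted_R):
        _, datasets = planted_world
        cands = fv.run_factor_number_arm(datasets[0], 1, R=planted_R)
        table = fv.evaluate_candidates(cands, datasets,
                                       "model_based_planning", "most_negative")
        assert table.table["percentile_beaten"].iloc[0] == 100.0

    def test_identical_candidates_tie_at_rank_one(self, planted_world,
                                                  planted_R):
        _, datasets = planted_world
        cands = fv.run_factor_number_arm(datasets[0], 1, R=planted_R)
        import copy
        clone = copy.deepcopy(cands[0])
        clone.candidate_id = "clone"
        clone.solution_key = "clone"
        table = fv.evaluate_candidates(cands + [clone], datasets,
                                       "model_based_planning", "most_negative")
        assert (table.table["rank"] == 1.0).all()

    def test_dataset_order_invariance(self, planted_world, planted_R):
        _, datasets = planted_world
        cands = fv.run_factor_number_arm(datasets[0], 2, R=planted_R)
        t1 = fv.evaluate_candidates(cands, datasets,
                                    "model_based_planning", "most_negative")
        t2 = fv.evaluate_candidates(cands, datasets[::-1],
                                    "model_based_planning", "most_negative")
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_non_converged_excluded_from_ranking(self, planted_world,
                                                 planted_R):
        _, datasets = planted_world
        cands = fv.run_factor_number_arm(datasets[0], 2, R=planted_R)
        cands[0].converged = False
        table = fv.evaluate_candidates(cands, datasets,
                                       "model_based_planning", "most_negative")
        row = table.table.set_index("candidate_id").loc[cands[0].candidate_id]
        assert np.isnan(row["rank"])
        assert cands[0].candidate_id in table.excluded
        cands[0].converged = True


class TestCompareToBenchmark:
    def test_self_comparison(self, planted_world, planted_R):
        _, datasets = planted_world
        cands = fv.run_factor_number_arm(datasets[0], 1, R=planted_R)
        out = fv.compare_to_benchmark(cands[0], cands[0], datasets[0])
        assert out.score_correlation == pytest.approx(1.0)
        assert out.loading_correlation == pytest.approx(1.0)

    def test_negated_weights_sign_aligned(self, planted_world, planted_R):
        _, datasets = planted_world
        cands = fv.run_factor_number_arm(datasets[0], 1, R=planted_R)
        import copy
        neg = copy.deepcopy(cands[0])
        neg.item_weights = -neg.item_weights
        neg.item_loadings = -neg.item_loadings
        out = fv.compare_to_benchmark(neg, cands[0], datasets[0])
        assert out.flipped
        assert out.score_correlation == pytest.approx(1.0)
        assert out.loading_correlation == pytest.approx(1.0)

    def test_latent_correlation_recovered_without_alignment(self):
        """Two planted factors correlated 0.5: highly reliable sum-score
        candidates (40 clean items each) recover the latent correlation."""
        spec0 = fv.build_default_spec(2, [40, 40], 2, seed=8)
        Phi = np.array([[1.0, 0.5], [0.5, 1.0]])
        # strip cross-loadings so each sum score measures one factor only
        L = spec0.loading_matrix.copy()
        qmap = spec0.questionnaires()
        L.loc[qmap["Q1"], "F2"] = 0.0
        L.loc[qmap["Q2"], "F1"] = 0.0
        spec = fv.LatentSpec(
            loading_matrix=L, factor_corr=Phi,
            item_thresholds=spec0.item_thresholds,
            questionnaire_of_item=spec0.questionnaire_of_item,
            n_categories=spec0.n_categories)
        ds = fv.simulate_responses(spec, 5000, seed=77)
        ds.name = "discovery"
        means = ds.responses.mean()
        sds = ds.responses.std(ddof=0)

        def sum_candidate(label):
            weights = pd.Series(0.0, index=ds.responses.columns)
            weights[qmap[label]] = 1.0
            return fv.CandidateDimension(
                candidate_id=f"sum_{label}", arm="combination",
                questionnaire_subset=("Q1", "Q2"), k=1, factor_index=1,
                item_weights=weights, item_loadings=L[
                    {"Q1": "F1", "Q2": "F2"}[label]],
                converged=True, scale_means=means, scale_sds=sds,
                solution_key=f"sum_{label}")

        out = fv.compare_to_benchmark(sum_candidate("Q1"), sum_candidate("Q2"),
                                      ds, sign_align=False)
        # sum scores carry small reliability attenuation below the planted 0.5
        assert abs(out.score_correlation) == pytest.approx(0.5, abs=0.05)
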