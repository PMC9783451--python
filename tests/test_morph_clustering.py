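"""Trait matrix assembly, Ward.D2 agglomeration, gap statistic, classification."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage

from morphsong import morph_clustering as mc
from morphsong import synthetic_cohort as sc
from morphsong.pipeline import PipelineConfig, cohort_feature_table


def song_row(ind, song_type, base=0.0):
    row = {"individual_id": ind, "song_type": song_type}
    rel = np.full(6, 1 / 6)
    row.update(
        {
            "dominant_frequency": 5000.0 + base,
            "amplitude_db": -20.0 + base,
            "frequency_evenness": -0.2 + base / 100,
        }
    )
    for lab, v in zip("ABCDEF", rel):
        row[f"rel_amplitude_{lab}"] = v + base / 1000
    return row


def wing_row(ind, base=0.0, file_gaps=None):
    row = {
        "individual_id": ind,
        "harp_width": 2.0 + base,
        "mirror_size": 1.5 + base,
        "scraper_present": int(base < 1),
        "mirror_present": int(base < 2),
        "file_gaps_present": int(base > 1) if file_gaps is None else file_gaps,
    }
    for i in range(1, 11):
        row[f"shape_pc{i}"] = base * i / 10
    return row


class TestAssembleTraitMatrix:
    def test_complete_case_filter_drops_and_reports(self):
        songs = pd.DataFrame(
            [song_row("a", "calling", 0), song_row("a", "courtship", 1),
             song_row("b", "calling", 2),  # b is missing its courtship song
             song_row("c", "calling", 3), song_row("c", "courtship", 4)]
        )
        wings = pd.DataFrame([wing_row("a", 0), wing_row("b", 1), wing_row("c", 2)])
        matrix = mc.assemble_trait_matrix(songs, wings)
        assert set(matrix.individuals) == {"a", "c"}
        assert matrix.dropped == ("b",)

    def test_columns_scaled_to_mean_zero_unit_sd(self, matrix42):
        values = matrix42.values
        np.testing.assert_allclose(values.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(values.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_default_cohort_yields_59_by_33(self, matrix42):
        assert matrix42.shape == (59, 33)

    def test_zero_variance_trait_named(self):
        songs = []
        for ind, base in [("a", 0.0), ("b", 1.0), ("c", 2.0)]:
            songs.append(song_row(ind, "calling", base))
            songs.append(song_row(ind, "courtship", base + 0.5))
        wings = pd.DataFrame(
            [wing_row("a", 0, file_gaps=0), wing_row("b", 1, file_gaps=0),
             wing_row("c", 2, file_gaps=0)]
        )
        with pytest.raises(ValueError, match="zero-variance.*file_gaps_present"):
            mc.assemble_trait_matrix(pd.DataFrame(songs), wings)

    def test_disjoint_ids_error(self):
        songs = pd.DataFrame(
            [song_row("a", "calling"), song_row("a", "courtship")]
        )
        wings = pd.DataFrame([wing_row("z")])
        with pytest.raises(ValueError, match="shared"):
            mc.assemble_trait_matrix(songs, wings)


class TestWardCluster:
    def test_two_points_merge_at_their_distance(self):
        x = np.array([[0.0, 0.0], [3.0, 4.0]])
        result = mc.ward_cluster(x)
        assert result.merges.shape == (1, 4)
        assert result.heights[0] == pytest.approx(5.0)

    def test_collinear_points_first_merge_is_closest_pair(self):
        x = np.array([[0.0], [1.0], [10.0]])
        result = mc.ward_cluster(x)
        assert result.heights[0] == pytest.approx(1.0)
        assert set(result.merges[0, :2]) == {0, 1}

    def test_matches_reference_ward_d2_heights(self):
        x = np.random.default_rng(3).normal(size=(20, 5))
        mine = mc.ward_cluster(x).merges
        ref = linkage(x, method="ward")
        np.testing.assert_allclose(mine[:, 2], ref[:, 2], atol=1e-8)
        np.testing.assert_array_equal(mine[:, 3], ref[:, 3])

    def test_heights_monotone_non_decreasing(self, matrix42):
        heights = mc.ward_cluster(matrix42).heights
        assert np.all(np.diff(heights) >= -1e-10)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match="two rows"):
            mc.ward_cluster(np.ones((1, 3)))

    def test_duplicate_rows_allowed(self):
        x = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        result = mc.ward_cluster(x)
        assert result.heights[0] == pytest.approx(0.0)

    def test_newick_export_parses(self, matrix42):
        import dendropy

        tree_str = mc.to_newick(mc.ward_cluster(matrix42))
        tree = dendropy.Tree.get(data=tree_str, schema="newick")
        assert len(tree.leaf_nodes()) == 59


class TestGapStatistic:
    def test_single_blob_selects_one_cluster(self):
        blob = np.random.default_rng(7).normal(0, 1, size=(40, 4))
        assert mc.gap_statistic(blob, k_max=6, B=50, seed=7).best_k == 1

    def test_three_separated_blobs_select_three(self):
        rng = np.random.default_rng(7)
        centers = np.array([[0, 0, 0], [8, 0, 0], [0, 8, 0]])
        x = np.vstack([rng.normal(c, 1, size=(20, 3)) for c in centers])
        assert mc.gap_statistic(x, k_max=8, B=50, seed=7).best_k == 3

    def test_seeded_determinism(self, matrix42):
        a = mc.gap_statistic(matrix42, k_max=6, B=20, seed=5)
        b = mc.gap_statistic(matrix42, k_max=6, B=20, seed=5)
        assert np.array_equal(a.gap, b.gap)
        assert a.best_k == b.best_k

    def test_row_order_invariance(self):
        rng = np.random.default_rng(8)
        x = np.vstack(
            [rng.normal(0, 1, (15, 3)), rng.normal(9, 1, (15, 3))]
        )
        perm = rng.permutation(len(x))
        a = mc.gap_statistic(x, k_max=5, B=20, seed=4)
        b = mc.gap_statistic(x[perm], k_max=5, B=20, seed=4)
        np.testing.assert_allclose(a.gap, b.gap, atol=1e-9)
        assert a.best_k == b.best_k

    def test_invalid_parameters(self, matrix42):
        with pytest.raises(ValueError, match="k_max"):
            mc.gap_statistic(matrix42, k_max=0, B=20)
        with pytest.raises(ValueError, match="B"):
            mc.gap_statistic(matrix42, k_max=3, B=5)

    def test_best_k_rules_agree_on_obvious_structure(self):
        rng = np.random.default_rng(9)
        x = np.vstack([rng.normal(0, 1, (20, 2)), rng.normal(12, 1, (20, 2))])
        for rule in ("firstSEmax", "globalSEmax", "Tibs2001SEmax", "firstmax"):
            assert mc.gap_statistic(x, k_max=5, B=30, seed=2, rule=rule).best_k == 2


class TestMorphRecovery:
    def test_clusters_match_generator_labels(self, matrix42, truth42):
        labels = mc.cut_tree(mc.ward_cluster(matrix42), 3)
        truth = truth42.loc[list(matrix42.individuals), "morph"]
        agreement = (
            pd.crosstab(truth.values, labels).max(axis=0).sum() / len(labels)
        )
        assert agreement >= 0.95

    @pytest.mark.parametrize("seed", range(1, 6))
    def test_recovery_across_seeds(self, seed):
        cohort = sc.generate_cohort(sc.CohortSpec(seed=seed, n_individuals=45))
        song_df, wing_df = cohort_feature_table(cohort, PipelineConfig(seed=seed))
        matrix = mc.assemble_trait_matrix(song_df, wing_df)
        labels = mc.cut_tree(mc.ward_cluster(matrix), 3)
        truth = cohort.truth.set_index("individual_id").loc[
            list(matrix.individuals), "morph"
        ]
        agreement = (
            pd.crosstab(truth.values, labels).max(axis=0).sum() / len(labels)
        )
        assert agreement >= 0.95


class TestClassifyNearestCentroid:
    def training(self):
        rng = np.random.default_rng(10)
        rows = {}
        labels = {}
        for m, (amp, freq) in {
            "ancestral": (-12.0, 4800.0),
            "purring": (-32.0, 9000.0),
            "rattling": (-18.0, 6500.0),
        }.items():
            for i in range(5):
                rid = f"{m}{i}"
                rows[rid] = {
                    "mirror_present": 0 if m == "purring" else 1,
                    "harp_width": 1.4 if m == "purring" else 2.5,
                    "calling_amplitude_db": amp + rng.normal(0, 1),
                    "calling_frequency_evenness": -0.2,
                    "calling_dominant_frequency": freq + rng.normal(0, 100),
                    "file_gaps_present": 1 if m == "rattling" else 0,
                }
                labels[rid] = m
        return pd.DataFrame(rows).T, pd.Series(labels)

    def test_exact_centroid_match_distance_zero(self):
        training, labels = self.training()
        centroid = training.loc[labels == "rattling"].mean().to_frame("cand").T
        out = mc.classify_nearest_centroid(centroid, training, labels)
        assert out[0].morph == "rattling"
        assert out[0].distances["rattling"] == pytest.approx(0.0, abs=1e-9)

    def test_purring_without_courtship_classified(self, features42, matrix42, truth42):
        song_df, wing_df = features42
        # candidate built from calling + wing traits only (no courtship columns)
        from morphsong.pipeline import _individual_feature_table

        features = _individual_feature_table(song_df, wing_df)
        train_ids = list(matrix42.individuals)
        purring_ids = truth42.index[truth42.morph == "purring"]
        candidate = features.loc[
            [purring_ids[0]],
            [c for c in features.columns if not c.startswith("courtship")],
        ]
        out = mc.classify_nearest_centroid(
            candidate,
            features.loc[train_ids],
            truth42.loc[train_ids, "morph"],
        )
        assert out[0].morph == "purring"
        assert out[0].method == "rule_classified"

    def test_tie_goes_to_first_morph_with_warning(self):
        training = pd.DataFrame(
            {
                "t1": {"a1": 0.0, "a2": 0.0, "b1": 2.0, "b2": 2.0},
                "t2": {"a1": 1.0, "a2": -1.0, "b1": 1.0, "b2": -1.0},
            }
        )
        labels = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        candidate = pd.DataFrame({"t1": {"c": 1.0}, "t2": {"c": 0.0}})
        with pytest.warns(UserWarning, match="equidistant"):
            out = mc.classify_nearest_centroid(
                candidate, training, labels, diagnostic_traits=("t1", "t2")
            )
        assert out[0].morph == "A"

    def test_no_diagnostic_traits_error(self):
        training, labels = self.training()
        candidate = pd.DataFrame({"unrelated": {"c": 1.0}})
        with pytest.raises(ValueError, match="diagnostic"):
            mc.classify_nearest_centroid(candidate, training, labels)
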