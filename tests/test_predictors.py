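import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crhunter.predictors import (
    NO_TEMPLATE,
    SCORE_COLUMNS,
    CRHunterModel,
    FeatureCache,
    FusionConfig,
    SVMConfig,
    TemplateHit,
    build_structural_vectors,
    build_sequence_vectors,
    crhunter_score,
    fuse,
    read_template_hits,
    scale_features,
    template_predict,
    train_feature_predictor,
    write_template_hits,
)
from crhunter.tessellation import ResidueContactGraph


class TestScaleFeatures:
    def _table(self):
        return pd.DataFrame(
            {
                "pssm_A": [0.0, 2.0, -2.0],
                "is_H": [1.0, 0.0, 1.0],
                "other": [1.0, 2.0, 3.0],
                "flat": [5.0, 5.0, 5.0],
            }
        )

    def test_pssm_logistic_maps_zero_to_half(self):
        scaled, _ = scale_features(self._table(), {"pssm_A"}, {"is_H"})
        assert scaled.loc[0, "pssm_A"] == pytest.approx(0.5)
        assert scaled.loc[1, "pssm_A"] == pytest.approx(1 / (1 + np.exp(-2.0)))

    def test_training_mean_maps_to_half(self):
        scaled, _ = scale_features(self._table(), {"pssm_A"}, {"is_H"})
        assert scaled.loc[1, "other"] == pytest.approx(0.5)  # 2.0 is the mean

    def test_binary_columns_untouched_and_zero_variance_constant(self):
        scaled, _ = scale_features(self._table(), {"pssm_A"}, {"is_H"})
        assert scaled["is_H"].tolist() == [1.0, 0.0, 1.0]
        assert (scaled["flat"] == 0.5).all()

    def test_stats_reused_at_prediction_time(self):
        train = self._table()
        _, stats = scale_features(train, {"pssm_A"}, {"is_H"})
        test = train.copy()
        test["other"] = [10.0, 20.0, 30.0]
        scaled, _ = scale_features(test, {"pssm_A"}, {"is_H"}, stats)
        sd = train["other"].std(ddof=0)
        expected = 1 / (1 + np.exp(-(10.0 - 2.0) / sd))
        assert scaled.loc[0, "other"] == pytest.approx(expected)

    def test_unknown_column_rejected(self):
        with pytest.raises(ValueError, match="nope"):
            scale_features(self._table(), {"nope"}, set())

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_outputs_in_open_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        table = pd.DataFrame(
            {"pssm_A": rng.normal(0, 50, 10), "x": rng.normal(3, 9, 10)}
        )
        scaled, _ = scale_features(table, {"pssm_A"}, set())
        assert ((scaled > 0) & (scaled < 1)).all().all()


class TestStructuralVectors:
    def _graph(self, counts, n=6):
        return ResidueContactGraph(n, counts)

    def _table(self, n=6, f=3):
        return pd.DataFrame(np.arange(n * f, dtype=float).reshape(n, f))

    def test_padding_with_indicators(self):
        graph = self._graph({(0, 1): 12, (0, 2): 10}, n=6)
        vectors = build_structural_vectors(self._table(), graph, window=4)
        f = 3
        assert vectors.shape == (6, f + 4 * (f + 1))
        row = vectors[0]
        np.testing.assert_allclose(row[:3], [0, 1, 2])  # target block
        np.testing.assert_allclose(row[3:7], [3, 4, 5, 0])  # neighbor 1 (res 1)
        np.testing.assert_allclose(row[7:11], [6, 7, 8, 0])  # neighbor 2 (res 2)
        np.testing.assert_allclose(row[11:15], [0, 0, 0, 1])  # padded
        np.testing.assert_allclose(row[15:19], [0, 0, 0, 1])  # padded

    def test_window_zero_is_target_only(self):
        graph = self._graph({(0, 1): 12})
        vectors = build_structural_vectors(self._table(), graph, window=0)
        np.testing.assert_allclose(vectors, self._table().to_numpy())

    def test_neighbor_order_matches_microenvironment(self):
        from crhunter.tessellation import microenvironment

        graph = self._graph({(0, 1): 9, (0, 4): 15, (0, 5): 9}, n=6)
        vectors = build_structural_vectors(self._table(), graph, window=3)
        order = [j for j, _ in microenvironment(graph, 0, 9)]
        assert order == [4, 1, 5]
        f = 3
        for slot, j in enumerate(order):
            block = vectors[0, f + slot * (f + 1) : f + (slot + 1) * (f + 1)]
            np.testing.assert_allclose(block[:f], self._table().to_numpy()[j])


class TestTrainFeaturePredictor:
    def _toy(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([1] * (n // 3) + [0] * (2 * n // 3))
        x = rng.normal(size=(len(y), 2)) + np.where(y[:, None] == 1, 6.0, 0.0)
        return x, y

    def test_separable_toy_perfect_training_accuracy(self):
        x, y = self._toy()
        model = train_feature_predictor(x, y, SVMConfig(seed=3))
        pred = (model.predict(x[model.training_indices]) >= 0.5).astype(int)
        assert (pred == y[model.training_indices]).all()

    def test_same_seed_identical_subsample_and_predictions(self):
        x, y = self._toy(seed=1)
        m1 = train_feature_predictor(x, y, SVMConfig(seed=11))
        m2 = train_feature_predictor(x, y, SVMConfig(seed=11))
        np.testing.assert_array_equal(m1.training_indices, m2.training_indices)
        np.testing.assert_array_equal(m1.predict(x), m2.predict(x))

    def test_subsample_respects_ratio(self):
        x, y = self._toy(n=90)
        model = train_feature_predictor(x, y, SVMConfig(seed=0, neg_pos_ratio=1.5))
        labels = y[model.training_indices]
        assert labels.sum() == 30
        assert (labels == 0).sum() == 45

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            train_feature_predictor(np.zeros((4, 2)), np.zeros(4), SVMConfig())


class TestTemplatePredict:
    def test_catalytic_transfer(self):
        hits = [TemplateHit("t1", 0.9, {0: 5, 1: 6, 2: 7})]
        scores, best = template_predict(4, hits, {"t1": {6}})
        np.testing.assert_allclose(scores, [0, 1, 0, 0])
        assert best == 0.9

    def test_empty_hits_sentinel(self):
        scores, best = template_predict(3, [], {})
        np.testing.assert_allclose(scores, 0.0)
        assert best == NO_TEMPLATE

    def test_top_hit_selected_with_tie_break(self):
        hits = [
            TemplateHit("b", 0.8, {0: 0}),
            TemplateHit("a", 0.8, {0: 1}),
        ]
        scores, _ = template_predict(1, hits, {"a": {1}, "b": set()})
        assert scores[0] == 1.0  # tie broken to template id 'a'

    @pytest.mark.parametrize("seed", range(5))
    def test_score_sum_equals_set_intersection(self, seed):
        rng = np.random.default_rng(seed)
        n, t = 30, 40
        tpos = rng.choice(t, size=20, replace=False)
        mapping = {int(q): int(tpos[k]) for k, q in enumerate(rng.choice(n, 20, replace=False))}
        catalytic = set(int(v) for v in rng.choice(t, size=8, replace=False))
        scores, _ = template_predict(n, [TemplateHit("t", 0.7, mapping)], {"t": catalytic})
        assert scores.sum() == len({q for q, tp in mapping.items() if tp in catalytic})

    def test_out_of_range_template_position(self):
        hits = [TemplateHit("t", 0.9, {0: 99})]
        with pytest.raises(IndexError):
            template_predict(2, hits, {"t": {1}}, template_lengths={"t": 10})

    def test_mapping_must_be_injective(self):
        with pytest.raises(ValueError):
            TemplateHit("t", 0.9, {0: 1, 1: 1})


class TestFusion:
    def test_above_cutoff_blend_hand_arithmetic(self):
        fused = fuse(np.array([0.8]), np.array([1.0]), 0.7, weight=0.55, cutoff=0.6)
        assert fused[0] == pytest.approx(0.55 * 0.8 + 0.45 * 1.0)
        assert fused[0] == pytest.approx(0.89)

    def test_below_cutoff_returns_feature_score_bitwise(self):
        fscore = np.array([0.123456789, 0.9, 0.0])
        fused = fuse(fscore, np.array([1.0, 1.0, 1.0]), 0.5, weight=0.55, cutoff=0.6)
        assert (fused == fscore).all()

    def test_zero_template_scores_scale_by_weight(self):
        fscore = np.array([0.4, 0.6])
        fused = fuse(fscore, np.zeros(2), 0.9, weight=0.55, cutoff=0.6)
        np.testing.assert_allclose(fused, 0.55 * fscore)

    def test_crhunter_blend(self):
        assert crhunter_score(np.array([0.9]), np.array([0.3]), 0.5)[0] == pytest.approx(0.6)
        str_scores = np.array([0.1, 0.7])
        np.testing.assert_array_equal(crhunter_score(str_scores, np.zeros(2), 1.0), str_scores)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_fusion_monotone_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.random(5)
        t = rng.integers(0, 2, 5).astype(float)
        cfg = FusionConfig()
        fused = fuse(f, t, 0.9, cfg.alpha, cfg.sp_cutoff)
        assert ((fused >= 0) & (fused <= 1)).all()
        bumped = fuse(np.minimum(f + 0.05, 1.0), t, 0.9, cfg.alpha, cfg.sp_cutoff)
        assert (bumped >= fused).all()
        blended = crhunter_score(fused, rng.random(5), cfg.gamma)
        assert ((blended >= 0) & (blended <= 1)).all()


class TestTemplateHitIO:
    def test_round_trip(self, tmp_path):
        hits = {
            "q1": [TemplateHit("t1", 0.91, {0: 0, 2: 3}), TemplateHit("t2", 0.4, {1: 1})],
            "q2": [TemplateHit("t3", 0.7, {})],
        }
        path = tmp_path / "hits.tsv"
        write_template_hits(hits, path)
        loaded = read_template_hits(path)
        assert loaded["q1"][0].template_id == "t1"
        assert loaded["q1"][0].mapping == {0: 0, 2: 3}
        assert loaded["q1"][1].similarity == pytest.approx(0.4)
        assert loaded["q2"][0].mapping == {}


class TestEndToEndModel:
    @pytest.fixture(scope="class")
    def model(self, small_bench, small_cache):
        return CRHunterModel.fit(
            small_bench.records,
            template_annotations=small_bench.template_annotations,
            svm_config=SVMConfig(seed=5),
            cache=small_cache,
        )

    def test_score_columns_and_ranges(self, model, small_bench, small_cache):
        scored = model.predict(small_bench.records[0], cache=small_cache)
        assert list(scored.columns) == SCORE_COLUMNS
        assert set(np.unique(scored["tscore_str"])) <= {0.0, 1.0}
        for column in SCORE_COLUMNS:
            assert scored[column].between(0, 1).all()

    def test_without_templates_hybrid_equals_feature(self, model, small_bench, small_cache):
        from dataclasses import replace

        record = replace(small_bench.records[1], str_hits=[], seq_hits=[])
        scored = model.predict(record, cache=small_cache)
        assert (scored["strhunter"] == scored["fscore_str"]).all()
        assert (scored["seqhunter"] == scored["fscore_seq"]).all()
        np.testing.assert_array_equal(
            scored["crhunter"],
            0.5 * scored["fscore_str"] + 0.5 * scored["fscore_seq"],
        )

    def test_model_persistence_round_trip(self, model, small_bench, small_cache, tmp_path):
        path = tmp_path / "model.joblib"
        model.save(path)
        reloaded = CRHunterModel.load(path)
        a = model.predict(small_bench.records[2], cache=small_cache)
        b = reloaded.predict(small_bench.records[2], cache=small_cache)
        pd.testing.assert_frame_equal(a, b)
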