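import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from engdd.config import RunConfig
from engdd.data_io import InteractionSet
from engdd.ensemble import (EnsembleWeights, classify, rank_candidates,
                            simplex_grid, soft_vote, train_engdd,
                            tune_weights)
from engdd.grownet import predict_grownet
from engdd.metrics import pr_auc


def small_cfg(**kw) -> RunConfig:
    """Desk-scale hyperparameters for fast end-to-end tests."""
    cfg = RunConfig()
    cfg.grownet.num_nets = 3
    cfg.dnn.epochs = 10
    cfg.cascade.n_trees = 10
    cfg.cascade.max_layers = 2
    cfg.pca.d = 8
    for k, v in kw.items():
        setattr(cfg.ensemble, k, v)
    return cfg


@pytest.fixture(scope="module")
def tiny_dataset(tiny_world):
    from engdd.features import apply_pca, build_pairs, fit_pca
    from engdd.sampling_cv import sample_negatives
    drugs, targets, inter, _ = tiny_world
    neg = sample_negatives(inter, drugs.entity_ids, targets.entity_ids,
                           1.0, seed=5)
    pd_ = fit_pca(drugs, 8)
    pt = fit_pca(targets, 8)
    return build_pairs(apply_pca(pd_, drugs), drugs.entity_ids,
                       apply_pca(pt, targets), targets.entity_ids,
                       inter, neg.pairs)


class TestSoftVote:
    def test_vertex_weight_returns_component(self):
        pg, pd_, pf = np.array([0.2, 0.7]), np.array([0.9, 0.1]), \
            np.array([0.5, 0.5])
        out = soft_vote(pg, pd_, pf, EnsembleWeights(1, 0, 0))
        np.testing.assert_array_equal(out, pg)

    def test_equal_weights_are_arithmetic_mean(self):
        out = soft_vote(np.array([0.9]), np.array([0.6]), np.array([0.3]),
                        EnsembleWeights(1 / 3, 1 / 3, 1 / 3))
        assert out[0] == pytest.approx(0.6)

    def test_constant_inputs_fixed_point(self):
        c = np.full(4, 0.37)
        out = soft_vote(c, c, c, EnsembleWeights(0.2, 0.3, 0.5))
        np.testing.assert_allclose(out, 0.37)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            soft_vote(np.zeros(2), np.zeros(3), np.zeros(2),
                      EnsembleWeights(1, 0, 0))

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            EnsembleWeights(-0.1, 0.6, 0.5)

    def test_off_simplex_rejected(self):
        with pytest.raises(ValueError):
            EnsembleWeights(0.5, 0.5, 0.5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_bounded_by_component_range(self, seed):
        rng = np.random.default_rng(seed)
        pg, pd_, pf = rng.random((3, 10))
        a = rng.random(3)
        a /= a.sum()
        out = soft_vote(pg, pd_, pf, EnsembleWeights(*a))
        stack = np.vstack([pg, pd_, pf])
        assert (out >= stack.min(axis=0) - 1e-12).all()
        assert (out <= stack.max(axis=0) + 1e-12).all()


class TestClassify:
    def test_threshold_is_strict(self):
        np.testing.assert_array_equal(
            classify(np.array([0.5, 0.49, 0.51])), [0, 0, 1])

    def test_all_ones(self):
        assert classify(np.ones(3)).sum() == 3


class TestTuneWeights:
    def test_grid_has_66_points_at_step_point_one(self):
        assert len(simplex_grid(0.1)) == 66

    def test_perfect_component_gets_vertex(self):
        rng = np.random.default_rng(0)
        y = np.r_[np.ones(30, dtype=int), np.zeros(30, dtype=int)]
        pg = np.r_[rng.uniform(0.8, 1.0, 30), rng.uniform(0.0, 0.2, 30)]
        pd_, pf = rng.random(60), rng.random(60)
        w = tune_weights(pg, pd_, pf, y)
        assert w.as_tuple() == (1.0, 0.0, 0.0)

    def test_never_worse_than_any_vertex(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 80)
        y[:2] = [0, 1]
        pg, pd_, pf = rng.random((3, 80))
        w = tune_weights(pg, pd_, pf, y)
        tuned = pr_auc(soft_vote(pg, pd_, pf, w), y)
        for vertex in [(1, 0, 0), (0, 1, 0), (0, 0, 1)]:
            s = soft_vote(pg, pd_, pf, EnsembleWeights(*vertex))
            assert tuned >= pr_auc(s, y) - 1e-12

    def test_single_class_validation_rejected(self):
        with pytest.raises(ValueError):
            tune_weights(np.zeros(3), np.zeros(3), np.zeros(3),
                         np.ones(3, dtype=int))


class TestTrainEngdd:
    def test_returns_valid_probabilities(self, tiny_dataset):
        model = train_engdd(tiny_dataset, small_cfg(), seed=0)
        p = model.predict_proba(tiny_dataset.X)
        assert ((p >= 0) & (p <= 1)).all()
        assert model.validation_auprs["ensemble"] >= max(
            model.validation_auprs[k]
            for k in ("grownet", "dnn", "cascade")) - 1e-12

    def test_forced_vertex_reduces_to_grownet(self, tiny_dataset):
        model = train_engdd(tiny_dataset, small_cfg(weights=(1, 0, 0)),
                            seed=0)
        np.testing.assert_allclose(
            model.predict_proba(tiny_dataset.X),
            predict_grownet(model.grownet, tiny_dataset.X), atol=1e-12)

    def test_fixed_seed_identical_weights(self, tiny_dataset):
        w1 = train_engdd(tiny_dataset, small_cfg(), seed=4).weights
        w2 = train_engdd(tiny_dataset, small_cfg(), seed=4).weights
        assert w1.as_tuple() == w2.as_tuple()


@pytest.fixture(scope="module")
def trained(tiny_world):
    from engdd.pipeline import train_full
    drugs, targets, inter, _ = tiny_world
    cfg = small_cfg()
    return train_full(drugs, targets, inter, cfg, seed=0), \
        drugs, targets, inter


class TestRankCandidates:
    def test_universe_smaller_than_k(self, trained):
        model, drugs, targets, inter = trained
        sub_d = drugs.restrict(drugs.entity_ids[:10])
        sub_t = targets.restrict(targets.entity_ids[:8])
        report = rank_candidates(model, sub_d, sub_t, inter, top_k=100)
        assert len(report.frame) == 80
        assert list(report.frame["rank"]) == list(range(1, 81))

    def test_known_pairs_flagged(self, trained):
        model, drugs, targets, inter = trained
        report = rank_candidates(model, drugs, targets, inter)
        flagged = {tuple(r) for r in
                   report.frame.loc[report.frame["known"],
                                    ["drug_id", "target_id"]].to_numpy()}
        assert flagged == inter.pairs

    def test_scores_match_per_pair_invocation(self, trained):
        from engdd.features import apply_pca
        model, drugs, targets, inter = trained
        report = rank_candidates(model, drugs, targets, inter)
        rows = report.frame.sample(10, random_state=0)
        dr = apply_pca(model.pca_drug, drugs)
        tr = apply_pca(model.pca_target, targets)
        d_idx = {e: i for i, e in enumerate(drugs.entity_ids)}
        t_idx = {e: i for i, e in enumerate(targets.entity_ids)}
        for _, row in rows.iterrows():
            x = np.hstack([dr[d_idx[row.drug_id]],
                           tr[t_idx[row.target_id]]])[None, :]
            assert model.predict_proba(x)[0] == pytest.approx(row.score,
                                                              abs=1e-9)
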