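"""Focal loss, GCN training/prediction, four-tier calls, NED screening."""

import numpy as np
import pytest

from gastrograph.classifier import (FourTierProbs, GcnModelState, GcnTrainConfig,
                                    ScreeningConfig, calibrate_screening_threshold,
                                    classify_four_tier, focal_loss, predict_four_tier,
                                    screen_slide, train_gcn)
from gastrograph.graphs import GraphConfig, GraphNode, SlideGraph, build_graph


class TestFourTierProbs:
    def test_valid_simplex(self):
        p = FourTierProbs(0.7, 0.1, 0.1, 0.1)
        assert p.as_array().sum() == pytest.approx(1.0)

    def test_rejects_non_simplex(self):
        with pytest.raises(ValueError):
            FourTierProbs(0.7, 0.1, 0.1, 0.2)
        with pytest.raises(ValueError):
            FourTierProbs(1.2, -0.2, 0.0, 0.0)


class TestFocalLoss:
    def test_certain_prediction_is_zero(self):
        assert focal_loss(FourTierProbs(1.0, 0.0, 0.0, 0.0), "NED") == 0.0

    def test_gamma_zero_is_cross_entropy(self):
        p = FourTierProbs(0.2, 0.3, 0.4, 0.1)
        assert focal_loss(p, "HGD", gamma=0.0, alpha=1.0) == pytest.approx(-np.log(0.4))

    def test_half_confidence_closed_form(self):
        # p_t = 0.5, gamma=2, alpha=1: 0.25 * ln 2
        p = FourTierProbs(0.5, 0.5, 0.0, 0.0)
        assert focal_loss(p, "LGD", gamma=2.0, alpha=1.0) == \
            pytest.approx(0.25 * np.log(2.0))

    def test_down_weights_easy_examples(self):
        easy = focal_loss(FourTierProbs(0.9, 0.1, 0.0, 0.0), "NED", gamma=2.0)
        hard = focal_loss(FourTierProbs(0.3, 0.7, 0.0, 0.0), "NED", gamma=2.0)
        ce_ratio = -np.log(0.9) / -np.log(0.3)
        assert easy / hard < ce_ratio  # focusing exponent shrinks easy losses more

    def test_invalid_class_raises(self):
        with pytest.raises(ValueError):
            focal_loss(FourTierProbs(1.0, 0.0, 0.0, 0.0), "BAD")


class TestClassifyFourTier:
    @pytest.mark.parametrize("probs,expected", [
        ((0.7, 0.1, 0.1, 0.1), "NED"),
        ((0.1, 0.2, 0.1, 0.6), "IIN"),
        ((0.25, 0.25, 0.25, 0.25), "IIN"),   # exact tie -> most severe
        ((0.4, 0.4, 0.1, 0.1), "LGD"),       # two-way tie -> more severe of the two
    ])
    def test_argmax_with_severity_tie_break(self, probs, expected):
        assert classify_four_tier(FourTierProbs(*probs)) == expected

    def test_matches_max_scan_on_random_simplexes(self, rng):
        for _ in range(200):
            arr = rng.dirichlet(np.ones(4))
            call = classify_four_tier(FourTierProbs.from_array(arr))
            idx = ["NED", "LGD", "HGD", "IIN"].index(call)
            assert arr[idx] == arr.max()


def _class_graphs(n_per_class=6, d=8, noise=0.1, seed=0, n_nodes=5):
    """Graphs whose node features cluster by class: easily separable."""
    rng = np.random.default_rng(seed)
    cats = ["NED", "LGD", "HGD", "IIN"]
    graphs = []
    for ci, cat in enumerate(cats):
        for k in range(n_per_class):
            center = np.zeros(d)
            center[ci] = 2.5
            nodes = [GraphNode(i, 0, i, float(rng.random()),
                               (center + noise * rng.standard_normal(d)).astype(np.float32))
                     for i in range(n_nodes)]
            graphs.append(build_graph(nodes, GraphConfig(n_nodes=n_nodes, gamma="auto"),
                                      slide_id=f"{cat}{k}", label=cat))
    return graphs


class TestTrainGcn:
    def test_seeded_determinism(self):
        graphs = _class_graphs(3)
        cfg = GcnTrainConfig(epochs=10, seed=9)
        m1 = train_gcn(graphs, cfg=cfg)
        m2 = train_gcn(graphs, cfg=cfg)
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])

    def test_learns_separable_graphs(self):
        graphs = _class_graphs(6)
        model = train_gcn(graphs, cfg=GcnTrainConfig(epochs=40, seed=0))
        calls = [classify_four_tier(predict_four_tier(model, g)) for g in graphs]
        acc = np.mean([c == g.label for c, g in zip(calls, graphs)])
        assert acc >= 0.9
        assert model.loss_trace[-1] < model.loss_trace[0]

    def test_single_node_graphs_train_and_predict(self):
        rng = np.random.default_rng(0)
        graphs = []
        for ci, cat in enumerate(["NED", "LGD", "HGD", "IIN"]):
            for k in range(2):
                f = np.zeros(4, dtype=np.float32)
                f[ci] = 1.0 + 0.05 * rng.standard_normal()
                nodes = [GraphNode(0, 0, 0, 0.5, f)]
                graphs.append(build_graph(nodes, GraphConfig(n_nodes=1, gamma=0.0),
                                          label=cat))
        model = train_gcn(graphs, cfg=GcnTrainConfig(epochs=5, seed=1))
        probs = predict_four_tier(model, graphs[0])
        assert probs.as_array().sum() == pytest.approx(1.0, abs=1e-6)

    def test_missing_labels_raise(self):
        graphs = _class_graphs(2)
        with pytest.raises(ValueError):
            train_gcn(graphs, labels=["NED"])


@pytest.fixture(scope="module")
def model_and_graphs():
    graphs = _class_graphs(4)
    return train_gcn(graphs, cfg=GcnTrainConfig(epochs=15, seed=2)), graphs


class TestPredictFourTier:
    def test_simplex_within_tolerance(self, model_and_graphs):
        model, graphs = model_and_graphs
        for g in graphs:
            assert abs(predict_four_tier(model, g).as_array().sum() - 1.0) < 1e-6

    def test_untrained_model_still_emits_simplex(self):
        graphs = _class_graphs(1)
        model = train_gcn(graphs, cfg=GcnTrainConfig(epochs=1, seed=3))
        assert predict_four_tier(model, graphs[0]).as_array().sum() == \
            pytest.approx(1.0, abs=1e-6)

    def test_node_permutation_invariance(self, model_and_graphs, rng):
        model, graphs = model_and_graphs
        g = graphs[5]
        perm = rng.permutation(len(g.nodes))
        permuted = SlideGraph(g.slide_id, [g.nodes[i] for i in perm],
                              g.adjacency[np.ix_(perm, perm)], g.gamma, g.label)
        a = predict_four_tier(model, g).as_array()
        b = predict_four_tier(model, permuted).as_array()
        assert np.allclose(a, b, atol=1e-9)

    def test_dimension_mismatch_raises(self, model_and_graphs):
        model, _ = model_and_graphs
        nodes = [GraphNode(0, 0, 0, 0.5, np.zeros(3, np.float32))]
        bad = build_graph(nodes, GraphConfig(n_nodes=1))
        with pytest.raises(ValueError):
            predict_four_tier(model, bad)

    def test_save_load_reproduces_outputs(self, model_and_graphs, tmp_path):
        model, graphs = model_and_graphs
        model.save(tmp_path / "gcn.npz")
        loaded = GcnModelState.load(tmp_path / "gcn.npz")
        for g in graphs[:4]:
            assert np.array_equal(predict_four_tier(model, g).as_array(),
                                  predict_four_tier(loaded, g).as_array())


class TestScreening:
    def test_threshold_is_max_positive_p_ned(self):
        cfg = calibrate_screening_threshold(np.array([0.1, 0.2, 0.6, 0.9]),
                                            np.array([True, True, False, False]))
        assert cfg.threshold == 0.2
        decisions = [screen_slide(p, cfg) for p in (0.1, 0.2, 0.6, 0.9)]
        assert decisions == ["retained-for-review", "retained-for-review",
                             "benign-screened-out", "benign-screened-out"]

    def test_single_positive(self):
        cfg = calibrate_screening_threshold(np.array([0.4]), np.array([True]))
        assert cfg.threshold == 0.4

    def test_guarantee_dominates_yield(self):
        # all positives score above all benigns: nothing gets screened out
        cfg = calibrate_screening_threshold(np.array([0.8, 0.9, 0.3, 0.2]),
                                            np.array([True, True, False, False]))
        assert all(screen_slide(p, cfg) == "retained-for-review"
                   for p in (0.8, 0.9, 0.3, 0.2))

    def test_no_positives_refused(self):
        with pytest.raises(ValueError):
            calibrate_screening_threshold(np.array([0.5]), np.array([False]))

    def test_boundary_is_strict(self):
        cfg = ScreeningConfig(0.5)
        assert screen_slide(0.5, cfg) == "retained-for-review"
        assert screen_slide(0.5 + 1e-9, cfg) == "benign-screened-out"

    def test_decision_is_monotone_step_in_p_ned(self):
        cfg = ScreeningConfig(0.37)
        grid = np.linspace(0, 1, 101)
        flags = [screen_slide(p, cfg) == "benign-screened-out" for p in grid]
        assert flags == sorted(flags)  # single False->True transition

    def test_structural_guarantee_for_arbitrary_scores(self, rng):
        """Whatever the model emits, calibration yields 100% sensitivity and
        NPV on the calibration set."""
        for _ in range(20):
            p_ned = rng.random(50)
            is_pos = rng.random(50) < 0.4
            if not is_pos.any():
                is_pos[0] = True
            cfg = calibrate_screening_threshold(p_ned, is_pos)
            screened = p_ned > cfg.threshold
            assert not (screened & is_pos).any()          # sensitivity = 100%
            assert np.all(~is_pos[screened])              # NPV = 100%

    def test_raising_t_never_screens_out_more(self, rng):
        p_ned = rng.random(30)
        out_low = (p_ned > 0.3).sum()
        out_high = (p_ned > 0.6).sum()
        assert out_high <= out_low

    def test_json_roundtrip(self, tmp_path):
        cfg = ScreeningConfig(0.25, "val", 7)
        cfg.to_json(tmp_path / "s.json")
        loaded = ScreeningConfig.from_json(tmp_path / "s.json")
        assert loaded == cfg
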