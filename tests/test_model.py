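"""Gated-attention MIL model: per-operation oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wsimil as w
from oracles import oracle_attention, oracle_forward, oracle_pool, oracle_project


class TestProjectInstances:
    def test_zero_vector_maps_to_zero(self, small_params):
        h = w.project_instances(np.zeros((1, 16)), small_params)
        np.testing.assert_array_equal(h, np.zeros((1, 8)))

    def test_selector_weights_pick_leading_coordinates(self, small_params):
        params = small_params.copy()
        params.W1 = np.hstack([np.eye(8), np.zeros((8, 8))])
        z = np.arange(16, dtype=float)[None]
        np.testing.assert_array_equal(w.project_instances(z, params), z[:, :8])

    def test_matches_matrix_product_oracle(self, small_params, rng):
        Z = rng.normal(size=(6, 16))
        np.testing.assert_allclose(
            w.project_instances(Z, small_params),
            oracle_project(Z.tolist(), small_params.W1.tolist()),
            rtol=1e-10,
        )

    def test_dim_mismatch_rejected(self, small_params):
        with pytest.raises(ValueError, match="dim"):
            w.project_instances(np.zeros((2, 7)), small_params)


class TestAttentionScores:
    def test_single_instance_gets_full_attention(self, small_params, rng):
        h = rng.normal(size=(1, 8))
        np.testing.assert_allclose(w.attention_scores(h, small_params, 0), [1.0])

    def test_identical_instances_uniform(self, small_params):
        h = np.tile(np.linspace(-1, 1, 8), (5, 1))
        np.testing.assert_allclose(w.attention_scores(h, small_params, 1),
                                   np.full(5, 0.2), atol=1e-12)

    def test_matches_scalar_oracle(self, small_params, rng):
        h = rng.normal(size=(5, 8))
        for i in range(2):
            expected = oracle_attention(h.tolist(), small_params.Va.tolist(),
                                        small_params.Ua.tolist(),
                                        small_params.Wa[i].tolist())
            np.testing.assert_allclose(
                w.attention_scores(h, small_params, i), expected, rtol=1e-10
            )


class TestAttentionPool:
    def test_uniform_weights_give_column_mean(self, rng):
        h = rng.normal(size=(7, 8))
        np.testing.assert_allclose(w.attention_pool(h, np.full(7, 1 / 7)),
                                   h.mean(axis=0), rtol=1e-12)

    def test_one_hot_selects_instance(self, rng):
        h = rng.normal(size=(4, 8))
        a = np.array([0.0, 0.0, 1.0, 0.0])
        np.testing.assert_array_equal(w.attention_pool(h, a), h[2])

    def test_matches_loop_oracle(self, rng):
        h = rng.normal(size=(6, 8))
        a = rng.dirichlet(np.ones(6))
        np.testing.assert_allclose(w.attention_pool(h, a),
                                   oracle_pool(h.tolist(), a.tolist()), rtol=1e-10)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="length"):
            w.attention_pool(rng.normal(size=(4, 8)), np.ones(3) / 3)


class TestSlideScores:
    def test_zero_classifiers_give_uniform_probs(self, small_params, rng):
        params = small_params.copy()
        params.Wc = np.zeros_like(params.Wc)
        _, probs = w.slide_scores(rng.normal(size=(2, 8)), params)
        np.testing.assert_allclose(probs, [0.5, 0.5])

    def test_binary_softmax_is_logistic(self, small_params, rng):
        h_slide = rng.normal(size=(2, 8))
        s, probs = w.slide_scores(h_slide, small_params)
        t = s[0] - s[1]
        np.testing.assert_allclose(probs[0], 1 / (1 + np.exp(-t)), rtol=1e-12)

    def test_matches_dot_product_oracle(self, small_params, rng):
        h_slide = rng.normal(size=(2, 8))
        s, _ = w.slide_scores(h_slide, small_params)
        expected = [float(np.sum([small_params.Wc[i][j] * h_slide[i][j]
                                  for j in range(8)])) for i in range(2)]
        np.testing.assert_allclose(s, expected, rtol=1e-10)


class TestInstanceClusterScores:
    def test_zero_head_gives_zero_scores(self, small_params, rng):
        params = small_params.copy()
        params.Winst = np.zeros_like(params.Winst)
        assert not w.instance_cluster_scores(rng.normal(size=(3, 8)), params, 0).any()

    def test_zero_instances_give_zero_scores(self, small_params):
        assert not w.instance_cluster_scores(np.zeros((3, 8)), small_params, 1).any()

    def test_matches_matrix_product_oracle(self, small_params, rng):
        h = rng.normal(size=(4, 8))
        got = w.instance_cluster_scores(h, small_params, 1)
        expected = h @ small_params.Winst[1].T
        np.testing.assert_allclose(got, expected, rtol=1e-12)


class TestPseudoLabels:
    def test_strict_ordering(self):
        top, bottom = w.assign_pseudo_labels(np.array([0.7, 0.2, 0.1]), 1)
        assert top.tolist() == [0] and bottom.tolist() == [2]

    def test_tie_break_prefers_lower_index_and_disjoint(self):
        top, bottom = w.assign_pseudo_labels(np.full(4, 0.25), 1)
        assert top.tolist() == [0]
        assert bottom.tolist() == [1]  # lowest index not already taken

    def test_matches_sort_oracle(self, rng):
        a = rng.random(20)
        top, bottom = w.assign_pseudo_labels(a, 4)
        order = np.argsort(-a)
        assert sorted(top) == sorted(order[:4])
        assert sorted(bottom) == sorted(order[-4:])
        assert not set(top) & set(bottom)

    def test_oversized_k_reduced_with_warning(self):
        with pytest.warns(UserWarning, match="reduced"):
            top, bottom = w.assign_pseudo_labels(np.array([0.5, 0.3, 0.2]), 2)
        assert len(top) == len(bottom) == 1


class TestForward:
    def test_permutation_invariance(self, small_params, rng):
        Z = rng.normal(size=(9, 16))
        perm = rng.permutation(9)
        f1 = w.forward(Z, small_params)
        f2 = w.forward(Z[perm], small_params)
        np.testing.assert_allclose(f1.probs, f2.probs, rtol=1e-10)
        np.testing.assert_allclose(f1.h_slide, f2.h_slide, rtol=1e-10)
        np.testing.assert_allclose(f1.a[:, perm], f2.a, rtol=1e-10)

    def test_single_instance_bag_pools_to_it(self, small_params, rng):
        Z = rng.normal(size=(1, 16))
        f = w.forward(Z, small_params)
        for i in range(2):
            np.testing.assert_allclose(f.h_slide[i], f.h[0], rtol=1e-12)

    def test_matches_end_to_end_oracle(self, small_params, rng):
        Z = rng.normal(size=(7, 16))
        f = w.forward(Z, small_params)
        a, h_slide, s, probs, p_inst = oracle_forward(Z, small_params)
        np.testing.assert_allclose(f.a, a, rtol=1e-8)
        np.testing.assert_allclose(f.h_slide, h_slide, rtol=1e-8)
        np.testing.assert_allclose(f.s_slide, s, rtol=1e-8)
        np.testing.assert_allclose(f.probs, probs, rtol=1e-8)
        np.testing.assert_allclose(f.p_inst, p_inst, rtol=1e-8)

    def test_train_mode_requires_rng(self, small_params, rng):
        with pytest.raises(ValueError, match="RNG"):
            w.forward(rng.normal(size=(3, 16)), small_params, train=True)

    @settings(max_examples=25, deadline=None)
    @given(k=st.integers(1, 12), seed=st.integers(0, 1000))
    def test_attention_rows_are_distributions(self, small_params, k, seed):
        Z = np.random.default_rng(seed).normal(size=(k, 16))
        f = w.forward(Z, small_params)
        assert (f.a >= 0).all()
        np.testing.assert_allclose(f.a.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(f.probs.sum(), 1.0, atol=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(k=st.integers(2, 10), seed=st.integers(0, 1000))
    def test_pooled_representation_in_convex_hull(self, small_params, k, seed):
        Z = np.random.default_rng(seed).normal(size=(k, 16))
        f = w.forward(Z, small_params)
        lo = f.h.min(axis=0) - 1e-9
        hi = f.h.max(axis=0) + 1e-9
        for i in range(2):
            assert ((f.h_slide[i] >= lo) & (f.h_slide[i] <= hi)).all()


class TestCheckpoint:
    def test_round_trip(self, small_params, tmp_path):
        path = w.save_checkpoint(small_params, tmp_path / "ck.npz", meta={"seed": 1})
        params, meta = w.load_checkpoint(path)
        for k, v in small_params.arrays().items():
            np.testing.assert_array_equal(params.arrays()[k], v)
        assert meta == {"seed": 1}
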