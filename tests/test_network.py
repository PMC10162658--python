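"""Capsule math, branch geometry, and forward-graph contracts."""

import numpy as np
import pytest

from capsmhc._autodiff import Tensor
from capsmhc.network import (
    BranchConfig,
    CapsNetCore,
    CapsuleConfig,
    ConfigurationError,
    GeometryError,
    NetworkConfig,
    PredictorConfig,
    assert_pooling_free,
    default_mhc_branch,
    default_peptide_branch,
    dynamic_routing,
    squash,
)

RNG = np.random.default_rng(42)


def routing_reference(u_hat: np.ndarray, iterations: int):
    """Naive triple-loop dynamic routing, written independently of the
    vectorized implementation."""
    B, I, J, D = u_hat.shape
    vs = np.zeros((B, J, D))
    cs = np.zeros((B, I, J))
    for n in range(B):
        b = np.zeros((I, J))
        for it in range(iterations):
            c = np.exp(b - b.max(axis=1, keepdims=True))
            c = c / c.sum(axis=1, keepdims=True)
            s = np.zeros((J, D))
            for i in range(I):
                for j in range(J):
                    s[j] += c[i, j] * u_hat[n, i, j]
            v = np.zeros((J, D))
            for j in range(J):
                norm = np.linalg.norm(s[j])
                v[j] = (norm**2 / (1 + norm**2)) * s[j] / (norm + 1e-8)
            if it < iterations - 1:
                for i in range(I):
                    for j in range(J):
                        b[i, j] += float(u_hat[n, i, j] @ v[j])
        vs[n], cs[n] = v, c
    return vs, cs


class TestSquash:
    def test_zero_vector_maps_to_zero(self):
        assert np.allclose(squash(np.zeros(5)), 0.0)

    def test_unit_vector_halves(self):
        v = squash(np.array([1.0, 0.0]))
        assert np.isclose(np.linalg.norm(v), 0.5, atol=1e-6)

    def test_three_four_vector(self):
        v = squash(np.array([3.0, 4.0]))
        assert np.isclose(np.linalg.norm(v), 25 / 26, atol=1e-6)
        assert np.allclose(v, [0.576923, 0.769231], atol=1e-4)

    def test_norm_law_and_direction_on_random_vectors(self):
        s = RNG.normal(size=(1000, 8), scale=3.0)
        v = squash(s, axis=-1)
        ns = np.linalg.norm(s, axis=-1)
        nv = np.linalg.norm(v, axis=-1)
        assert np.allclose(nv, ns**2 / (1 + ns**2), atol=1e-6)
        assert np.all(nv < 1.0)
        cos = np.sum(s * v, axis=-1) / (ns * nv)
        assert np.allclose(cos, 1.0, atol=1e-6)


class TestDynamicRouting:
    def test_matches_triple_loop_oracle_on_random_instances(self):
        for trial in range(50):
            rng = np.random.default_rng(trial)
            B, I, J, D = 1, 2, int(rng.integers(2, 6)), int(rng.integers(2, 5))
            r = int(rng.integers(1, 5))
            u_hat = rng.normal(size=(B, I, J, D))
            v, c = dynamic_routing(u_hat, iterations=r)
            v_ref, c_ref = routing_reference(u_hat, r)
            assert np.allclose(v, v_ref, atol=1e-6)
            assert np.allclose(c, c_ref, atol=1e-6)

    def test_couplings_sum_to_one_every_iteration(self):
        u_hat = RNG.normal(size=(3, 2, 5, 4))
        for r in range(1, 5):
            _, c = dynamic_routing(u_hat, iterations=r)
            assert np.allclose(c.sum(axis=-1), 1.0, atol=1e-6)

    def test_single_iteration_is_uniform_coupling_closed_form(self):
        u_hat = RNG.normal(size=(2, 2, 6, 3))
        v, c = dynamic_routing(u_hat, iterations=1)
        assert np.allclose(c, 1 / 6)
        assert np.allclose(v, squash(u_hat.sum(axis=1) / 6, axis=-1), atol=1e-12)

    def test_single_output_capsule_routing_is_vacuous(self):
        u_hat = RNG.normal(size=(2, 2, 1, 4))
        for r in (1, 3):
            v, c = dynamic_routing(u_hat, iterations=r)
            assert np.allclose(c, 1.0)
            assert np.allclose(v, squash(u_hat.sum(axis=1), axis=-1), atol=1e-12)

    def test_rejects_zero_iterations(self):
        with pytest.raises(ConfigurationError):
            dynamic_routing(RNG.normal(size=(1, 2, 3, 4)), iterations=0)

    def test_gradient_flows_through_routing(self):
        u = Tensor(RNG.normal(size=(1, 2, 3, 4)), requires_grad=True)
        v, _ = dynamic_routing(u, iterations=3)
        (v * v).sum().backward()
        assert u.grad is not None and np.all(np.isfinite(u.grad))


class TestBranchGeometry:
    def test_default_branches_satisfy_latent_contract(self):
        default_peptide_branch()
        default_mhc_branch()  # constructors validate the 20 x 11 contract

    def test_bad_geometry_rejected(self):
        with pytest.raises(GeometryError):
            BranchConfig(
                role="peptide",
                input_positions=15,
                conv_layers=((20, 3, 1), (20, 4, 1)),  # lands on 10, not 11
                attention_after=1,
            )

    def test_attention_position_validated(self):
        with pytest.raises(ConfigurationError):
            BranchConfig(
                role="peptide",
                input_positions=15,
                conv_layers=((20, 3, 1), (20, 2, 1), (20, 2, 1)),
                attention_after=0,
            )


class TestForward:
    @pytest.fixture(scope="class")
    def core(self):
        return CapsNetCore(NetworkConfig())

    def test_branch_outputs_are_20x11_for_batch_100(self, core):
        pep = RNG.normal(size=(100, 23, 15))
        mhc = RNG.normal(size=(100, 23, 385))
        pl, ml = core.latents(pep, mhc)
        assert pl.shape == (100, 20, 11)
        assert ml.shape == (100, 20, 11)

    def test_batch_of_one(self, core):
        pl, ml = core.latents(RNG.normal(size=(1, 23, 15)), RNG.normal(size=(1, 23, 385)))
        assert pl.shape == (1, 20, 11) and ml.shape == (1, 20, 11)

    def test_batch_mismatch_raises(self, core):
        with pytest.raises(GeometryError):
            core.forward(RNG.normal(size=(2, 23, 15)), RNG.normal(size=(3, 23, 385)))

    def test_wrong_input_geometry_raises(self, core):
        with pytest.raises(GeometryError):
            core.latents(RNG.normal(size=(2, 23, 14)), RNG.normal(size=(2, 23, 385)))

    def test_scores_align_with_batch_and_are_probabilities(self, core):
        scores, _ = core.forward(RNG.normal(size=(7, 23, 15)), RNG.normal(size=(7, 23, 385)))
        assert scores.shape == (7,)
        assert np.all((scores.data > 0) & (scores.data < 1))

    def test_zero_weights_give_half_score_and_zero_capsules(self):
        core = CapsNetCore(NetworkConfig())
        core.set_all_weights(0.0)
        scores, cap = core.forward(
            RNG.normal(size=(3, 23, 15)), RNG.normal(size=(3, 23, 385)), capture=True
        )
        assert np.allclose(scores.data, 0.5)  # sigmoid(0)
        state = cap["routing_state"]
        assert np.allclose(state.u_hat, 0.0) and np.allclose(state.v, 0.0)
        assert np.allclose(state.c, 1 / 16)  # uniform couplings

    def test_forward_is_deterministic(self):
        pep = RNG.normal(size=(4, 23, 15))
        mhc = RNG.normal(size=(4, 23, 385))
        a = CapsNetCore(NetworkConfig(seed=5)).predict_scores(pep, mhc)
        b = CapsNetCore(NetworkConfig(seed=5)).predict_scores(pep, mhc)
        assert np.array_equal(a, b)

    def test_capsule_output_norms_obey_squash_law(self, core):
        _, cap = core.forward(
            RNG.normal(size=(4, 23, 15)), RNG.normal(size=(4, 23, 385)), capture=True
        )
        state = cap["routing_state"]
        ns = np.linalg.norm(state.s, axis=-1)
        nv = np.linalg.norm(state.v, axis=-1)
        assert np.all(nv < 1.0)
        assert np.allclose(nv, ns**2 / (1 + ns**2), atol=1e-6)

    def test_routing_disabled_equals_single_iteration(self):
        pep = RNG.normal(size=(3, 23, 15))
        mhc = RNG.normal(size=(3, 23, 385))
        uniform = CapsNetCore(NetworkConfig(routing=False, seed=2)).predict_scores(pep, mhc)
        one_iter = CapsNetCore(
            NetworkConfig(capsule=CapsuleConfig(routing_iterations=1), seed=2)
        ).predict_scores(pep, mhc)
        assert np.allclose(uniform, one_iter)

    def test_routing_vacuous_with_single_output_capsule(self):
        pep = RNG.normal(size=(3, 23, 15))
        mhc = RNG.normal(size=(3, 23, 385))
        cfg_r = NetworkConfig(
            capsule=CapsuleConfig(n_output_capsules=1, routing_iterations=3), seed=4
        )
        cfg_n = NetworkConfig(
            capsule=CapsuleConfig(n_output_capsules=1, routing_iterations=3),
            routing=False,
            seed=4,
        )
        assert np.allclose(
            CapsNetCore(cfg_r).predict_scores(pep, mhc),
            CapsNetCore(cfg_n).predict_scores(pep, mhc),
        )

    def test_concat_head_input_dimension_is_440(self):
        core = CapsNetCore(NetworkConfig(fusion="concat"))
        assert core.head.layers[0].w.shape[0] == 440

    def test_all_fusion_graphs_are_pooling_free(self):
        for fusion in ("capsule", "concat", "conv"):
            assert_pooling_free(CapsNetCore(NetworkConfig(fusion=fusion)))


class TestAttention:
    def test_weights_nonnegative_sum_to_one_and_rescale(self):
        from capsmhc.network import PositionAttention

        rng = np.random.default_rng(0)
        att = PositionAttention(rng, channels=6)
        x = Tensor(RNG.normal(size=(5, 6, 9)))
        w = att.weights(x).data
        assert np.all(w >= 0)
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-6)
        out = att(x).data
        assert np.allclose(out, x.data * w[:, None, :])

    def test_uniform_weights_divide_by_positions(self):
        from capsmhc.network import PositionAttention

        rng = np.random.default_rng(0)
        att = PositionAttention(rng, channels=6)
        att.w.data[...] = 0.0
        att.b.data[...] = 0.0
        x = Tensor(RNG.normal(size=(2, 6, 9)))
        assert np.allclose(att(x).data, x.data / 9)


class TestPredictorActivations:
    def test_tanh_scores_rescaled_to_unit_interval(self):
        core = CapsNetCore(
            NetworkConfig(predictor=PredictorConfig(output_activation="tanh"))
        )
        s = core.predict_scores(RNG.normal(size=(5, 23, 15)), RNG.normal(size=(5, 23, 385)))
        assert np.all((s >= 0) & (s <= 1))

    def test_softmax_scores_are_class1_probabilities(self):
        core = CapsNetCore(
            NetworkConfig(predictor=PredictorConfig(output_activation="softmax"))
        )
        s = core.predict_scores(RNG.normal(size=(5, 23, 15)), RNG.normal(size=(5, 23, 385)))
        assert np.all((s > 0) & (s < 1))

    def test_unknown_activation_rejected(self):
        with pytest.raises(ConfigurationError):
            PredictorConfig(output_activation="gelu")
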