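"""Model assembly, adaptive fusion arithmetic, initialisation scheme and
end-to-end probability contract."""

import numpy as np
import pytest

from aphidgrade import nn
from aphidgrade.fusion import (AdaptiveFusion, DualBranchClassifier,
                               FusionModelConfig, assemble,
                               initialize_weights, tiny_config)
from aphidgrade.nn import Tensor
from aphidgrade.nn.init import kaiming_normal, xavier_uniform


@pytest.fixture(scope="module")
def tiny_model():
    return assemble(tiny_config(), seed=0)


def _param_checksum(model):
    return {name: float(np.sum(p.data)) for name, p in model.named_parameters()}


class TestAssembly:
    def test_full_config_fusion_width_is_2304(self):
        cfg = FusionModelConfig(profile="full")
        assert cfg.fused_dim == 1536 + 768 == 2304

    def test_tiny_fusion_width_forced_by_config(self, tiny_model):
        assert tiny_model.fused_dim == 128 + 64 == 192
        assert tiny_model.fusion.interact.in_features == 192

    def test_named_submodules_present(self, tiny_model):
        for name in ("local_branch", "global_branch", "gcsa_local",
                     "gcsa_global", "fusion", "head"):
            assert tiny_model.get_submodule(name) is not None

    def test_same_seed_identical_parameters(self):
        a = assemble(tiny_config(), seed=9)
        b = assemble(tiny_config(), seed=9)
        assert _param_checksum(a) == _param_checksum(b)

    def test_head_terminates_in_num_classes(self, tiny_model):
        assert tiny_model.head[-1].out_features == 4

    def test_gcsa_toggle_strictly_reduces_parameter_count(self):
        with_gcsa = assemble(tiny_config(), seed=0)
        without = assemble(tiny_config(use_gcsa=False), seed=0)
        assert without.num_parameters() < with_gcsa.num_parameters()

    def test_single_branch_variant_has_no_global_branch(self):
        model = assemble(tiny_config(hybrid=False), seed=0)
        assert model.fused_dim == 128
        assert "global_branch" not in model._modules

    def test_invalid_dropout_rejected(self):
        with pytest.raises(ValueError):
            FusionModelConfig(dropout=1.0)


class TestAdaptiveFusion:
    def test_identity_configuration_is_concatenation(self):
        fus = AdaptiveFusion(3, 2, gates=False, interaction=False)
        a = Tensor(np.array([[1.0, 2.0, 3.0]], np.float32))
        b = Tensor(np.array([[4.0, 5.0]], np.float32))
        out = fus(a, b)
        assert np.array_equal(out.data, [[1, 2, 3, 4, 5]])

    def test_zero_inputs_give_zero_pre_interaction(self):
        fus = AdaptiveFusion(3, 2, gates=True, interaction=False,
                             rng=np.random.default_rng(0))
        out = fus(Tensor(np.zeros((2, 3))), Tensor(np.zeros((2, 2))))
        assert np.all(out.data == 0.0)

    def test_toy_dims_match_dense_algebra_oracle(self):
        rng = np.random.default_rng(1)
        fus = AdaptiveFusion(2, 2, gates=True, interaction=True,
                             gate="vector", rng=rng)
        a = rng.normal(size=(3, 2)).astype(np.float32)
        b = rng.normal(size=(3, 2)).astype(np.float32)
        sig = lambda z: 1.0 / (1.0 + np.exp(-z))
        ga = sig(a @ fus.gate_local.weight.data.T + fus.gate_local.bias.data) * a
        gb = sig(b @ fus.gate_global.weight.data.T + fus.gate_global.bias.data) * b
        cat = np.concatenate([ga, gb], axis=1)
        expect = np.maximum(cat @ fus.interact.weight.data.T
                            + fus.interact.bias.data, 0.0)
        out = fus(Tensor(a), Tensor(b))
        assert np.allclose(out.data, expect, atol=1e-5)

    def test_dim_mismatch_rejected(self):
        fus = AdaptiveFusion(3, 2)
        with pytest.raises(ValueError):
            fus(Tensor(np.zeros((1, 2))), Tensor(np.zeros((1, 2))))

    def test_scalar_gate_variant(self):
        fus = AdaptiveFusion(3, 2, gate="scalar",
                             rng=np.random.default_rng(2))
        assert fus.gate_local.out_features == 1
        out = fus(Tensor(np.ones((2, 3))), Tensor(np.ones((2, 2))))
        assert out.shape == (2, 5)


class TestForwardContract:
    def test_probability_rows_sum_to_one(self, tiny_model):
        rng = np.random.default_rng(3)
        images = rng.random((4, 80, 80, 3)).astype(np.float32)
        probs = tiny_model.predict_proba(images)
        assert probs.shape == (4, 4)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_batch_permutation_equivariance_in_eval(self, tiny_model):
        rng = np.random.default_rng(4)
        images = rng.random((5, 64, 64, 3)).astype(np.float32)
        perm = np.array([3, 0, 4, 1, 2])
        p1 = tiny_model.predict_proba(images)
        p2 = tiny_model.predict_proba(images[perm])
        assert np.allclose(p1[perm], p2, atol=1e-5)

    def test_non_rgb_input_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.predict_proba(np.zeros((2, 64, 64, 1), np.float32))

    def test_gradient_reaches_every_parameter_group(self):
        """One training step on one batch leaves no dead branch."""
        model = assemble(tiny_config(), seed=1)
        model.train()
        rng = np.random.default_rng(5)
        images = rng.random((4, 64, 64, 3)).astype(np.float32)
        labels = np.array([0, 1, 2, 3])
        xl, xg = model.preprocess(images)
        logits = model.forward_tensors(Tensor(xl), Tensor(xg))
        logp = logits.log_softmax()
        loss = -logp[np.arange(4), labels].mean()
        loss.backward()
        groups = {"local_branch": 0.0, "global_branch": 0.0,
                  "gcsa_local": 0.0, "gcsa_global": 0.0,
                  "fusion": 0.0, "head": 0.0}
        for name, p in model.named_parameters():
            top = name.split(".")[0]
            if p.grad is not None:
                groups[top] += float(np.abs(p.grad).sum())
        assert all(v > 0 for v in groups.values()), groups


class TestInitializationScheme:
    def test_all_biases_zero_after_init(self, tiny_model):
        for name, p in tiny_model.named_parameters():
            if name.endswith(".bias") and ("gcsa" in name or "fusion" in name
                                           or "head" in name):
                assert np.all(p.data == 0.0), name

    def test_kaiming_empirical_variance_matches_closed_form(self):
        """Var of a 3x3x64-fan-in Kaiming draw ~ 2/fan_in within 20%."""
        rng = np.random.default_rng(6)
        w = kaiming_normal(rng, (64, 64, 3, 3), fan_in=64 * 9)
        assert w.size >= 10_000
        target = 2.0 / (64 * 9)
        assert abs(w.var() - target) / target < 0.20

    def test_xavier_bound_holds(self):
        rng = np.random.default_rng(7)
        w = xavier_uniform(rng, (512, 1024), fan_in=1024, fan_out=512)
        bound = np.sqrt(6.0 / (1024 + 512))
        assert np.abs(w).max() <= bound

    def test_gcsa_convs_redrawn_by_scheme(self):
        model = assemble(tiny_config(), seed=2)
        w = model.gcsa_local.spatial.conv1.weight
        fan_in = int(np.prod(w.shape[1:]))
        assert abs(w.data.var() - 2.0 / fan_in) / (2.0 / fan_in) < 0.5
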