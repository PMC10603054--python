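import numpy as np
import pytest

from dynrbp.autograd import Tensor
from dynrbp.dataset import FixedSample, tokenize
from dynrbp.model import (BindingModel, BindingPredictor, CNNBlock,
                          ModelConfig, MultiScaleResidual, PyramidPredictor,
                          UnifiedAlignment, pooled_length_trajectory,
                          variant_effect)

from conftest import make_sample


def oracle_trajectory(length):
    """Independent arithmetic oracle for the pooled length sequence."""
    out = [length]
    while out[-1] > 1:
        cur = out[-1]
        if cur < 3:
            cur = 3  # right-padded
        out.append((cur - 3) // 2 + 1)
    return out


SMALL = ModelConfig.small()
RNG = np.random.default_rng(0)


class TestCNNBlock:
    @pytest.mark.parametrize("kernel", [1, 3, 5, 7])
    def test_length_preserved_and_nonnegative(self, kernel):
        rng = np.random.default_rng(1)
        block = CNNBlock(8, 16, kernel, SMALL, rng)
        out = block(Tensor(rng.normal(size=(2, 8, 33))))
        assert out.shape == (2, 16, 33)
        assert np.all(out.data >= 0)

    def test_zero_kernel_identity_bn_gives_zero(self):
        rng = np.random.default_rng(2)
        block = CNNBlock(4, 4, 3, SMALL, rng)
        block.conv.weight.data[:] = 0.0
        block.eval()  # BN uses running stats (mean 0, var 1) -> identity
        out = block(Tensor(rng.normal(size=(1, 4, 10))))
        assert np.allclose(out.data, 0.0)


class TestUnifiedAlignment:
    def test_default_shapes(self):
        cfg = ModelConfig()
        ua = UnifiedAlignment(cfg, np.random.default_rng(0))
        seq = Tensor(RNG.normal(size=(2, 768, 99)))
        struct = Tensor(RNG.normal(size=(2, 1, 99)))
        s, t = ua(seq, struct)
        assert s.shape == (2, 128, 99)
        assert t.shape == (2, 128, 99)

    def test_sentinel_structure_stays_finite(self):
        ua = UnifiedAlignment(SMALL, np.random.default_rng(0))
        seq = Tensor(RNG.normal(size=(2, 64, 99)))
        struct = Tensor(np.full((2, 1, 99), -1.0))
        s, t = ua(seq, struct)
        assert np.all(np.isfinite(t.data))

    def test_channels_independent_of_length(self):
        ua = UnifiedAlignment(SMALL, np.random.default_rng(0))
        for L in (20, 50, 99):
            s, t = ua(Tensor(RNG.normal(size=(1, 64, L))),
                      Tensor(RNG.normal(size=(1, 1, L))))
            assert s.shape == (1, 64, L)

    def test_length_mismatch_raises(self):
        ua = UnifiedAlignment(SMALL, np.random.default_rng(0))
        with pytest.raises(ValueError, match="length"):
            ua(Tensor(np.zeros((1, 64, 10))), Tensor(np.zeros((1, 1, 12))))


class TestMultiScaleResidual:
    def test_output_shape(self):
        h = MultiScaleResidual(SMALL, np.random.default_rng(0))
        out = h(Tensor(RNG.normal(size=(2, 64, 40))))
        assert out.shape == (2, 64, 40)

    def test_zero_branches_give_relu_of_input(self):
        h = MultiScaleResidual(SMALL, np.random.default_rng(0))
        for branch in h.branches:
            for block in branch.layers:
                block.conv.weight.data[:] = 0.0
        h.eval()
        x = RNG.normal(size=(1, 64, 12))
        out = h(Tensor(x))
        assert np.allclose(out.data, np.maximum(x, 0.0), atol=1e-6)

    @pytest.mark.parametrize("branch_idx", [0, 1, 2, 3])
    def test_receptive_field_by_impulse_probe(self, branch_idx):
        cfg = SMALL
        h = MultiScaleResidual(cfg, np.random.default_rng(3))
        # positive weights avoid cancellation; eval-mode BN is affine
        branch = h.branches[branch_idx]
        for block in branch.layers:
            block.conv.weight.data = np.abs(block.conv.weight.data) + 0.01
            block.bn.running_mean[:] = 0.0
            block.bn.running_var[:] = 1.0
        branch.train(False)
        L = 41
        x = np.zeros((1, cfg.align_channels, L))
        x[0, :, L // 2] = 1.0
        out = branch(Tensor(x)).data[0]
        nonzero = np.flatnonzero(out.sum(axis=0) > 1e-9)
        kernel = cfg.hmrn_branch_kernels[branch_idx]
        depth = cfg.hmrn_branch_depths[branch_idx]
        rf = depth * (kernel - 1) + 1
        assert len(nonzero) == rf
        assert nonzero[0] == L // 2 - (rf - 1) // 2


class TestPyramidPredictor:
    def test_printed_trajectory_99(self):
        assert pooled_length_trajectory(99) == [99, 49, 24, 11, 5, 2, 1]

    @pytest.mark.parametrize("L", list(range(1, 40)) + [99, 256, 512])
    def test_trajectory_matches_oracle(self, L):
        assert pooled_length_trajectory(L) == oracle_trajectory(L)

    def test_forward_reduces_to_length_one(self):
        cfg = ModelConfig.small(seq_len=30)
        p = PyramidPredictor(cfg, np.random.default_rng(0))
        p.eval()
        out = p(Tensor(RNG.normal(size=(2, 128, 30))))
        assert out.shape == (2, 128)

    def test_maxpool_of_constant_channel_is_constant(self):
        x = Tensor(np.full((1, 4, 9), 3.5))
        assert np.allclose(x.maxpool1d(3, 2).data, 3.5)


class TestBindingModel:
    def _model(self, seed=0, **kwargs):
        cfg = ModelConfig.small(**kwargs)
        return BindingModel(cfg, seed=seed)

    def test_zero_head_gives_half(self):
        m = self._model()
        m.head.weight.data[:] = 0.0
        m.head.bias.data[:] = 0.0
        p = m.predict_proba(Tensor(RNG.normal(size=(3, 64, 99))),
                            Tensor(RNG.normal(size=(3, 1, 99))))
        assert np.allclose(p, 0.5)

    def test_fuzz_probability_in_open_interval(self):
        m = self._model(seed=5)
        for seed in range(3):
            r = np.random.default_rng(seed)
            p = m.predict_proba(Tensor(r.normal(size=(2, 64, 99))),
                                Tensor(r.normal(size=(2, 1, 99))))
            assert np.all((p > 0) & (p < 1))
            assert np.all(np.isfinite(p))

    def test_eval_determinism(self):
        m = self._model(seed=6)
        x = Tensor(RNG.normal(size=(1, 64, 99)))
        s = Tensor(RNG.normal(size=(1, 1, 99)))
        assert np.array_equal(m.predict_proba(x, s), m.predict_proba(x, s))

    def test_nonfinite_input_rejected(self):
        m = self._model()
        x = np.zeros((1, 64, 99))
        x[0, 0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            m(Tensor(x), Tensor(np.zeros((1, 1, 99))))

    def test_parameter_count_architecture_determinism(self):
        n1 = sum(p.data.size for p in BindingModel(SMALL, seed=1).parameters())
        n2 = sum(p.data.size for p in BindingModel(SMALL, seed=99).parameters())
        assert n1 == n2

    def test_add_combine_mode(self):
        cfg = ModelConfig.small()
        cfg = ModelConfig(d_model=64, seq_len=99, align_channels=64,
                          hmrn_branch_channels=16, dprbp_channels=64,
                          combine="add")
        m = BindingModel(cfg, seed=0)
        p = m.predict_proba(Tensor(RNG.normal(size=(1, 64, 99))),
                            Tensor(RNG.normal(size=(1, 1, 99))))
        assert 0 < p[0] < 1

    def test_config_validation(self):
        with pytest.raises(ValueError, match="branch"):
            ModelConfig(hmrn_branch_channels=33)
        with pytest.raises(ValueError, match="dprbp_channels"):
            ModelConfig(dprbp_channels=100)

    def test_hmrn_is_live_after_training(self, small_predictor, tiny_dataset):
        # a briefly trained toy model must change predictions when the
        # multi-scale stage is bypassed
        from dynrbp.training import TrainConfig, train

        samples, _ = tiny_dataset
        pred = small_predictor
        train(pred, samples[:40], samples[40:50],
              TrainConfig(max_epochs=1, patience=1, seed=0, batch_size=16))
        sample = samples[0]
        p_full = pred.predict(sample)
        identity = lambda x: x
        orig_seq, orig_struct = pred.model.seq_hmrn.forward, pred.model.struct_hmrn.forward
        try:
            pred.model.seq_hmrn.forward = identity
            pred.model.struct_hmrn.forward = identity
            p_bypassed = pred.predict(sample)
        finally:
            pred.model.seq_hmrn.forward = orig_seq
            pred.model.struct_hmrn.forward = orig_struct
        assert p_full != p_bypassed


class TestVariantEffect:
    def test_identity_substitution_warns_zero_delta(self, small_predictor):
        s = make_sample(seed=1)
        pos = 10
        with pytest.warns(UserWarning, match="delta is 0"):
            p_ref, p_alt, delta = variant_effect(small_predictor, s, pos,
                                                 s.sequence[pos - 1])
        assert delta == 0.0

    def test_substitution_and_revert(self, small_predictor):
        s = make_sample(seed=2)
        pos, ref = 50, s.sequence[49]
        alt = "A" if ref != "A" else "C"
        p_ref, p_alt, delta = variant_effect(small_predictor, s, pos, alt)
        assert delta == pytest.approx(p_alt - p_ref)
        mutated = FixedSample(sequence=s.sequence[:49] + alt + s.sequence[50:],
                              label=s.label, structure=s.structure)
        _, p_back, _ = variant_effect(small_predictor, mutated, pos, ref)
        assert p_back == pytest.approx(p_ref, abs=1e-12)

    @pytest.mark.parametrize("pos", [1, 2, 3, 50, 99, 100, 101])
    def test_changed_token_count_combinatorial(self, pos):
        # oracle: tokens covering base pos (1-based) for k=3
        k = 3
        s = make_sample(seed=3)
        alt = "A" if s.sequence[pos - 1] != "A" else "G"
        mutated = s.sequence[:pos - 1] + alt + s.sequence[pos:]
        t_ref = tokenize(s.sequence, k).interior
        t_alt = tokenize(mutated, k).interior
        changed = sum(a != b for a, b in zip(t_ref, t_alt))
        n_tok = len(t_ref)
        expected = len([i for i in range(max(0, pos - k), min(n_tok, pos))])
        assert changed == expected
        assert changed <= k

    def test_bad_position_rejected(self, small_predictor):
        with pytest.raises(ValueError, match="position"):
            variant_effect(small_predictor, make_sample(seed=4), 0, "A")


class TestCheckpoint:
    def test_round_trip_predictions(self, tmp_path, small_predictor):
        path = tmp_path / "model.npz"
        small_predictor.save(path)
        loaded = BindingPredictor.load(path)
        s = make_sample(seed=9)
        assert loaded.predict(s) == pytest.approx(small_predictor.predict(s),
                                                  abs=1e-6)
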