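import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from decontrast3d.volume import Volume
from decontrast3d.preprocess import NormalizationSpec, normalize_array, denormalize_array
from decontrast3d.networks import GeneratorConfig, DiscriminatorConfig
from decontrast3d.objectives import LossWeights
from decontrast3d.phantom import default_clinical_spec, generate_phantom
from decontrast3d.engine import (
    TrainConfig,
    lr_at_epoch,
    plan_patches,
    convert_volume,
    train,
    save_checkpoint,
    load_checkpoint,
)
from decontrast3d.nn import Adam


class TestLrSchedule:
    def test_constant_through_first_half(self):
        cfg = TrainConfig()
        assert lr_at_epoch(1, cfg) == pytest.approx(2e-4)
        assert lr_at_epoch(50, cfg) == pytest.approx(2e-4)
        assert lr_at_epoch(100, cfg) == pytest.approx(2e-4)

    def test_linear_decay_midpoint_and_endpoint(self):
        cfg = TrainConfig()
        assert lr_at_epoch(150, cfg) == pytest.approx(1e-4, abs=1e-12)
        assert lr_at_epoch(200, cfg) == pytest.approx(0.0, abs=1e-15)

    def test_out_of_range_epoch_rejected(self):
        cfg = TrainConfig()
        for epoch in (0, 201, -5):
            with pytest.raises(ValueError):
                lr_at_epoch(epoch, cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(total_epochs=100, const_lr_epochs=150)


class TestPlanPatches:
    def test_single_patch_when_sizes_match(self):
        plan = plan_patches((64, 64, 64), (64, 64, 64))
        assert plan.corners == [(0, 0, 0)]

    def test_stride_arithmetic_on_one_axis(self):
        plan = plan_patches((96, 64, 64), (64, 64, 64), overlap_fraction=0.5)
        xs = sorted({c[0] for c in plan.corners})
        assert xs == [0, 32]

    def test_last_corner_clamped_to_boundary(self):
        plan = plan_patches((70, 64, 64), (64, 64, 64), overlap_fraction=0.5)
        xs = sorted({c[0] for c in plan.corners})
        assert xs == [0, 6]

    def test_overlap_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            plan_patches((64, 64, 64), (32, 32, 32), overlap_fraction=0.95)

    @settings(max_examples=25, deadline=None)
    @given(
        st.tuples(st.integers(8, 40), st.integers(8, 40), st.integers(8, 40)),
        st.sampled_from([0.0, 0.25, 0.5, 0.75]),
    )
    def test_every_voxel_covered(self, shape, overlap):
        patch = tuple(max(2, s // 2) for s in shape)
        plan = plan_patches(shape, patch, overlap)
        assert plan.coverage().min() >= 1


class TestConvertVolume:
    def test_identity_generator_reproduces_input(self, rng):
        v = Volume(rng.uniform(-500, 500, (32, 32, 16)))
        plan = plan_patches(v.shape, (16, 16, 8), 0.5)
        out = convert_volume(lambda p: p, v, plan)
        np.testing.assert_allclose(out.grid, v.grid, atol=1e-9)

    def test_constant_generator_average_in_overlap(self, rng):
        v = Volume(rng.uniform(-100, 100, (24, 16, 16)))
        plan = plan_patches(v.shape, (16, 16, 16), 0.5)
        norm = NormalizationSpec()
        out = convert_volume(lambda p: np.full_like(p, 0.25), v, plan, norm)
        np.testing.assert_allclose(
            out.grid, denormalize_array(np.full(v.shape, 0.25), norm), atol=1e-9
        )

    def test_two_patch_average_with_test_double(self):
        # generator returns a on the first patch, b on the second
        v = Volume(np.zeros((24, 16, 16)))
        plan = plan_patches(v.shape, (16, 16, 16), 0.5)
        assert len(plan.corners) == 2
        vals = iter([0.2, 0.6])

        def fake(p):
            return np.full_like(p, next(vals))

        norm = NormalizationSpec()
        out = normalize_array(
            convert_volume(fake, v, plan, norm).grid, norm
        )
        np.testing.assert_allclose(out[:8], 0.2, atol=1e-9)     # patch 1 only
        np.testing.assert_allclose(out[8:16], 0.4, atol=1e-9)   # overlap mean
        np.testing.assert_allclose(out[16:], 0.6, atol=1e-9)    # patch 2 only

    def test_matches_brute_force_accumulation_oracle(self, rng):
        v = Volume(rng.uniform(-300, 300, (32, 32, 32)))
        plan = plan_patches(v.shape, (16, 16, 16), 0.5)
        norm = NormalizationSpec()

        def g(p):
            return np.tanh(p * 1.7 - 0.1)

        out = convert_volume(g, v, plan, norm)
        acc = np.zeros(v.shape)
        cnt = np.zeros(v.shape)
        normed = normalize_array(v.grid, norm)
        for corner in plan.corners:
            sl = tuple(slice(c, c + 16) for c in corner)
            acc[sl] += g(normed[sl])
            cnt[sl] += 1
        expected = denormalize_array(acc / cnt, norm)
        np.testing.assert_allclose(out.grid, expected, atol=1e-9)

    def test_commutes_with_constant_offset(self, rng):
        v = Volume(rng.uniform(-0.5, 0.5, (24, 16, 16)))
        plan = plan_patches(v.shape, (16, 16, 16), 0.5)
        norm = NormalizationSpec((-1.0, 1.0))

        def g(p):
            return 0.5 * p

        base = convert_volume(g, v, plan, norm)
        shifted = convert_volume(lambda p: g(p) + 0.1, v, plan, norm)
        np.testing.assert_allclose(
            shifted.grid - base.grid, 0.1 * (norm.high - norm.low) / 2, atol=1e-9
        )

    def test_volume_smaller_than_patch_is_padded_and_cropped(self, rng):
        v = Volume(rng.uniform(-100, 100, (10, 12, 6)))
        plan = plan_patches((16, 16, 8), (16, 16, 8))
        out = convert_volume(lambda p: p, v, plan)
        assert out.shape == v.shape
        np.testing.assert_allclose(out.grid, v.grid, atol=1e-9)


TOY_GEN = GeneratorConfig(n_levels=2, base_channels=4, max_channels=8,
                          patch_size=(16, 16, 8))
TOY_DISC = DiscriminatorConfig(n_layers=2, base_channels=4, max_channels=8,
                               patch_size=(16, 16, 8))


def tiny_cases(n=2, shape=(32, 32, 32)):
    cases = []
    for i in range(n):
        spec = default_clinical_spec(volume_shape=shape, seed=100 + i)
        ncect, cect, _ = generate_phantom(spec)
        cases.append((cect, ncect))
    return cases


class TestTraining:
    def test_smoke_run_finite_losses(self):
        cfg = TrainConfig(total_epochs=2, const_lr_epochs=1,
                          patches_per_case=1, seed=0)
        result = train(tiny_cases(), TOY_GEN, TOY_DISC, LossWeights(), cfg)
        assert len(result.history) == 2
        for rec in result.history:
            assert all(np.isfinite(v) for v in rec.values())

    def test_same_seed_reproduces_loss_history(self):
        cfg = TrainConfig(total_epochs=2, const_lr_epochs=1,
                          patches_per_case=1, seed=3)
        cases = tiny_cases()
        h1 = train(cases, TOY_GEN, TOY_DISC, LossWeights(), cfg).history
        h2 = train(cases, TOY_GEN, TOY_DISC, LossWeights(), cfg).history
        for a, b in zip(h1, h2):
            for key in a:
                assert a[key] == pytest.approx(b[key], rel=1e-9)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train([], TOY_GEN, TOY_DISC, LossWeights(), TrainConfig())

    def test_identity_task_drives_l1_down(self):
        # zero enhancement: CECT == NCECT, the generator learns the identity
        cases = []
        for i in range(2):
            spec = default_clinical_spec(volume_shape=(32, 32, 32), seed=i)
            ncect, _, _ = generate_phantom(spec)
            cases.append((ncect, ncect))
        cfg = TrainConfig(total_epochs=8, const_lr_epochs=4,
                          patches_per_case=2, seed=1)
        result = train(cases, TOY_GEN, TOY_DISC, LossWeights(), cfg)
        first, last = result.history[0]["g_l1"], result.history[-1]["g_l1"]
        assert last < first
        assert last < 0.05


class TestCheckpoints:
    def test_round_trip_restores_weights_and_meta(self, tmp_path):
        cfg = TrainConfig(total_epochs=1, const_lr_epochs=1,
                          patches_per_case=1, seed=5)
        result = train(tiny_cases(), TOY_GEN, TOY_DISC, LossWeights(), cfg)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, result.generator, result.discriminator,
                        Adam(result.generator.parameters()),
                        Adam(result.discriminator.parameters()),
                        epoch=1, cfg=cfg, history=result.history)
        gen, disc, meta = load_checkpoint(path)
        assert meta["epoch"] == 1
        for (ka, pa), (kb, pb) in zip(result.generator.named_parameters(),
                                      gen.named_parameters()):
            assert ka == kb
            np.testing.assert_array_equal(pa.data, pb.data)
        x = np.random.default_rng(0).normal(size=(1, 16, 16, 8))
        from decontrast3d.nn import Tensor
        np.testing.assert_array_equal(result.generator(Tensor(x)).data,
                                      gen(Tensor(x)).data)
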