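"""Architecture contracts, gradient-penalty closed forms, sampling and
dataset assembly of the conditional WGAN-GP."""

import numpy as np
import pandas as pd
import pytest

from idhgan import autodiff as ad
from idhgan.gan_balancer import (GanConfig, GanState, assemble_dataset,
                                 gradient_penalty, init_networks,
                                 sample_synthetic, train_cwgan_gp)
from tests.conftest import make_two_gaussian_table

FAST = GanConfig(batch_size=128, epochs=3, seed=0)


class TestInitNetworks:
    def test_generator_output_dimension_matches_features(self):
        state = init_networks(10, FAST, seed=0)
        out = sample_synthetic(state, 7, label=1, seed=1)
        assert out.shape == (7, 11)  # 10 features + label column

    def test_same_seed_identical_parameters(self):
        a = init_networks(5, FAST, seed=3)
        b = init_networks(5, FAST, seed=3)
        for k in a.gen_params:
            np.testing.assert_array_equal(a.gen_params[k], b.gen_params[k])
        for k in a.critic_params:
            np.testing.assert_array_equal(a.critic_params[k],
                                          b.critic_params[k])

    def test_fresh_samples_inside_open_unit_interval(self):
        state = init_networks(4, FAST, seed=0)
        out = sample_synthetic(state, 100, label=0, seed=2)
        cont = out[[f"f{i}" for i in range(4)]].to_numpy()
        assert (np.abs(cont) < 1.0).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GanConfig(gp_weight=-1.0)
        with pytest.raises(ValueError):
            GanConfig(n_critic=0)
        with pytest.raises(ValueError):
            init_networks(0, FAST)


class TestGradientPenalty:
    def _linear_critic(self, w):
        w = np.asarray(w, float).reshape(-1, 1)
        return lambda xh, yh: xh @ ad.Tensor(w)

    def test_unit_norm_linear_critic_gives_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(16, 2))
        pen = gradient_penalty(self._linear_critic([1.0, 0.0]), x, x + 0.1,
                               np.zeros((16, 2)), 5.0, rng)
        assert float(pen.data) == pytest.approx(0.0, abs=1e-12)

    def test_norm_two_linear_critic_closed_form(self):
        # D(x) = w.x with ||w|| = 2: penalty = lambda * (2 - 1)^2 = 5
        rng = np.random.default_rng(0)
        x = rng.normal(size=(16, 2))
        pen = gradient_penalty(self._linear_critic([2.0, 0.0]), x, x + 0.1,
                               np.zeros((16, 2)), 5.0, rng)
        assert float(pen.data) == pytest.approx(5.0, rel=1e-9)

    def test_zero_weight_disables_penalty(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 2))
        pen = gradient_penalty(self._linear_critic([3.0, 4.0]), x, x + 1.0,
                               np.zeros((8, 2)), 0.0, rng)
        assert float(pen.data) == 0.0

    def test_shape_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            gradient_penalty(self._linear_critic([1.0, 0.0]),
                             np.zeros((4, 2)), np.zeros((3, 2)),
                             np.zeros((4, 2)), 5.0, rng)

    def test_penalty_nonnegative_for_real_critic(self):
        from idhgan.gan_balancer import critic_forward

        state = init_networks(3, FAST, seed=1)
        live = {k: ad.Tensor(v, requires_grad=True)
                for k, v in state.critic_params.items()}
        rng = np.random.default_rng(2)
        x = rng.uniform(-0.9, 0.9, size=(32, 3))
        y = np.tile([1.0, 0.0], (32, 1))
        pen = gradient_penalty(
            lambda xh, yh: critic_forward(live, xh, yh, FAST,
                                          state.sn_vectors),
            x, x[::-1].copy(), y, 5.0, rng)
        assert float(pen.data) >= 0.0


class TestTraining:
    def test_short_run_losses_finite_and_logged(self):
        df = make_two_gaussian_table(n=1000, seed=4)
        state = train_cwgan_gp(df, FAST)
        losses = np.array([v for _, _, v in state.loss_history])
        assert np.isfinite(losses).all()
        assert len(losses) > 0

    def test_n_critic_pattern_in_history(self):
        df = make_two_gaussian_table(n=1000, seed=4)
        state = train_cwgan_gp(df, FAST)
        kinds = [k for _, k, _ in state.loss_history]
        # every generator step is preceded by exactly n_critic critic steps
        gen_positions = [i for i, k in enumerate(kinds) if k == "generator"]
        for prev, cur in zip([-1] + gen_positions[:-1], gen_positions):
            between = kinds[prev + 1:cur]
            assert between == ["critic"] * FAST.n_critic

    def test_same_seed_identical_final_generator(self):
        df = make_two_gaussian_table(n=600, seed=4)
        a = train_cwgan_gp(df, FAST)
        b = train_cwgan_gp(df, FAST)
        for k in a.gen_params:
            np.testing.assert_array_equal(a.gen_params[k], b.gen_params[k])

    def test_single_class_table_rejected(self):
        df = make_two_gaussian_table(n=200, seed=1)
        df["idh_next"] = 1.0
        with pytest.raises(ValueError):
            train_cwgan_gp(df, FAST)


class TestSampling:
    def test_zero_draw_is_empty(self):
        state = init_networks(3, FAST, seed=0)
        assert sample_synthetic(state, 0, label=1).empty

    def test_conditioning_label_column(self):
        state = init_networks(3, FAST, seed=0)
        out = sample_synthetic(state, 500, label=1, seed=3)
        assert len(out) == 500
        assert (out["idh_next"] == 1.0).all()

    def test_sampling_deterministic_given_seed(self):
        state = init_networks(3, FAST, seed=0)
        pd.testing.assert_frame_equal(
            sample_synthetic(state, 50, label=0, seed=9),
            sample_synthetic(state, 50, label=0, seed=9))

    def test_binary_columns_snapped(self):
        state = init_networks(3, FAST, seed=0,
                              binary_mask=np.array([False, True, False]))
        out = sample_synthetic(state, 200, label=1, seed=5)
        assert set(np.unique(out["f1"])) <= {0.0, 1.0}

    def test_negative_count_rejected(self):
        state = init_networks(2, FAST, seed=0)
        with pytest.raises(ValueError):
            sample_synthetic(state, -1, label=0)


class TestAssembleDataset:
    def _train(self, n_pos, n_neg, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.uniform(-0.9, 0.9, size=(n_pos + n_neg, 2)),
                          columns=["f0", "f1"])
        df["idh_next"] = [1.0] * n_pos + [0.0] * n_neg
        return df

    def test_balance_count_arithmetic(self):
        train = self._train(20, 80)
        state = init_networks(2, FAST, seed=0)
        out = assemble_dataset(train, state, mode="balance")
        assert len(out) == 160
        assert (out["idh_next"] == 1).sum() == 80
        assert (out["idh_next"] == 1).mean() == 0.5

    def test_original_rows_preserved_verbatim(self):
        train = self._train(20, 80)
        state = init_networks(2, FAST, seed=0)
        out = assemble_dataset(train, state, mode="balance")
        originals = out[~out["synthetic"]].drop(columns="synthetic")
        pd.testing.assert_frame_equal(originals, train)

    def test_augment_default_doubles_dataset(self):
        train = self._train(15, 85)
        state = init_networks(2, FAST, seed=0)
        out = assemble_dataset(train, state, mode="augment")
        assert len(out) == 200
        assert out["synthetic"].sum() == 100

    def test_balance_rejected_when_not_deficient(self):
        train = self._train(50, 50)
        state = init_networks(2, FAST, seed=0)
        with pytest.raises(ValueError):
            assemble_dataset(train, state, mode="balance")


class TestStatePersistence:
    def test_save_load_round_trip(self, tmp_path):
        df = make_two_gaussian_table(n=600, seed=4)
        state = train_cwgan_gp(df, FAST)
        path = tmp_path / "gan_state.npz"
        state.save(path)
        loaded = GanState.load(path)
        for k in state.gen_params:
            np.testing.assert_array_equal(state.gen_params[k],
                                          loaded.gen_params[k])
        pd.testing.assert_frame_equal(
            sample_synthetic(state, 20, 1, seed=1),
            sample_synthetic(loaded, 20, 1, seed=1))
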