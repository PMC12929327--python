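"""Bi-level optimizer correctness: finite-difference oracles, degeneration
contracts, partition conservation, reproducibility."""

import numpy as np
import pytest

import metacvs.autodiff as ad
from metacvs.backbone import tiny_config
from metacvs.dataset_io import MixedBatch
from metacvs.exceptions import ConfigError, DataError, DivergenceError
from metacvs.losses import LossWeights, primary_loss
from metacvs.meta import (MetaConfig, OptState, ParamPartition, batch_losses,
                          inner_adapt, outer_gradient, outer_update, train,
                          train_joint_baseline)
from metacvs.network import forward, group_of, init_model


@pytest.fixture(scope="module")
def tiny_setup():
    cfg = tiny_config()
    params = init_model(cfg, seed=7)
    rng = np.random.default_rng(7)
    from metacvs.dataset_io import LabeledFrameClip
    def clip(dual):
        frames = rng.random((cfg.frame_length, cfg.input_size, cfg.input_size, 3))
        mask = (rng.integers(0, cfg.n_classes, (cfg.input_size, cfg.input_size))
                if dual else None)
        crit = tuple(bool(x) for x in rng.integers(0, 2, 3))
        return LabeledFrameClip(frames, crit, mask, "p0", 0)
    duals = [clip(True) for _ in range(3)]
    prims = [clip(False) for _ in range(2)]
    return cfg, params, MixedBatch(duals, prims)


def _dot(gdict, vdict):
    return sum(float((gdict[k] * vdict[k]).sum()) for k in gdict)


def _shifted(params, v, eps):
    return {k: ad.parameter(p.data + eps * v[k]) for k, p in params.items()}


class TestGradientOracles:
    def test_inner_gradient_matches_central_differences(self, tiny_setup):
        cfg, params, batch = tiny_setup
        mcfg = MetaConfig(alpha_l=1e-2, alpha_g=1e-3, m=3, n=2)
        _, _, l_total = batch_losses(params, cfg, batch.dual_samples,
                                     mcfg.loss_weights, need_seg=True)
        names = list(params)
        grads = ad.grad(l_total, [params[k] for k in names])
        g = {k: t.data for k, t in zip(names, grads)}
        rng = np.random.default_rng(0)
        for trial in range(3):
            v = {k: rng.normal(size=params[k].shape) for k in names}
            eps = 1e-6

            def at(p):
                return float(batch_losses(p, cfg, batch.dual_samples,
                                          mcfg.loss_weights, True)[2].data)

            fd = (at(_shifted(params, v, eps)) - at(_shifted(params, v, -eps))) / (2 * eps)
            assert abs(_dot(g, v) - fd) / abs(fd) < 1e-3

    def test_inner_step_equals_theta_minus_alpha_grad(self, tiny_setup):
        cfg, params, batch = tiny_setup
        mcfg = MetaConfig(alpha_l=1e-3, alpha_g=1e-3, m=3, n=2)
        _, _, l_total = batch_losses(params, cfg, batch.dual_samples,
                                     mcfg.loss_weights, need_seg=True)
        names = list(params)
        grads = ad.grad(l_total, [params[k] for k in names])
        tilde, _ = inner_adapt(params, cfg, mcfg, batch.dual_samples)
        for k, gt in zip(names, grads):
            assert np.allclose(tilde[k].data, params[k].data - 1e-3 * gt.data,
                               atol=1e-15)

    def test_second_order_outer_gradient_matches_composed_fd(self, tiny_setup):
        cfg, params, batch = tiny_setup
        mcfg = MetaConfig(alpha_l=1e-2, alpha_g=1e-3, m=3, n=2,
                          gradient_mode="second_order")
        og = outer_gradient(params, cfg, mcfg, batch)

        def composed(p):
            tilde, _ = inner_adapt(p, cfg, mcfg, batch.dual_samples)
            frames = np.stack([c.frames for c in batch.all_samples])
            labels = np.array([[float(x) for x in c.criteria]
                               for c in batch.all_samples])
            logits, _ = forward(tilde, cfg, frames)
            return float(primary_loss(logits, labels).data)

        rng = np.random.default_rng(1)
        for trial in range(3):
            v = {k: rng.normal(size=params[k].shape) for k in params}
            eps = 1e-6
            fd = (composed(_shifted(params, v, eps))
                  - composed(_shifted(params, v, -eps))) / (2 * eps)
            assert abs(_dot(og, v) - fd) / abs(fd) < 1e-3

    def test_first_order_converges_to_second_order_as_alpha_l_vanishes(
            self, tiny_setup):
        cfg, params, batch = tiny_setup
        diffs = []
        for al in (1e-2, 1e-6):
            g1 = outer_gradient(params, cfg, MetaConfig(
                alpha_l=al, alpha_g=1e-3, m=3, n=2), batch)
            g2 = outer_gradient(params, cfg, MetaConfig(
                alpha_l=al, alpha_g=1e-3, m=3, n=2,
                gradient_mode="second_order"), batch)
            num = np.sqrt(sum(((g1[k] - g2[k]) ** 2).sum() for k in g1))
            den = np.sqrt(sum((g2[k] ** 2).sum() for k in g2))
            diffs.append(num / den)
        assert diffs[1] < 1e-3          # vanishing-alpha_l limit
        assert diffs[1] < diffs[0]      # difference shrinks with alpha_l

    def test_descent_at_some_small_alpha(self, tiny_setup):
        cfg, params, batch = tiny_setup
        base = float(batch_losses(params, cfg, batch.dual_samples,
                                  LossWeights(), True)[2].data)
        improved = False
        for al in (1e-2, 1e-3, 1e-4):
            mcfg = MetaConfig(alpha_l=al, alpha_g=1e-3, m=3, n=2)
            tilde, _ = inner_adapt(params, cfg, mcfg, batch.dual_samples)
            after = float(batch_losses(tilde, cfg, batch.dual_samples,
                                       LossWeights(), True)[2].data)
            improved = improved or after < base
        assert improved


class TestInnerAdapt:
    def test_zero_alpha_is_bitwise_identity(self, tiny_setup):
        cfg, params, batch = tiny_setup
        mcfg = MetaConfig(alpha_l=0.0, alpha_g=1e-3, m=3, n=2)
        tilde, _ = inner_adapt(params, cfg, mcfg, batch.dual_samples)
        for k in params:
            assert np.array_equal(tilde[k].data, params[k].data)

    def test_input_parameters_not_mutated(self, tiny_setup):
        cfg, params, batch = tiny_setup
        before = {k: p.data.copy() for k, p in params.items()}
        mcfg = MetaConfig(alpha_l=1e-2, alpha_g=1e-3, m=3, n=2)
        inner_adapt(params, cfg, mcfg, batch.dual_samples)
        for k in params:
            assert np.array_equal(params[k].data, before[k])

    def test_missing_mask_rejected(self, tiny_setup):
        cfg, params, batch = tiny_setup
        mcfg = MetaConfig(alpha_l=1e-2, alpha_g=1e-3, m=3, n=2)
        with pytest.raises(DataError):
            inner_adapt(params, cfg, mcfg, batch.primary_only_samples)


class TestOuterUpdate:
    def test_only_shared_and_primary_groups_step_from_theta(self, tiny_setup):
        cfg, params, batch = tiny_setup
        mcfg = MetaConfig(alpha_l=1e-2, alpha_g=1e-3, m=3, n=2)
        tilde, _ = inner_adapt(params, cfg, mcfg, batch.dual_samples)
        new, _ = outer_update(params, tilde, cfg, mcfg, batch, OptState())
        for k in params:
            if group_of(k) == "Aux":
                assert np.array_equal(new[k].data, tilde[k].data)
            else:
                assert not np.array_equal(new[k].data, tilde[k].data) or \
                    np.array_equal(tilde[k].data, params[k].data)

    def test_mismatched_partition_rejected(self, tiny_setup):
        cfg, params, batch = tiny_setup
        mcfg = MetaConfig(alpha_l=1e-2, alpha_g=1e-3, m=3, n=2)
        tilde, _ = inner_adapt(params, cfg, mcfg, batch.dual_samples)
        tilde.pop(next(iter(tilde)))
        with pytest.raises(ConfigError):
            outer_update(params, tilde, cfg, mcfg, batch)

    def test_aux_discard_mode_keeps_original(self, tiny_setup):
        cfg, params, batch = tiny_setup
        mcfg = MetaConfig(alpha_l=1e-2, alpha_g=1e-3, m=3, n=2,
                          aux_persist=False)
        tilde, _ = inner_adapt(params, cfg, mcfg, batch.dual_samples)
        new, _ = outer_update(params, tilde, cfg, mcfg, batch, OptState())
        for k in params:
            if group_of(k) == "Aux":
                assert np.array_equal(new[k].data, params[k].data)


class TestTrainingLoops:
    def test_meta_trainer_degenerates_to_plain_gradient_descent(self, tiny_setup):
        """n=0, alpha_l=0, w_aux=0: trajectory bitwise equals single-task GD."""
        cfg, _, batch = tiny_setup
        pool = batch.dual_samples * 3          # 9 dual clips
        weights = LossWeights(w_pri=1.0, w_aux=0.0)
        mcfg = MetaConfig(alpha_l=0.0, alpha_g=1e-2, m=4, n=0,
                          optimizer="sgd", loss_weights=weights, seed=11)
        meta_state = train(pool, cfg, mcfg, steps=50)
        # plain GD over the same trainable set as the meta outer loop
        plain_state = train_joint_baseline(pool, cfg, mcfg, steps=50,
                                           update_groups=("B", "Pri"))
        for k in meta_state.params:
            assert np.array_equal(meta_state.params[k].data,
                                  plain_state.params[k].data), k

    def test_same_seed_same_trajectory(self, tiny_setup):
        cfg, _, batch = tiny_setup
        pool = batch.dual_samples * 2 + batch.primary_only_samples * 2
        mcfg = MetaConfig(alpha_l=1e-2, alpha_g=1e-3, m=3, n=1, seed=5)
        s1 = train(pool, cfg, mcfg, steps=5)
        s2 = train(pool, cfg, mcfg, steps=5)
        for k in s1.params:
            assert np.array_equal(s1.params[k].data, s2.params[k].data)
        assert s1.history == s2.history

    def test_loss_trace_length_and_bookkeeping(self, tiny_setup, tmp_path):
        cfg, _, batch = tiny_setup
        pool = batch.dual_samples * 2 + batch.primary_only_samples
        mcfg = MetaConfig(alpha_l=1e-2, alpha_g=1e-3, m=2, n=1, seed=1,
                          checkpoint_every=2)
        state = train(pool, cfg, mcfg, steps=4, out_dir=tmp_path)
        assert state.step == 4
        assert len(state.history) == 4
        assert {h["step"] for h in state.history} == {1, 2, 3, 4}
        assert (tmp_path / "checkpoint_000002.npz").exists()
        assert (tmp_path / "checkpoint_final.npz").exists()

    def test_joint_baseline_smoothed_loss_decreases(self, tiny_setup):
        cfg, _, batch = tiny_setup
        pool = batch.dual_samples * 4
        mcfg = MetaConfig(alpha_l=0.0, alpha_g=5e-3, m=4, n=0,
                          optimizer="adam", seed=2)
        state = train_joint_baseline(pool, cfg, mcfg, steps=60)
        trace = np.array([h["L_total_inner"] for h in state.history])
        assert trace[-15:].mean() < trace[:15].mean()

    def test_divergence_guard_reports_step(self, tiny_setup):
        cfg, _, batch = tiny_setup
        pool = batch.dual_samples * 2
        mcfg = MetaConfig(alpha_l=0.0, alpha_g=1e12, m=2, n=0,
                          optimizer="sgd", seed=3)
        with pytest.raises(DivergenceError, match="step"):
            train(pool, cfg, mcfg, steps=50)

    def test_resume_reproduces_trajectory(self, tiny_setup):
        cfg, _, batch = tiny_setup
        pool = batch.dual_samples * 2 + batch.primary_only_samples
        mcfg = MetaConfig(alpha_l=1e-2, alpha_g=1e-3, m=2, n=1, seed=9)
        full = train(pool, cfg, mcfg, steps=6)
        half = train(pool, cfg, mcfg, steps=3)
        resumed = train(pool, cfg, mcfg, steps=3, state=half)
        for k in full.params:
            assert np.array_equal(full.params[k].data, resumed.params[k].data)


class TestParamPartition:
    def test_counts_cover_all_parameters(self, tiny_setup):
        cfg, params, _ = tiny_setup
        part = ParamPartition(params)
        counts = part.counts()
        assert sum(counts.values()) == sum(p.size for p in params.values())
        names = sum((part.names(g) for g in ("B", "Pri", "Aux")), [])
        assert sorted(names) == sorted(params)
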