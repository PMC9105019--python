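"""PWC sampling, learning-rate schedule, alternating updates, fit/resume."""

import numpy as np
import pytest

from mammogan.patching import Patch, PatchCategory
from mammogan.training import (PatchPair, PatchPool, TrainConfig, fit,
                               init_state, lr_schedule, pwc_sample_pair,
                               tiny_train_config, train_step)


def _patch(cat, side=8, seed=0):
    rng = np.random.default_rng(seed)
    mask = {PatchCategory.BREAST: np.ones((side, side)),
            PatchCategory.BACKGROUND: np.zeros((side, side))}.get(cat)
    if mask is None:
        mask = np.zeros((side, side))
        mask[:side // 2] = 1
    return Patch(rng.normal(size=(side, side)), mask.astype(np.uint8), cat,
                 (0, 0), side)


def _pool(counts):
    patches = []
    for cat, n in counts.items():
        patches.extend(_patch(cat, seed=i) for i in range(n))
    return PatchPool(patches)


class TestPwcSampling:
    def test_ten_thousand_draws_zero_mismatches(self, rng):
        dfm = _pool({PatchCategory.BREAST: 5, PatchCategory.BOUNDARY: 10,
                     PatchCategory.BACKGROUND: 3})
        ffdm = _pool({PatchCategory.BREAST: 4, PatchCategory.BOUNDARY: 7,
                      PatchCategory.BACKGROUND: 2})
        mismatches = 0
        for _ in range(10000):
            pair = pwc_sample_pair(dfm, ffdm, rng)
            mismatches += (pair.dfm_patch.category
                           is not pair.ffdm_patch.category)
        assert mismatches == 0

    def test_boundary_draw_returns_boundary_partner(self, rng):
        dfm = _pool({PatchCategory.BOUNDARY: 5})
        ffdm = _pool({PatchCategory.BOUNDARY: 5, PatchCategory.BREAST: 5})
        for _ in range(50):
            pair = pwc_sample_pair(dfm, ffdm, rng)
            assert pair.ffdm_patch.category is PatchCategory.BOUNDARY

    def test_missing_category_fallback_and_error_modes(self, rng):
        dfm = _pool({PatchCategory.BACKGROUND: 5, PatchCategory.BREAST: 5})
        ffdm = _pool({PatchCategory.BREAST: 5})
        stats = {}
        for _ in range(100):
            pair = pwc_sample_pair(dfm, ffdm, rng, stats=stats)
            assert pair.dfm_patch.category is PatchCategory.BREAST
        assert stats["fallbacks"] > 0
        with pytest.raises(LookupError):
            for _ in range(100):
                pwc_sample_pair(dfm, ffdm, rng, on_missing="error")

    def test_disjoint_pools_rejected(self, rng):
        dfm = _pool({PatchCategory.BREAST: 3})
        ffdm = _pool({PatchCategory.BACKGROUND: 3})
        with pytest.raises(ValueError):
            pwc_sample_pair(dfm, ffdm, rng)

    def test_pair_invariant_enforced(self):
        with pytest.raises(ValueError):
            PatchPair(_patch(PatchCategory.BREAST),
                      _patch(PatchCategory.BACKGROUND))


class TestLrSchedule:
    CFG = TrainConfig(lr_initial=5e-4, epochs_constant=80, epochs_decay=120)

    def test_constant_phase(self):
        assert lr_schedule(0, self.CFG) == 5e-4
        assert lr_schedule(79, self.CFG) == 5e-4

    def test_decays_to_zero_at_final_epoch(self):
        assert lr_schedule(199, self.CFG) == pytest.approx(0.0, abs=5e-4 / 120)

    def test_midpoint_of_decay(self):
        assert lr_schedule(140, self.CFG) == pytest.approx(2.5e-4,
                                                           abs=5e-4 / 120)

    def test_non_increasing_piecewise_linear_single_knot(self):
        lrs = [lr_schedule(e, self.CFG) for e in range(200)]
        diffs = np.diff(lrs)
        assert np.all(diffs <= 1e-15)
        slopes = {round(d, 12) for d in diffs}
        assert len(slopes) == 2          # one flat piece, one linear piece

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lr_schedule(200, self.CFG)
        with pytest.raises(ValueError):
            lr_schedule(-1, self.CFG)


def _mini_batch(rng, n=2, side=16):
    pairs = []
    for i in range(n):
        mask = np.zeros((side, side), dtype=np.uint8)
        mask[:side // 2] = 1
        a = Patch(rng.normal(size=(side, side)).clip(-1, 1), mask,
                  PatchCategory.BOUNDARY, (0, 0), side)
        b = Patch(rng.normal(size=(side, side)).clip(-1, 1), mask,
                  PatchCategory.BOUNDARY, (0, 0), side)
        pairs.append(PatchPair(a, b))
    return pairs


class TestTrainStep:
    CFG = tiny_train_config(batch_size=2, gen_width=8, disc_width=8)

    def test_phase_isolation_generators_fixed_during_critic_update(self, rng):
        state = init_state(self.CFG)
        state.opt_g.lr = 0.0                      # inert generator optimizer
        g_before = {k: v.copy() for k, v in state.G.state_dict().items()}
        d_before = {k: v.copy() for k, v in state.D_X.state_dict().items()}
        train_step(state, _mini_batch(rng), self.CFG)
        for k, v in state.G.state_dict().items():
            np.testing.assert_array_equal(v, g_before[k])
        assert any(not np.array_equal(v, d_before[k])
                   for k, v in state.D_X.state_dict().items())

    def test_phase_isolation_critics_fixed_during_generator_update(self, rng):
        state = init_state(self.CFG)
        state.opt_d.lr = 0.0
        d_before = {k: v.copy() for k, v in state.D_Y.state_dict().items()}
        g_before = {k: v.copy() for k, v in state.G.state_dict().items()}
        train_step(state, _mini_batch(rng), self.CFG)
        for k, v in state.D_Y.state_dict().items():
            np.testing.assert_array_equal(v, d_before[k])
        assert any(not np.array_equal(v, g_before[k])
                   for k, v in state.G.state_dict().items())

    def test_identical_seeds_give_identical_losses(self, rng):
        batch = _mini_batch(rng)
        traces = []
        for _ in range(2):
            state = init_state(self.CFG)
            trace = [train_step(state, batch, self.CFG) for _ in range(3)]
            traces.append([(b.total, f.total, dx, dy)
                           for b, f, dx, dy in trace])
        assert traces[0] == traces[1]

    def test_loss_breakdowns_are_consistent(self, rng):
        state = init_state(self.CFG)
        bd_g, bd_f, l_dx, l_dy = train_step(state, _mini_batch(rng), self.CFG)
        for bd in (bd_g, bd_f):
            assert bd.total == pytest.approx(bd.l_gan + 10.0 * bd.l_cyc)
        assert l_dx >= 0 and l_dy >= 0


class TestFit:
    def _pools(self, tiny_dataset):
        return (PatchPool(tiny_dataset.film_pool),
                PatchPool(tiny_dataset.digital_pool))

    def test_smoke_run_logs_every_iteration(self, tiny_dataset, tmp_path):
        cfg = tiny_train_config(seed=1, max_iters=4)
        fp, dp = self._pools(tiny_dataset)
        state, log = fit(cfg, fp, dp, out_dir=tmp_path)
        assert len(log) == 4 and state.iteration == 4
        assert (tmp_path / "final.npz").exists()
        assert (tmp_path / "train_log.jsonl").exists()

    def test_resume_reproduces_uninterrupted_trace(self, tiny_dataset, tmp_path):
        fp, dp = self._pools(tiny_dataset)
        full_cfg = tiny_train_config(seed=2, max_iters=8)
        _, full_log = fit(full_cfg, fp, dp)

        half_cfg = tiny_train_config(seed=2, max_iters=4)
        fit(half_cfg, fp, dp, out_dir=tmp_path)
        _, resumed = fit(full_cfg, fp, dp, resume_from=tmp_path / "final.npz")
        np.testing.assert_array_equal(
            full_log.iloc[4:][["loss_G", "loss_F"]].to_numpy(),
            resumed[["loss_G", "loss_F"]].to_numpy())

    def test_same_seed_reproduces_trace(self, tiny_dataset):
        fp, dp = self._pools(tiny_dataset)
        cfg = tiny_train_config(seed=3, max_iters=3)
        _, log1 = fit(cfg, fp, dp)
        _, log2 = fit(cfg, fp, dp)
        np.testing.assert_array_equal(log1.to_numpy(), log2.to_numpy())


def test_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(lambda_weight=0.0)
    with pytest.raises(ValueError):
        TrainConfig(batch_size=0)
    assert TrainConfig().total_epochs == 200
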