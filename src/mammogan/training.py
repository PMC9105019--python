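"""Training loop: category-constrained pair sampling and alternating updates.

Pair-with-constraint (PWC) sampling: a film patch is drawn uniformly from
the whole film pool, its category (breast / boundary / background) is read,
and the digital patch is then drawn uniformly from that category's digital
sub-pool — never across categories, so a background patch can never be
paired with breast tissue.

Each iteration performs one discriminator update (both critics, generators
frozen) followed by one generator update (both generators, critics frozen),
the alternating scheme of cycle-consistent adversarial training.  The
learning rate stays at its initial value for the first ``epochs_constant``
epochs and then decays linearly to zero over ``epochs_decay`` more.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from .losses import loss_generator_total, scale_mse_vs_target, target_stack
from .nn import Adam, MultiScaleDiscriminator, UNetGenerator, \
    load_modules, save_modules
from .patching import Patch, PatchCategory, SOBEL_SCALE, SOBEL_X, SOBEL_Y


class TrainingDivergenceError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    """Hyperparameters; defaults follow the published training protocol
    (lambda = 10, Adam, batch 16, lr 5e-4, 80 constant + 120 decay epochs).
    """

    lambda_weight: float = 10.0
    batch_size: int = 16
    lr_initial: float = 5e-4
    epochs_constant: int = 80
    epochs_decay: int = 120
    seed: int = 0
    betas: Tuple[float, float] = (0.5, 0.999)
    # architecture
    gen_depth: int = 4
    gen_width: int = 64
    gen_n_res: int = 2
    disc_layers: int = 4
    disc_width: int = 64
    n_scales: int = 3
    # desk-scale controls
    max_iters: Optional[int] = None       # cap total iterations if set
    checkpoint_every: int = 20            # epochs
    pwc_on_missing: str = "resample"      # or "error"
    dtype: str = "float32"                # network/activation precision

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs_constant < 1 or self.epochs_decay < 1:
            raise ValueError("counts must be positive")
        if not (self.lambda_weight > 0 and self.lr_initial > 0):
            raise ValueError("lambda_weight and lr_initial must be positive")

    @property
    def total_epochs(self) -> int:
        return self.epochs_constant + self.epochs_decay


def tiny_train_config(**overrides) -> TrainConfig:
    """2-level networks, width 16, batch 4 — minutes on one CPU."""
    base = dict(batch_size=4, gen_depth=2, gen_width=16, gen_n_res=1,
                disc_layers=2, disc_width=16, max_iters=500)
    base.update(overrides)
    return TrainConfig(**base)


@dataclass(frozen=True)
class PatchPair:
    dfm_patch: Patch
    ffdm_patch: Patch

    def __post_init__(self):
        if self.dfm_patch.category != self.ffdm_patch.category:
            raise ValueError("PWC violated: pair categories differ")


class PatchPool:
    """A categorized patch index supporting uniform and per-category draws."""

    def __init__(self, patches: Sequence[Patch]):
        if not patches:
            raise ValueError("empty patch pool")
        self.patches = list(patches)
        self.by_category: Dict[PatchCategory, List[int]] = {c: [] for c in PatchCategory}
        for i, p in enumerate(self.patches):
            self.by_category[p.category].append(i)

    def __len__(self):
        return len(self.patches)

    def categories(self):
        return {c for c, idx in self.by_category.items() if idx}


def pwc_sample_pair(dfm_pool: PatchPool, ffdm_pool: PatchPool,
                    rng: np.random.Generator, on_missing: str = "resample",
                    max_tries: int = 1000, stats: Optional[dict] = None
                    ) -> PatchPair:
    """Draw one category-matched (film, digital) pair.

    The film patch is drawn first from the full pool; the digital patch is
    then drawn from the same-category sub-pool.  If that sub-pool is empty
    the film draw is repeated (default; counted in ``stats['fallbacks']``)
    or an error is raised.
    """
    if not (dfm_pool.categories() & ffdm_pool.categories()):
        raise ValueError("pools share no category; PWC sampling impossible")
    for _ in range(max_tries):
        d_idx = int(rng.integers(len(dfm_pool)))
        dfm = dfm_pool.patches[d_idx]
        sub = ffdm_pool.by_category[dfm.category]
        if not sub:
            if on_missing == "error":
                raise LookupError(
                    f"digital pool has no {dfm.category.value} patches")
            if stats is not None:
                stats["fallbacks"] = stats.get("fallbacks", 0) + 1
            continue
        f_idx = sub[int(rng.integers(len(sub)))]
        return PatchPair(dfm, ffdm_pool.patches[f_idx])
    raise LookupError("PWC sampling exhausted its retry budget")


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Constant for ``epochs_constant`` epochs, then linear decay to zero."""
    if not (0 <= epoch < cfg.total_epochs):
        raise ValueError(f"epoch {epoch} outside [0, {cfg.total_epochs})")
    if epoch < cfg.epochs_constant:
        return cfg.lr_initial
    frac = (epoch - cfg.epochs_constant + 1) / cfg.epochs_decay
    return max(0.0, cfg.lr_initial * (1.0 - frac))


# ---------------------------------------------------------------------------
# differentiable pyramid (gradients flow into the generators)

_SOBEL_KERNELS = {}


def _sobel_tensors(dtype):
    if dtype not in _SOBEL_KERNELS:
        _SOBEL_KERNELS[dtype] = (Tensor(SOBEL_X[None, None].astype(dtype)),
                                 Tensor(SOBEL_Y[None, None].astype(dtype)))
    return _SOBEL_KERNELS[dtype]


def pyramid_tensors(x: Tensor, n_scales: int = 3) -> List[Tensor]:
    """[image, Sobel-magnitude] planes at factor-2 scales, as graph nodes."""
    kx, ky = _sobel_tensors(x.data.dtype.type)
    levels = []
    cur = x
    for l in range(n_scales):
        if l > 0:
            cur = ad.avg_pool2(cur)
        padded = ad.pad2d(cur, (1, 1, 1, 1), mode="replicate")
        gx = ad.scale(ad.conv2d(padded, kx), SOBEL_SCALE)
        gy = ad.scale(ad.conv2d(padded, ky), SOBEL_SCALE)
        mag = ad.sqrt_safe(ad.add(ad.mul(gx, gx), ad.mul(gy, gy)))
        levels.append(ad.concat_channels([cur, mag]))
    return levels


@dataclass
class TrainState:
    G: UNetGenerator                 # film -> digital
    F: UNetGenerator                 # digital -> film
    D_X: MultiScaleDiscriminator     # critic on the film domain
    D_Y: MultiScaleDiscriminator     # critic on the digital domain
    opt_g: Adam
    opt_d: Adam
    iteration: int = 0
    epoch: int = 0
    fallback_count: int = 0


def init_state(cfg: TrainConfig) -> TrainState:
    seeds = np.random.SeedSequence(cfg.seed).spawn(4)
    rngs = [np.random.default_rng(s) for s in seeds]
    dtype = np.dtype(cfg.dtype).type
    G = UNetGenerator(cfg.gen_depth, cfg.gen_width, cfg.gen_n_res,
                      rng=rngs[0], dtype=dtype)
    F = UNetGenerator(cfg.gen_depth, cfg.gen_width, cfg.gen_n_res,
                      rng=rngs[1], dtype=dtype)
    D_X = MultiScaleDiscriminator(cfg.n_scales, 2, cfg.disc_width,
                                  cfg.disc_layers, rng=rngs[2], dtype=dtype)
    D_Y = MultiScaleDiscriminator(cfg.n_scales, 2, cfg.disc_width,
                                  cfg.disc_layers, rng=rngs[3], dtype=dtype)
    gen_params = {f"G.{k}": v for k, v in G.parameters().items()}
    gen_params.update({f"F.{k}": v for k, v in F.parameters().items()})
    disc_params = {f"D_X.{k}": v for k, v in D_X.parameters().items()}
    disc_params.update({f"D_Y.{k}": v for k, v in D_Y.parameters().items()})
    return TrainState(G, F, D_X, D_Y,
                      Adam(gen_params, cfg.lr_initial, cfg.betas),
                      Adam(disc_params, cfg.lr_initial, cfg.betas))


def _stack(pairs: Sequence[PatchPair], dtype):
    x = np.stack([p.dfm_patch.pixels for p in pairs])[:, None].astype(dtype)
    y = np.stack([p.ffdm_patch.pixels for p in pairs])[:, None].astype(dtype)
    mx = np.stack([p.dfm_patch.mask for p in pairs]).astype(np.float64)
    my = np.stack([p.ffdm_patch.mask for p in pairs]).astype(np.float64)
    return x, y, mx, my


def _disc_loss_combined(disc, real_t: Tensor, fake_t: Tensor,
                        mask_real, mask_fake, n_sc: int) -> Tensor:
    """sum_l [ mse(D(real), m_1) + mse(D(fake), m_0) ], evaluated on one
    concatenated batch per scale (algebraically identical, one BLAS pass)."""
    n = real_t.data.shape[0]
    both = ad.concat_batch([real_t, fake_t])
    outs = disc.forward(pyramid_tensors(both, n_sc))
    total = None
    for level, out in enumerate(outs, start=1):
        h, w = out.data.shape[-2:]
        tgt = np.concatenate([target_stack(1, mask_real, level, (h, w)),
                              target_stack(0, mask_fake, level, (h, w))])
        term = ad.scale(ad.mse(out, tgt.astype(out.data.dtype)), 2.0)
        total = term if total is None else ad.add(total, term)
    return total


def train_step(state: TrainState, batch: Sequence[PatchPair], cfg: TrainConfig
               ):
    """One alternating update; returns loss breakdowns for G and F plus the
    two critic losses.

    The generator forward graph is built once per iteration: the critic
    update consumes detached fakes from it, and the subsequent generator
    update backpropagates through the same graph against the freshly
    updated critics (generator weights are untouched by the critic step, so
    the cached activations stay exact).
    """
    dtype = np.dtype(cfg.dtype).type
    x_np, y_np, mx, my = _stack(batch, dtype)
    n_sc = cfg.n_scales
    n = x_np.shape[0]

    # one shared generator forward pass
    x_t, y_t = Tensor(x_np), Tensor(y_np)
    y_hat = state.G.forward(x_t)                      # G: film -> digital
    f_out = state.F.forward(ad.concat_batch([y_t, y_hat]))
    x_hat, rec_x = ad.split_batch(f_out, n)           # F(y), F(G(x))
    rec_y = state.G.forward(x_hat)                    # G(F(y))

    # --- discriminator phase (generators frozen: fakes detached) ----------
    state.opt_d.zero_grad()
    l_dx = _disc_loss_combined(state.D_X, x_t, x_hat.detach(), mx, my, n_sc)
    l_dy = _disc_loss_combined(state.D_Y, y_t, y_hat.detach(), my, mx, n_sc)
    l_d = ad.add(l_dx, l_dy)
    if not np.isfinite(l_d.data):
        raise TrainingDivergenceError("non-finite discriminator loss")
    l_d.backward()
    state.opt_d.step()

    # --- generator phase (critics frozen: opt_d not stepped) --------------
    state.opt_g.zero_grad()
    state.opt_d.zero_grad()          # discard any grads the G pass adds
    adv_g = scale_mse_vs_target(state.D_Y.forward(pyramid_tensors(y_hat, n_sc)),
                                1, mx)
    adv_f = scale_mse_vs_target(state.D_X.forward(pyramid_tensors(x_hat, n_sc)),
                                1, my)
    cyc_x = ad.l1(rec_x, x_np)
    cyc_y = ad.l1(rec_y, y_np)
    total = ad.add(ad.add(adv_g, adv_f),
                   ad.scale(ad.add(cyc_x, cyc_y), cfg.lambda_weight))
    if not np.isfinite(total.data):
        raise TrainingDivergenceError("non-finite generator loss")
    total.backward()
    state.opt_g.step()
    state.opt_d.zero_grad()

    bd_g = loss_generator_total(float(adv_g.data), float(cyc_x.data),
                                cfg.lambda_weight)
    bd_f = loss_generator_total(float(adv_f.data), float(cyc_y.data),
                                cfg.lambda_weight)
    state.iteration += 1
    return bd_g, bd_f, float(l_dx.data), float(l_dy.data)


def _set_lr(state: TrainState, lr: float):
    state.opt_g.lr = lr
    state.opt_d.lr = lr


def save_checkpoint(path, state: TrainState, cfg: TrainConfig,
                    sampler_rng: Optional[np.random.Generator] = None):
    meta = {"iteration": state.iteration, "epoch": state.epoch,
            "fallback_count": state.fallback_count,
            "config": {k: v for k, v in vars(cfg).items()}}
    if sampler_rng is not None:
        meta["sampler_state"] = sampler_rng.bit_generator.state
    save_modules(path, {"G": state.G, "F": state.F,
                        "D_X": state.D_X, "D_Y": state.D_Y},
                 {"opt_g": state.opt_g, "opt_d": state.opt_d}, meta)


def load_checkpoint(path, cfg: TrainConfig):
    state = init_state(cfg)
    load_modules(path, {"G": state.G, "F": state.F,
                        "D_X": state.D_X, "D_Y": state.D_Y},
                 {"opt_g": state.opt_g, "opt_d": state.opt_d})
    meta_path = Path(str(path) + ".json")
    sampler_state = None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        state.iteration = int(meta.get("iteration", 0))
        state.epoch = int(meta.get("epoch", 0))
        state.fallback_count = int(meta.get("fallback_count", 0))
        sampler_state = meta.get("sampler_state")
    return state, sampler_state


def fit(cfg: TrainConfig, dfm_pool: PatchPool, ffdm_pool: PatchPool,
        out_dir=None, resume_from=None, log_every: int = 1):
    """Run the alternating loop over PWC-sampled batches.

    An epoch is one pass of ``max(|film pool|, |digital pool|)`` sampled
    pairs (the pools are unpaired, so epoch length is a convention).  With
    ``cfg.max_iters`` set, training stops after that many iterations
    regardless of epochs — the desk-scale mode.  Returns the final state
    and the per-iteration loss log as a DataFrame; with ``out_dir`` the log
    is persisted as JSONL next to the checkpoints.
    """
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    n_pairs = max(len(dfm_pool), len(ffdm_pool))
    iters_per_epoch = max(1, int(np.ceil(n_pairs / cfg.batch_size)))

    sampler_rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed).spawn(5)[4])
    if resume_from is not None:
        state, sampler_state = load_checkpoint(resume_from, cfg)
        if sampler_state is not None:
            sampler_rng.bit_generator.state = sampler_state
    else:
        state = init_state(cfg)

    log: List[dict] = []
    log_path = out_dir / "train_log.jsonl" if out_dir is not None else None
    total_iters = cfg.max_iters if cfg.max_iters is not None \
        else cfg.total_epochs * iters_per_epoch

    while state.iteration < total_iters:
        state.epoch = min(state.iteration // iters_per_epoch,
                          cfg.total_epochs - 1)
        lr = lr_schedule(state.epoch, cfg)
        _set_lr(state, lr)
        stats: dict = {}
        batch = [pwc_sample_pair(dfm_pool, ffdm_pool, sampler_rng,
                                 on_missing=cfg.pwc_on_missing, stats=stats)
                 for _ in range(cfg.batch_size)]
        state.fallback_count += stats.get("fallbacks", 0)
        try:
            bd_g, bd_f, l_dx, l_dy = train_step(state, batch, cfg)
        except TrainingDivergenceError:
            if out_dir is not None:
                save_checkpoint(out_dir / "diverged.npz", state, cfg,
                                sampler_rng)
            raise
        if state.iteration % log_every == 0:
            rec = {"iteration": state.iteration, "epoch": state.epoch,
                   "lr": lr, "loss_G": bd_g.total, "loss_F": bd_f.total,
                   "loss_D_X": l_dx, "loss_D_Y": l_dy,
                   "l_cyc_x": bd_g.l_cyc, "l_cyc_y": bd_f.l_cyc}
            log.append(rec)
            if log_path is not None:
                with open(log_path, "a") as fh:
                    fh.write(json.dumps(rec) + "\n")
        if (out_dir is not None and state.iteration % iters_per_epoch == 0
                and (state.iteration // iters_per_epoch) % cfg.checkpoint_every == 0):
            save_checkpoint(out_dir / f"ckpt_iter{state.iteration}.npz",
                            state, cfg, sampler_rng)

    if out_dir is not None:
        save_checkpoint(out_dir / "final.npz", state, cfg, sampler_rng)
    return state, pd.DataFrame(log)
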