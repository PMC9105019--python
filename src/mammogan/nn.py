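"""Network building blocks for the translation model.

The generator is a U-Net whose convolutional blocks are residual blocks and
whose up path mirrors the down path with skip concatenations; it is fully
convolutional, so weights trained on patches apply to whole mammograms.  The
discriminator is a set of three independent patch critics, one per pyramid
scale, each consuming a 2-channel [image, gradient-map] plane and emitting a
2-channel map (real/fake prediction plane + breast-region probability
plane).

No normalization layers are used anywhere: a spatial-statistic normalizer
(instance/group norm) makes the output of a patch depend on global image
statistics, which would break the equality between whole-image and tiled
inference that the fully-convolutional design is meant to guarantee.
"""

from __future__ import annotations

import json
from typing import Dict, List, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class: a named tree of parameter tensors."""

    def __init__(self):
        self._params: Dict[str, Tensor] = {}
        self._children: Dict[str, "Module"] = {}

    def register(self, name: str, tensor: Tensor) -> Tensor:
        self._params[name] = tensor
        return tensor

    def add_child(self, name: str, module: "Module") -> "Module":
        self._children[name] = module
        return module

    def parameters(self) -> Dict[str, Tensor]:
        out = dict(self._params)
        for cname, child in self._children.items():
            for pname, p in child.parameters().items():
                out[f"{cname}.{pname}"] = p
        return out

    def zero_grad(self):
        for p in self.parameters().values():
            p.zero_grad()

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]):
        params = self.parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.array(state[k], dtype=p.data.dtype)


class Conv2d(Module):
    """Convolution with symmetric padding folded in.

    Weights are drawn from N(0, 0.02), the GAN-standard initialization;
    biases start at zero.
    """

    def __init__(self, in_ch, out_ch, kernel, stride=1, pad=0,
                 pad_mode="constant", rng=None, init_std=0.02,
                 dtype=np.float64):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.stride = stride
        self.pad = pad
        self.pad_mode = pad_mode
        w = rng.normal(0.0, init_std, size=(out_ch, in_ch, kernel, kernel))
        self.w = self.register("w", Tensor(w.astype(dtype), requires_grad=True))
        self.b = self.register("b", Tensor(np.zeros(out_ch, dtype=dtype),
                                           requires_grad=True))

    def forward(self, x: Tensor) -> Tensor:
        if self.pad:
            x = ad.pad2d(x, (self.pad,) * 4, mode=self.pad_mode)
        return ad.conv2d(x, self.w, self.b, stride=self.stride)


class ResBlock(Module):
    """x + conv(relu(conv(x))) with reflection padding, width preserved."""

    def __init__(self, ch, rng=None, dtype=np.float64):
        super().__init__()
        self.c1 = self.add_child("c1", Conv2d(ch, ch, 3, pad=1,
                                              pad_mode="reflect", rng=rng,
                                              dtype=dtype))
        self.c2 = self.add_child("c2", Conv2d(ch, ch, 3, pad=1,
                                              pad_mode="reflect", rng=rng,
                                              dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        h = ad.relu(self.c1.forward(x))
        return ad.add(x, self.c2.forward(h))


class UNetGenerator(Module):
    """Residual U-Net mapping one grayscale plane to another in [-1, 1].

    Parameters
    ----------
    depth : number of down/up sampling levels; input sides must be
        multiples of ``2**depth``.
    base_width : channel count at the first level; doubles per level.
    n_res : residual blocks per level on each path.
    final : output activation, ``tanh`` (translation), ``sigmoid``
        (segmentation probability) or ``linear``.
    """

    def __init__(self, depth=4, base_width=64, n_res=2, in_ch=1, out_ch=1,
                 final="tanh", rng=None, dtype=np.float64):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.depth = depth
        self.final = final
        kw = {"rng": rng, "dtype": dtype}
        widths = [base_width * 2 ** i for i in range(depth + 1)]
        self.stem = self.add_child("stem", Conv2d(in_ch, widths[0], 3, pad=1,
                                                  pad_mode="reflect", **kw))
        self.down_res: List[List[ResBlock]] = []
        self.down_samp: List[Conv2d] = []
        for i in range(depth):
            blocks = [self.add_child(f"down{i}_res{j}",
                                     ResBlock(widths[i], rng, dtype))
                      for j in range(n_res)]
            self.down_res.append(blocks)
            self.down_samp.append(self.add_child(
                f"down{i}_samp", Conv2d(widths[i], widths[i + 1], 3, stride=2,
                                        pad=1, pad_mode="reflect", **kw)))
        self.mid = [self.add_child(f"mid_res{j}",
                                   ResBlock(widths[depth], rng, dtype))
                    for j in range(n_res)]
        self.up_conv: List[Conv2d] = []
        self.up_fuse: List[Conv2d] = []
        self.up_res: List[List[ResBlock]] = []
        for i in reversed(range(depth)):
            self.up_conv.append(self.add_child(
                f"up{i}_conv", Conv2d(widths[i + 1], widths[i], 3, pad=1,
                                      pad_mode="reflect", **kw)))
            self.up_fuse.append(self.add_child(
                f"up{i}_fuse", Conv2d(2 * widths[i], widths[i], 3, pad=1,
                                      pad_mode="reflect", **kw)))
            self.up_res.append([self.add_child(f"up{i}_res{j}",
                                               ResBlock(widths[i], rng, dtype))
                                for j in range(n_res)])
        self.head = self.add_child("head", Conv2d(widths[0], out_ch, 3, pad=1,
                                                  pad_mode="reflect", **kw))

    def forward(self, x: Tensor) -> Tensor:
        H, W = x.shape[-2:]
        div = 2 ** self.depth
        if H % div or W % div:
            raise ValueError(
                f"input sides ({H},{W}) must be multiples of 2**depth = {div}")
        h = ad.relu(self.stem.forward(x))
        skips = []
        for blocks, samp in zip(self.down_res, self.down_samp):
            for blk in blocks:
                h = blk.forward(h)
            skips.append(h)
            h = ad.relu(samp.forward(h))
        for blk in self.mid:
            h = blk.forward(h)
        for conv, fuse, blocks, skip in zip(self.up_conv, self.up_fuse,
                                            self.up_res, reversed(skips)):
            h = ad.relu(conv.forward(ad.upsample_nearest2(h)))
            h = ad.relu(fuse.forward(ad.concat_channels([h, skip])))
            for blk in blocks:
                h = blk.forward(h)
        out = self.head.forward(h)
        if self.final == "tanh":
            return ad.tanh(out)
        if self.final == "sigmoid":
            return ad.sigmoid(out)
        return out


class ScaleDiscriminator(Module):
    """Patch critic for one pyramid scale.

    ``n_layers`` stride-2 kernel-4 convolutions with leaky-ReLU, then a 1x1
    convolution to 2 channels.  Channel 1 stays linear (least-squares GAN);
    channel 2 passes through a sigmoid so it reads as a breast-region
    probability.  Output side = input side / 2**n_layers.
    """

    def __init__(self, in_ch=2, base_width=64, n_layers=4, rng=None,
                 dtype=np.float64):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.n_layers = n_layers
        self.convs: List[Conv2d] = []
        ch = in_ch
        width = base_width
        for i in range(n_layers):
            self.convs.append(self.add_child(
                f"conv{i}", Conv2d(ch, width, 4, stride=2, pad=1, rng=rng,
                                   dtype=dtype)))
            ch = width
            width = min(width * 2, base_width * 8)
        self.out = self.add_child("out", Conv2d(ch, 2, 1, rng=rng, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for conv in self.convs:
            h = ad.leaky_relu(conv.forward(h))
        raw = self.out.forward(h)
        pred = Tensor(raw.data[:, 0:1], raw.requires_grad, (raw,))
        # slicing backward: route each channel's grad into the raw map
        mask_logit = Tensor(raw.data[:, 1:2], raw.requires_grad, (raw,))

        def bw_pred(g, _raw=raw):
            full = np.zeros_like(_raw.data)
            full[:, 0:1] = g
            _raw._accum(full)

        def bw_mask(g, _raw=raw):
            full = np.zeros_like(_raw.data)
            full[:, 1:2] = g
            _raw._accum(full)

        pred._backward = bw_pred
        mask_logit._backward = bw_mask
        return ad.concat_channels([pred, ad.sigmoid(mask_logit)])


class MultiScaleDiscriminator(Module):
    """Three independent per-scale critics (no weight sharing)."""

    def __init__(self, n_scales=3, in_ch=2, base_width=64, n_layers=4,
                 rng=None, dtype=np.float64):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.n_scales = n_scales
        self.n_layers = n_layers
        self.scales = [self.add_child(f"scale{l}",
                                      ScaleDiscriminator(in_ch, base_width,
                                                         n_layers, rng, dtype))
                       for l in range(n_scales)]

    def forward(self, pyramid: Sequence[Tensor]) -> List[Tensor]:
        if len(pyramid) != self.n_scales:
            raise ValueError(f"expected {self.n_scales} pyramid levels, "
                             f"got {len(pyramid)}")
        outs = []
        for level, sub in zip(pyramid, self.scales):
            if level.shape[1] != 2:
                raise ValueError("each pyramid level must have 2 channels")
            outs.append(sub.forward(level))
        return outs


class ConvClassifier(Module):
    """Small convolutional binary classifier (global-pooled sigmoid score)."""

    def __init__(self, base_width=8, n_layers=3, in_ch=1, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.convs: List[Conv2d] = []
        ch = in_ch
        width = base_width
        for i in range(n_layers):
            self.convs.append(self.add_child(
                f"conv{i}", Conv2d(ch, width, 3, stride=2, pad=1, rng=rng)))
            ch = width
            width *= 2
        self.out = self.add_child("out", Conv2d(ch, 1, 1, rng=rng))

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for conv in self.convs:
            h = ad.leaky_relu(conv.forward(h))
        logits = self.out.forward(h)
        return ad.sigmoid(_global_mean(logits))


def _global_mean(x: Tensor) -> Tensor:
    """Mean over the two trailing axes, keeping (N, C)."""
    n = x.data.shape[-1] * x.data.shape[-2]
    y = Tensor(x.data.mean(axis=(-2, -1)), x.requires_grad, (x,))

    def backward(g):
        x._accum(np.broadcast_to(g[..., None, None] / n, x.data.shape))

    y._backward = backward
    return y


class Adam:
    """Adam with (beta1, beta2) = (0.5, 0.999) by default (GAN convention)."""

    def __init__(self, params: Dict[str, Tensor], lr=5e-4, betas=(0.5, 0.999),
                 eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad ** 2
            p.data -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)

    def state_dict(self):
        return {"t": self.t,
                "m": {k: v.copy() for k, v in self.m.items()},
                "v": {k: v.copy() for k, v in self.v.items()}}

    def load_state_dict(self, state):
        self.t = int(state["t"])
        for k in self.m:
            self.m[k] = np.array(state["m"][k])
            self.v[k] = np.array(state["v"][k])


def save_modules(path, modules: Dict[str, Module], optimizers=None, meta=None):
    """Checkpoint: one npz of flat arrays plus a JSON sidecar of metadata."""
    arrays = {}
    for mname, mod in modules.items():
        for k, v in mod.state_dict().items():
            arrays[f"{mname}/{k}"] = v
    if optimizers:
        for oname, opt in optimizers.items():
            sd = opt.state_dict()
            arrays[f"__opt__/{oname}/t"] = np.asarray(sd["t"])
            for k, v in sd["m"].items():
                arrays[f"__opt__/{oname}/m/{k}"] = v
            for k, v in sd["v"].items():
                arrays[f"__opt__/{oname}/v/{k}"] = v
    np.savez(path, **arrays)
    if meta is not None:
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=2, default=str)


def load_modules(path, modules: Dict[str, Module], optimizers=None):
    with np.load(path) as data:
        arrays = {k: data[k] for k in data.files}
    for mname, mod in modules.items():
        prefix = f"{mname}/"
        state = {k[len(prefix):]: v for k, v in arrays.items()
                 if k.startswith(prefix)}
        mod.load_state_dict(state)
    if optimizers:
        for oname, opt in optimizers.items():
            prefix = f"__opt__/{oname}/"
            t = int(arrays[prefix + "t"])
            m = {k[len(prefix) + 2:]: v for k, v in arrays.items()
                 if k.startswith(prefix + "m/")}
            v = {k[len(prefix) + 2:]: vv for k, vv in arrays.items()
                 if k.startswith(prefix + "v/")}
            opt.load_state_dict({"t": t, "m": m, "v": v})
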