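"""Metrics and the downstream transfer-learning protocol.

The usefulness of the translation is measured not on pixels but on tasks:
a mass-segmentation task (dice coefficient, on images downsampled 4x from
the 100 um working resolution to 400 um) and a calcification-detection
task (ROC AUC on small tiles, tiles that are more than 80 % background
removed, a tile labeled 1 iff it contains a calcification).  For each
cross-validation fold two arms are compared: a baseline model trained on
the small real training split only, and a model pretrained on synthesized
digital images and then finetuned on the same real split at a reduced
learning rate.  Folds are grouped by anatomy/patient identifier so no
subject straddles a split.

dice = 2|A ∩ B| / (|A| + |B|);  AUC equals the Mann-Whitney statistic
P(score_pos > score_neg) + 0.5 P(tie).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import autodiff as ad
from .autodiff import Tensor
from .image import BreastMask, GrayscaleImage
from .nn import Adam, ConvClassifier, UNetGenerator
from .patching import background_fraction, downsample_avg


# ---------------------------------------------------------------------------
# metrics

def dice_score(truth: np.ndarray, pred: np.ndarray) -> float:
    """Overlap 2|A∩B|/(|A|+|B|); two empty masks agree perfectly (1.0)."""
    a = np.asarray(truth).astype(bool)
    b = np.asarray(pred).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve via midranks (ties count half)."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("labels and scores must be equal-length 1-D")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes present")
    ranks = sstats.rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# dataset construction

@dataclass(frozen=True)
class LabeledPatch:
    pixels: np.ndarray
    label: int
    origin_rc: Tuple[int, int]
    group: int = 0


def build_calc_patch_dataset(img: GrayscaleImage, mask: BreastMask,
                             calc_points: Sequence[Tuple[int, int]],
                             side: int = 224, max_background: float = 0.80,
                             group: int = 0) -> List[LabeledPatch]:
    """Non-overlapping tiles for calcification detection.

    Tiles with a background fraction strictly above ``max_background`` are
    removed; a kept tile is labeled 1 iff at least one calcification
    coordinate falls inside it.
    """
    H, W = img.shape
    out = []
    pts = [(int(r), int(c)) for r, c in calc_points]
    for r in range(0, H - side + 1, side):
        for c in range(0, W - side + 1, side):
            frac = background_fraction(mask.mask[r:r + side, c:c + side])
            if frac > max_background:
                continue
            label = int(any(r <= pr < r + side and c <= pc < c + side
                            for pr, pc in pts))
            out.append(LabeledPatch(img.pixels[r:r + side, c:c + side].copy(),
                                    label, (r, c), group))
    return out


@dataclass(frozen=True)
class SegExample:
    """One segmentation training example: image plane + binary lesion mask."""
    pixels: np.ndarray
    target: np.ndarray
    group: int = 0


def grouped_folds(groups: Sequence[int], folds: int, seed: int = 0
                  ) -> List[np.ndarray]:
    """Partition sample indices into folds, keeping each group intact."""
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < folds:
        raise ValueError(f"{len(uniq)} groups cannot fill {folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(uniq)
    assignment = {g: i % folds for i, g in enumerate(order)}
    return [np.flatnonzero([assignment[g] == f for g in groups])
            for f in range(folds)]


# ---------------------------------------------------------------------------
# small task models + their training

@dataclass
class ProtocolConfig:
    folds: int = 5
    seed: int = 0
    lr_baseline_seg: float = 1e-4
    lr_baseline_det: float = 5e-4
    lr_finetune: float = 5e-5
    batch_size: int = 8
    train_steps: int = 400
    pretrain_steps: int = 1200
    seg_depth: int = 1
    seg_width: int = 8
    det_width: int = 8
    det_layers: int = 3
    seg_threshold: float = 0.5


def _train_seg(model: UNetGenerator, data: Sequence[SegExample], steps: int,
               lr: float, batch: int, rng: np.random.Generator):
    opt = Adam(model.parameters(), lr=lr)
    n = len(data)
    for _ in range(steps):
        idx = rng.integers(n, size=min(batch, n))
        x = np.stack([data[i].pixels for i in idx])[:, None]
        t = np.stack([data[i].target for i in idx])[:, None].astype(np.float64)
        opt.zero_grad()
        prob = model.forward(Tensor(x))
        # dice term carries the tiny-lesion signal, BCE stabilizes the rest
        loss = ad.add(ad.soft_dice_loss(prob, t), ad.bce(prob, t))
        loss.backward()
        opt.step()


def _train_det(model: ConvClassifier, data: Sequence[LabeledPatch],
               steps: int, lr: float, batch: int, rng: np.random.Generator):
    opt = Adam(model.parameters(), lr=lr)
    n = len(data)
    for _ in range(steps):
        idx = rng.integers(n, size=min(batch, n))
        x = np.stack([data[i].pixels for i in idx])[:, None]
        t = np.array([data[i].label for i in idx], dtype=np.float64
                     ).reshape(-1, 1)
        opt.zero_grad()
        loss = ad.bce(model.forward(Tensor(x)), t)
        loss.backward()
        opt.step()


def _eval_seg(model, data, threshold) -> float:
    x = np.stack([ex.pixels for ex in data])[:, None]
    probs = model.forward(Tensor(x)).data[:, 0]
    return float(np.mean([dice_score(ex.target, p >= threshold)
                          for ex, p in zip(data, probs)]))


def _eval_det(model, data) -> float:
    labels = [p.label for p in data]
    if len(set(labels)) < 2:
        return float("nan")       # fold without both classes: AUC undefined
    x = np.stack([p.pixels for p in data])[:, None]
    scores = model.forward(Tensor(x)).data[:, 0]
    return roc_auc(labels, scores)


def run_protocol(task: str, real_train_set, pretrain_set=None,
                 folds: int = 5, cfg: Optional[ProtocolConfig] = None
                 ) -> pd.DataFrame:
    """Fivefold baseline-vs-finetuned comparison on one downstream task.

    ``task`` is ``"mass_segmentation"`` (SegExample items, dice) or
    ``"calc_detection"`` (LabeledPatch items, AUC).  The pretrained model is
    trained ONCE on ``pretrain_set`` (synthesized digital images — the set
    does not depend on the folds) and then finetuned per fold on the real
    training split at the reduced finetune rate; the baseline trains from
    scratch on the same split.  An empty pretrain set collapses the
    finetuned arm to the baseline.  Returns long-format rows
    (task, fold, arm, metric, value).
    """
    cfg = cfg or ProtocolConfig(folds=folds)
    if task not in ("mass_segmentation", "calc_detection"):
        raise ValueError(f"unknown task {task!r}")
    seg = task == "mass_segmentation"
    data = list(real_train_set)
    pretrain = list(pretrain_set) if pretrain_set else []
    fold_idx = grouped_folds([d.group for d in data], folds, cfg.seed)
    metric = "dice" if seg else "auc"
    lr0 = cfg.lr_baseline_seg if seg else cfg.lr_baseline_det
    train_fn = _train_seg if seg else _train_det

    def new_model(init_rng):
        if seg:
            return UNetGenerator(cfg.seg_depth, cfg.seg_width, 1,
                                 final="sigmoid", rng=init_rng)
        return ConvClassifier(cfg.det_width, cfg.det_layers, rng=init_rng)

    master = np.random.SeedSequence(cfg.seed)
    pre_seed, *fold_parents = master.spawn(folds + 1)
    pretrained_state = None
    if pretrain:
        s_init, s_train = pre_seed.spawn(2)
        model_pre = new_model(np.random.default_rng(s_init))
        train_fn(model_pre, pretrain, cfg.pretrain_steps, lr0,
                 cfg.batch_size, np.random.default_rng(s_train))
        pretrained_state = model_pre.state_dict()

    rows = []
    fold_seeds = [s.spawn(3) for s in fold_parents]
    for fold, val_ids in enumerate(fold_idx):
        val = [data[i] for i in val_ids]
        train = [data[i] for i in range(len(data)) if i not in set(val_ids)]
        seeds = fold_seeds[fold]
        for arm in ("baseline", "finetuned"):
            if arm == "finetuned" and not pretrain:
                # no pretraining set: the arm collapses to the baseline
                rows.append({**rows[-1], "arm": "finetuned"})
                continue
            rng = np.random.default_rng(seeds[0 if arm == "baseline" else 1])
            model = new_model(np.random.default_rng(seeds[2]))
            if arm == "finetuned":
                model.load_state_dict(pretrained_state)
                lr = cfg.lr_finetune
            else:
                lr = lr0
            train_fn(model, train, cfg.train_steps, lr, cfg.batch_size, rng)
            value = (_eval_seg(model, val, cfg.seg_threshold) if seg
                     else _eval_det(model, val))
            rows.append({"task": task, "fold": fold, "arm": arm,
                         "metric": metric, "value": value})
    return pd.DataFrame(rows)


def summarize_protocol(results: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sd per arm and the per-fold paired differences with a sign
    summary (no significance test: the comparison is directional)."""
    wide = results.pivot_table(index=["task", "fold"], columns="arm",
                               values="value").reset_index()
    wide["diff"] = wide["finetuned"] - wide["baseline"]
    out = []
    for task, grp in wide.groupby("task"):
        out.append({
            "task": task,
            "baseline_mean": grp["baseline"].mean(),
            "baseline_sd": grp["baseline"].std(ddof=1),
            "finetuned_mean": grp["finetuned"].mean(),
            "finetuned_sd": grp["finetuned"].std(ddof=1),
            "median_diff": grp["diff"].median(),
            "n_folds_improved": int((grp["diff"] > 0).sum()),
            "n_folds": len(grp),
        })
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# phantom adapters

def seg_examples_from_images(images, masks, groups, downsample: int = 4
                             ) -> List[SegExample]:
    """Downsample images (block mean) and lesion masks (majority) by the
    segmentation working factor and normalize pixels to [-1, 1]."""
    out = []
    for img, m, g in zip(images, masks, groups):
        px = downsample_avg(np.asarray(img, dtype=np.float64), downsample)
        lo, hi = px.min(), px.max()
        px = np.zeros_like(px) if hi <= lo else 2 * (px - lo) / (hi - lo) - 1
        tgt = (downsample_avg(np.asarray(m, dtype=np.float64), downsample)
               >= 0.5).astype(np.uint8)
        out.append(SegExample(px, tgt, int(g)))
    return out
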