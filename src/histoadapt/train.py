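"""Two-stage training: supervised source learning, then unsupervised
adversarial + Siamese adaptation of the target network.

Stage 1 minimizes the cross-entropy Lc of the source classifier with
mini-batch SGD (momentum 0.9, weight decay 5e-4, step-annealed learning
rate), keeping the checkpoint with the best validation patch accuracy.

Stage 2 freezes the source network and fine-tunes a copy of it on unlabeled
target patches with Adam at a fixed learning rate, interleaving three
updates per iteration:

  (i)  discriminator step on  LadvD = -E_s log D(f_s) - E_t log(1 - D(f_t))
  (ii) target-mapping step on LadvM = -E_t log D(f_t)   (inverted label)
  (iii) Siamese step on Ls, the binary cross-entropy of the same-WSI pair
        classifier, with pairs sampled half within one WSI, half across WSIs.

Together these realize the joint objective Lt = La + Ls with La = LadvD +
LadvM.  Class labels of the target domain are never used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize as sk_resize

from .errors import DivergenceError, SamplingError
from .models import Discriminator, build_target_net
from .nn import SGD, Adam, BatchNorm, sigmoid
from .wsi import LABELS

_CLAMP = 1e-7


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class SourceTrainConfig:
    batch_size: int = 128
    momentum: float = 0.9
    weight_decay: float = 0.0005
    lr0: float = 0.001
    anneal_factor: float = 0.1
    anneal_period: int | None = None  # default: every ceil(epochs/3) epochs
    epochs: int = 30
    resize: int = 256
    crop: int = 224
    hflip: bool = False
    seed: int = 0

    def __post_init__(self):
        if min(self.batch_size, self.epochs, self.resize, self.crop) < 1:
            raise ValueError("batch_size, epochs, resize and crop must be positive")
        if self.crop > self.resize:
            raise ValueError("crop must not exceed resize")

    @classmethod
    def tiny(cls, input_size=64, epochs=10, batch_size=16, seed=0, **kw):
        """Scaled-down preset: crop equals the net input, resize keeps the
        256:224 ratio of the full-scale recipe."""
        return cls(batch_size=batch_size, epochs=epochs, seed=seed,
                   resize=int(round(input_size * 256 / 224)), crop=input_size, **kw)


@dataclass
class AdaptConfig:
    lr: float = 0.00001  # fixed Adam learning rate
    batch_size: int = 128  # mini-batch for both La and Ls
    n_iterations: int = 2000
    pair_balance: float = 0.5
    use_adversarial: bool = True
    use_siamese: bool = True
    hidden_dims: tuple = (500, 500)
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0 or self.batch_size < 1 or self.n_iterations < 0:
            raise ValueError("lr, batch_size must be positive; n_iterations >= 0")
        if not 0.0 < self.pair_balance < 1.0:
            raise ValueError("pair_balance must lie in (0, 1)")


@dataclass
class PairBatch:
    """Index pairs into a row table plus the same-WSI indicator."""

    idx1: np.ndarray
    idx2: np.ndarray
    y: np.ndarray  # 1 iff the two patches share a WSI


# ---------------------------------------------------------------------------
# losses (values and analytic score gradients)
# ---------------------------------------------------------------------------

def _clamp(p):
    return np.clip(p, _CLAMP, 1.0 - _CLAMP)


def softmax_cross_entropy(scores, onehot):
    """Mean cross-entropy over the batch and its gradient wrt the scores."""
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(onehot, dtype=np.float64)
    if scores.shape != y.shape:
        raise ValueError("scores and labels must align")
    z = scores - scores.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = float(-(y * logp).sum(axis=1).mean())
    grad = (np.exp(logp) - y) / scores.shape[0]
    return loss, grad.astype(np.float32)


def classification_loss(scores, onehot):
    """Lc: mean over the batch of -sum_k y_k log softmax(scores)_k."""
    y = np.asarray(onehot)
    if not np.isin(y, (0, 1)).all() or not np.all(y.sum(axis=1) == 1):
        raise ValueError("labels must be one-hot")
    loss, _ = softmax_cross_entropy(scores, y)
    return loss


def adversarial_losses(discriminator, source_feats, target_feats, train=False):
    """(LadvD, LadvM) of a discriminator on source/target feature batches.

    LadvD scores real/fake domain labels; LadvM is the target-mapping loss
    with the domain label inverted.  Probabilities are clamped to
    [1e-7, 1-1e-7] before the logarithms.
    """
    fs = np.asarray(source_feats)
    ft = np.asarray(target_feats)
    if fs.shape[0] == 0 or ft.shape[0] == 0:
        raise ValueError("feature batches must be nonempty")
    ps = _clamp(discriminator.prob(fs, train=train))
    pt = _clamp(discriminator.prob(ft, train=train))
    ladv_d = float(-np.mean(np.log(ps)) - np.mean(np.log(1.0 - pt)))
    ladv_m = float(-np.mean(np.log(pt)))
    return ladv_d, ladv_m


def siamese_loss(pair_probs, ybar):
    """Ls: mean binary cross-entropy of the same-WSI pair classifier."""
    p = np.asarray(pair_probs, dtype=np.float64)
    y = np.asarray(ybar, dtype=np.float64)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("pair labels must be binary")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("pair probabilities must lie in [0, 1]")
    p = _clamp(p)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------

def one_hot(labels):
    idx = np.array([LABELS.index(l) for l in labels])
    out = np.zeros((len(idx), len(LABELS)), dtype=np.float32)
    out[np.arange(len(idx)), idx] = 1.0
    return out


def resize_stack(images, size):
    """Resize a (N, H, W, 3) uint8 stack to ``size``; float32 in [0, 255]."""
    images = np.asarray(images)
    if images.shape[1] == size and images.shape[2] == size:
        return images.astype(np.float32)
    out = np.empty((images.shape[0], size, size, 3), dtype=np.float32)
    for i, img in enumerate(images):
        out[i] = sk_resize(img, (size, size), preserve_range=True,
                           anti_aliasing=True)
    return out


def random_crop(batch, crop, rng, hflip=False):
    n, h, w = batch.shape[:3]
    ys = rng.integers(0, h - crop + 1, size=n)
    xs = rng.integers(0, w - crop + 1, size=n)
    out = np.empty((n, crop, crop, 3), dtype=np.float32)
    for i in range(n):
        out[i] = batch[i, ys[i] : ys[i] + crop, xs[i] : xs[i] + crop]
    if hflip:
        flip = rng.random(n) < 0.5
        out[flip] = out[flip, :, ::-1]
    return out


def center_crop(batch, crop):
    h, w = batch.shape[1:3]
    y0, x0 = (h - crop) // 2, (w - crop) // 2
    return np.ascontiguousarray(batch[:, y0 : y0 + crop, x0 : x0 + crop])


def to_net_input(batch_hwc):
    """(N, H, W, 3) pixels in [0, 255] -> NCHW float32 in [-0.5, 0.5]."""
    x = np.asarray(batch_hwc, dtype=np.float32) / 255.0 - 0.5
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def predict_scores(net, images, batch_size=64):
    """Evaluation-mode (features, logits) for an image stack.

    Images already at the net input size pass straight through; larger ones
    are center-cropped, smaller ones resized.
    """
    size = net.config.input_size
    images = np.asarray(images)
    if images.shape[1] == size and images.shape[2] == size:
        prep = images.astype(np.float32)
    elif images.shape[1] >= size and images.shape[2] >= size:
        prep = center_crop(images.astype(np.float32), size)
    else:
        prep = resize_stack(images, size)
    feats, scores = [], []
    for i in range(0, len(prep), batch_size):
        f, s = net.forward(to_net_input(prep[i : i + batch_size]), train=False)
        feats.append(f)
        scores.append(s)
    return np.concatenate(feats), np.concatenate(scores)


# ---------------------------------------------------------------------------
# stage 1: source training
# ---------------------------------------------------------------------------

def train_source(net, dataset, cfg=None):
    """Supervised SGD training of the source classifier.

    Training patches are resized then randomly cropped each epoch
    (optionally flipped); validation uses a single center crop.  Returns the
    network restored to its best-validation-accuracy checkpoint and a
    per-epoch history frame.
    """
    cfg = cfg or SourceTrainConfig()
    man = dataset.manifest
    domain = man.df["domain"].iloc[0]
    tr = man.rows(domain=domain, split="train")
    va = man.rows(domain=domain, split="val")
    if len(tr) == 0 or len(va) == 0:
        raise ValueError("manifest needs nonempty labeled train and val splits")
    ytr = one_hot(man.labels(tr))
    yva = np.array([LABELS.index(l) for l in man.labels(va)])
    xtr = resize_stack(dataset.patch_array(tr), cfg.resize)
    xva = center_crop(resize_stack(dataset.patch_array(va), cfg.resize), cfg.crop)

    rng = np.random.default_rng(cfg.seed)
    opt = SGD(net.param_layers(), lr=cfg.lr0, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    period = cfg.anneal_period or math.ceil(cfg.epochs / 3)
    history = []
    best_acc, best_state = -1.0, None
    n = len(xtr)
    for epoch in range(cfg.epochs):
        if epoch > 0 and epoch % period == 0:
            opt.lr *= cfg.anneal_factor
        perm = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            idx = perm[i : i + cfg.batch_size]
            xb = random_crop(xtr[idx], cfg.crop, rng, hflip=cfg.hflip)
            net.zero_grad()
            _, scores = net.forward(to_net_input(xb), train=True, rng=rng)
            loss, gscores = softmax_cross_entropy(scores, ytr[idx])
            if not np.isfinite(loss):
                raise DivergenceError("source training loss is non-finite",
                                      state=net.state())
            net.backward(gscores=gscores)
            opt.step()
            losses.append(loss)
        # xva is already cropped float pixels; forward directly
        val_scores = []
        for i in range(0, len(xva), cfg.batch_size):
            _, s = net.forward(to_net_input(xva[i : i + cfg.batch_size]), train=False)
            val_scores.append(s)
        val_scores = np.concatenate(val_scores)
        val_acc = float(np.mean(val_scores.argmax(axis=1) == yva))
        history.append({"epoch": epoch, "lr": opt.lr,
                        "train_loss": float(np.mean(losses)), "val_acc": val_acc})
        if val_acc > best_acc:
            best_acc, best_state = val_acc, net.state()
    net.load_state(best_state)
    return net, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# pair sampling
# ---------------------------------------------------------------------------

def sample_pairs(rows, batch_size, balance=0.5, rng=None):
    """Sample a balanced batch of same-WSI and cross-WSI patch pairs.

    ``rows`` is a manifest row table of the target training split; class
    labels are never consulted.  A fraction ``balance`` of pairs is drawn
    within a uniformly chosen WSI (two distinct patches), the rest across
    two distinct WSIs.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    wsis = rows.groupby("wsi_id", sort=True).indices  # wsi -> positional idx
    wsi_ids = sorted(wsis)
    multi = [w for w in wsi_ids if len(wsis[w]) >= 2]
    n_same = int(round(batch_size * balance))
    n_diff = batch_size - n_same
    if n_same > 0 and not multi:
        raise SamplingError("no WSI has two or more patches")
    if n_diff > 0 and len(wsi_ids) < 2:
        raise SamplingError("need at least two WSIs for cross-WSI pairs")
    i1, i2, y = [], [], []
    for _ in range(n_same):
        w = multi[rng.integers(len(multi))]
        a, b = rng.choice(len(wsis[w]), size=2, replace=False)
        i1.append(wsis[w][a])
        i2.append(wsis[w][b])
        y.append(1)
    for _ in range(n_diff):
        wa, wb = rng.choice(len(wsi_ids), size=2, replace=False)
        i1.append(wsis[wsi_ids[wa]][rng.integers(len(wsis[wsi_ids[wa]]))])
        i2.append(wsis[wsi_ids[wb]][rng.integers(len(wsis[wsi_ids[wb]]))])
        y.append(0)
    return PairBatch(np.array(i1), np.array(i2), np.array(y))


# ---------------------------------------------------------------------------
# stage 2: adversarial + Siamese adaptation
# ---------------------------------------------------------------------------

def adapt_target(source_net, source_ds, target_ds, cfg=None):
    """Unsupervised adaptation of a copied target network.

    The source network is frozen throughout (only forwarded in evaluation
    mode); the target network and discriminator are trained "at the same
    time" by interleaving the discriminator, mapping and Siamese updates
    each iteration.  Returns (target_net, discriminator, history).
    """
    cfg = cfg or AdaptConfig()
    # independent random streams so ablations (e.g. disabling the Siamese
    # term) leave the adversarial path's randomness unchanged — a
    # common-random-numbers design for paired comparisons
    ss = np.random.SeedSequence(cfg.seed)
    rng_batch, rng_pair, rng_drop, rng_pair_drop = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    target_net = build_target_net(source_net, seed=cfg.seed)
    disc = Discriminator(source_net.config.feature_channels, cfg.hidden_dims,
                         seed=cfg.seed + 1)
    src_rows = source_ds.manifest.rows(domain="source", split="train")
    tgt_rows = target_ds.manifest.rows(domain="target", split="train").reset_index(drop=True)
    size = source_net.config.input_size
    xs = to_net_input(center_crop(resize_stack(source_ds.patch_array(src_rows), size), size))
    xt = to_net_input(center_crop(resize_stack(target_ds.patch_array(tgt_rows), size), size))

    adam_d = Adam(disc.param_layers(), lr=cfg.lr)
    adam_t = Adam(target_net.param_layers(), lr=cfg.lr)
    bs = cfg.batch_size
    history = []
    for it in range(cfg.n_iterations):
        si = rng_batch.choice(len(xs), size=min(bs, len(xs)), replace=len(xs) < bs)
        ti = rng_batch.choice(len(xt), size=min(bs, len(xt)), replace=len(xt) < bs)
        ladv_d = ladv_m = ls = d_acc = np.nan
        fs = source_net.pooled_features(xs[si], train=False)
        ft = target_net.pooled_features(xt[ti], train=True, rng=rng_drop)
        mapping_grads = None
        if cfg.use_adversarial:
            # (i) discriminator step
            disc.zero_grad()
            logits = disc.forward(np.concatenate([fs, ft]), train=True)
            ns, nt = len(si), len(ti)
            ps, pt = _clamp(sigmoid(logits[:ns])), _clamp(sigmoid(logits[ns:]))
            ladv_d = float(-np.mean(np.log(ps)) - np.mean(np.log(1 - pt)))
            d_acc = 0.5 * (float((ps > 0.5).mean()) + float((pt <= 0.5).mean()))
            glog = np.concatenate([(ps - 1.0) / ns, pt / nt])
            disc.backward(glog)
            adam_d.step()
            # (ii) mapping gradients from LadvM (inverted domain label)
            disc.zero_grad()
            target_net.zero_grad()
            pt2 = _clamp(sigmoid(disc.forward(ft, train=True)))
            ladv_m = float(-np.mean(np.log(pt2)))
            gfeat = disc.backward((pt2 - 1.0) / nt)
            target_net.pooled_features_backward(gfeat)
            mapping_grads = [
                {k: g.copy() for k, g in layer.grads.items() if g is not None}
                for layer in target_net.param_layers()
            ]
        if cfg.use_siamese:
            # (iii) Siamese same-WSI gradients; the adversarial branch owns
            # the BN running statistics, so the auxiliary pair forward uses
            # batch stats without re-updating the running estimates
            pairs = sample_pairs(tgt_rows, bs, cfg.pair_balance, rng_pair)
            target_net.zero_grad()
            bns = [l for l in target_net.backbone.param_layers()
                   if isinstance(l, BatchNorm)]
            for l in bns:
                l.update_running = False
            try:
                probs = target_net.siamese_forward(xt[pairs.idx1],
                                                   xt[pairs.idx2],
                                                   train=True, rng=rng_pair_drop)
            finally:
                for l in bns:
                    l.update_running = True
            ls = siamese_loss(probs, pairs.y)
            glog = (_clamp(probs) - pairs.y) / len(pairs.y)
            target_net.siamese_backward(glog)
        # single joint update on the summed gradients of Lt = La + Ls
        if mapping_grads is not None:
            for layer, saved in zip(target_net.param_layers(), mapping_grads):
                for k, g in saved.items():
                    cur = layer.grads.get(k)
                    layer.grads[k] = g if cur is None else cur + g
        if cfg.use_adversarial or cfg.use_siamese:
            adam_t.step()
        for name, val in (("LadvD", ladv_d), ("LadvM", ladv_m), ("Ls", ls)):
            if not (np.isnan(val) or np.isfinite(val)):
                raise DivergenceError(f"{name} diverged at iteration {it}",
                                      state=target_net.state())
        history.append({"iteration": it, "LadvD": ladv_d, "LadvM": ladv_m,
                        "Ls": ls, "D_acc": d_acc})
    return target_net, disc, pd.DataFrame(
        history, columns=["iteration", "LadvD", "LadvM", "Ls", "D_acc"]
    )
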