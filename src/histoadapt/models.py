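"""Network constructors and forward contracts.

Three networks realize the adaptation framework:

* ``SourceNet`` — a fully convolutional classifier: six conv stages, each
  followed by batch normalization and ReLU (dropout 0.5 after stages 5 and
  6), then a 1x1 prediction conv without BN/ReLU whose spatial maps are
  collapsed by global average pooling into two class scores.  Having no
  fully connected layer, its parameter count is independent of input size.
  The pooled stage-6 ("Conv6") activations are the feature vector shared by
  the classifier, the domain discriminator and the Siamese head.
* ``Discriminator`` — three fully connected stages (BN+ReLU after the first
  two only) mapping a feature vector to a domain probability in (0, 1).
* ``TargetNet`` — initialized as a parameter copy of a trained source net,
  fine-tuned during adaptation while the source stays frozen; it adds a
  Siamese head (one linear stage on the concatenated pooled Conv6 features
  of two weight-sharing branches) scoring whether two patches come from the
  same WSI.
"""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .nn import BatchNorm, Conv2d, Dropout, Linear, ReLU, Sequential, sigmoid


@dataclass(frozen=True)
class NetConfig:
    input_size: int = 64
    conv_channels: tuple = (16, 32, 32, 32, 32)
    conv_kernels: tuple = (3, 3, 3, 3, 3)
    conv_strides: tuple = (2, 2, 2, 1, 2)
    feature_channels: int = 64  # stage-6 ("Conv6") width
    conv6_kernel: int = 3
    conv6_stride: int = 1
    n_classes: int = 2
    dropout_rate: float = 0.5
    preset: str = "tiny"

    @classmethod
    def tiny(cls, input_size=64):
        """CPU-scale preset; stride plan chosen per input size."""
        strides = {32: (2, 2, 1, 2, 1), 64: (2, 2, 2, 1, 2), 96: (2, 2, 2, 2, 1)}
        return cls(input_size=input_size,
                   conv_strides=strides.get(input_size, (2, 2, 2, 1, 2)))

    @classmethod
    def full_scale(cls, input_size=224):
        return cls(
            input_size=input_size,
            conv_channels=(96, 256, 384, 384, 256),
            conv_kernels=(11, 5, 3, 3, 3),
            conv_strides=(4, 2, 2, 1, 2),
            feature_channels=4096,
            conv6_kernel=3,
            preset="full",
        )

    def spatial_sizes(self):
        sizes = [self.input_size]
        kernels = list(self.conv_kernels) + [self.conv6_kernel]
        strides = list(self.conv_strides) + [self.conv6_stride]
        s = self.input_size
        n_stages = len(kernels)
        for i, (k, st) in enumerate(zip(kernels, strides)):
            s = (s + 2 * (k // 2) - k) // st + 1
            # spatial extent collapsing before the last stage means the
            # input is smaller than the stack's receptive field
            if s < 1 or (s == 1 and i < n_stages - 1):
                raise ConfigError(
                    f"input size {self.input_size} too small for the conv stack"
                )
            sizes.append(s)
        return sizes


def _build_backbone(config, rng):
    """Six conv stages (BN+ReLU each; dropout after stages 5 and 6)."""
    config.spatial_sizes()  # validates feasibility
    layers = []
    c_in = 3
    channels = list(config.conv_channels) + [config.feature_channels]
    kernels = list(config.conv_kernels) + [config.conv6_kernel]
    strides = list(config.conv_strides) + [config.conv6_stride]
    for i, (c_out, k, st) in enumerate(zip(channels, kernels, strides)):
        layers += [Conv2d(c_in, c_out, k, stride=st, rng=rng),
                   BatchNorm(c_out), ReLU()]
        if i in (4, 5):  # after stage 5 and stage 6
            layers.append(Dropout(config.dropout_rate))
        c_in = c_out
    return Sequential(layers)


class _ConvNet:
    """Shared machinery of source and target networks."""

    def __init__(self, config, seed):
        self.config = config
        rng = np.random.default_rng(seed)
        self.backbone = _build_backbone(config, rng)
        self.classifier = Conv2d(config.feature_channels, config.n_classes, 1,
                                 pad=0, rng=rng)
        self._rng = np.random.default_rng(rng.integers(0, 2**31))
        self._fwd_shape = None

    # -- forward / backward -------------------------------------------------
    def forward(self, x, train=False, rng=None):
        """Return (pooled feature vectors, class scores) for a patch batch."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected NCHW batch with 3 channels, got {x.shape}")
        if x.shape[2] != self.config.input_size or x.shape[3] != self.config.input_size:
            raise ValueError(
                f"input {x.shape[2]}x{x.shape[3]} does not match configured "
                f"size {self.config.input_size}"
            )
        a = self.backbone.forward(x, train=train, rng=rng if rng is not None else self._rng)
        self._fwd_shape = a.shape
        feats = a.mean(axis=(2, 3))
        maps = self.classifier.forward(a, train=train)
        scores = maps.mean(axis=(2, 3))
        return feats, scores

    def backward(self, gfeats=None, gscores=None):
        n, c, h, w = self._fwd_shape
        ga = np.zeros(self._fwd_shape, dtype=np.float32)
        if gscores is not None:
            gmaps = np.broadcast_to(
                np.asarray(gscores, dtype=np.float32)[:, :, None, None],
                (n, self.config.n_classes, h, w),
            ) / (h * w)
            ga += self.classifier.backward(np.ascontiguousarray(gmaps))
        if gfeats is not None:
            ga += np.asarray(gfeats, dtype=np.float32)[:, :, None, None] / (h * w)
        return self.backbone.backward(ga)

    def pooled_features(self, x, train=False, rng=None):
        """Backbone-only forward to the pooled Conv6 feature vector."""
        x = np.asarray(x, dtype=np.float32)
        a = self.backbone.forward(x, train=train, rng=rng if rng is not None else self._rng)
        self._fwd_shape = a.shape
        return a.mean(axis=(2, 3))

    def pooled_features_backward(self, gfeats):
        n, c, h, w = self._fwd_shape
        ga = np.asarray(gfeats, dtype=np.float32)[:, :, None, None] / (h * w)
        return self.backbone.backward(np.broadcast_to(ga, self._fwd_shape).copy())

    # -- parameter bookkeeping ----------------------------------------------
    def param_layers(self):
        return self.backbone.param_layers() + [self.classifier]

    def zero_grad(self):
        for layer in self.param_layers():
            layer.zero_grad()

    def state(self):
        out = {}
        for li, layer in enumerate(self.param_layers()):
            for name, arr in layer.params.items():
                out[f"{li}.{name}"] = arr.copy()
            if isinstance(layer, BatchNorm):
                out[f"{li}.running_mean"] = layer.running_mean.copy()
                out[f"{li}.running_var"] = layer.running_var.copy()
        return out

    def load_state(self, state):
        for li, layer in enumerate(self.param_layers()):
            for name in layer.params:
                src = state[f"{li}.{name}"]
                if layer.params[name].shape != src.shape:
                    raise ConfigError("checkpoint shape mismatch")
                layer.params[name][...] = src
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = state[f"{li}.running_mean"]
                layer.running_var[...] = state[f"{li}.running_var"]


class SourceNet(_ConvNet):
    """Fully convolutional source-domain classifier M_s with head C."""


class TargetNet(_ConvNet):
    """Target-domain network M_t fine-tuned from a frozen source net.

    Carries the copied classifier head (used for target class predictions)
    and a Siamese head f scoring same-WSI membership of patch pairs; the two
    Siamese branches are this very network, so they share all parameters.
    """

    def __init__(self, config, seed, feature_dim=None):
        super().__init__(config, seed)
        fdim = feature_dim or config.feature_channels
        # zero-initialized head: the pair classifier starts uninformative
        # (probability 0.5 everywhere) and feeds no gradient into the shared
        # backbone until its own weights have learned same-WSI structure
        self.siamese_head = Linear(2 * fdim, 1)
        self.siamese_head.params["W"][...] = 0.0
        self._pair_split = None

    def param_layers(self):
        return super().param_layers() + [self.siamese_head]

    def siamese_forward(self, x1, x2, train=False, rng=None):
        """Same-WSI probability for each pair (x1[i], x2[i]).

        Both branches run as one stacked batch through the shared backbone;
        the pooled Conv6 features are concatenated and passed through the
        one-layer perceptron head.
        """
        x1 = np.asarray(x1, dtype=np.float32)
        x2 = np.asarray(x2, dtype=np.float32)
        if x1.shape != x2.shape:
            raise ValueError(f"pair batches must match, got {x1.shape} vs {x2.shape}")
        n = x1.shape[0]
        feats = self.pooled_features(np.concatenate([x1, x2], axis=0),
                                     train=train, rng=rng)
        z = np.concatenate([feats[:n], feats[n:]], axis=1)
        logits = self.siamese_head.forward(z)[:, 0]
        self._pair_split = n
        return sigmoid(logits)

    def siamese_backward(self, glogits):
        n = self._pair_split
        gz = self.siamese_head.backward(np.asarray(glogits, dtype=np.float32)[:, None])
        fdim = gz.shape[1] // 2
        gfeats = np.concatenate([gz[:, :fdim], gz[:, fdim:]], axis=0)
        return self.pooled_features_backward(gfeats)

    def siamese_predict(self, x1, x2):
        """Evaluation-mode pair score, symmetrized over input order."""
        p12 = self.siamese_forward(x1, x2, train=False)
        p21 = self.siamese_forward(x2, x1, train=False)
        return 0.5 * (p12 + p21)


class Discriminator:
    """Three-FC-stage domain discriminator; BN+ReLU after the first two."""

    def __init__(self, feature_dim, hidden_dims=(500, 500), seed=0):
        if feature_dim < 1 or any(h < 1 for h in hidden_dims):
            raise ValueError("dimensions must be >= 1")
        rng = np.random.default_rng(seed)
        h1, h2 = hidden_dims
        self.net = Sequential([
            Linear(feature_dim, h1, rng=rng), BatchNorm(h1), ReLU(),
            Linear(h1, h2, rng=rng), BatchNorm(h2), ReLU(),
            Linear(h2, 1, rng=rng),
        ])

    def forward(self, feats, train=False):
        """Domain logits (pre-sigmoid) for a feature batch."""
        return self.net.forward(np.asarray(feats, dtype=np.float32), train=train)[:, 0]

    def prob(self, feats, train=False):
        return sigmoid(self.forward(feats, train=train))

    def backward(self, glogits):
        return self.net.backward(np.asarray(glogits, dtype=np.float32)[:, None])

    def param_layers(self):
        return self.net.param_layers()

    def zero_grad(self):
        self.net.zero_grad()


def build_source_net(config=None, seed=0):
    return SourceNet(config or NetConfig.tiny(), seed)


def source_forward(net, batch, train=False, rng=None):
    return net.forward(batch, train=train, rng=rng)


def build_discriminator(feature_dim, hidden_dims=(500, 500), seed=0):
    return Discriminator(feature_dim, hidden_dims, seed)


def build_target_net(source, seed=0):
    """Initialize the target network as an exact parameter copy of ``source``.

    The source network's parameters are deep-copied; mutating the target
    never touches the source.
    """
    target = TargetNet(source.config, seed)
    # overwrite backbone+classifier entries (shared layer indices) with the
    # source parameters; the freshly initialized Siamese head is kept.
    merged = target.state()
    merged.update(copy.deepcopy(source.state()))
    target.load_state(merged)
    return target


def siamese_forward(net, x1, x2, train=False, rng=None):
    return net.siamese_forward(x1, x2, train=train, rng=rng)


def parameter_count(net):
    return int(sum(p.size for layer in net.param_layers() for p in layer.params.values()))


def state_hash(net):
    """SHA-256 over the network's parameters (learnable weights only)."""
    h = hashlib.sha256()
    for li, layer in enumerate(net.param_layers()):
        for name in sorted(layer.params):
            h.update(f"{li}.{name}".encode())
            h.update(np.ascontiguousarray(layer.params[name]).tobytes())
    return h.hexdigest()
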