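"""scikit-learn-style estimator facades over the library.

These classes expose the framework's three computations in the familiar
fit/transform/predict idiom so they compose with sklearn pipelines and
model selection:

* :class:`StainNormalizer` — transformer; ``fit`` on a reference patch,
  ``transform`` re-renders patches in the reference's stain basis.
* :class:`SourcePatchClassifier` — classifier; ``fit`` trains the fully
  convolutional source network on labeled patches, ``predict`` /
  ``predict_proba`` classify patch stacks, ``decision_function`` exposes
  the raw logits used by ensemble averaging.
* :class:`AdversarialDomainAdapter` — ``fit`` adapts a copy of a fitted
  source classifier to unlabeled target patches (grouped by WSI id) with
  the adversarial + Siamese objective; ``predict`` classifies target
  patches with the adapted network.

Images are (N, H, W, 3) uint8 stacks throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .models import NetConfig, SourceNet, state_hash
from .stain import DEFAULT_I0, ReferenceProfile, normalize_to_reference
from .synthdata import SyntheticDataset, SyntheticTruth
from .train import (AdaptConfig, SourceTrainConfig, adapt_target, predict_scores,
                    train_source)
from .wsi import LABELS, Manifest, PatchRecord


def _check_images(X):
    X = np.asarray(X)
    if X.ndim == 3:
        X = X[None]
    if X.ndim != 4 or X.shape[-1] != 3:
        raise ValueError(f"expected (N, H, W, 3) image stack, got {X.shape}")
    return X


class StainNormalizer(TransformerMixin, BaseEstimator):
    """Normalize patches to a reference patch's stain basis and scale."""

    def __init__(self, method="macenko", I0=DEFAULT_I0, sparsity=0.1,
                 n_iter=200, seed=0):
        self.method = method
        self.I0 = I0
        self.sparsity = sparsity
        self.n_iter = n_iter
        self.seed = seed

    def _stain_kwargs(self):
        if self.method == "spcn":
            return {"sparsity": self.sparsity, "n_iter": self.n_iter}
        return {}

    def fit(self, X, y=None):
        ref = _check_images(X)
        if len(ref) != 1:
            raise ValueError("fit expects exactly one reference patch")
        self.reference_profile_ = ReferenceProfile.from_patch(
            ref[0], method=self.method, I0=self.I0, seed=self.seed,
            **self._stain_kwargs()
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_profile_")
        X = _check_images(X)
        return np.stack([
            normalize_to_reference(x, self.reference_profile_, method=self.method,
                                   I0=self.I0, seed=self.seed,
                                   **self._stain_kwargs())
            for x in X
        ])


def _dataset_from_arrays(X, y, wsi_ids, domain, split_seed, val_frac=0.15):
    """Wrap labeled arrays in a SyntheticDataset-shaped container with a
    per-WSI train/val split (each WSI acts as its own patient)."""
    wsi_ids = np.asarray(wsi_ids, dtype=object)
    uniq = sorted(set(wsi_ids))
    rng = np.random.default_rng(split_seed)
    order = list(rng.permutation(uniq))
    n_val = (
        max(1, int(round(val_frac * len(uniq))))
        if val_frac > 0 and len(uniq) >= 2
        else 0
    )
    val_set = set(order[:n_val])
    records, images = [], {}
    for i, (img, lab, wid) in enumerate(zip(X, y, wsi_ids)):
        pid = f"{domain}-{i:06d}"
        images[pid] = img
        records.append(PatchRecord(
            patch_id=pid, wsi_id=str(wid), patient_id=f"pt-{wid}",
            label=str(lab), domain=domain,
            split="val" if wid in val_set else "train",
        ))
    manifest = Manifest.from_records(records)
    truth = SyntheticTruth(stain_matrix=None, labels={}, concentrations={},
                           wsi_multipliers={}, blob_counts={})
    return SyntheticDataset(images=images, manifest=manifest, truth=truth,
                            seed=split_seed, spec=None)


class SourcePatchClassifier(ClassifierMixin, BaseEstimator):
    """Fully convolutional patch classifier trained with mini-batch SGD."""

    def __init__(self, preset="tiny", input_size=64, epochs=10, batch_size=16,
                 lr0=0.001, momentum=0.9, weight_decay=0.0005,
                 anneal_factor=0.1, anneal_period=None, hflip=False,
                 val_frac=0.15, seed=0):
        self.preset = preset
        self.input_size = input_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr0 = lr0
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.anneal_factor = anneal_factor
        self.anneal_period = anneal_period
        self.hflip = hflip
        self.val_frac = val_frac
        self.seed = seed

    def _net_config(self):
        if self.preset == "full":
            return NetConfig.full_scale(self.input_size)
        return NetConfig.tiny(self.input_size)

    def fit(self, X, y, wsi_ids=None):
        X = _check_images(X)
        y = np.asarray(y)
        unknown = set(y) - set(LABELS)
        if unknown:
            raise ValueError(f"labels must be in {LABELS}, got extra {unknown}")
        if wsi_ids is None:
            wsi_ids = [f"{lab}-{i}" for i, lab in enumerate(y)]
        dataset = _dataset_from_arrays(X, y, wsi_ids, "source", self.seed,
                                       self.val_frac)
        cfg = SourceTrainConfig.tiny(
            input_size=self.input_size, epochs=self.epochs,
            batch_size=self.batch_size, seed=self.seed, hflip=self.hflip,
            lr0=self.lr0, momentum=self.momentum,
            weight_decay=self.weight_decay, anneal_factor=self.anneal_factor,
            anneal_period=self.anneal_period,
        )
        net = SourceNet(self._net_config(), seed=self.seed)
        self.net_, self.history_ = train_source(net, dataset, cfg)
        self.classes_ = np.asarray(LABELS)
        self.source_hash_ = state_hash(self.net_)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "net_")
        _, scores = predict_scores(self.net_, _check_images(X))
        return scores

    def predict_proba(self, X):
        scores = self.decision_function(X)
        z = scores - scores.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[self.decision_function(X).argmax(axis=1)]


class AdversarialDomainAdapter(BaseEstimator):
    """Adversarial + Siamese adaptation of a fitted source classifier."""

    def __init__(self, n_iterations=2000, batch_size=128, lr=0.00001,
                 pair_balance=0.5, use_adversarial=True, use_siamese=True,
                 hidden_dims=(500, 500), seed=0):
        self.n_iterations = n_iterations
        self.batch_size = batch_size
        self.lr = lr
        self.pair_balance = pair_balance
        self.use_adversarial = use_adversarial
        self.use_siamese = use_siamese
        self.hidden_dims = hidden_dims
        self.seed = seed

    def fit(self, X, y=None, *, wsi_ids, source, X_source, source_wsi_ids=None):
        """Adapt to unlabeled target patches ``X`` grouped by ``wsi_ids``.

        ``source`` is a fitted :class:`SourcePatchClassifier`; ``X_source``
        supplies the source-domain patches whose features anchor the
        discriminator.  Target labels are never consulted.
        """
        check_is_fitted(source, "net_")
        X = _check_images(X)
        xs = _check_images(X_source)
        if source_wsi_ids is None:
            source_wsi_ids = [f"s{i}" for i in range(len(xs))]
        src_ds = _dataset_from_arrays(xs, ["low"] * len(xs), source_wsi_ids,
                                      "source", self.seed, val_frac=0.0)
        # target labels are withheld: record placeholders only in truth-free rows
        records, images = [], {}
        for i, (img, wid) in enumerate(zip(X, np.asarray(wsi_ids, dtype=object))):
            pid = f"target-{i:06d}"
            images[pid] = img
            records.append(PatchRecord(patch_id=pid, wsi_id=str(wid),
                                       patient_id=f"pt-{wid}", label="",
                                       domain="target", split="train"))
        tgt_ds = SyntheticDataset(
            images=images, manifest=Manifest.from_records(records),
            truth=SyntheticTruth(None, {}, {}, {}, {}), seed=self.seed, spec=None,
        )
        cfg = AdaptConfig(lr=self.lr, batch_size=self.batch_size,
                          n_iterations=self.n_iterations,
                          pair_balance=self.pair_balance,
                          use_adversarial=self.use_adversarial,
                          use_siamese=self.use_siamese,
                          hidden_dims=tuple(self.hidden_dims), seed=self.seed)
        self.net_, self.discriminator_, self.history_ = adapt_target(
            source.net_, src_ds, tgt_ds, cfg
        )
        self.classes_ = np.asarray(LABELS)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "net_")
        _, scores = predict_scores(self.net_, _check_images(X))
        return scores

    def predict(self, X):
        return self.classes_[self.decision_function(X).argmax(axis=1)]

    def predict_pair_proba(self, X1, X2):
        """Symmetrized same-WSI probability for patch pairs."""
        check_is_fitted(self, "net_")
        from .train import to_net_input

        return self.net_.siamese_predict(to_net_input(_check_images(X1)),
                                         to_net_input(_check_images(X2)))
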