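"""Shared fixtures: study conditions and (expensive) trained networks.

The study conditions are a synthetic source domain with a strong class
texture gap and a target domain shifted by a 15-degree stain rotation plus
a reduced class-texture contrast.  Patches are 32x32 with the tiny network
preset so the full two-stage pipeline runs on one CPU.
"""

from dataclasses import replace
from types import SimpleNamespace

import numpy as np
import pytest

from histoadapt.models import NetConfig, SourceNet, state_hash
from histoadapt.synthdata import (ClassTexture, SyntheticDomainSpec,
                                  generate_domain_pair)
from histoadapt.train import (AdaptConfig, SourceTrainConfig, adapt_target,
                              predict_scores, train_source)

PATCH_SIZE = 64
N_WSIS_PER_CLASS = 10
PATCHES_PER_WSI = 12
EPOCHS = 10
BATCH = 16
ADAPT_ITERATIONS = 500
SEEDS = (0, 1, 2)


def source_spec():
    return SyntheticDomainSpec()


def target_spec():
    """15-degree stain rotation plus reduced class-texture contrast."""
    base = source_spec()
    return replace(
        base.with_stain_rotation(15.0),
        class_texture={
            "low": ClassTexture(3.5, 3.0, 0.15),
            "high": ClassTexture(6.5, 3.0, 0.05),
        },
    )


def target_accuracy(net, dataset):
    """Patch accuracy of a network on a target dataset's test split."""
    rows = dataset.manifest.rows(domain="target", split="test")
    _, scores = predict_scores(net, dataset.patch_array(rows))
    ytrue = np.array(
        [0 if dataset.truth.labels[p] == "low" else 1 for p in rows["patch_id"]]
    )
    return float((scores.argmax(axis=1) == ytrue).mean())


@pytest.fixture(scope="session")
def small_pair():
    """A small source/target pair for cheap structural tests."""
    return generate_domain_pair(source_spec(), target_spec(), 3, 4, seed=11,
                                patch_size=PATCH_SIZE)


@pytest.fixture(scope="session")
def study():
    """Per-seed datasets and trained source networks under study conditions."""
    out = {}
    for seed in SEEDS:
        src, tgt = generate_domain_pair(
            source_spec(), target_spec(), N_WSIS_PER_CLASS, PATCHES_PER_WSI,
            seed=100 + seed, patch_size=PATCH_SIZE,
        )
        net = SourceNet(NetConfig.tiny(PATCH_SIZE), seed=seed)
        net, history = train_source(
            net, src,
            SourceTrainConfig.tiny(input_size=PATCH_SIZE, epochs=EPOCHS,
                                   batch_size=BATCH, seed=seed),
        )
        out[seed] = SimpleNamespace(
            source=src, target=tgt, net=net, history=history,
            source_hash=state_hash(net),
        )
    return out


@pytest.fixture(scope="session")
def adapted(study):
    """Full-objective (Lt) and adversarial-only (La) adapted networks."""
    out = {}
    for seed, run in study.items():
        cfg = AdaptConfig(batch_size=BATCH, n_iterations=ADAPT_ITERATIONS,
                          seed=seed)
        lt_net, disc, lt_hist = adapt_target(run.net, run.source, run.target, cfg)
        la_net, _, _ = adapt_target(run.net, run.source, run.target,
                                    replace(cfg, use_siamese=False))
        out[seed] = SimpleNamespace(lt=lt_net, la=la_net, discriminator=disc,
                                    history=lt_hist)
    return out
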