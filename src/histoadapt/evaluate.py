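"""Inference and evaluation: stain-ensemble prediction, WSI majority vote,
accuracy/confusion reporting and the McNemar paired test.

The color-normalization adaptation path classifies a target patch by
normalizing it to each of N_l reference patches drawn uniformly from the
source training split, forwarding every normalized version through the
frozen source network, and averaging the raw class logits with equal
weights before the softmax.  Whole-slide labels are the majority vote over
patch predictions.  Paired classifier comparisons use the exact conditional
McNemar test on the discordant counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .errors import DegenerateStainError, InsufficientTissueError, SamplingError
from .stain import ReferenceProfile, normalize_to_reference
from .train import predict_scores
from .wsi import LABELS

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# reference sampling
# ---------------------------------------------------------------------------

@dataclass
class ReferenceSet:
    """N_l source-train reference patches with their stain profiles."""

    patch_ids: list
    patches: list
    profiles: list  # ReferenceProfile per patch
    method: str
    seed: int

    def __len__(self):
        return len(self.patch_ids)


def sample_references(manifest_rows, images, n_refs, seed, method="macenko",
                      **stain_kwargs):
    """Uniformly sample ``n_refs`` references without replacement.

    Patches failing stain estimation are resampled (and logged) so every
    returned reference carries a valid profile.
    """
    if n_refs < 1:
        raise SamplingError("n_refs must be >= 1")
    ids = sorted(manifest_rows["patch_id"])
    if len(ids) < n_refs:
        raise SamplingError(f"only {len(ids)} eligible patches for N_l={n_refs}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    chosen_ids, chosen_patches, profiles = [], [], []
    for pos in order:
        pid = ids[pos]
        patch = images[pid]
        try:
            prof = ReferenceProfile.from_patch(patch, method=method,
                                               seed=seed, **stain_kwargs)
        except (InsufficientTissueError, DegenerateStainError) as exc:
            logger.warning("reference %s failed stain estimation (%s); resampling",
                           pid, exc)
            continue
        chosen_ids.append(pid)
        chosen_patches.append(patch)
        profiles.append(prof)
        if len(chosen_ids) == n_refs:
            return ReferenceSet(chosen_ids, chosen_patches, profiles, method, seed)
    raise SamplingError("not enough patches passed stain estimation")


# ---------------------------------------------------------------------------
# ensemble prediction
# ---------------------------------------------------------------------------

@dataclass
class EnsembleLogits:
    """Averaged logits with the per-reference raw logits retained."""

    per_reference: np.ndarray  # (N_l, n_classes)

    @property
    def mean(self):
        return self.per_reference.mean(axis=0)


def softmax(z):
    z = np.asarray(z, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def ensemble_predict(patch, refs, source_net, method=None, seed=0):
    """Ensemble-normalized prediction for a single patch.

    The patch is normalized to each reference and forwarded through the
    frozen source net; logits are averaged with equal weights and the mean
    is softmaxed.  If every normalization fails the un-normalized patch is
    used as fallback (with a warning) so a prediction is always returned.
    """
    method = method or refs.method
    versions = []
    for prof in refs.profiles:
        try:
            versions.append(normalize_to_reference(patch, prof, method=method,
                                                   seed=seed))
        except (InsufficientTissueError, DegenerateStainError) as exc:
            logger.warning("normalization failed (%s); skipping reference", exc)
    if not versions:
        logger.warning("all normalizations failed; falling back to raw patch")
        versions = [np.asarray(patch)]
    _, logits = predict_scores(source_net, np.stack(versions))
    ens = EnsembleLogits(per_reference=logits)
    return ens, softmax(ens.mean)


def ensemble_predict_batch(patches, refs, source_net, method=None, seed=0):
    """Vectorized ensemble prediction over a patch stack.

    Returns (probs (N, n_classes), per-reference logits (N, N_l, n_classes)).
    Normalization failures fall back per patch-reference to the raw patch.
    """
    method = method or refs.method
    patches = np.asarray(patches)
    n, nl = len(patches), len(refs)
    all_versions = np.empty((n * nl,) + patches.shape[1:], dtype=np.uint8)
    k = 0
    for patch in patches:
        for prof in refs.profiles:
            try:
                all_versions[k] = normalize_to_reference(patch, prof,
                                                         method=method, seed=seed)
            except (InsufficientTissueError, DegenerateStainError):
                all_versions[k] = patch
            k += 1
    _, logits = predict_scores(source_net, all_versions)
    per_ref = logits.reshape(n, nl, -1)
    probs = softmax(per_ref.mean(axis=1))
    return probs, per_ref


# ---------------------------------------------------------------------------
# WSI-level vote and reports
# ---------------------------------------------------------------------------

def predict_wsi(patch_labels, patch_high_probs=None):
    """Majority vote over one WSI's patch predictions.

    ``patch_labels`` are per-patch class labels; ties are broken toward
    the class favored by the mean predicted high-grade probability (``high``
    iff that mean is >= 0.5).  Returns (label, tie_flag).
    """
    labels = list(patch_labels)
    if not labels:
        raise ValueError("a WSI needs at least one patch prediction")
    counts = {lab: labels.count(lab) for lab in LABELS}
    if counts["low"] != counts["high"]:
        return max(LABELS, key=lambda l: counts[l]), False
    if patch_high_probs is None:
        return "high", True
    return ("high" if float(np.mean(patch_high_probs)) >= 0.5 else "low"), True


@dataclass
class EvalReport:
    """Accuracy and row-normalized confusion at patch or WSI level."""

    level: str
    accuracy: float
    confusion: np.ndarray  # rows: truth (low, high); row-normalized
    n_items: int
    ties: int = 0
    metadata: dict = field(default_factory=dict)

    def to_dict(self):
        return {
            "level": self.level,
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "n_items": self.n_items,
            "ties": self.ties,
            "metadata": self.metadata,
        }


def evaluate_run(predictions, truth, level="patch", ties=0, metadata=None):
    """Accuracy plus a row-normalized 2x2 confusion matrix.

    Rows index the true class (low, high); each realized row sums to one.
    """
    pred = np.asarray(list(predictions))
    true = np.asarray(list(truth))
    if pred.shape != true.shape or len(pred) == 0:
        raise ValueError("predictions and truth must align and be nonempty")
    for arr in (pred, true):
        bad = set(arr) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels {bad}")
    acc = float(np.mean(pred == true))
    conf = np.zeros((2, 2))
    for t, p in zip(true, pred):
        conf[LABELS.index(t), LABELS.index(p)] += 1
    sums = conf.sum(axis=1, keepdims=True)
    conf = np.divide(conf, sums, out=np.zeros_like(conf), where=sums > 0)
    return EvalReport(level=level, accuracy=acc, confusion=conf,
                      n_items=len(pred), ties=ties, metadata=metadata or {})


# ---------------------------------------------------------------------------
# McNemar paired test
# ---------------------------------------------------------------------------

@dataclass
class McNemarResult:
    b: int  # baseline-only-correct discordant count
    c: int  # adapted-only-correct discordant count
    p_value: float
    degenerate: bool = False

    def __iter__(self):
        return iter((self.b, self.c, self.p_value))


def mcnemar_test(baseline_correct, adapted_correct, mid_p=False):
    """Exact conditional McNemar test on paired correctness flags.

    b and c are the discordant counts; conditioned on n = b + c the null
    distribution of min(b, c) is Binomial(n, 1/2), giving the exact
    two-sided p = min(1, 2 P(X <= min(b, c))).  With ``mid_p`` half the
    point probability is subtracted.  n = 0 returns p = 1 with a
    degenerate-case flag.
    """
    base = np.asarray(baseline_correct, dtype=bool)
    adap = np.asarray(adapted_correct, dtype=bool)
    if base.shape != adap.shape:
        raise ValueError("flags must be aligned on the same test items")
    b = int(np.sum(base & ~adap))
    c = int(np.sum(~base & adap))
    n = b + c
    if n == 0:
        return McNemarResult(b=b, c=c, p_value=1.0, degenerate=True)
    k = min(b, c)
    p = 2.0 * float(binom.cdf(k, n, 0.5))
    if mid_p:
        p -= float(binom.pmf(k, n, 0.5))
    return McNemarResult(b=b, c=c, p_value=min(1.0, p))
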