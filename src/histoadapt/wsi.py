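"""Patch extraction, tissue filtering, manifests and patient-exclusive splits.

A whole-slide image enters as a plain raster; it is tiled into patches on a
regular grid, patches with too little tissue are dropped, and the survivors
are recorded in a :class:`Manifest` — one row per patch carrying the WSI,
patient, class label, domain tag and split.  Splits are assigned at the
patient level so that no patient contributes images to both the training
and the testing side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.color import rgb2gray

from .errors import StratificationError, WithheldLabelError

MANIFEST_COLUMNS = ("patch_id", "wsi_id", "patient_id", "label", "domain", "split", "path")
LABELS = ("low", "high")
WITHHELD = ""  # empty label field marks a label-withheld row

# A pixel is tissue when its luminance falls below this fraction of white.
TISSUE_GRAY_THRESHOLD = 0.8
# Patches with tissue fraction below this are discarded.
MIN_TISSUE_FRACTION = 0.5


@dataclass(frozen=True)
class PatchRecord:
    patch_id: str
    wsi_id: str
    patient_id: str
    label: str  # "low", "high" or WITHHELD
    domain: str  # "source" | "target"
    split: str  # "train" | "val" | "test"
    path: str = ""


@dataclass
class WSIRecord:
    wsi_id: str
    patient_id: str
    label: str
    patch_ids: list = field(default_factory=list)


class Manifest:
    """Ordered collection of patch records with integrity checks.

    The class label of label-withheld rows (target-domain train/val) is not
    readable through :meth:`labels`; ground truth for synthetic data lives in
    the generating dataset's ``truth`` channel instead.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy().reset_index(drop=True)
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"manifest missing columns {missing}")
        df = df[list(MANIFEST_COLUMNS)].astype(str)
        df.loc[df["label"].isin(("nan", "None")), "label"] = WITHHELD
        if df["patch_id"].duplicated().any():
            raise ValueError("duplicate patch_id in manifest")
        bad = df[(df["label"] == WITHHELD) & ~((df["domain"] == "target") & df["split"].isin(("train", "val")))]
        if len(bad):
            raise ValueError("withheld labels are only allowed for target train/val rows")
        bad_lab = df[(df["label"] != WITHHELD) & ~df["label"].isin(LABELS)]
        if len(bad_lab):
            raise ValueError(f"unknown labels: {sorted(set(bad_lab['label']))}")
        self.df = df

    def __len__(self):
        return len(self.df)

    def rows(self, domain=None, split=None):
        sel = self.df
        if domain is not None:
            sel = sel[sel["domain"] == domain]
        if split is not None:
            sel = sel[sel["split"] == split]
        return sel

    def labels(self, rows=None):
        """Class labels of the selected rows; raises on withheld rows."""
        rows = self.df if rows is None else rows
        if (rows["label"] == WITHHELD).any():
            raise WithheldLabelError(
                "selection contains label-withheld rows (target train/val)"
            )
        return rows["label"].to_numpy()

    @property
    def n_source(self):
        return int((self.df["domain"] == "source").sum())

    @property
    def n_target(self):
        return int((self.df["domain"] == "target").sum())

    def wsi_records(self, domain=None, split=None):
        out = []
        for wsi_id, grp in self.rows(domain=domain, split=split).groupby("wsi_id", sort=True):
            labels = set(grp["label"]) - {WITHHELD}
            out.append(WSIRecord(
                wsi_id=wsi_id,
                patient_id=grp["patient_id"].iloc[0],
                label=labels.pop() if labels else WITHHELD,
                patch_ids=list(grp["patch_id"]),
            ))
        return out

    def to_csv(self, path):
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path):
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        return cls(df)

    @classmethod
    def from_records(cls, records):
        return cls(pd.DataFrame([r.__dict__ for r in records], columns=MANIFEST_COLUMNS))


def extract_patches(slide_image, patch_size, stride=None):
    """Tile a slide into patches on a regular grid.

    Returns ``(patches, coordinates)`` in row-major order; coordinates are
    0-based pixel offsets of each patch's top-left corner with half-open
    extents, so ``slide[y:y+p, x:x+p]`` reproduces the patch exactly.
    Trailing remainders smaller than a patch are dropped.
    """
    stride = patch_size if stride is None else stride
    slide = np.asarray(slide_image)
    h, w = slide.shape[:2]
    if h < patch_size or w < patch_size:
        warnings.warn("slide smaller than one patch; no patches extracted")
        return [], []
    patches, coords = [], []
    for y in range(0, h - patch_size + 1, stride):
        for x in range(0, w - patch_size + 1, stride):
            patches.append(slide[y : y + patch_size, x : x + patch_size])
            coords.append((y, x))
    return patches, coords


def tissue_fraction(patch):
    """Fraction of pixels whose luminance is below 0.8 of white."""
    gray = rgb2gray(np.asarray(patch))
    return float(np.mean(gray < TISSUE_GRAY_THRESHOLD))


@dataclass
class SplitParams:
    train_frac: float = 0.8
    val_frac_of_train: float = 0.1  # fraction of training *patients* held out
    tissue_threshold: float = MIN_TISSUE_FRACTION
    seed: int = 0
    max_tries: int = 100
    domain: str = "source"


def _assign_patient_splits(patients, labels_by_patient, params, rng):
    patients = sorted(patients)
    n = len(patients)
    n_test = max(1, int(round((1.0 - params.train_frac) * n))) if n >= 2 else 0
    classes = sorted(set(labels_by_patient.values()))
    for _ in range(params.max_tries):
        order = list(rng.permutation(patients))
        test = set(order[:n_test])
        trainval = order[n_test:]
        n_val = (
            max(1, int(round(params.val_frac_of_train * len(trainval))))
            if len(trainval) >= 2
            else 0
        )
        val = set(trainval[:n_val])
        train = set(trainval[n_val:])
        ok = True
        # every class must appear on the training side (train+val, which are
        # patient-exclusive with test) and in test when it is large enough
        parts = [train | val] + ([test] if n_test >= len(classes) else [])
        for part in parts:
            got = {labels_by_patient[p] for p in part}
            if not set(classes) <= got:
                ok = False
        if ok:
            return {p: "test" for p in test} | {p: "val" for p in val} | {
                p: "train" for p in train
            }
        warnings.warn("split missed a class in train or test; reshuffling")
    raise StratificationError(
        "could not place every class in both train and test splits"
    )


def filter_and_split(patches, meta, params=None):
    """Drop low-tissue patches and assign patient-exclusive splits.

    ``meta`` is a sequence of dicts with keys ``patch_id``, ``wsi_id``,
    ``patient_id``, ``label`` (and optionally ``path``).  Patches whose
    tissue fraction falls below the threshold are removed; the survivors'
    patients are split 80/20 into train/test with a validation subset carved
    from the training patients.  Deterministic given ``params.seed`` and
    independent of input order.
    """
    params = params or SplitParams()
    order = np.argsort([m["patch_id"] for m in meta])  # order independence
    keep = [
        i for i in order if tissue_fraction(patches[i]) >= params.tissue_threshold
    ]
    labels_by_patient = {}
    for i in keep:
        m = meta[i]
        prev = labels_by_patient.setdefault(m["patient_id"], m["label"])
        if prev != m["label"]:
            # a patient may carry WSIs of both grades; stratify on the first seen
            pass
    rng = np.random.default_rng(params.seed)
    split_of = _assign_patient_splits(
        labels_by_patient.keys(), labels_by_patient, params, rng
    )
    records = []
    for i in keep:
        m = meta[i]
        records.append(PatchRecord(
            patch_id=m["patch_id"],
            wsi_id=m["wsi_id"],
            patient_id=m["patient_id"],
            label=m["label"],
            domain=params.domain,
            split=split_of[m["patient_id"]],
            path=m.get("path", ""),
        ))
    return Manifest.from_records(records), keep
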