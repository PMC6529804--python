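"""Seeded synthetic H&E-like patch generator with ground truth.

Patches are rendered through the same two-stain Beer-Lambert model the
stain module inverts: a hematoxylin channel made of nuclear "blobs" whose
density separates low- from high-grade tissue, an eosin channel that is a
smooth low-frequency cytoplasm field, and occasional lumen discs where both
stains are nearly absent.  Patches are grouped into virtual WSIs; each WSI
draws one multiplicative density random effect, so patches of one WSI are
correlated — the structure the Siamese same-WSI regularizer exploits.
Domains differ through their stain-vector angles (staining shift) and class
texture parameters (morphology shift).

Everything is generated from explicit seeds and regenerating with the same
seed is bit-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import GenerationIntegrityError, SpecError
from .stain import StainMatrix, canonical_stain_order
from .wsi import WITHHELD, Manifest, PatchRecord

# Fixed orthonormal 2-plane of RGB-OD space in which stain angles live.
_E1 = np.array([0.85, 0.45, 0.27])
_E1 /= np.linalg.norm(_E1)
_v = np.array([0.15, 0.30, 0.95])
_E2 = _v - (_v @ _E1) * _E1
_E2 /= np.linalg.norm(_E2)


def stain_vector_from_angle(angle_deg):
    """Unit absorption vector at ``angle_deg`` within the fixed OD 2-plane."""
    t = np.radians(angle_deg)
    v = np.cos(t) * _E1 + np.sin(t) * _E2
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class ClassTexture:
    """Blob-process parameters of one tissue grade."""

    blob_density: float  # expected blobs per 1e3 px^2
    blob_radius: float  # mean blob radius, px
    lumen_fraction: float  # expected fraction of area carved into lumina


@dataclass(frozen=True)
class SyntheticDomainSpec:
    """Generative parameters of one staining/texture domain.

    ``stain_angles`` are (hematoxylin, eosin) angles in degrees within a
    fixed 2-plane of RGB-OD space; ``max_concentration`` caps each stain's
    optical-density contribution; ``wsi_effect_sd`` is the sd of the
    truncated-normal per-WSI density multiplier.
    """

    stain_angles: tuple = (50.0, 10.0)
    max_concentration: tuple = (1.0, 0.6)
    background_intensity: tuple = (255.0, 255.0, 255.0)
    noise_sd: float = 2.0
    class_texture: dict = field(
        default_factory=lambda: {
            "low": ClassTexture(2.0, 3.0, 0.15),
            "high": ClassTexture(8.0, 3.0, 0.05),
        }
    )
    wsi_effect_sd: float = 0.15

    def __post_init__(self):
        ah, ae = self.stain_angles
        if abs(ah - ae) < 5.0:
            raise SpecError("stain angles must differ by at least 5 degrees")
        for v in (stain_vector_from_angle(ah), stain_vector_from_angle(ae)):
            if np.any(v < -1e-9):
                raise SpecError(
                    f"stain angle outside the nonnegative cone: {self.stain_angles}"
                )
        if any(m <= 0 for m in self.max_concentration):
            raise SpecError("max_concentration must be positive per stain")
        i0 = np.asarray(self.background_intensity, dtype=float)
        if np.any(i0 <= 0) or np.any(i0 > 255):
            raise SpecError("background_intensity must lie in (0, 255]")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be nonnegative")
        if not {"low", "high"} <= set(self.class_texture):
            raise SpecError("class_texture must define 'low' and 'high'")
        if not (
            self.class_texture["high"].blob_density
            > self.class_texture["low"].blob_density
        ):
            raise SpecError("high-grade blob density must exceed low-grade")

    def stain_matrix(self):
        cols = np.stack(
            [stain_vector_from_angle(a) for a in self.stain_angles], axis=1
        )
        cols = np.maximum(cols, 0.0)
        cols /= np.linalg.norm(cols, axis=0)
        return StainMatrix(canonical_stain_order(cols))

    def with_stain_rotation(self, degrees):
        ah, ae = self.stain_angles
        return replace(self, stain_angles=(ah + degrees, ae + degrees))


def render_patch(concentrations, spec, seed):
    """Render per-pixel stain concentrations to an 8-bit RGB patch.

    ``I_ch = I0_ch * 10 ** (-(S @ c)_ch) + noise`` clipped to [0, 255] and
    rounded; ``S`` comes from the spec's stain angles.
    """
    conc = np.asarray(concentrations, dtype=np.float64)
    if conc.ndim != 3 or conc.shape[-1] != 2:
        raise ValueError(f"concentrations must be (H, W, 2), got {conc.shape}")
    if not np.all(np.isfinite(conc)):
        raise ValueError("concentrations must be finite")
    if np.any(conc < 0):
        raise ValueError("concentrations must be nonnegative")
    s = spec.stain_matrix().columns  # raises SpecError/Degenerate on bad spec
    od = conc @ s.T
    i0 = np.asarray(spec.background_intensity, dtype=np.float64)
    img = i0 * np.power(10.0, -od)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def expected_blob_count(texture, patch_size, multiplier=1.0):
    """Poisson mean of the nuclear blob count for one patch."""
    return texture.blob_density * patch_size * patch_size / 1e3 * multiplier


def _concentration_map(texture, spec, patch_size, multiplier, rng):
    """One patch's (H, W, 2) concentration map plus its blob count."""
    h = w = patch_size
    max_h, max_e = spec.max_concentration
    n_blobs = int(rng.poisson(expected_blob_count(texture, patch_size, multiplier)))
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    hema = np.zeros((h, w))
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r = max(1.0, rng.gamma(4.0, texture.blob_radius / 4.0))
        amp = rng.uniform(0.7, 1.0) * max_h
        hema += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * (r / 1.5) ** 2))
    hema = np.clip(hema, 0.0, max_h)
    # smooth cytoplasm field with a low floor so near-pure nuclei exist
    f = gaussian_filter(rng.standard_normal((h, w)), sigma=patch_size / 8.0)
    lo, hi = f.min(), f.max()
    f01 = (f - lo) / (hi - lo) if hi > lo else np.full_like(f, 0.5)
    eosin = max_e * (0.05 + 0.90 * f01)
    # nuclei displace cytoplasm: eosin is suppressed where hematoxylin is dense,
    # so dense nuclear cores are near-pure hematoxylin
    eosin *= 1.0 - 0.9 * (hema / max_h)
    # lumen discs: both stains nearly absent
    lumen_r = 2.0 * texture.blob_radius
    n_lumen = int(
        rng.poisson(texture.lumen_fraction * h * w / (np.pi * lumen_r**2))
    )
    for _ in range(n_lumen):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= lumen_r**2
        hema[mask] *= 0.05
        eosin[mask] *= 0.05
    return np.stack([hema, eosin], axis=-1), n_blobs


@dataclass
class WSIFragment:
    """Patches of one virtual WSI, sharing label and density random effect."""

    wsi_id: str
    patient_id: str
    label: str
    multiplier: float
    patch_ids: list
    patches: list
    concentrations: list
    blob_counts: list


def generate_wsi(class_label, n_patches, spec, seed, patch_size=64, wsi_id=None,
                 patient_id=None):
    """Generate one virtual WSI: ``n_patches`` patches of one class.

    One WSI-level density multiplier ~ Normal(1, wsi_effect_sd), truncated
    positive, scales the class blob density of every member patch.
    """
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    if class_label not in spec.class_texture:
        raise ValueError(f"unknown class label {class_label!r}")
    rng = np.random.default_rng(seed)
    if spec.wsi_effect_sd > 0:
        multiplier = 0.0
        while multiplier <= 0.0:
            multiplier = rng.normal(1.0, spec.wsi_effect_sd)
    else:
        multiplier = 1.0
    wsi_id = wsi_id or f"wsi{seed:08d}"
    patient_id = patient_id or f"pt-{wsi_id}"
    texture = spec.class_texture[class_label]
    patch_ids, patches, concs, counts = [], [], [], []
    for i in range(n_patches):
        conc, n_blobs = _concentration_map(texture, spec, patch_size, multiplier, rng)
        noise_seed = int(rng.integers(0, 2**31))
        patches.append(render_patch(conc, spec, noise_seed))
        concs.append(conc.astype(np.float32))
        patch_ids.append(f"{wsi_id}-p{i:03d}")
        counts.append(n_blobs)
    return WSIFragment(wsi_id, patient_id, class_label, float(multiplier),
                       patch_ids, patches, concs, counts)


@dataclass
class SyntheticTruth:
    """Generating ground truth retained for evaluation and oracles."""

    stain_matrix: StainMatrix
    labels: dict  # patch_id -> class label (including withheld rows)
    concentrations: dict  # patch_id -> (H, W, 2) float32
    wsi_multipliers: dict  # wsi_id -> float
    blob_counts: dict  # patch_id -> int


@dataclass
class SyntheticDataset:
    """Images + manifest + generating truth of one synthetic domain."""

    images: dict  # patch_id -> (H, W, 3) uint8
    manifest: Manifest
    truth: SyntheticTruth
    seed: int
    spec: SyntheticDomainSpec

    def patch_array(self, rows=None):
        rows = self.manifest.df if rows is None else rows
        return np.stack([self.images[pid] for pid in rows["patch_id"]])

    def content_hash(self):
        h = hashlib.sha256()
        for pid in sorted(self.images):
            h.update(pid.encode())
            h.update(np.ascontiguousarray(self.images[pid]).tobytes())
        return h.hexdigest()


def _split_wsi_indices(n, rng):
    """Assign n per-class WSIs to train/val/test (~80/20, val from train)."""
    order = list(rng.permutation(n))
    if n == 1:
        return {order[0]: "train"}
    n_test = max(1, int(round(0.2 * n)))
    trainval = order[n_test:]
    n_val = max(1, int(round(0.1 * len(trainval)))) if len(trainval) >= 2 else 0
    out = {i: "test" for i in order[:n_test]}
    out |= {i: "val" for i in trainval[:n_val]}
    out |= {i: "train" for i in trainval[n_val:]}
    return out


def generate_dataset(spec, n_wsis_per_class, patches_per_wsi, seed, domain="source",
                     patch_size=64, withhold_train_labels=False):
    """Generate one domain's dataset of virtual WSIs with manifest and truth."""
    if n_wsis_per_class < 1 or patches_per_wsi < 1:
        raise ValueError("counts must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    split_rng = np.random.default_rng(ss.spawn(1)[0])
    images, records = {}, []
    truth = SyntheticTruth(spec.stain_matrix(), {}, {}, {}, {})
    for label in ("low", "high"):
        splits = _split_wsi_indices(n_wsis_per_class, split_rng)
        child_seeds = ss.spawn(n_wsis_per_class)
        for k in range(n_wsis_per_class):
            wsi_id = f"{domain}-{label}-{k:03d}"
            frag = generate_wsi(label, patches_per_wsi, spec, child_seeds[k],
                                patch_size=patch_size, wsi_id=wsi_id)
            split = splits[k]
            withheld = withhold_train_labels and split in ("train", "val")
            truth.wsi_multipliers[wsi_id] = frag.multiplier
            for pid, patch, conc, nb in zip(frag.patch_ids, frag.patches,
                                            frag.concentrations, frag.blob_counts):
                images[pid] = patch
                truth.labels[pid] = label
                truth.concentrations[pid] = conc
                truth.blob_counts[pid] = nb
                records.append(PatchRecord(
                    patch_id=pid, wsi_id=wsi_id, patient_id=frag.patient_id,
                    label=WITHHELD if withheld else label,
                    domain=domain, split=split,
                ))
    return SyntheticDataset(images=images, manifest=Manifest.from_records(records),
                            truth=truth, seed=seed, spec=spec)


def generate_domain_pair(source_spec, target_spec, n_wsis_per_class,
                         patches_per_wsi, seed, patch_size=64):
    """Generate a (source, target) dataset pair with shared class semantics.

    Target train/val rows carry withheld labels in the manifest (unsupervised
    adaptation uses no target annotations); the generating labels remain in
    the target dataset's ``truth`` for evaluation only.
    """
    ss = np.random.SeedSequence(seed)
    s_seed, t_seed = ss.spawn(2)
    source = generate_dataset(source_spec, n_wsis_per_class, patches_per_wsi,
                              s_seed, domain="source", patch_size=patch_size)
    target = generate_dataset(target_spec, n_wsis_per_class, patches_per_wsi,
                              t_seed, domain="target", patch_size=patch_size,
                              withhold_train_labels=True)
    if source_spec != target_spec and source.content_hash() == target.content_hash():
        raise GenerationIntegrityError(
            "source and target specs differ but produced identical pixels"
        )
    return source, target
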