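"""Volume ingestion, preprocessing, augmentation and dataset splitting.

Volumes (NIfTI ``.nii``/``.nii.gz`` or NRRD) are read case-by-case from a
directory layout of ``<case>/image.*`` plus an optional ``<case>/label.*``,
resliced axially into 2D grayscale arrays, resized, and z-score normalized
per volume. The labeled fraction is applied at the case (volume) level so
nearly identical adjacent slices never straddle the labeled/unlabeled or
train/test boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .backbone import ConfigurationError, InputError

SD_FLOOR = 1e-8

_IMAGE_SUFFIXES = (".nii.gz", ".nii", ".nrrd")


class DataError(IOError):
    """A volume could not be read or fails validation."""


@dataclass
class LabeledSlice:
    image: np.ndarray  # (H, W) float32, normalized
    mask: np.ndarray   # (H, W) integer classes
    case_id: str


@dataclass
class UnlabeledSlice:
    image: np.ndarray
    case_id: str


@dataclass
class DatasetSplit:
    """Labeled set D^L, unlabeled set D^U and a held-out test set.

    Case ids never repeat across the three subsets.
    """

    labeled: list = field(default_factory=list)      # LabeledSlice
    unlabeled: list = field(default_factory=list)    # UnlabeledSlice
    test: list = field(default_factory=list)         # (case_id, images, masks)

    def __post_init__(self):
        lab = {s.case_id for s in self.labeled}
        unl = {s.case_id for s in self.unlabeled}
        tst = {c[0] for c in self.test}
        if (lab & unl) or (lab & tst) or (unl & tst):
            raise ConfigurationError("a case id appears in more than one subset")
        if not self.labeled:
            raise ConfigurationError("the labeled set must contain at least one case")


def _read_volume(path: Path) -> np.ndarray:
    import SimpleITK as sitk

    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise DataError(f"cannot read volume {path}: {exc}") from exc
    # (z, y, x) -> slices along the first axis
    return sitk.GetArrayFromImage(img)


def _find_file(case_dir: Path, stem: str) -> Path | None:
    for suffix in _IMAGE_SUFFIXES:
        p = case_dir / (stem + suffix)
        if p.exists():
            return p
    return None


def load_volume(path, num_classes: int | None = None):
    """Load one case directory -> (slice stack, mask stack or None).

    ``path`` is a directory holding ``image.*`` and optionally ``label.*``.
    """
    case_dir = Path(path)
    image_path = _find_file(case_dir, "image")
    if image_path is None:
        raise DataError(f"case {case_dir.name}: no image.* volume found")
    images = _read_volume(image_path).astype(np.float32)
    if images.ndim == 2:
        images = images[None]
    label_path = _find_file(case_dir, "label")
    masks = None
    if label_path is not None:
        masks = np.rint(_read_volume(label_path)).astype(np.int64)
        if masks.ndim == 2:
            masks = masks[None]
        if masks.shape != images.shape:
            raise DataError(
                f"case {case_dir.name}: image {images.shape} vs label "
                f"{masks.shape} shape mismatch")
        if num_classes is not None:
            bad = set(np.unique(masks)) - set(range(num_classes))
            if bad:
                raise DataError(
                    f"case {case_dir.name}: label values {sorted(bad)} outside "
                    f"[0, {num_classes})")
    return images, masks


def load_cases(root, num_classes: int | None = None):
    """All case subdirectories of ``root`` as (case_id, images, masks)."""
    root = Path(root)
    cases = []
    for case_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        images, masks = load_volume(case_dir, num_classes=num_classes)
        cases.append((case_dir.name, images, masks))
    if not cases:
        raise DataError(f"no case directories found under {root}")
    return cases


def preprocess(images: np.ndarray, masks: np.ndarray | None = None,
               target_size: int = 256):
    """Resize slices to ``target_size``^2 and z-score the volume.

    Images are resized bilinearly, masks by nearest neighbour (no new class
    values can appear). Normalization is per volume: mean 0, sd 1 over all
    voxels, with an sd floor for constant-intensity volumes.
    """
    images = np.asarray(images, dtype=np.float32)
    if images.ndim != 3:
        raise InputError(f"expected a (slices, H, W) stack, got {images.shape}")
    if images.shape[1:] != (target_size, target_size):
        images = np.stack([
            resize(s, (target_size, target_size), order=1, mode="reflect",
                   anti_aliasing=True, preserve_range=True)
            for s in images]).astype(np.float32)
    sd = float(images.std())
    if sd < SD_FLOOR:
        warnings.warn("constant-intensity volume; applying sd floor")
        sd = SD_FLOOR
    images = (images - images.mean()) / sd
    if masks is None:
        return images, None
    masks = np.asarray(masks)
    if masks.shape[1:] != (target_size, target_size):
        masks = np.stack([
            resize(m, (target_size, target_size), order=0, mode="constant",
                   preserve_range=True, anti_aliasing=False)
            for m in masks]).astype(np.int64)
    return images, masks.astype(np.int64)


# the 8-element dihedral group: (quarter-turns, flip?)
DIHEDRAL = [(k, f) for f in (False, True) for k in range(4)]


def apply_dihedral(arr: np.ndarray, element) -> np.ndarray:
    k, flip = element
    out = np.rot90(arr, k)
    if flip:
        out = out[:, ::-1]
    return np.ascontiguousarray(out)


def invert_dihedral(arr: np.ndarray, element) -> np.ndarray:
    k, flip = element
    out = arr[:, ::-1] if flip else arr
    return np.ascontiguousarray(np.rot90(out, -k))


def augment(image: np.ndarray, mask: np.ndarray | None,
            rng: np.random.Generator):
    """Apply a uniformly drawn dihedral transform to image (and mask) alike."""
    element = DIHEDRAL[rng.integers(len(DIHEDRAL))]
    image = apply_dihedral(image, element)
    if mask is None:
        return image, None
    return image, apply_dihedral(mask, element)


def make_split(cases, labeled_fraction: float, seed: int,
               test_fraction: float = 0.2) -> DatasetSplit:
    """Case-level partition into labeled / unlabeled / test subsets.

    Cases are first split into train and test volumes; within train,
    ``ceil(labeled_fraction * n_train)`` cases contribute labeled slices and
    the remaining cases contribute images only (their labels are discarded).
    """
    if not 0.0 < labeled_fraction <= 1.0:
        raise ConfigurationError(
            f"labeled_fraction must lie in (0, 1], got {labeled_fraction}")
    if not 0.0 <= test_fraction < 1.0:
        raise ConfigurationError(
            f"test_fraction must lie in [0, 1), got {test_fraction}")
    cases = list(cases)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cases))
    n_test = int(round(test_fraction * len(cases)))
    n_train = len(cases) - n_test
    if n_train < 1:
        raise ConfigurationError("split leaves no training cases")
    n_labeled = int(np.ceil(labeled_fraction * n_train))
    if n_labeled < 1:
        raise ConfigurationError("labeled_fraction yields zero labeled cases")
    split = DatasetSplit.__new__(DatasetSplit)
    split.labeled, split.unlabeled, split.test = [], [], []
    for rank, idx in enumerate(order):
        case_id, images, masks = cases[idx]
        if rank < n_labeled:
            if masks is None:
                raise DataError(f"case {case_id} selected as labeled but has no labels")
            for img, m in zip(images, masks):
                split.labeled.append(LabeledSlice(img, m, case_id))
        elif rank < n_train:
            for img in images:
                split.unlabeled.append(UnlabeledSlice(img, case_id))
        else:
            split.test.append((case_id, np.asarray(images), np.asarray(masks)))
    split.__post_init__()
    return split
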