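"""Volume/manifest I/O, cropping, intensity normalization, splits, augmentation.

Coordinates are 0-based with axis order (x, y, z) matching the NIfTI array
layout; crops use half-open windows [c-25, c+25). HU values are clipped to
[-1000, 400] (air through contrast-free soft tissue) and mapped affinely to
[0, 1] exactly once per pipeline — ``ModelInput`` carries a flag so the
mapping is never applied twice.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "CTSubvolume", "ModelInput", "TrainValSplit",
    "read_volume", "write_volume", "crop_subvolume", "normalize_intensity",
    "make_split", "augment", "build_model_input", "load_cohort",
    "HU_CLIP",
]

HU_CLIP = (-1000.0, 400.0)
CROP_SIZE = 50


@dataclass
class CTSubvolume:
    """A HU-valued grid with voxel spacing; the unit of model input."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing components must be strictly positive")


@dataclass
class ModelInput:
    """Channels-last (D, H, W, C) stack: normalized image (+ binary mask)."""

    data: np.ndarray
    normalized: bool = True
    origin_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, np.float32)
        if self.data.ndim != 4 or self.data.shape[3] not in (1, 2):
            raise ValueError(f"ModelInput must be (D, H, W, 1|2), got {self.data.shape}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[3]


@dataclass
class TrainValSplit:
    train_ids: tuple
    val_ids: tuple
    fraction: float
    seed: int


def read_volume(path: str | Path) -> CTSubvolume:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=img.get_data_dtype())
    spacing = tuple(round(float(z), 6) for z in img.header.get_zooms()[:3])
    return CTSubvolume(values=arr, spacing_mm=spacing, origin_id=Path(path).stem)


def write_volume(path: str | Path, sub: CTSubvolume) -> None:
    affine = np.diag(list(sub.spacing_mm) + [1.0])
    img = nib.Nifti1Image(sub.values, affine)
    img.header.set_zooms(sub.spacing_mm)
    img.header.set_data_dtype(sub.values.dtype)
    nib.save(img, str(path))


def crop_subvolume(volume: np.ndarray, centre, size: int = CROP_SIZE) -> np.ndarray:
    """Extract the half-open ``size``^3 window [c - size//2, c + size - size//2).

    No resampling and no implicit padding: a window that exceeds the grid
    raises instead of being clipped.
    """
    volume = np.asarray(volume)
    half = size // 2
    starts = [int(c) - half for c in centre]
    for ax, s in enumerate(starts):
        if s < 0 or s + size > volume.shape[ax]:
            raise IndexError(
                f"crop window [{s}, {s + size}) exceeds axis {ax} of size "
                f"{volume.shape[ax]}")
    sl = tuple(slice(s, s + size) for s in starts)
    return volume[sl]


def centre_crop(volume: np.ndarray, size: int = CROP_SIZE) -> np.ndarray:
    """Crop the central ``size``^3 window."""
    centre = [n // 2 for n in volume.shape[:3]]
    return crop_subvolume(volume, centre, size)


def normalize_intensity(values: np.ndarray) -> np.ndarray:
    """Clip HU to [-1000, 400] and map affinely onto [0, 1]."""
    values = np.asarray(values, np.float32)
    if not np.all(np.isfinite(values)):
        raise ValueError("volume contains non-finite voxels")
    lo, hi = HU_CLIP
    return ((np.clip(values, lo, hi) - lo) / (hi - lo)).astype(np.float32)


def build_model_input(volume_hu: np.ndarray, mask: np.ndarray | None = None,
                      origin_id: str = "") -> ModelInput:
    """Stack a normalized image channel (and optional binary mask channel)."""
    img = normalize_intensity(volume_hu)
    channels = [img]
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != img.shape:
            raise ValueError("mask and volume shapes differ")
        channels.append((mask > 0).astype(np.float32))
    return ModelInput(data=np.stack(channels, axis=-1), normalized=True,
                      origin_id=origin_id)


def make_split(ids, fraction: float = 0.8, seed: int = 0,
               groups: dict | None = None) -> TrainValSplit:
    """Uniformly random train/validation partition, deterministic per seed.

    With ``groups`` (id -> group key, e.g. patient), whole groups are
    assigned to one side so that correlated segmentations never straddle
    the split; |train| then matches round(fraction * N) as closely as the
    group sizes allow.
    """
    ids = list(ids)
    if len(ids) < 5:
        raise ValueError("need at least 5 ids to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_train = round(fraction * len(ids))
    if groups is None:
        perm = rng.permutation(len(ids))
        train = tuple(ids[i] for i in perm[:n_train])
        val = tuple(ids[i] for i in perm[n_train:])
    else:
        keys = sorted({groups[i] for i in ids}, key=str)
        order = rng.permutation(len(keys))
        train_list: list = []
        val_list: list = []
        for gi in order:
            members = [i for i in ids if groups[i] == keys[gi]]
            (train_list if len(train_list) + len(members) <= n_train else val_list
             ).extend(members)
        train, val = tuple(train_list), tuple(val_list)
    return TrainValSplit(train_ids=train, val_ids=val, fraction=fraction, seed=seed)


def _draw_crop_origin(rng: np.random.Generator, context_shape,
                      size: int = CROP_SIZE) -> tuple[int, int, int]:
    """Uniform random origin of a ``size``^3 crop inside ``context_shape``."""
    return tuple(int(rng.integers(0, n - size + 1)) for n in context_shape[:3])


def augment(inp: ModelInput, seed_or_rng, size: int = CROP_SIZE) -> ModelInput:
    """Training-time augmentation: random crop, axis flips, right-angle rotation.

    Applies, in order: a random ``size``^3 crop from the context grid, an
    independent flip along each axis (p = 0.5 each), and a rotation by a
    random multiple of 90 degrees in a random axis pair. All channels
    (image and mask) undergo identical geometric transforms; intensity
    values are never altered.
    """
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator) else seed_or_rng
    data = inp.data
    if any(n < size for n in data.shape[:3]):
        raise ValueError(f"context {data.shape[:3]} smaller than {size}^3")
    o = _draw_crop_origin(rng, data.shape, size)
    out = data[o[0]:o[0] + size, o[1]:o[1] + size, o[2]:o[2] + size, :]
    for ax in range(3):
        if rng.random() < 0.5:
            out = np.flip(out, axis=ax)
    axes = [(0, 1), (0, 2), (1, 2)][int(rng.integers(3))]
    out = np.rot90(out, k=int(rng.integers(4)), axes=axes)
    return ModelInput(data=np.ascontiguousarray(out), normalized=inp.normalized,
                      origin_id=inp.origin_id)


def load_cohort(manifest: pd.DataFrame | str | Path, variant: str = "noSEG",
                with_masks: bool = False):
    """Load a cohort manifest into arrays ready for training/evaluation.

    Returns (X, y, records) where X is (n, s, s, s, c) float32 with the
    image channel normalized to [0, 1] (s is the stored grid size, 60 with
    context), y is the 0/1 label vector (premalignant = 1), and records is
    the manifest as a DataFrame. With ``with_masks=True`` the (centre-crop
    aligned) binary masks are returned as a fourth element, for evaluation
    only.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    if variant not in ("SEG", "noSEG"):
        raise ValueError("variant must be 'SEG' or 'noSEG'")
    xs, masks = [], []
    for _, row in manifest.iterrows():
        vol = read_volume(row["volume_path"]).values
        mask = None
        if variant == "SEG" or with_masks:
            mask = read_volume(row["mask_path"]).values
        if variant == "SEG":
            xs.append(build_model_input(vol, mask, origin_id=row["polyp_id"]).data)
        else:
            xs.append(build_model_input(vol, origin_id=row["polyp_id"]).data)
        if with_masks:
            masks.append((mask > 0).astype(np.uint8))
    X = np.stack(xs)
    y = (manifest["class_label"] == "premalignant").to_numpy().astype(np.int64)
    if with_masks:
        return X, y, manifest.reset_index(drop=True), np.stack(masks)
    return X, y, manifest.reset_index(drop=True)
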