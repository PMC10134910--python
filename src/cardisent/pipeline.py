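"""Imaging I/O and preprocessing: normalization, resampling, cropping, splits.

Preprocessing mirrors common cine-MR practice: each 2-D slice is
standardized by its mean and intensity range and rescaled to [0, 1],
volumes are resampled in-plane to a fixed 1.37 mm/pixel grid (bilinear for
images, nearest-neighbour for label maps; through-plane spacing is left
untouched), and slices are centre-cropped or zero-padded to a square crop.
Study splits are always at the subject level.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

DEFAULT_SPACING_MM = 1.37
DEFAULT_CROP = 192


@dataclass
class SlabBatch:
    """A batch of preprocessed 2-D slices with optional labels.

    ``onehot`` has one channel per class and sums to 1 at every pixel.
    ``provenance`` carries (subject, frame, slice) triples for traceability.
    """

    images: np.ndarray  # (B, H, W) in [0, 1]
    masks: np.ndarray | None = None  # (B, H, W) uint8
    onehot: np.ndarray | None = None  # (B, L, H, W)
    provenance: list[tuple[int, int, int]] | None = None


def one_hot(masks: np.ndarray, n_classes: int = 4) -> np.ndarray:
    """(B, H, W) integer labels -> (B, L, H, W) one-hot float32."""
    eye = np.eye(n_classes, dtype=np.float32)
    return eye[masks].transpose(0, 3, 1, 2)


def normalize_slice(slc: np.ndarray) -> np.ndarray:
    """Mean/range standardization followed by a min-max rescale to [0, 1].

    Constant slices map to all zeros.
    """
    slc = np.asarray(slc, dtype=np.float32)
    if slc.ndim != 2:
        raise ValueError("normalize_slice expects a 2-D array")
    if not np.all(np.isfinite(slc)):
        raise ValueError("normalize_slice: input contains non-finite values")
    rng = float(slc.max() - slc.min())
    if rng == 0.0:
        return np.zeros_like(slc)
    out = (slc - slc.mean()) / rng
    out = out - out.min()
    return (out / out.max()).astype(np.float32)


def resample(
    volume: np.ndarray,
    source_spacing: float,
    target_spacing: float = DEFAULT_SPACING_MM,
    is_mask: bool = False,
) -> np.ndarray:
    """In-plane resampling of a (..., H, W) array to target mm/pixel."""
    if source_spacing <= 0 or target_spacing <= 0:
        raise ValueError("spacings must be positive")
    factor = source_spacing / target_spacing
    if factor == 1.0:
        return np.asarray(volume).copy()
    order = 0 if is_mask else 1
    zoom = [1.0] * (volume.ndim - 2) + [factor, factor]
    out = ndimage.zoom(volume, zoom, order=order, mode="grid-constant",
                       cval=0.0, grid_mode=True)
    return out.astype(volume.dtype) if is_mask else out.astype(np.float32)


def crop_or_pad(slc: np.ndarray, size: int = DEFAULT_CROP) -> np.ndarray:
    """Centre crop (larger inputs) or symmetric zero-pad (smaller inputs).

    Index convention is 0-based and half-open: a 256 -> 192 crop keeps rows
    and columns [32, 224).
    """
    if size % 2:
        raise ValueError("crop size must be even")
    out = np.asarray(slc)
    for axis in (-2, -1):
        n = out.shape[axis]
        if n > size:
            lo = (n - size) // 2
            sl = [slice(None)] * out.ndim
            sl[axis] = slice(lo, lo + size)
            out = out[tuple(sl)]
        elif n < size:
            before = (size - n) // 2
            after = size - n - before
            pads = [(0, 0)] * out.ndim
            pads[axis] = (before, after)
            out = np.pad(out, pads)
    return out


def split(
    n_subjects_or_study,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Subject-level train/val/test split.

    Validation and test sizes are floored; the remainder goes to training
    (20 subjects at 0.7/0.15/0.15 -> 14/3/3).  Deterministic under ``seed``.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = (
        n_subjects_or_study
        if isinstance(n_subjects_or_study, (int, np.integer))
        else n_subjects_or_study.n_subjects
    )
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError("every partition must contain at least one subject")
    order = np.random.default_rng(seed).permutation(n)
    return {
        "train": np.sort(order[:n_train]),
        "val": np.sort(order[n_train : n_train + n_val]),
        "test": np.sort(order[n_train + n_val :]),
    }


# ------------------------------------------------------------------- file I/O
def write_nifti(path, volume: np.ndarray, pixel_spacing: float,
                slice_thickness: float) -> None:
    import nibabel as nib

    affine = np.diag([pixel_spacing, pixel_spacing, slice_thickness, 1.0])
    data = np.asarray(volume)
    if data.dtype == np.uint8:
        img = nib.Nifti1Image(data.transpose(2, 1, 0), affine)
        img.header.set_data_dtype(np.uint8)
    else:
        img = nib.Nifti1Image(data.transpose(2, 1, 0).astype(np.float32), affine)
    nib.save(img, os.fspath(path))


def read_nifti(path):
    """Returns (volume (slices, H, W), pixel_spacing, slice_thickness)."""
    import nibabel as nib

    img = nib.load(os.fspath(path))
    zooms = img.header.get_zooms()
    vol = np.asanyarray(img.dataobj).transpose(2, 1, 0)
    return vol, float(zooms[0]), float(zooms[2])


def write_png(path, slc: np.ndarray) -> None:
    import imageio.v3 as iio

    arr = np.clip(np.asarray(slc, dtype=np.float32), 0, 1)
    iio.imwrite(os.fspath(path), (arr * 255).astype(np.uint8))


def read_png(path) -> np.ndarray:
    import imageio.v3 as iio

    arr = iio.imread(os.fspath(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr.astype(np.float32) / 255.0)


def write_study(study, out_dir) -> None:
    """Write a phantom study: NIfTI volumes per subject/frame + manifest CSV."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    cfg = study.config
    for i in range(study.n_subjects):
        for f, frame in enumerate(("ED", "ES")):
            base = os.path.join(out_dir, f"subject{i:03d}_{frame}")
            write_nifti(base + "_img.nii.gz", study.images[i, f],
                        cfg.pixel_spacing, cfg.slice_thickness)
            write_nifti(base + "_mask.nii.gz", study.masks[i, f],
                        cfg.pixel_spacing, cfg.slice_thickness)
    study.truth.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)


def read_study_dir(in_dir):
    """Read back a study directory written by :func:`write_study`.

    Returns (images, masks, manifest DataFrame, pixel_spacing, thickness).
    """
    in_dir = os.fspath(in_dir)
    manifest = pd.read_csv(os.path.join(in_dir, "manifest.csv"))
    images, masks = [], []
    spacing = thickness = None
    for i in manifest["subject"]:
        per_frame_img, per_frame_mask = [], []
        for frame in ("ED", "ES"):
            base = os.path.join(in_dir, f"subject{int(i):03d}_{frame}")
            vol, spacing, thickness = read_nifti(base + "_img.nii.gz")
            m, _, _ = read_nifti(base + "_mask.nii.gz")
            per_frame_img.append(vol)
            per_frame_mask.append(m.astype(np.uint8))
        images.append(per_frame_img)
        masks.append(per_frame_mask)
    return (np.asarray(images, dtype=np.float32), np.asarray(masks),
            manifest, spacing, thickness)
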