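"""Preprocessing: Z-score normalization, background cropping, label-region
remapping, 3D-to-2D slicing with tumor-free slice filtering, and the
on-disk slice store.

The pipeline for one case is: normalize each 3D modality volume to zero
mean and unit SD (labels are never normalized), crop the in-plane dims with
a centered window (240 -> 160 for BraTS-shaped data) to shrink the black
background, slice along the third axis, drop slices whose cropped label
slice contains no tumor voxel, and stack the four modality slices as
channels.  Region masks (WT/TC/ET) come from the label algebra
wt = {1,2,4}, tc = {1,4}, et = {4}.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    LabelVolume,
    MultimodalVolume,
    RegionMasks,
    SliceSample,
    ValidationError,
    check_labels,
)

logger = logging.getLogger(__name__)

#: Default in-plane crop for BraTS-shaped (240x240) data.
DEFAULT_CROP = (160, 160)


def zscore_normalize(volume: np.ndarray, support: str = "volume") -> np.ndarray:
    """Normalize one modality volume to zero mean and unit SD.

    ``support`` selects the voxels over which mean/SD are computed:
    ``"volume"`` (all voxels, the default) or ``"nonzero"`` (brain-only,
    excluding the zero background).  The affine map is always applied to
    every voxel.  SD is the population SD (ddof=0).  A constant input has
    zero SD and returns an all-zeros array with a warning.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.size == 0:
        raise ValidationError("cannot normalize an empty array")
    if support == "volume":
        sel = volume.reshape(-1)
    elif support == "nonzero":
        sel = volume[volume != 0]
        if sel.size == 0:
            sel = volume.reshape(-1)
    else:
        raise ValidationError(f"unknown norm support {support!r}")
    mean = sel.mean()
    sd = sel.std()
    if sd == 0:
        logger.warning("constant volume (SD=0); returning zeros")
        return np.zeros_like(volume, dtype=np.float32)
    return ((volume - mean) / sd).astype(np.float32)


def _inplane_axes(ndim: int) -> tuple[int, int]:
    # (H, W[, D]) arrays index in-plane at (0, 1); channel-first 4D at (1, 2)
    if ndim in (2, 3):
        return 0, 1
    if ndim == 4:
        return 1, 2
    raise ValidationError(f"cannot infer in-plane axes for a {ndim}D array")


def crop_background(array: np.ndarray, crop_size: tuple[int, int] = DEFAULT_CROP) -> np.ndarray:
    """Centered in-plane crop; channel and depth axes pass through untouched.

    The same deterministic window (rows/cols ``(n - c)//2 .. (n - c)//2 + c - 1``)
    applies to intensities and labels of a case, keeping them aligned.
    """
    array = np.asarray(array)
    ax_h, ax_w = _inplane_axes(array.ndim)
    ch, cw = int(crop_size[0]), int(crop_size[1])
    h, w = array.shape[ax_h], array.shape[ax_w]
    if ch > h or cw > w:
        raise ValidationError(
            f"crop size {crop_size} exceeds in-plane dims ({h}, {w})"
        )
    h0 = (h - ch) // 2
    w0 = (w - cw) // 2
    idx = [slice(None)] * array.ndim
    idx[ax_h] = slice(h0, h0 + ch)
    idx[ax_w] = slice(w0, w0 + cw)
    return array[tuple(idx)]


def labels_to_regions(labels: np.ndarray) -> RegionMasks:
    """Map tumor labels to the nested WT/TC/ET evaluation regions.

    wt = labels in {1, 2, 4}; tc = labels in {1, 4}; et = label 4.
    Any value outside {0, 1, 2, 4} raises a validation error naming it.
    """
    labels = np.asarray(labels)
    check_labels(labels)
    return RegionMasks(
        wt=np.isin(labels, (1, 2, 4)),
        tc=np.isin(labels, (1, 4)),
        et=labels == 4,
    )


def slice_and_filter(
    volume: MultimodalVolume,
    labels: LabelVolume,
    crop_size: tuple[int, int] = DEFAULT_CROP,
    case_id: str = "case000",
    norm_support: str = "volume",
    keep_empty: bool = False,
) -> list[SliceSample]:
    """Turn one 3D case into normalized, cropped, tumor-bearing 2D samples.

    Normalization statistics are computed per 3D modality volume (before
    slicing); slicing runs along the third array axis in ascending order.
    Slices whose cropped label slice has no voxel in {1, 2, 4} are dropped
    unless ``keep_empty`` (used when evaluating whole volumes).
    """
    if volume.shape != labels.shape:
        raise ValidationError(
            f"volume shape {volume.shape} does not match labels {labels.shape}"
        )
    normed = np.stack([zscore_normalize(m, support=norm_support) for m in volume.data])
    normed = crop_background(normed, crop_size)
    cropped_labels = crop_background(labels.data, crop_size)

    samples: list[SliceSample] = []
    for z in range(cropped_labels.shape[2]):
        lab2d = cropped_labels[:, :, z]
        if not keep_empty and not np.any(lab2d):
            continue
        samples.append(
            SliceSample(
                image=np.ascontiguousarray(normed[:, :, :, z]),
                masks=labels_to_regions(lab2d),
                case_id=case_id,
                slice_index=z,
            )
        )
    return samples


# -- slice store -------------------------------------------------------------


def save_slice_dataset(samples: list[SliceSample], out_dir: str | Path) -> Path:
    """Write samples as one ``.npz`` per slice plus a CSV manifest.

    Returns the manifest path.  Layout: ``<case>_z<idx>.npz`` holding
    ``image`` (4,h,w float32) and ``masks`` (3,h,w uint8 in wt/tc/et order).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        fname = f"{s.case_id}_z{s.slice_index:03d}.npz"
        np.savez_compressed(
            out_dir / fname,
            image=s.image.astype(np.float32),
            masks=s.masks.stack().astype(np.uint8),
        )
        rows.append({"case": s.case_id, "slice": s.slice_index, "path": fname})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=["case", "slice", "path"]).to_csv(manifest, index=False)
    return manifest


def load_slice_dataset(in_dir: str | Path) -> list[SliceSample]:
    """Read a slice store back, ordered by (case, ascending slice index)."""
    in_dir = Path(in_dir)
    manifest = in_dir / "manifest.csv"
    if not manifest.exists():
        raise IOError(f"no manifest.csv in {in_dir}")
    df = pd.read_csv(manifest).sort_values(["case", "slice"])
    samples = []
    for row in df.itertuples():
        with np.load(in_dir / row.path) as z:
            image = z["image"]
            m = z["masks"].astype(bool)
        samples.append(
            SliceSample(
                image=image,
                masks=RegionMasks(wt=m[0], tc=m[1], et=m[2]),
                case_id=str(row.case),
                slice_index=int(row.slice),
            )
        )
    return samples
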