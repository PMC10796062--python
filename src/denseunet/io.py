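"""NIfTI, YAML and report I/O adapters.

Volumes are stored on disk as NIfTI-1 (via nibabel) with the array's
(H, W, D) axes mapped directly onto the NIfTI (x, y, z) axes and the affine
carried through unchanged.  Integer label volumes round-trip losslessly;
float volumes round-trip at float32 precision.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .containers import MODALITIES, LabelVolume, MultimodalVolume


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI file; returns ``(array, affine)``.

    Raises ``IOError`` with the path on missing or unparseable files.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
    except Exception as exc:
        raise IOError(f"could not read NIfTI file {path}: {exc}") from exc
    return data, np.asarray(img.affine)


def write_nifti(array: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    """Write an array as NIfTI-1; integer arrays keep an integer dtype."""
    path = Path(path)
    array = np.asarray(array)
    if array.dtype.kind in "iu":
        array = array.astype(np.int16)
    else:
        array = array.astype(np.float32)
    try:
        nib.save(nib.Nifti1Image(array, np.asarray(affine, dtype=float)), path)
    except Exception as exc:
        raise IOError(f"could not write NIfTI file {path}: {exc}") from exc
    return path


def read_case(directory: str | Path, case_id: str) -> tuple[MultimodalVolume, LabelVolume]:
    """Read one BraTS-style case (``<case>_<mod>.nii.gz`` + ``<case>_seg``)."""
    directory = Path(directory)
    arrays, affine = [], None
    for mod in MODALITIES:
        arr, affine = read_nifti(directory / f"{case_id}_{mod}.nii.gz")
        arrays.append(np.asarray(arr, dtype=np.float32))
    seg, _ = read_nifti(directory / f"{case_id}_seg.nii.gz")
    return (
        MultimodalVolume(np.stack(arrays), affine),
        LabelVolume(np.asarray(seg, dtype=np.int16), affine),
    )


def list_cases(directory: str | Path) -> list[str]:
    """Case ids present in a directory, from the ``*_seg.nii.gz`` files."""
    directory = Path(directory)
    return sorted(p.name[: -len("_seg.nii.gz")] for p in directory.glob("*_seg.nii.gz"))


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    return out or {}


def dump_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
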