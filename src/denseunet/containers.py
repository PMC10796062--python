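"""In-memory containers shared across the pipeline.

Axis convention: volumes are (H, W, D) with the acquisition slices stacked
along the last axis; multimodal data adds a leading channel axis with the
fixed modality order ``MODALITIES = (t1, t2, t1ce, flair)``.  All consumers
rely on that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed channel order for multimodal arrays. Do not reorder.
MODALITIES: tuple[str, ...] = ("t1", "t2", "t1ce", "flair")

#: Tumor label values: 0 healthy, 1 necrotic/non-enhancing, 2 edema, 4 enhancing.
VALID_LABELS = frozenset({0, 1, 2, 4})

#: Evaluation regions, nested as ET <= TC <= WT.
REGIONS: tuple[str, ...] = ("wt", "tc", "et")


class ValidationError(ValueError):
    """Raised when an array violates a domain invariant (e.g. a stray label)."""


@dataclass
class MultimodalVolume:
    """Four co-registered 3D intensity arrays, one per modality.

    ``data`` has shape (4, H, W, D) in the fixed :data:`MODALITIES` order;
    ``affine`` is the voxel-to-world matrix carried through NIfTI I/O.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4 or self.data.shape[0] != len(MODALITIES):
            raise ValidationError(
                f"expected (4, H, W, D) multimodal array, got shape {self.data.shape}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def modality(self, name: str) -> np.ndarray:
        return self.data[MODALITIES.index(name)]


@dataclass
class LabelVolume:
    """Integer tumor-label volume aligned to a :class:`MultimodalVolume`."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"expected (H, W, D) label array, got {self.data.shape}")
        if self.data.dtype.kind not in "iu":
            raise ValidationError(f"label volume must be integer, got {self.data.dtype}")
        check_labels(self.data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def check_labels(arr: np.ndarray) -> None:
    """Raise :class:`ValidationError` naming any label outside {0, 1, 2, 4}."""
    present = set(np.unique(arr).tolist())
    bad = present - VALID_LABELS
    if bad:
        raise ValidationError(
            f"unexpected label value(s) {sorted(bad)}; allowed labels are {sorted(VALID_LABELS)}"
        )


@dataclass
class RegionMasks:
    """Binary masks for the three nested evaluation regions.

    wt (whole tumor) = labels {1, 2, 4}; tc (tumor core) = labels {1, 4};
    et (enhancing tumor) = label {4}.  The label algebra forces
    et <= tc <= wt pointwise.
    """

    wt: np.ndarray
    tc: np.ndarray
    et: np.ndarray

    def __post_init__(self) -> None:
        self.wt = np.asarray(self.wt, dtype=bool)
        self.tc = np.asarray(self.tc, dtype=bool)
        self.et = np.asarray(self.et, dtype=bool)
        if not (self.wt.shape == self.tc.shape == self.et.shape):
            raise ValidationError("region masks must share one shape")

    def __getitem__(self, region: str) -> np.ndarray:
        return getattr(self, region)

    def stack(self) -> np.ndarray:
        """(3, ...) array in region order wt, tc, et."""
        return np.stack([self.wt, self.tc, self.et])

    def is_nested(self) -> bool:
        return bool(np.all(self.et <= self.tc) and np.all(self.tc <= self.wt))


@dataclass
class SliceSample:
    """One 2D training unit: a 4-channel normalized slice plus region masks."""

    image: np.ndarray  # (4, h, w) float
    masks: RegionMasks
    case_id: str
    slice_index: int
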