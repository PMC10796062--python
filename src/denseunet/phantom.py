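"""Seeded synthetic multimodal brain-tumor phantoms.

Each case is a brain ellipsoid containing three concentric tumor
compartments -- peritumoral edema (label 2) enclosing an enhancing shell
(label 4) around a necrotic interior (label 1) -- voxelized on a BraTS-like
grid and rendered in four MR modalities (t1, t2, t1ce, flair) as
piecewise-constant tissue-class means plus additive Gaussian noise.  The
modality contrasts differ per compartment (edema brightest in flair, the
enhancing shell brightest in t1ce), so multimodal fusion carries real
information downstream.  Background intensity has mean 0 in every modality.

The generator is a statistical stand-in for real acquisitions: it emulates
label semantics, nesting, modality contrast and noise, not MR physics.
Case streams are seeded per ``(seed, case_index)``, so a fixed seed gives
byte-identical volumes and the stream for one index does not depend on
``n_cases``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import MODALITIES, LabelVolume, MultimodalVolume

#: Tissue classes, in the order used by ``modality_contrasts`` rows.
TISSUE_CLASSES = ("background", "brain", "necrotic", "edema", "enhancing")

#: Mean intensity per modality (rows: t1, t2, t1ce, flair) and tissue class
#: (columns in ``TISSUE_CLASSES`` order).  Arbitrary units; background is 0.
DEFAULT_CONTRASTS: dict[str, tuple[float, ...]] = {
    "t1": (0.0, 0.55, 0.25, 0.35, 0.45),
    "t2": (0.0, 0.40, 0.55, 0.70, 0.50),
    "t1ce": (0.0, 0.50, 0.20, 0.35, 0.95),
    "flair": (0.0, 0.35, 0.45, 0.90, 0.55),
}


class ConfigurationError(ValueError):
    """Invalid phantom configuration; the message names the offending field."""


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, contrast and noise settings for one phantom batch.

    ``compartment_radii`` are the (edema, enhancing-shell, necrotic-core)
    outer radii in voxels and must be strictly decreasing: voxels inside
    the innermost radius get label 1, the shell between the inner two radii
    label 4, and the remaining outer shell label 2.
    """

    volume_shape: tuple[int, int, int] = (240, 240, 155)
    brain_radius_frac: float = 0.85
    tumor_center: tuple[float, float, float] | None = None  # None -> volume center
    compartment_radii: tuple[float, float, float] = (30.0, 18.0, 10.0)
    modality_contrasts: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CONTRASTS)
    )
    noise_sd: float = 0.03
    center_jitter: float = 3.0  # per-case uniform jitter of the tumor center, voxels
    radius_jitter_frac: float = 0.1  # per-case relative jitter of all radii
    seed: int = 0
    n_cases: int = 1

    def validate(self) -> None:
        if len(self.volume_shape) != 3 or any(s <= 0 for s in self.volume_shape):
            raise ConfigurationError(
                f"volume_shape must be three positive integers, got {self.volume_shape}"
            )
        r = self.compartment_radii
        if len(r) != 3 or any(x <= 0 for x in r) or not (r[0] > r[1] > r[2]):
            raise ConfigurationError(
                "compartment_radii must be three strictly decreasing positive "
                f"values (edema > shell > core), got {r}"
            )
        if not 0.0 < self.brain_radius_frac <= 1.0:
            raise ConfigurationError(
                f"brain_radius_frac must lie in (0, 1], got {self.brain_radius_frac}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for mod in MODALITIES:
            row = self.modality_contrasts.get(mod)
            if row is None or len(row) != len(TISSUE_CLASSES):
                raise ConfigurationError(
                    f"modality_contrasts[{mod!r}] must give one mean per tissue "
                    f"class {TISSUE_CLASSES}"
                )
            if row[0] != 0.0:
                raise ConfigurationError(
                    f"modality_contrasts[{mod!r}] background mean must be 0, got {row[0]}"
                )
        if self.n_cases < 1:
            raise ConfigurationError(f"n_cases must be >= 1, got {self.n_cases}")


#: Named presets: the BraTS-shaped default and a small grid for fast runs.
PRESETS: dict[str, PhantomConfig] = {
    "brats": PhantomConfig(),
    "small": PhantomConfig(
        volume_shape=(64, 64, 24),
        compartment_radii=(10.0, 6.0, 3.0),
        center_jitter=2.0,
    ),
}


def preset(name: str, **overrides) -> PhantomConfig:
    """Return a preset configuration, optionally with fields replaced."""
    if name not in PRESETS:
        raise ConfigurationError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[name]
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return d2 <= 1.0


def generate_case(config: PhantomConfig, case_index: int) -> tuple[MultimodalVolume, LabelVolume]:
    """Generate one phantom case (4 modalities + labels) for ``case_index``.

    The per-case RNG stream is seeded by ``(seed, case_index)``: tumor center
    and radii are jittered per case, then the label volume and per-modality
    noise are drawn from the same stream.
    """
    config.validate()
    if not 0 <= case_index < config.n_cases:
        raise ConfigurationError(
            f"case_index {case_index} out of range for n_cases={config.n_cases}"
        )
    rng = np.random.default_rng([config.seed, case_index])
    shape = tuple(config.volume_shape)

    center = np.array(
        config.tumor_center
        if config.tumor_center is not None
        else [(s - 1) / 2.0 for s in shape],
        dtype=float,
    )
    center = center + rng.uniform(-config.center_jitter, config.center_jitter, size=3)
    radii = np.array(config.compartment_radii) * (
        1.0 + rng.uniform(-config.radius_jitter_frac, config.radius_jitter_frac)
    )

    brain_center = [(s - 1) / 2.0 for s in shape]
    brain_axes = [config.brain_radius_frac * s / 2.0 for s in shape]
    brain = _ellipsoid_mask(shape, brain_center, brain_axes)

    labels = np.zeros(shape, dtype=np.int16)
    edema = _ellipsoid_mask(shape, center, [radii[0]] * 3) & brain
    shell = _ellipsoid_mask(shape, center, [radii[1]] * 3) & brain
    core = _ellipsoid_mask(shape, center, [radii[2]] * 3) & brain
    labels[edema] = 2
    labels[shell] = 4
    labels[core] = 1

    class_masks = [
        ~brain,                      # background
        brain & (labels == 0),       # healthy brain tissue
        labels == 1,                 # necrotic / non-enhancing
        labels == 2,                 # edema
        labels == 4,                 # enhancing
    ]
    data = np.empty((len(MODALITIES),) + shape, dtype=np.float32)
    for ch, mod in enumerate(MODALITIES):
        means = config.modality_contrasts[mod]
        img = np.zeros(shape, dtype=np.float32)
        for mean, mask in zip(means, class_masks):
            if mean:
                img[mask] = mean
        if config.noise_sd > 0:
            img += rng.normal(0.0, config.noise_sd, size=shape).astype(np.float32)
        data[ch] = img

    affine = np.eye(4)
    return MultimodalVolume(data, affine), LabelVolume(labels, affine)


def generate_cases(config: PhantomConfig):
    """Yield ``(case_id, MultimodalVolume, LabelVolume)`` for every case."""
    for i in range(config.n_cases):
        vol, lab = generate_case(config, i)
        yield f"case{i:03d}", vol, lab


def write_case(
    volume: MultimodalVolume,
    labels: LabelVolume,
    directory: str | Path,
    case_id: str = "case000",
) -> list[Path]:
    """Write one case as five NIfTI files with BraTS-style suffixes.

    Files are ``<case>_t1/_t2/_t1ce/_flair/_seg.nii.gz``.  The directory is
    validated (and created) before any file is written, so an invalid path
    leaves no partial output.
    """
    from .io import write_nifti  # deferred: keeps phantom importable without nibabel

    if not str(directory):
        raise IOError("output directory path is empty")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if volume.shape != labels.shape:
        raise ValueError(
            f"volume shape {volume.shape} does not match labels {labels.shape}"
        )
    paths = []
    for ch, mod in enumerate(MODALITIES):
        p = directory / f"{case_id}_{mod}.nii.gz"
        write_nifti(volume.data[ch], volume.affine, p)
        paths.append(p)
    seg = directory / f"{case_id}_seg.nii.gz"
    write_nifti(labels.data, labels.affine, seg)
    paths.append(seg)
    return paths
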