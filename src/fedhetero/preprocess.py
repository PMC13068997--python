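"""CT volume standardization and augmentation.

The chain mirrors a common abdominal-CT preparation pipeline: resample to
isotropic voxel spacing (trilinear for intensities, nearest-neighbor for
masks), clip to the [-1000, 2000] Hounsfield-unit window, per-patient
z-score normalization, and extraction of a fixed-size region of interest
centered on an organ mask (zero-padded where it extends past the volume;
after z-scoring, zero is the mean intensity).  Training-time augmentation
applies seeded random flips, zoom in [0.9, 1.2], Gaussian noise
(sigma = 0.01), multiplicative intensity scaling in [0.7, 1.3], and 90-degree
rotations.

Volumes are plain numpy grids with spacing metadata; NIfTI I/O goes
through nibabel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.ndimage as ndi

__all__ = [
    "VolumeGrid",
    "AugmentConfig",
    "resample_isotropic",
    "clip_hu",
    "zscore",
    "crop_roi",
    "augment",
    "rotate90",
    "zoom_volume",
    "preprocess_chain",
    "read_nifti",
    "write_nifti",
    "make_phantom",
]


@dataclass(frozen=True)
class VolumeGrid:
    """3-D intensity grid with voxel spacing (mm) and an optional mask."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError("volume must be 3-D")
        object.__setattr__(self, "data", data)
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError("spacing must be three positive values (mm)")
        object.__setattr__(self, "spacing", spacing)
        if self.mask is not None:
            mask = np.asarray(self.mask).astype(bool)
            if mask.shape != data.shape:
                raise ValueError("mask shape must match the volume")
            object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


def resample_isotropic(v: VolumeGrid, target_mm: float = 1.0) -> VolumeGrid:
    """Resample to isotropic spacing: trilinear intensities, nearest mask.

    The output shape is ``round(shape * spacing / target)`` per axis; output
    voxel ``j`` samples input coordinate ``j * target / spacing`` with edge
    clamping.
    """
    if target_mm <= 0:
        raise ValueError("target spacing must be positive")
    in_shape = np.array(v.shape)
    in_spacing = np.array(v.spacing)
    out_shape = np.maximum(1, np.round(in_shape * in_spacing / target_mm)).astype(int)
    if np.array_equal(out_shape, in_shape) and np.allclose(in_spacing, target_mm):
        return VolumeGrid(v.data.copy(), (target_mm,) * 3,
                          None if v.mask is None else v.mask.copy())
    grids = np.meshgrid(
        *(np.arange(n) * target_mm / sp for n, sp in zip(out_shape, in_spacing)),
        indexing="ij",
    )
    coords = np.stack(grids)
    data = ndi.map_coordinates(v.data, coords, order=1, mode="nearest")
    mask = None
    if v.mask is not None:
        mask = ndi.map_coordinates(v.mask.astype(np.float64), coords, order=0,
                                   mode="nearest").astype(bool)
    return VolumeGrid(data, (target_mm,) * 3, mask)


def clip_hu(v: VolumeGrid, lo: float = -1000.0, hi: float = 2000.0) -> VolumeGrid:
    """Clamp intensities to a Hounsfield window."""
    if lo >= hi:
        raise ValueError("lo must be < hi")
    return replace(v, data=np.clip(v.data, lo, hi))


def zscore(v: VolumeGrid) -> VolumeGrid:
    """Per-patient standardization over the whole volume (population std).

    A constant volume has no scale; it maps to all zeros with a warning.
    """
    sd = float(v.data.std())
    if sd == 0.0:
        warnings.warn("constant volume: z-score output is all zeros", stacklevel=2)
        return replace(v, data=np.zeros_like(v.data))
    return replace(v, data=(v.data - v.data.mean()) / sd)


def _centroid_index(mask: np.ndarray) -> tuple[int, ...]:
    # voxel centroid, rounded down at exact .5 (2.5 -> 2, 2.6 -> 3)
    c = np.mean(np.argwhere(mask), axis=0)
    return tuple(int(np.ceil(ci - 0.5)) for ci in c)


def crop_roi(v: VolumeGrid, roi_shape: tuple[int, int, int] = (256, 256, 128)) -> VolumeGrid:
    """Fixed-size crop centered on the mask centroid, zero-padded at edges."""
    if v.mask is None or not v.mask.any():
        raise ValueError("crop_roi requires a non-empty companion mask")
    center = _centroid_index(v.mask)
    out = np.zeros(roi_shape, dtype=np.float64)
    out_mask = np.zeros(roi_shape, dtype=bool)
    src, dst = [], []
    for ax in range(3):
        start = center[ax] - roi_shape[ax] // 2
        stop = start + roi_shape[ax]
        s0, s1 = max(start, 0), min(stop, v.shape[ax])
        if s0 >= s1:
            raise ValueError("ROI does not intersect the volume")
        src.append(slice(s0, s1))
        dst.append(slice(s0 - start, s1 - start))
    out[tuple(dst)] = v.data[tuple(src)]
    out_mask[tuple(dst)] = v.mask[tuple(src)]
    return VolumeGrid(out, v.spacing, out_mask)


def rotate90(v: VolumeGrid, axis: int, k: int = 1) -> VolumeGrid:
    """Rotate by k * 90 degrees about one axis (in the plane of the others)."""
    axes = tuple(a for a in range(3) if a != axis)
    data = np.rot90(v.data, k=k, axes=axes).copy()
    mask = None if v.mask is None else np.rot90(v.mask, k=k, axes=axes).copy()
    return VolumeGrid(data, v.spacing, mask)


def zoom_volume(v: VolumeGrid, factor: float) -> VolumeGrid:
    """Trilinear zoom, then center crop / zero-pad back to the input shape."""
    if factor == 1.0:
        return v
    data = ndi.zoom(v.data, factor, order=1)
    mask = None if v.mask is None else ndi.zoom(v.mask.astype(float), factor, order=0) > 0.5
    out = np.zeros(v.shape, dtype=np.float64)
    out_mask = np.zeros(v.shape, dtype=bool) if mask is not None else None
    src, dst = [], []
    for ax in range(3):
        n_in, n_out = data.shape[ax], v.shape[ax]
        if n_in >= n_out:
            off = (n_in - n_out) // 2
            src.append(slice(off, off + n_out))
            dst.append(slice(0, n_out))
        else:
            off = (n_out - n_in) // 2
            src.append(slice(0, n_in))
            dst.append(slice(off, off + n_in))
    out[tuple(dst)] = data[tuple(src)]
    if out_mask is not None:
        out_mask[tuple(dst)] = mask[tuple(src)]
    return VolumeGrid(out, v.spacing, out_mask)


@dataclass(frozen=True)
class AugmentConfig:
    """Training-time augmentation parameters.

    Flips and 90-degree rotations fire independently with probability 0.5
    (a convention; the application probabilities are a free choice of the
    pipeline); zoom, noise and intensity scaling always apply with drawn
    parameters.  Set ``zoom_range=(1, 1)``, ``noise_sigma=0``,
    ``scale_range=(1, 1)`` and the probabilities to 0 for an identity
    transform.
    """

    flip_prob: float = 0.5
    zoom_range: tuple[float, float] = (0.9, 1.2)
    noise_sigma: float = 0.01
    scale_range: tuple[float, float] = (0.7, 1.3)
    additive_scale: bool = False  # interpret scaling as an additive offset instead
    rotate_prob: float = 0.5


def augment(v: VolumeGrid, rng_seed: int, config: AugmentConfig = AugmentConfig()) -> VolumeGrid:
    """Apply the seeded augmentation stack; deterministic given the seed."""
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 0xA06]))
    out = v
    for ax in range(3):
        if rng.random() < config.flip_prob:
            data = np.flip(out.data, axis=ax).copy()
            mask = None if out.mask is None else np.flip(out.mask, axis=ax).copy()
            out = VolumeGrid(data, out.spacing, mask)
    factor = float(rng.uniform(*config.zoom_range))
    out = zoom_volume(out, factor)
    if config.noise_sigma > 0:
        out = replace(out, data=out.data + rng.normal(0.0, config.noise_sigma, out.shape))
    scale = float(rng.uniform(*config.scale_range))
    if config.additive_scale:
        out = replace(out, data=out.data + (scale - 1.0))
    else:
        out = replace(out, data=out.data * scale)
    if rng.random() < config.rotate_prob:
        axis = int(rng.integers(0, 3))
        k = int(rng.integers(1, 4))
        out = rotate90(out, axis, k)
    return out


def preprocess_chain(
    v: VolumeGrid,
    target_mm: float = 1.0,
    hu_window: tuple[float, float] = (-1000.0, 2000.0),
    roi_shape: tuple[int, int, int] | None = (256, 256, 128),
    crop_before_zscore: bool = False,
) -> VolumeGrid:
    """resample -> clip -> z-score -> crop (the narrative order; the crop
    can optionally be moved before the z-score)."""
    out = resample_isotropic(v, target_mm)
    out = clip_hu(out, *hu_window)
    if roi_shape is not None and crop_before_zscore:
        out = crop_roi(out, roi_shape)
    out = zscore(out)
    if roi_shape is not None and not crop_before_zscore:
        out = crop_roi(out, roi_shape)
    return out


def read_nifti(path, mask_path=None) -> VolumeGrid:
    """Load a NIfTI volume (and optional mask) with spacing from the header."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0.5
    return VolumeGrid(data, spacing, mask)


def write_nifti(v: VolumeGrid, path, mask_path=None) -> None:
    """Write a volume (and optional mask) with a diagonal spacing affine."""
    import nibabel as nib

    affine = np.diag([*v.spacing, 1.0])
    nib.save(nib.Nifti1Image(v.data.astype(np.float32), affine), str(path))
    if mask_path is not None and v.mask is not None:
        nib.save(nib.Nifti1Image(v.mask.astype(np.uint8), affine), str(mask_path))


def make_phantom(
    shape: tuple[int, int, int] = (24, 24, 12),
    spacing: tuple[float, float, float] = (2.0, 2.0, 3.0),
    organ_center: tuple[float, float, float] | None = None,
    organ_radius_mm: float = 10.0,
    seed: int = 0,
) -> VolumeGrid:
    """Synthetic CT phantom: soft-tissue background with an air/bone ramp
    and a spherical "organ" of elevated intensity, plus its mask."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xFA47]))
    zi, yi, xi = np.indices(shape)
    ramp = -1200.0 + 3500.0 * zi / max(1, shape[0] - 1)  # spans past the HU window
    data = ramp + rng.normal(0.0, 20.0, shape)
    if organ_center is None:
        organ_center = tuple((s - 1) / 2.0 for s in shape)
    dist_mm = np.sqrt(
        ((zi - organ_center[0]) * spacing[0]) ** 2
        + ((yi - organ_center[1]) * spacing[1]) ** 2
        + ((xi - organ_center[2]) * spacing[2]) ** 2
    )
    mask = dist_mm <= organ_radius_mm
    data[mask] = 60.0 + rng.normal(0.0, 5.0, int(mask.sum()))
    return VolumeGrid(data, spacing, mask)
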