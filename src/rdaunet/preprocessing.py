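"""CT image conditioning: HU windowing, grid resizing, dataset splitting,
contour overlays, DICOM-series conversion, and flip/rotate augmentation.

The Hounsfield window clamps intensities to a diagnostic range and rescales
to [0,1]; the default liver soft-tissue window is [-100, 400] HU.  Images
are resized with bilinear interpolation and masks with nearest-neighbour so
they remain binary.  All coordinates are 0-based row-major (row, column).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, FormatError, InputError, ShapeError

__all__ = [
    "WindowSpec",
    "SplitResult",
    "CTVolume",
    "DEFAULT_WINDOW",
    "window_hu",
    "resize_to_grid",
    "split_dataset",
    "overlay_contour",
    "boundary_pixels",
    "dicom_series_to_nifti",
    "augment",
    "equalize_histogram",
]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)  # 4-connectivity


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    """A Hounsfield window [hu_min, hu_max] mapped linearly onto [0,1]."""

    hu_min: float = -100.0
    hu_max: float = 400.0

    def __post_init__(self) -> None:
        if not self.hu_min < self.hu_max:
            raise ConfigurationError(
                f"hu_min ({self.hu_min}) must be strictly below hu_max ({self.hu_max})"
            )


DEFAULT_WINDOW = WindowSpec(-100.0, 400.0)


@dataclasses.dataclass
class SplitResult:
    """A train/validation partition of sample identifiers."""

    train_ids: list
    val_ids: list
    ratio: float
    seed: int


@dataclasses.dataclass
class CTVolume:
    """HU-valued voxel grid with physical metadata.

    ``voxels`` is (slices, height, width); ``spacing`` is mm per voxel on
    each axis; ``origin`` the physical position of voxel (0,0,0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise InputError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise InputError("volume contains non-finite HU values")


# ------------------------------------------------------------------ windowing
def window_hu(image: np.ndarray, window: WindowSpec = DEFAULT_WINDOW) -> np.ndarray:
    """Clamp to [hu_min, hu_max] and rescale linearly onto [0,1].

    Idempotent on already-windowed data only in the sense that re-windowing
    the *HU* image reproduces the same output; on [0,1] data apply a
    (0,1)-window to keep it a no-op.
    """
    arr = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise InputError("image contains non-finite values")
    clipped = np.clip(arr, window.hu_min, window.hu_max)
    return (clipped - window.hu_min) / (window.hu_max - window.hu_min)


def equalize_histogram(image01: np.ndarray) -> np.ndarray:
    """Optional contrast equalization on a [0,1] image (off by default in
    the pipeline); thin wrapper over scikit-image."""
    from skimage import exposure

    return exposure.equalize_hist(np.asarray(image01))


# -------------------------------------------------------------------- resizing
def resize_to_grid(image: np.ndarray, target: int, is_mask: bool = False) -> np.ndarray:
    """Resize a square grid to (target, target).

    Images use bilinear interpolation; masks use nearest-neighbour and stay
    in {0,1}.
    """
    from skimage.transform import resize

    arr = np.asarray(image)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ShapeError(f"expected a square 2-D grid, got shape {arr.shape}")
    if arr.shape[0] == target:
        return arr.copy()
    if is_mask:
        out = resize(
            arr.astype(np.float32), (target, target), order=0,
            anti_aliasing=False, preserve_range=True,
        )
        return (out > 0.5).astype(arr.dtype if arr.dtype != bool else np.uint8)
    out = resize(
        arr.astype(np.float64), (target, target), order=1,
        anti_aliasing=False, preserve_range=True,
    )
    return out.astype(np.float32)


# ------------------------------------------------------------------- splitting
def split_dataset(ids: list, ratio: float = 0.8, seed: int = 0) -> SplitResult:
    """Uniformly shuffle ``ids`` under ``seed`` and cut at round(ratio * n)."""
    if len(ids) == 0:
        raise InputError("cannot split an empty id list")
    if not 0 < ratio < 1:
        raise ConfigurationError(f"ratio must be in (0,1), got {ratio}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(ratio * len(ids)))
    shuffled = [ids[i] for i in perm]
    return SplitResult(
        train_ids=shuffled[:n_train],
        val_ids=shuffled[n_train:],
        ratio=ratio,
        seed=seed,
    )


# -------------------------------------------------------------------- overlays
def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Boolean boundary of a binary mask: mask minus its 4-connected erosion."""
    m = np.asarray(mask).astype(bool)
    eroded = ndimage.binary_erosion(m, structure=_CROSS, border_value=0)
    return m & ~eroded


def overlay_contour(
    image: np.ndarray, mask: np.ndarray, color: tuple[float, float, float] = (1.0, 0.0, 0.0)
) -> np.ndarray:
    """Render the mask's contour on a grayscale [0,1] image.

    The image is replicated to three channels and pixels on the mask
    boundary (mask minus its one-pixel 4-connected erosion) are set to
    ``color``; every other pixel is unchanged.
    """
    img = np.asarray(image, dtype=np.float64)
    m = np.asarray(mask)
    if img.shape != m.shape:
        raise InputError(f"image {img.shape} and mask {m.shape} must share a grid")
    rgb = np.stack([img, img, img], axis=-1)
    rgb[boundary_pixels(m)] = np.asarray(color, dtype=np.float64)
    return rgb


# ---------------------------------------------------------------------- DICOM
def dicom_series_to_nifti(
    series_dir: str | Path, out_path: str | Path | None = None
) -> CTVolume:
    """Read a single-series DICOM stack into an HU volume (optionally writing
    NIfTI with spacing/origin preserved in the header).

    Slices are ordered by their position along the slice axis; the rescale
    slope/intercept from each header converts stored values to HU.
    """
    import pydicom

    series_dir = Path(series_dir)
    files = sorted(
        p for p in series_dir.iterdir() if p.is_file() and p.suffix.lower() in (".dcm", "")
    )
    if not files:
        raise FormatError(f"no DICOM files found in {series_dir}")
    slices = []
    series_uid = None
    for path in files:
        ds = pydicom.dcmread(str(path))
        uid = getattr(ds, "SeriesInstanceUID", None)
        if series_uid is None:
            series_uid = uid
        elif uid != series_uid:
            raise FormatError(f"mixed series: {path.name} belongs to a different series")
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is None:
            raise FormatError(f"missing ImagePositionPatient tag in {path.name}")
        slices.append((float(pos[2]), ds, path))
    slices.sort(key=lambda t: t[0])

    arrays = []
    for z, ds, path in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arrays.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    voxels = np.stack(arrays, axis=0)

    first = slices[0][1]
    py, px = (float(v) for v in getattr(first, "PixelSpacing", [1.0, 1.0]))
    if len(slices) > 1:
        dz = slices[1][0] - slices[0][0]
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    origin = tuple(float(v) for v in first.ImagePositionPatient)
    volume = CTVolume(voxels=voxels, spacing=(abs(dz), py, px), origin=origin)

    if out_path is not None:
        import nibabel as nib

        # NIfTI axes (x, y, z) <- volume axes (z, y, x)
        affine = np.diag([px, py, abs(dz), 1.0])
        affine[:3, 3] = origin
        nib.save(nib.Nifti1Image(voxels.transpose(2, 1, 0), affine), str(out_path))
    return volume


# ---------------------------------------------------------------- augmentation
_AUGMENT_OPS = ("hflip", "vflip", "rot90")


def augment(
    image: np.ndarray,
    masks: list[np.ndarray],
    ops: list[str],
    seed: int | None = None,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Apply the same spatial transform to an image and its masks.

    ``ops`` entries are ``hflip``, ``vflip``, ``rot90`` (one quarter-turn)
    or ``rot90:k`` for k quarter-turns.  With ``seed`` given, each listed op
    is applied with probability 1/2 and the rotation count is drawn from
    {0,1,2,3}; without a seed the ops apply deterministically in order.
    """
    img = np.asarray(image)
    ms = [np.asarray(m) for m in masks]
    for m in ms:
        if m.shape != img.shape:
            raise InputError(f"mask shape {m.shape} does not match image {img.shape}")
    rng = np.random.default_rng(seed) if seed is not None else None

    def apply_all(fn):
        nonlocal img, ms
        img = fn(img)
        ms = [fn(m) for m in ms]

    for op in ops:
        name, _, arg = op.partition(":")
        if name not in _AUGMENT_OPS:
            raise ConfigurationError(f"unknown augmentation op {op!r}")
        if name == "hflip":
            if rng is None or rng.random() < 0.5:
                apply_all(lambda a: a[:, ::-1])
        elif name == "vflip":
            if rng is None or rng.random() < 0.5:
                apply_all(lambda a: a[::-1, :])
        else:
            k = int(arg) if arg else (int(rng.integers(0, 4)) if rng is not None else 1)
            if k % 4:
                apply_all(lambda a: np.rot90(a, k))
    return img.copy(), [m.copy() for m in ms]
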