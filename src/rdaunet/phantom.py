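"""Synthetic CT-like liver phantoms with paired ground truth.

Real abdominal CT with expert liver/lesion annotation cannot be shipped, so
this module fabricates the minimal structure the segmentation task needs:
a single-channel HU-valued slice containing an air background, a soft-tissue
body oval, one large connected "liver" region (an ellipse perturbed by a
low-frequency radial deformation so its boundary is not analytic), and 0-5
circular "lesion" blobs strictly inside the liver, each tissue class drawn
from its own HU interval with additive Gaussian noise on top.  Generation is
a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import gzip
import hashlib
import json
from pathlib import Path

import numpy as np

from .errors import ConfigurationError

__all__ = ["PhantomConfig", "PhantomSample", "generate_phantom", "generate_dataset"]


# --------------------------------------------------------------------- config
@dataclasses.dataclass
class PhantomConfig:
    """Geometry and intensity model of the phantom.

    HU intervals follow typical abdominal CT: air background around
    -1000 HU, soft tissue 0-60, liver parenchyma 40-70, and hyperenhanced
    lesions 80-140 (bright after windowing, as contrast-adjusted lesions
    appear).  ``noise_sd`` is the standard deviation of the additive
    Gaussian HU noise.
    """

    image_size: int = 512
    liver_axes_range: tuple[float, float] = (0.18, 0.28)  # fraction of image size
    lesion_count_range: tuple[int, int] = (0, 5)
    lesion_radius_range: tuple[float, float] = (8.0, 28.0)  # px at image_size scale
    hu_background: tuple[float, float] = (-1000.0, -800.0)
    hu_soft_tissue: tuple[float, float] = (0.0, 60.0)
    hu_liver: tuple[float, float] = (40.0, 70.0)
    hu_lesion: tuple[float, float] = (80.0, 140.0)
    noise_sd: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.image_size <= 0:
            raise ConfigurationError(f"image_size must be > 0, got {self.image_size}")
        for name in (
            "liver_axes_range",
            "lesion_count_range",
            "lesion_radius_range",
            "hu_background",
            "hu_soft_tissue",
            "hu_liver",
            "hu_lesion",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name}: min {lo} > max {hi}")
        if self.lesion_count_range[0] < 0:
            raise ConfigurationError("lesion_count_range: counts must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        min_semi_axis = self.liver_axes_range[0] * self.image_size
        if self.lesion_radius_range[1] >= min_semi_axis:
            raise ConfigurationError(
                "lesion_radius_range: max radius "
                f"{self.lesion_radius_range[1]} must be smaller than the liver "
                f"minor semi-axis ({min_semi_axis:.1f} px)"
            )
        if not (
            self.hu_lesion[0] > self.hu_background[1]
            or self.hu_lesion[1] < self.hu_background[0]
        ):
            raise ConfigurationError(
                "hu_lesion: interval overlaps hu_background; classes must be distinguishable"
            )

    @classmethod
    def desk_scale(cls, **overrides) -> "PhantomConfig":
        """A 64x64 profile with proportionally scaled lesion geometry, used
        by the fast CPU demonstration pipeline."""
        base = dict(image_size=64, lesion_radius_range=(1.5, 4.0), lesion_count_range=(0, 3))
        base.update(overrides)
        cfg = cls(**base)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        for key, val in d.items():
            if isinstance(val, list):
                d[key] = tuple(val)
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclasses.dataclass
class PhantomSample:
    """One slice: HU image plus aligned binary liver and lesion masks."""

    image: np.ndarray  # (H, W) float32, HU
    liver_mask: np.ndarray  # (H, W) uint8 in {0,1}
    lesion_mask: np.ndarray  # (H, W) uint8 in {0,1}, subset of liver_mask
    sample_id: str = ""
    seed: int = 0


# ----------------------------------------------------------------- generation
def _radial_region(
    size: int,
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    rng: np.random.Generator,
    wobble: float = 0.0,
) -> np.ndarray:
    """Boolean mask of a (possibly radially perturbed) ellipse.

    The boundary radius is modulated by a low-frequency harmonic series
    r(theta) = 1 + sum_k a_k cos(k theta + phi_k), k in {2,3,4}, with
    |a_k| <= wobble/3 each, keeping the region star-shaped and connected.
    """
    rows, cols = np.mgrid[0:size, 0:size].astype(np.float64)
    dy = rows - center[0]
    dx = cols - center[1]
    rho = np.sqrt((dy / semi_axes[0]) ** 2 + (dx / semi_axes[1]) ** 2)
    if wobble > 0:
        theta = np.arctan2(dy, dx)
        boundary = np.ones_like(rho)
        for k in (2, 3, 4):
            amp = rng.uniform(-wobble / 3, wobble / 3)
            phase = rng.uniform(0, 2 * np.pi)
            boundary += amp * np.cos(k * theta + phase)
    else:
        boundary = 1.0
    return rho <= boundary


def generate_phantom(config: PhantomConfig, seed: int | None = None) -> PhantomSample:
    """Generate one phantom slice; bit-identical for identical (config, seed)."""
    config.validate()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    size = config.image_size
    center = size / 2.0

    # body oval (soft tissue) on an air background
    body = _radial_region(
        size,
        (center, center),
        (0.42 * size, 0.46 * size),
        rng,
        wobble=0.03,
    )

    # liver: perturbed ellipse, offset toward the upper-left of the body
    a = rng.uniform(*config.liver_axes_range) * size
    b = rng.uniform(*config.liver_axes_range) * size
    liver_center = (
        center + rng.uniform(-0.06, 0.0) * size,
        center + rng.uniform(-0.12, -0.04) * size,
    )
    liver = _radial_region(size, liver_center, (a, b), rng, wobble=0.12)
    liver &= body  # anatomy: the organ lies inside the body

    # lesions: disks strictly inside the liver, pairwise disjoint
    from scipy import ndimage

    n_lesions = int(rng.integers(config.lesion_count_range[0], config.lesion_count_range[1] + 1))
    lesion = np.zeros((size, size), dtype=bool)
    interior_dist = ndimage.distance_transform_edt(liver)
    rows, cols = np.mgrid[0:size, 0:size]
    placed: list[tuple[float, float, float]] = []
    for _ in range(n_lesions):
        radius = rng.uniform(*config.lesion_radius_range)
        for _attempt in range(60):
            ok = interior_dist > radius + 1.0
            for (pr, pc, prad) in placed:
                ok &= np.hypot(rows - pr, cols - pc) > radius + prad + 2.0
            candidates = np.flatnonzero(ok.ravel())
            if candidates.size:
                pick = candidates[rng.integers(candidates.size)]
                cr, cc = divmod(int(pick), size)
                lesion |= np.hypot(rows - cr, cols - cc) <= radius
                placed.append((cr, cc, radius))
                break
            radius = max(config.lesion_radius_range[0], radius * 0.8)
        else:
            raise RuntimeError(
                f"could not place lesion {len(placed) + 1}/{n_lesions}; "
                "liver too small for the configured lesion geometry"
            )

    image = np.empty((size, size), dtype=np.float64)
    image[:] = rng.uniform(*config.hu_background)
    image[body] = rng.uniform(*config.hu_soft_tissue)
    image[liver] = rng.uniform(*config.hu_liver)
    image[lesion] = rng.uniform(*config.hu_lesion)
    if config.noise_sd > 0:
        image += rng.normal(0.0, config.noise_sd, size=image.shape)

    return PhantomSample(
        image=image.astype(np.float32),
        liver_mask=liver.astype(np.uint8),
        lesion_mask=lesion.astype(np.uint8),
        sample_id=f"phantom_{seed:08d}",
        seed=seed,
    )


# -------------------------------------------------------------------- dataset
def _write_nifti_deterministic(path: Path, data: np.ndarray, spacing: float = 1.0) -> None:
    """Write a NIfTI file whose bytes depend only on the array contents.

    Gzip normally embeds a timestamp; writing through ``gzip.GzipFile`` with
    ``mtime=0`` keeps re-runs byte-identical.
    """
    import nibabel as nib

    affine = np.diag([spacing, spacing, 1.0, 1.0])
    img = nib.Nifti1Image(data[..., None], affine)
    raw = img.to_bytes()
    if path.suffix == ".gz":
        with open(path, "wb") as fh:
            with gzip.GzipFile(fileobj=fh, mode="wb", mtime=0) as gz:
                gz.write(raw)
    else:
        path.write_bytes(raw)


def generate_dataset(
    config: PhantomConfig, n: int, seed: int, out_dir: str | Path
) -> dict:
    """Write ``n`` phantoms as NIfTI triples plus a JSON manifest.

    Per-sample seeds are spawned deterministically from ``seed``; re-running
    with identical arguments reproduces identical files.  Returns the
    manifest dictionary (also written to ``out_dir/manifest.json``).
    """
    config.validate()
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise IOError(f"output directory {out_dir} is not writable: {exc}") from exc

    sample_seeds = (
        np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64) % (2**31)
    ).astype(int)
    samples = []
    for i, s_seed in enumerate(sample_seeds):
        sample = generate_phantom(config, int(s_seed))
        sid = f"sample_{i:04d}"
        paths = {
            "image_path": f"{sid}_image.nii.gz",
            "liver_mask_path": f"{sid}_liver.nii.gz",
            "lesion_mask_path": f"{sid}_lesion.nii.gz",
        }
        _write_nifti_deterministic(out_dir / paths["image_path"], sample.image)
        _write_nifti_deterministic(out_dir / paths["liver_mask_path"], sample.liver_mask)
        _write_nifti_deterministic(out_dir / paths["lesion_mask_path"], sample.lesion_mask)
        samples.append({"sample_id": sid, **paths, "seed": int(s_seed)})

    manifest = {
        "config": config.to_dict(),
        "n": n,
        "seed": seed,
        "samples": samples,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def manifest_checksum(out_dir: str | Path) -> str:
    """SHA-256 over the manifest and every file it lists (re-run comparison)."""
    out_dir = Path(out_dir)
    h = hashlib.sha256()
    h.update((out_dir / "manifest.json").read_bytes())
    manifest = json.loads((out_dir / "manifest.json").read_text())
    for sample in manifest["samples"]:
        for key in ("image_path", "liver_mask_path", "lesion_mask_path"):
            h.update((out_dir / sample[key]).read_bytes())
    return h.hexdigest()
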