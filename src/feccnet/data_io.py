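"""Volume/slice I/O, splitting, augmentation, and noise corruption.

The real-data path reads T1 MRI volumes in NIfTI-1 format, min-max rescales
each volume to the [0, 255] intensity scale, cuts it into axial 2D slices
(the third array axis), and pairs each slice with its binary lesion mask.
Slices are resized to the network input size (bilinear for images,
nearest-neighbour + re-binarisation for masks) and split 8:1:1 into
train/val/test. The split unit defaults to the patient/case so no subject
leaks across partitions.

Augmentation (applied online, image and mask geometrically locked):
rotation within ±15°, smooth elastic deformation, additive Gaussian noise.
Noise-robustness experiments corrupt slices with i.i.d. N(0, sigma²) noise
on the [0, 255] scale, clipped back to [0, 255].
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .errors import ConfigurationError, DataFormatError, InputError
from .metrics import stratify_by_lesion_size


@dataclass
class Volume:
    """A 3D scalar volume with voxel spacing (mm) and affine orientation."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray


@dataclass
class SliceRecord:
    """One 2D grayscale slice on the [0, 255] scale with its binary mask."""

    image: np.ndarray
    mask: np.ndarray
    case_id: str
    slice_index: int
    stratum: str

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise InputError("image and mask must share a shape")


@dataclass
class SplitConfig:
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    unit: str = "case"

    def __post_init__(self) -> None:
        if min(self.ratios) <= 0:
            raise ConfigurationError("split ratios must be positive")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ConfigurationError("split ratios must sum to 1")
        if self.unit not in ("case", "slice"):
            raise ConfigurationError("split unit must be 'case' or 'slice'")


@dataclass
class AugmentConfig:
    rotation_deg: float = 15.0
    elastic_alpha: float = 15.0
    elastic_sigma: float = 3.0
    noise_sd: float = 10.0
    p_each: float = 0.5


def load_volume(path) -> Volume:
    """Read a NIfTI-1 volume (.nii or .nii.gz); no resampling."""
    import nibabel as nib

    path = Path(path)
    try:
        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:
        raise DataFormatError(f"cannot read NIfTI volume at {path}: {exc}") from exc
    if not np.all(np.isfinite(data)):
        raise DataFormatError(f"non-finite voxels in {path}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data=data, spacing=zooms, affine=np.asarray(img.affine))


def rescale_volume(data: np.ndarray) -> np.ndarray:
    """Min-max rescale a whole volume to [0, 255] (flat volumes map to 0)."""
    lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        return np.zeros_like(data, dtype=np.float64)
    return (data - lo) * (255.0 / (hi - lo))


def extract_axial_slices(vol: Volume, mask_vol: Volume, case_id: str = "case") -> list[SliceRecord]:
    """One record per index along the axial (third) axis; values conserved."""
    if vol.data.shape != mask_vol.data.shape:
        raise InputError(
            f"volume {vol.data.shape} and mask {mask_vol.data.shape} shapes differ"
        )
    img = rescale_volume(vol.data)
    msk = (mask_vol.data > 0.5).astype(np.uint8)
    records = []
    for k in range(img.shape[2]):
        m = msk[:, :, k]
        records.append(
            SliceRecord(
                image=np.ascontiguousarray(img[:, :, k]),
                mask=np.ascontiguousarray(m),
                case_id=case_id,
                slice_index=k,
                stratum=stratify_by_lesion_size(m),
            )
        )
    return records


def resize_record(rec: SliceRecord, size: int) -> SliceRecord:
    """Resize to size x size: bilinear image, nearest-neighbour mask."""
    if size < 1:
        raise ConfigurationError("size must be >= 1")
    if rec.image.shape == (size, size):
        return rec
    image = _sk_resize(rec.image, (size, size), order=1, preserve_range=True,
                       anti_aliasing=rec.image.shape[0] > size)
    mask = _sk_resize(rec.mask.astype(float), (size, size), order=0,
                      preserve_range=True, anti_aliasing=False)
    mask = (mask > 0.5).astype(np.uint8)
    return SliceRecord(image=image, mask=mask, case_id=rec.case_id,
                       slice_index=rec.slice_index,
                       stratum=stratify_by_lesion_size(mask))


def split_dataset(records, cfg: SplitConfig = SplitConfig()):
    """Deterministic, disjoint, exhaustive train/val/test split."""
    records = list(records)
    if not records:
        raise InputError("no records to split")
    if cfg.unit == "case":
        units = sorted({r.case_id for r in records})
    else:
        units = list(range(len(records)))
    rng = np.random.default_rng(cfg.seed)
    order = list(rng.permutation(len(units)))
    # largest-remainder allocation of unit counts to the three partitions
    n = len(units)
    exact = [r * n for r in cfg.ratios]
    counts = [int(e) for e in exact]
    while sum(counts) < n:
        rema = [e - c for e, c in zip(exact, counts)]
        counts[int(np.argmax(rema))] += 1
    picks = []
    start = 0
    for c in counts:
        chosen = {units[order[i]] for i in range(start, start + c)}
        picks.append(chosen)
        start += c
    if cfg.unit == "case":
        parts = [[r for r in records if r.case_id in p] for p in picks]
    else:
        parts = [[records[i] for i in sorted(p)] for p in picks]
    return tuple(parts)


def add_gaussian_noise(image: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Add i.i.d. N(0, sigma²) noise on the [0, 255] scale, clipped."""
    if sigma < 0:
        raise ConfigurationError("sigma must be >= 0")
    image = np.asarray(image, dtype=np.float64)
    if sigma == 0:
        return image.copy()
    noisy = image + rng.normal(0.0, sigma, size=image.shape)
    return np.clip(noisy, 0.0, 255.0)


def rotate_pair(image, mask, angle_deg: float):
    """Rotate image (bilinear) and mask (bilinear + 0.5 threshold) together."""
    if angle_deg == 0.0:
        return np.asarray(image, float).copy(), np.asarray(mask, np.uint8).copy()
    img = ndimage.rotate(np.asarray(image, float), angle_deg, reshape=False,
                         order=1, mode="nearest")
    msk = ndimage.rotate(np.asarray(mask, float), angle_deg, reshape=False,
                         order=1, mode="nearest")
    return img, (msk > 0.5).astype(np.uint8)


def elastic_pair(image, mask, rng, alpha: float = 15.0, sigma: float = 3.0):
    """Apply one smooth random displacement field to image and mask alike."""
    shape = np.asarray(image).shape
    dx = ndimage.gaussian_filter(rng.standard_normal(shape), sigma) * alpha
    dy = ndimage.gaussian_filter(rng.standard_normal(shape), sigma) * alpha
    ii, jj = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    coords = [ii + dx, jj + dy]
    img = ndimage.map_coordinates(np.asarray(image, float), coords, order=1, mode="reflect")
    msk = ndimage.map_coordinates(np.asarray(mask, float), coords, order=1, mode="reflect")
    return img, (msk > 0.5).astype(np.uint8)


def augment(rec: SliceRecord, rng: np.random.Generator,
            cfg: AugmentConfig = AugmentConfig()) -> SliceRecord:
    """Randomly compose rotation, elastic deformation, and noise addition."""
    img, msk = np.asarray(rec.image, float), np.asarray(rec.mask, np.uint8)
    if rng.random() < cfg.p_each:
        img, msk = rotate_pair(img, msk, float(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)))
    if rng.random() < cfg.p_each:
        img, msk = elastic_pair(img, msk, rng, cfg.elastic_alpha, cfg.elastic_sigma)
    if rng.random() < cfg.p_each:
        img = add_gaussian_noise(img, cfg.noise_sd, rng)
    return SliceRecord(image=img, mask=msk, case_id=rec.case_id,
                       slice_index=rec.slice_index,
                       stratum=stratify_by_lesion_size(msk))


# ---- on-disk layout: PNG pairs + CSV manifest -------------------------

def write_slices(records, out_dir, split_labels=None) -> pd.DataFrame:
    """Write image/mask PNG pairs and a manifest CSV; returns the manifest."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(records):
        stem = f"{rec.case_id}_{rec.slice_index:04d}"
        iio.imwrite(out_dir / "images" / f"{stem}.png",
                    np.clip(np.round(rec.image), 0, 255).astype(np.uint8))
        iio.imwrite(out_dir / "masks" / f"{stem}.png",
                    (rec.mask.astype(np.uint8) * 255))
        row = {"case_id": rec.case_id, "slice_index": rec.slice_index,
               "stratum": rec.stratum}
        if split_labels is not None:
            row["split"] = split_labels[i]
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def read_slices(in_dir) -> list[SliceRecord]:
    """Read back the PNG + manifest layout written by :func:`write_slices`."""
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    records = []
    for _, row in manifest.iterrows():
        stem = f"{row.case_id}_{int(row.slice_index):04d}"
        image = np.asarray(iio.imread(in_dir / "images" / f"{stem}.png"), float)
        mask = (np.asarray(iio.imread(in_dir / "masks" / f"{stem}.png")) > 127).astype(np.uint8)
        records.append(SliceRecord(image=image, mask=mask, case_id=str(row.case_id),
                                   slice_index=int(row.slice_index),
                                   stratum=stratify_by_lesion_size(mask)))
    return records


def manifest_checksum(path) -> str:
    """MD5 of a manifest file's bytes (reproducibility probe)."""
    return hashlib.md5(Path(path).read_bytes()).hexdigest()
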