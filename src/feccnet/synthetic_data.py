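"""Seeded generator of pseudo-brain slices with ground-truth lesions.

Each slice is an elliptical bright "brain" on a dark background with smooth
intensity texture; lesions are irregular hypo-intense blobs grown by
randomised frontier accretion (Eden growth) inside the brain, mimicking the
darker appearance of chronic-stroke infarcts on T1 MRI. The total lesion
pixel count is sampled inside the requested stratum's interval and hit
exactly, so requested and recomputed stratum labels always agree.

Every lesion pixel is strictly darker than the underlying brain texture by
at least half of ``lesion_intensity_drop`` — a learnable-contrast
guarantee. The generator emulates lesion-size strata, class imbalance and
texture; it does not attempt anatomy or MRI physics (no bias fields, no
partial-volume effects).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data_io import SliceRecord, write_slices
from .errors import ConfigurationError
from .metrics import LARGE, LESION_FREE, MEDIUM, SMALL, MEDIUM_MAX, SMALL_MAX

_ORDER = (LESION_FREE, SMALL, MEDIUM, LARGE)


@dataclass
class SynthConfig:
    """Study conditions of the synthetic cohort.

    ``stratum_mix`` orders proportions as (lesion_free, small, medium,
    large). Intensities are on the [0, 255] scale: brain ~175, background
    ~35, lesions darker than local brain by (drop/2, drop].
    """

    image_size: int = 512
    n_slices: int = 100
    stratum_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    lesion_intensity_drop: float = 60.0
    texture_noise_sd: float = 8.0
    n_lesions_range: tuple[int, int] = (1, 3)
    brain_intensity: float = 175.0
    background_intensity: float = 35.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 16:
            raise ConfigurationError("image_size must be >= 16")
        if abs(sum(self.stratum_mix) - 1.0) > 1e-9:
            raise ConfigurationError("stratum_mix must sum to 1")
        if min(self.stratum_mix) < 0:
            raise ConfigurationError("stratum_mix entries must be non-negative")
        if self.n_lesions_range[0] < 1 or self.n_lesions_range[1] < self.n_lesions_range[0]:
            raise ConfigurationError("invalid n_lesions_range")


def _brain_mask(size: int, rng: np.random.Generator) -> np.ndarray:
    """Random rotated ellipse covering roughly half the frame."""
    cy = size / 2 + rng.uniform(-0.03, 0.03) * size
    cx = size / 2 + rng.uniform(-0.03, 0.03) * size
    a = rng.uniform(0.38, 0.45) * size
    b = rng.uniform(0.34, 0.42) * size
    theta = rng.uniform(0, np.pi)
    ii, jj = np.mgrid[0:size, 0:size]
    u = (ii - cy) * np.cos(theta) + (jj - cx) * np.sin(theta)
    v = -(ii - cy) * np.sin(theta) + (jj - cx) * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _grow_blob(allowed: np.ndarray, target: int, rng: np.random.Generator) -> np.ndarray | None:
    """Grow an irregular connected blob of exactly ``target`` pixels."""
    coords = np.argwhere(allowed)
    if len(coords) < target:
        return None
    blob = np.zeros_like(allowed)
    seed = tuple(coords[rng.integers(len(coords))])
    blob[seed] = True
    frontier = set()

    def add_neighbours(i, j):
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if 0 <= ni < allowed.shape[0] and 0 <= nj < allowed.shape[1]:
                if allowed[ni, nj] and not blob[ni, nj]:
                    frontier.add((ni, nj))

    add_neighbours(*seed)
    count = 1
    while count < target:
        if not frontier:
            return None  # boxed in before reaching the budget
        pick = list(frontier)[rng.integers(len(frontier))]
        frontier.discard(pick)
        blob[pick] = True
        count += 1
        add_neighbours(*pick)
    return blob


def _sample_target(stratum: str, capacity: int, rng: np.random.Generator) -> int:
    """Sample a total lesion pixel budget within the stratum's interval."""
    if stratum == LESION_FREE:
        return 0
    if stratum == SMALL:
        hi = min(SMALL_MAX, capacity + 1)
        if hi <= 1:
            raise ConfigurationError("small-lesion budget infeasible at this image size")
        return int(rng.integers(1, hi))
    if stratum == MEDIUM:
        if capacity < SMALL_MAX:
            raise ConfigurationError("medium-lesion budget infeasible at this image size")
        return int(rng.integers(SMALL_MAX, min(MEDIUM_MAX, capacity + 1)))
    if stratum == LARGE:
        if capacity < MEDIUM_MAX:
            raise ConfigurationError(
                f"large-lesion budget infeasible: only {capacity} interior brain "
                "pixels available at this image size"
            )
        hi = min(int(1.5 * MEDIUM_MAX), capacity)
        return int(rng.integers(MEDIUM_MAX, hi + 1))
    raise ConfigurationError(f"unknown stratum '{stratum}'")


def generate_slice(cfg: SynthConfig, stratum: str, rng: np.random.Generator,
                   case_id: str = "synth", slice_index: int = 0,
                   return_background: bool = False):
    """Generate one slice whose mask pixel count lies in the stratum interval.

    With ``return_background=True`` also returns the pre-lesion image, so the
    per-pixel contrast guarantee (lesion darker than the local brain texture
    by at least drop/2) can be verified exactly.
    """
    size = cfg.image_size
    brain = _brain_mask(size, rng)
    tex = ndimage.gaussian_filter(rng.standard_normal((size, size)), size / 24.0)
    sd = tex.std()
    tex = tex * (cfg.texture_noise_sd / sd) if sd > 0 else tex
    image = np.full((size, size), cfg.background_intensity, dtype=np.float64)
    image += rng.normal(0.0, 2.0, size=(size, size))
    image[brain] = cfg.brain_intensity + tex[brain]

    interior = ndimage.binary_erosion(brain, iterations=2)
    capacity = int(0.75 * np.count_nonzero(interior))
    target = _sample_target(stratum, capacity, rng)

    background = image.copy()
    mask = np.zeros((size, size), dtype=np.uint8)
    if target > 0:
        k_max = min(cfg.n_lesions_range[1], max(1, target // 20))
        k_min = min(cfg.n_lesions_range[0], k_max)
        k = int(rng.integers(k_min, k_max + 1))
        # split the budget into k parts of at least 1 pixel
        cuts = np.sort(rng.choice(np.arange(1, target), size=k - 1, replace=False)) if k > 1 else []
        parts = np.diff([0, *cuts, target]).astype(int)
        lesion = np.zeros((size, size), dtype=bool)
        for part in parts:
            blob = None
            for _ in range(8):  # retry with fresh seeds if growth gets boxed in
                blob = _grow_blob(interior & ~lesion, int(part), rng)
                if blob is not None:
                    break
            if blob is None:
                raise ConfigurationError(
                    "lesion growth infeasible: brain interior too small for the "
                    f"requested {stratum} budget at image_size={size}"
                )
            lesion |= blob
        drop = cfg.lesion_intensity_drop
        u = rng.uniform(0.0, 0.5, size=int(lesion.sum()))
        image[lesion] -= drop * (1.0 - u)  # darker by (drop/2, drop]
        mask[lesion] = 1

    image = np.clip(image, 0.0, 255.0)
    record = SliceRecord(image=image, mask=mask, case_id=case_id,
                         slice_index=slice_index, stratum=stratum)
    if return_background:
        return record, np.clip(background, 0.0, 255.0)
    return record


def allocate_counts(n_slices: int, mix) -> list[int]:
    """Largest-remainder allocation of slices to strata (within ±1 of exact)."""
    exact = [m * n_slices for m in mix]
    counts = [int(e) for e in exact]
    while sum(counts) < n_slices:
        rema = [e - c for e, c in zip(exact, counts)]
        counts[int(np.argmax(rema))] += 1
    return counts


def generate_dataset(cfg: SynthConfig, out_dir=None, write_nifti: bool = False):
    """Generate ``cfg.n_slices`` records; optionally write the PNG/CSV layout.

    Returns ``(records, manifest)``. With ``out_dir`` set, writes the same
    per-slice PNG + manifest.csv layout `data_io` emits, plus (optionally) a
    NIfTI stack of the images and masks for exercising the volume reader.
    """
    rng = np.random.default_rng(cfg.seed)
    counts = allocate_counts(cfg.n_slices, cfg.stratum_mix)
    labels = [s for s, c in zip(_ORDER, counts) for _ in range(c)]
    labels = [labels[i] for i in rng.permutation(len(labels))]
    records = [
        generate_slice(cfg, stratum, rng, case_id=f"synth{i:04d}", slice_index=i)
        for i, stratum in enumerate(labels)
    ]
    if out_dir is not None:
        manifest = write_slices(records, out_dir)
        if write_nifti:
            import nibabel as nib

            img_stack = np.stack([r.image for r in records], axis=2)
            msk_stack = np.stack([r.mask for r in records], axis=2).astype(np.uint8)
            nib.save(nib.Nifti1Image(img_stack, np.eye(4)),
                     str(Path(out_dir) / "stack_images.nii.gz"))
            nib.save(nib.Nifti1Image(msk_stack, np.eye(4)),
                     str(Path(out_dir) / "stack_masks.nii.gz"))
    else:
        import pandas as pd

        manifest = pd.DataFrame(
            {"case_id": [r.case_id for r in records],
             "slice_index": [r.slice_index for r in records],
             "stratum": [r.stratum for r in records]}
        )
    return records, manifest
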