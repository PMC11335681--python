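"""Synthetic CT-like phantom slices for desk-scale testing.

Generates 2D grayscale slices that reproduce the difficulties of pancreatic
tumor CT: a tumor occupying a very small fraction of the image, at low
contrast to the pancreas that contains it, with indistinct (noise-blurred)
boundaries, on a textured background that invites false positives.  Every
slice carries exact pancreas and tumor masks, so all downstream modules are
testable without any external dataset.

Intensity model (configured means, [0, 1] scale):
  background 0.35, pancreas 0.50, tumor 0.50 + ``tumor_contrast_delta``.
A low-pass-filtered noise field textures the whole image and i.i.d. Gaussian
noise of scale ``noise_sigma`` is added before clamping; the masks are the
exact pre-noise ellipse supports (a pixel belongs to an ellipse iff its
center satisfies the ellipse inequality).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

BACKGROUND_MEAN = 0.35
PANCREAS_MEAN = 0.50


@dataclass
class PhantomConfig:
    image_size: int = 64
    pancreas_area_frac_range: tuple[float, float] = (0.02, 0.08)
    tumor_area_frac_range: tuple[float, float] = (0.002, 0.02)
    tumor_contrast_delta: float = 0.05
    noise_sigma: float = 0.03
    texture_sigma: float = 0.02
    texture_scale: float = 4.0
    slices_per_case: int = 10
    tumor_slice_range: tuple[int, int] = (4, 8)
    seed: int = 0

    def __post_init__(self):
        if max(self.tumor_area_frac_range) > min(self.pancreas_area_frac_range):
            raise ValueError(
                "tumor_area_frac_range max must be below pancreas_area_frac_range min "
                f"(got {self.tumor_area_frac_range} vs {self.pancreas_area_frac_range})"
            )
        if PANCREAS_MEAN + self.tumor_contrast_delta > 1.0 or self.tumor_contrast_delta < 0:
            raise ValueError("tumor_contrast_delta must keep intensities in [0, 1]")
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")


@dataclass
class SliceSample:
    image: np.ndarray
    pancreas_mask: np.ndarray
    tumor_mask: np.ndarray
    case_id: str
    slice_index: int = 0

    def __post_init__(self):
        if self.pancreas_mask.shape != self.image.shape or self.tumor_mask.shape != self.image.shape:
            raise ValueError("masks must match image shape")


def _ellipse_mask(size: int, cy, cx, a, b, theta) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    y = yy - cy
    x = xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = x * ct + y * st
    v = -x * st + y * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _sample_ellipse(rng, size, frac_range, center_bounds, max_tries=100):
    lo, hi = frac_range
    for _ in range(max_tries):
        frac = rng.uniform(lo, hi)
        q = rng.uniform(0.5, 1.0)
        area = frac * size * size
        a = np.sqrt(area / (np.pi * q))
        b = q * a
        theta = rng.uniform(0, np.pi)
        cy = rng.uniform(*center_bounds)
        cx = rng.uniform(*center_bounds)
        mask = _ellipse_mask(size, cy, cx, a, b, theta)
        count = mask.sum()
        # accept only if rasterized area respects the configured bounds
        # (with the +-20% rasterization tolerance on the bound itself)
        if 0.8 * lo * size * size <= count <= 1.2 * hi * size * size:
            return mask, (cy, cx, a, b, theta)
    raise RuntimeError("could not place ellipse within area bounds")


def generate_slice(
    config: PhantomConfig,
    rng: np.random.Generator,
    case_id: str = "case",
    slice_index: int = 0,
    with_tumor: bool = True,
) -> SliceSample:
    """Generate one phantom slice from ``rng``'s current state.

    The tumor ellipse is resampled (bounded retries) until fully nested in
    the pancreas ellipse; raises ``RuntimeError`` when the retry budget is
    exhausted.
    """
    size = config.image_size
    panc, (cy, cx, a, b, theta) = _sample_ellipse(
        rng, size, config.pancreas_area_frac_range, (0.25 * size, 0.75 * size)
    )
    tumor = np.zeros_like(panc)
    if with_tumor:
        lo_t, hi_t = config.tumor_area_frac_range
        for attempt in range(200):
            jy = rng.normal(0, 0.25 * b)
            jx = rng.normal(0, 0.25 * a)
            frac = rng.uniform(lo_t, hi_t)
            q = rng.uniform(0.5, 1.0)
            area = frac * size * size
            ta = np.sqrt(area / (np.pi * q))
            tb = q * ta
            tth = rng.uniform(0, np.pi)
            cand = _ellipse_mask(size, cy + jy, cx + jx, ta, tb, tth)
            count = cand.sum()
            ok_area = 0.8 * lo_t * size * size <= count <= 1.2 * hi_t * size * size
            if ok_area and count > 0 and not np.any(cand & ~panc):
                tumor = cand
                break
        else:
            raise RuntimeError("could not nest tumor ellipse inside pancreas ellipse")

    texture = gaussian_filter(rng.normal(0.0, 1.0, (size, size)), config.texture_scale)
    std = texture.std()
    if std > 0:
        texture *= config.texture_sigma / std
    image = np.full((size, size), BACKGROUND_MEAN) + texture
    image[panc] = PANCREAS_MEAN + texture[panc]
    image[tumor] = PANCREAS_MEAN + config.tumor_contrast_delta + texture[tumor]
    image = image + rng.normal(0.0, config.noise_sigma, (size, size))
    image = np.clip(image, 0.0, 1.0)
    return SliceSample(
        image=image,
        pancreas_mask=panc.astype(np.uint8),
        tumor_mask=tumor.astype(np.uint8),
        case_id=case_id,
        slice_index=slice_index,
    )


def generate_case(config: PhantomConfig, seed: int) -> list[SliceSample]:
    """A coherent stack: pancreas on every slice, tumor on a contiguous
    subrange whose length is drawn from ``tumor_slice_range``."""
    if config.slices_per_case < 1:
        raise ValueError("slices_per_case must be >= 1")
    t_lo, t_hi = config.tumor_slice_range
    if t_hi > config.slices_per_case:
        raise ValueError(
            f"tumor_slice_range {config.tumor_slice_range} exceeds "
            f"slices_per_case={config.slices_per_case}"
        )
    rng = np.random.default_rng(seed)
    case_id = f"case_{seed:08d}"
    n_tumor = int(rng.integers(t_lo, t_hi + 1))
    start = int(rng.integers(0, config.slices_per_case - n_tumor + 1))
    out = []
    for i in range(config.slices_per_case):
        with_tumor = start <= i < start + n_tumor
        out.append(generate_slice(config, rng, case_id=case_id, slice_index=i, with_tumor=with_tumor))
    return out


def generate_dataset(config: PhantomConfig, n_cases: int, out_dir) -> "DatasetManifest":
    """Write ``n_cases`` phantom cases as PNG pairs plus a JSON manifest."""
    from .data_io import DatasetManifest, ManifestEntry, write_mask_png, write_slice_png

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for c in range(n_cases):
        case_seed = config.seed * 100003 + c
        for s in generate_case(config, case_seed):
            stem = f"{s.case_id}_slice{s.slice_index:03d}"
            img = out_dir / f"{stem}_image.png"
            pm = out_dir / f"{stem}_pancreas.png"
            tm = out_dir / f"{stem}_tumor.png"
            write_slice_png(img, s.image)
            write_mask_png(pm, s.pancreas_mask)
            write_mask_png(tm, s.tumor_mask)
            entries.append(
                ManifestEntry(
                    case_id=s.case_id,
                    image_path=str(img),
                    pancreas_mask_path=str(pm),
                    tumor_mask_path=str(tm),
                    slice_index=s.slice_index,
                    has_tumor=bool(s.tumor_mask.any()),
                )
            )
    manifest = DatasetManifest(entries=entries)
    manifest.save(out_dir / "manifest.json")
    return manifest


def slices_to_volume(slices: list[SliceSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack a case into (volume, label) arrays with slices on the last axis.

    Labels follow the organ convention used for real data: 1 = pancreas,
    2 = tumor (tumor pixels override pancreas).
    """
    vol = np.stack([s.image for s in slices], axis=-1)
    lab = np.zeros_like(vol, dtype=np.uint8)
    for k, s in enumerate(slices):
        lab[..., k][s.pancreas_mask > 0] = 1
        lab[..., k][s.tumor_mask > 0] = 2
    return vol, lab
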