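"""Readers/writers for NIfTI volumes and PNG slice/mask pairs.

Conventions used package-wide:
  * axial slices are indexed along the last NIfTI axis, 0-based;
  * images are 8-bit grayscale PNG (float [0,1] <-> uint8 [0,255]);
  * masks are 0/255 PNG and binarized at threshold 127 on read;
  * label volumes use the organ convention 1 = pancreas, 2 = tumor, with
    the pancreas *organ* mask taken as label in {1, 2} (the tumor sits
    inside the organ) and the tumor mask as label == 2;
  * dataset splits are by case: no case ever straddles train and test.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

from .phantom import SliceSample

logger = logging.getLogger(__name__)


@dataclass
class ManifestEntry:
    case_id: str
    image_path: str
    pancreas_mask_path: str | None
    tumor_mask_path: str | None
    slice_index: int
    has_tumor: bool = False


@dataclass
class DatasetManifest:
    entries: list[ManifestEntry] = field(default_factory=list)
    split: dict[str, str] = field(default_factory=dict)  # case_id -> train|test

    def case_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.case_id, None)
        return list(seen)

    def subset(self, tag: str) -> list[ManifestEntry]:
        return [e for e in self.entries if self.split.get(e.case_id) == tag]

    def save(self, path) -> None:
        payload = {"entries": [asdict(e) for e in self.entries], "split": self.split}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        raw = json.loads(Path(path).read_text())
        return cls(
            entries=[ManifestEntry(**e) for e in raw["entries"]],
            split=dict(raw.get("split", {})),
        )


def write_slice_png(path, image: np.ndarray) -> None:
    arr = np.clip(np.round(np.asarray(image, dtype=float) * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def write_mask_png(path, mask: np.ndarray) -> None:
    arr = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Image.fromarray(arr, mode="L").save(path)


def _read_png(path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("L"))
    except OSError as exc:
        raise OSError(f"unreadable image file: {path}") from exc


def read_slice(image_path, pancreas_mask_path=None, tumor_mask_path=None,
               case_id: str = "", slice_index: int = 0) -> SliceSample:
    """Load a PNG slice with optional masks.

    Missing mask paths yield all-zero masks (with a logged warning); masks
    are binarized at 127 on the 0-255 scale.
    """
    img = _read_png(image_path).astype(float) / 255.0

    def load_mask(p, name):
        if p is None:
            logger.warning("no %s mask for %s; using all-zero mask", name, image_path)
            return np.zeros(img.shape, dtype=np.uint8)
        m = _read_png(p)
        if m.shape != img.shape:
            raise ValueError(
                f"mask {p} has shape {m.shape}, expected {img.shape} to match {image_path}"
            )
        return (m > 127).astype(np.uint8)

    return SliceSample(
        image=img,
        pancreas_mask=load_mask(pancreas_mask_path, "pancreas"),
        tumor_mask=load_mask(tumor_mask_path, "tumor"),
        case_id=case_id or Path(image_path).stem,
        slice_index=slice_index,
    )


def read_manifest_entry(entry: ManifestEntry) -> SliceSample:
    return read_slice(
        entry.image_path,
        entry.pancreas_mask_path,
        entry.tumor_mask_path,
        case_id=entry.case_id,
        slice_index=entry.slice_index,
    )


def _window(volume: np.ndarray, center: float | None, width: float | None) -> np.ndarray:
    """Linear intensity window to [0, 1]; default is min-max per volume."""
    if center is None or width is None:
        lo, hi = float(volume.min()), float(volume.max())
        if hi <= lo:
            return np.zeros_like(volume, dtype=float)
        return (volume - lo) / (hi - lo)
    lo = center - width / 2.0
    return np.clip((volume - lo) / width, 0.0, 1.0)


def nifti_to_slices(
    volume_path,
    label_path,
    out_dir,
    keep_rule: str = "labeled_only",
    case_id: str | None = None,
    window_center: float | None = None,
    window_width: float | None = None,
) -> list[ManifestEntry]:
    """Convert a NIfTI volume + label pair into per-slice PNG files.

    keep_rule="labeled_only" keeps only slices with a nonzero tumor label
    (label == 2); keep_rule="all" keeps every axial slice.
    """
    if keep_rule not in ("all", "labeled_only"):
        raise ValueError(f"unknown keep_rule: {keep_rule!r} (expected 'all' or 'labeled_only')")
    vol = np.asanyarray(nib.load(str(volume_path)).dataobj).astype(float)
    lab = np.asanyarray(nib.load(str(label_path)).dataobj)
    if vol.shape != lab.shape:
        raise ValueError(
            f"volume shape {vol.shape} != label shape {lab.shape} "
            f"({volume_path} vs {label_path})"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    case_id = case_id or Path(str(volume_path)).name.split(".")[0]
    vol01 = _window(vol, window_center, window_width)

    records: list[ManifestEntry] = []
    for k in range(vol.shape[-1]):
        lab_k = lab[..., k]
        tumor = lab_k == 2
        if keep_rule == "labeled_only" and not tumor.any():
            continue
        pancreas = (lab_k == 1) | tumor
        stem = f"{case_id}_slice{k:03d}"
        img_p = out_dir / f"{stem}_image.png"
        pan_p = out_dir / f"{stem}_pancreas.png"
        tum_p = out_dir / f"{stem}_tumor.png"
        try:
            write_slice_png(img_p, vol01[..., k])
            write_mask_png(pan_p, pancreas)
            write_mask_png(tum_p, tumor)
        except OSError as exc:
            raise OSError(f"failed writing slice PNGs under {out_dir}: {exc}") from exc
        records.append(
            ManifestEntry(
                case_id=case_id,
                image_path=str(img_p),
                pancreas_mask_path=str(pan_p),
                tumor_mask_path=str(tum_p),
                slice_index=k,
                has_tumor=bool(tumor.any()),
            )
        )
    return records


def split_cases(manifest: DatasetManifest, train_fraction: float, seed: int) -> DatasetManifest:
    """Deterministic case-level split: shuffle case ids by ``seed`` and tag
    the first ceil(train_fraction * n_cases) as train, the rest as test."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    cases = manifest.case_ids()
    if len(cases) < 2:
        raise ValueError("need at least 2 cases to split")
    order = np.random.default_rng(seed).permutation(len(cases))
    n_train = math.ceil(train_fraction * len(cases))
    split = {}
    for rank, idx in enumerate(order):
        split[cases[idx]] = "train" if rank < n_train else "test"
    return DatasetManifest(entries=list(manifest.entries), split=split)
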